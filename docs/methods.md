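# Methods

## The motion model

A chromosomal locus near a double-strand break is modelled as a particle
performing Brownian motion with diffusion coefficient `D` (µm²/s) inside a
hard reflecting sphere of radius `R` (µm) — the confinement radius the
analysis is meant to recover. Per frame interval `Δt` an isotropic Gaussian
step with per-axis variance `2·D·Δt` is proposed; if the step leaves the
sphere, it is mirrored at the sphere surface: the exact exit point of the
step segment is found and the remainder of the step is reflected
specularly about the tangent plane there, iterating if the reflected
remainder crosses the surface again. The initial position is drawn from
the stationary distribution (uniform in the ball), so tracks are
stationary from frame 0.

A hard sphere was chosen over a harmonic tether deliberately: the
stationary distribution of reflected Brownian motion in a ball is exactly
uniform, each axis then has variance `R²/5`, and the closed-form radius
estimator below is *exact* for that geometry. This makes parameter
recovery a sharp test rather than a model-fit exercise.

The reflection scheme matters numerically. Radial mirroring (placing an
escaped point at distance `2R − r` along its own radius) has a stationary
bias that is first order in the step size — at the default `D = 2×10⁻³`
µm²/s and `Δt = 30` s the per-frame step is ~0.43·R and the per-axis
variance came out ~13% low. Specular reflection at the surface-crossing
point removes this: the measured variance is within 0.5% of `R²/5` at the
same step size, so no sub-stepping is needed.

Both the locus and the spindle-pole-body fiducial are displaced by one
shared Gaussian random-walk drift (`drift_sd` µm/frame/axis, default
0.05), emulating nuclear and stage motion; the fiducial is otherwise
fixed. Because the drift is shared bit-exactly, the channel difference
removes it identically — the simulated analogue of why the fiducial design
works.

## Defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| `confinement_radius` | 0.8 µm | centre of the 0.5–1.1 µm range typical of DSB loci |
| `diffusion_coeff` | 2×10⁻³ µm²/s | MSD approaches its plateau within the 20-min lapse |
| `frame_interval`, `n_frames` | 30 s, 41 | one volume every 30 s for 20 min, t = 0 included |
| `n_slices`, `z_step` | 15, 300 nm | 15 optical slices of 0.3 µm |
| `pixel_size` | 160 nm | 16 µm EMCCD pixel behind a 100× objective |
| `psf_sigma_xy`, `psf_sigma_z` | 1.3 px, 1.5 slices | diffraction-limited spot at these samplings |
| noise: photons/read/background | 500 / 2 / 20 | comfortably above the SNR≈5 regime the detector is specified for |

Localization noise of the real tracker is unknown; the default adds none
to coordinate tables (`localization_sd = 0`) and lets the rendered-stack
path carry realistic photon statistics instead. All generators draw from
one seeded `numpy.random.Generator` per call; cohorts spawn one child
stream per cell. Identical seed and config reproduce outputs bit for bit.

## Fiducial correction and MSD

Per shared frame: `(focus − fiducial)` in pixel/slice units, converted to
µm (`pixel_size` laterally, `z_step` axially), then per-axis
mean-subtraction over retained frames. Cells with fewer than 80% of frames
shared between channels are excluded — an explicit inclusion rule chosen
here, since field practice varies; it is configurable
(`min_coverage`).

The per-cell MSD at lag `k·Δt` averages squared displacements over **all**
observed pairs `(i, i+k)` (overlapping time average); pairs spanning a
missing frame are simply absent, never interpolated. A non-overlapping
mode exists for sensitivity analysis. The ensemble curve is the unweighted
across-cell mean with SEM over cells (cells are the independent unit; a
single cell reports SEM 0).

MSD and Rc use the lateral (x, y) coordinates by default: the estimator
below is defined on the lateral axes, and axial localization is
several-fold worse than lateral in spinning-disk data. 3D MSD is available
via `dims=3` and is labelled as such in outputs.

## The radius-of-confinement estimator

For the mean-centred lateral positions:

- `σx²`, `σy²` — **unbiased** (n−1) variances, the convention of a normal
  fit to the position histogram; `σ² = (σx² + σy²)/2`.
- `Δx₀²`, `Δy₀²` — **population** (n) mean squared deviations;
  `Δr₀² = Δx₀² + Δy₀²`.
- `Rc = sqrt(5/4 · (2σ² + Δr₀²))`.

The two denominators are kept distinct on purpose and are pinned by tests
(the four-point hand example `(±1, 0)` µm gives `σ² = 2/3`, `Δr₀² = 1`,
`Rc = 1.7078` µm). σ² and Δr₀² estimate the same scatter up to the n/(n−1)
factor; the formula is implemented literally rather than simplified, so
results match what the defining expression yields at any n. For points
uniform in a 3D ball of radius R the estimator returns R (each lateral
axis contributes `R²/5`); for points uniform in a 2D disk it returns
`√(5/4)·R ≈ 1.118·R`. Degenerate tracks (all positions identical) return
`Rc = 0` with a flag. `Rc²` equals `5/4 ×` the 2D MSD plateau in the
long-track limit — the two summaries are consistent estimators of the same
geometry, which the suite verifies to 5%.

### Finite-sampling bias

A 41-frame, 30 s acquisition does not let the locus visit its whole
confinement volume, so the per-cell Rc underestimates R. Measured on
400-cell cohorts at `D = 2×10⁻³` µm²/s (the suite recomputes this curve at
smaller n): mean bias −3.0% at R = 0.6 µm, −5.0% at R = 0.8 µm, −8.3% at
R = 1.0 µm, with a per-cell CV of 7–10%. The bias grows with R because
mixing time scales as `R²/D`. Comparisons between conditions acquired with
the same geometry are unaffected in ordering, which is how such numbers
are used; absolute radii from short tracks should be read with this bias
in mind. Long tracks (≥2000 frames) recover R to well within 3%.

## Spot detection and linking

The detector is a documented, auditable stand-in for the unpublished
tracker used in this field's MATLAB pipelines: difference-of-Gaussians
band-pass (inner σ 1 px, outer 3 px; 1 and 3 slices axially), response
standardized per z-slice by a MAD-based robust noise scale, local maxima
above `threshold` (default 5) robust-sd, lateral non-maximum suppression
at `min_separation`, and intensity-weighted centroid refinement in a ±2 px
window. Per-slice standardization is needed because the filter's reflect
boundary inflates the noise variance of edge slices; a one-outer-scale
lateral margin is excluded for the same reason. Spots closer than
`min_separation` merge into one detection — resolving them is out of
scope. On rendered stacks at SNR ≥ 5 the lateral RMSE is < 0.1 px and the
axial RMSE < 0.5 slice.

Linking is greedy nearest-neighbour frame to frame with a displacement
gate and gaps up to `max_gap` frames; ties are broken by higher intensity,
then detection order, making results deterministic. No interpolation ever
fills a gap. With two spindle-pole bodies in view, the fiducial track
sharing the most frames with the focus track wins, ties broken by mean
proximity. A Kalman/LAP tracker was considered and rejected: at 30 s
sampling of a confined locus the assignment problem is nearly trivial and
the simple scheme is fully auditable.

## qPCR calculators

Replicate Cq values are averaged **before** differencing (aggregation at
the Cq level), then `ΔCq(digest−mock)` per site feeds the
fraction-resected equation exactly as written; the ADH1 control gene's ΔCq
enters the denominator ratio. Primer efficiencies are inputs (default 2.0,
the ideal); no standard-curve calibration is implemented. Estimates above
1 — possible with noisy Cq or an underestimated cut fraction `f` — are
returned raw with a QC flag, never clamped. The synthetic Cq generator is
the exact algebraic inverse of the estimator at zero noise, and the suite
verifies the round trip to 1e-12 across fractions 0.05–0.95 and f ∈ {0.5,
0.8, 1.0}. A fraction of 0 would require an infinite digest Cq; the
generator emits a 40-cycle ceiling with a flag.

The cutting fold change `2^−(ΔCt − ΔCt,0h)` is exact by construction. The
conversion from fold change to the `f` used in the resection equation is a
convention of this package (`f = 1 − fold_remaining` of intact template
relative to 0 h), exposed behind an explicit flag (`--f-from-cutting`)
because published practice does not specify one; `f` can equally be
supplied as a constant or per timepoint.

## Statistics

Pairwise contrasts use the classical pooled-variance Student t
(two-sided); Welch's form is behind a flag. Many-to-one comparisons
compute one-way ANOVA F plus Dunnett-adjusted p-values via the
equicorrelated multivariate-t distribution (scipy's quasi-Monte-Carlo
integration, seeded; the method string is recorded in every result row).
Raw p-values use the same pooled-error statistic the Dunnett procedure
adjusts, and adjusted p is floored at raw p so integration noise can never
invert their ordering. Under a simulated global null (3 groups of 10,
10⁴ replicates) the measured family-wise error is 0.052, consistent with
the nominal 0.05. Significance tiers: ns p ≥ 0.05, \* p < 0.05, \*\* p <
0.01, \*\*\* p < 0.001, applied to the adjusted p.

Day-paired cohorting restricts each contrast to acquisition days on which
both the condition and the reference were imaged; a condition with no
overlapping day is an error, not a silent drop. Viability pools colonies
across the plate triplicate (sum selective / sum permissive) with SEM
across per-plate ratios; normalization divides by a reference condition's
survival (e.g. nocodazole-treated wild type). No normality or
equal-variance diagnostics are run beyond warnings — the tests are applied
unconditionally, as is standard in this assay literature.

## What the synthetic data does and does not show

The generator reproduces the *geometry and statistics* of the assays:
confined motion with a shared-drift fiducial, diffraction-limited spots
under Poisson-Gaussian noise, Cq tables algebraically consistent with
chosen resection fractions, binomial colony counts. It omits photophysics
(blinking, bleaching), cell-to-cell variability in D and R beyond what the
user configures, chromatin viscoelasticity (real loci are subdiffusive at
short lags), segmentation (one cell per stack), and qPCR artefacts such as
efficiency drift or pipetting covariance. Passing tests therefore certify
the *computations* — estimator correctness, exact inversions, calibrated
error rates, determinism — not the biological fidelity of any particular
parameter value.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 5–50 cells, tracks of 41–3000
frames, 10⁵-point uniform samples, and 10⁴ null replicates for the FWER
check — sizes at which the targeted tolerances (1–5% for stochastic
recoveries, 1e-12 for algebraic identities) are comfortably resolved on a
single CPU in about a minute. Tolerances on stochastic assertions are set
from the Monte-Carlo error of the statistic at those sizes, never tuned to
an observed run. Ties in linking are deterministic by construction;
degenerate inputs (zero-variance tracks, zero fractions, missing
treatments) raise or flag rather than propagate NaN.
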