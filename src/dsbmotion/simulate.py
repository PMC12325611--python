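"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design end to end: a chromosomal locus
(Ddc2-GFP focus at an HO-induced double-strand break) confined inside the
nucleus, a spindle-pole-body (Spc42-mCherry) fiducial sharing the same
whole-nucleus drift, two-channel 3D stacks of both spots, restriction-digest
qPCR quantification-cycle tables, and colony counts from plating assays.

Motion model
------------
The locus performs reflected Brownian motion inside a hard sphere of radius
``confinement_radius``: per frame, an isotropic Gaussian step of per-axis
variance ``2*D*dt`` is proposed and, if it leaves the sphere, specularly
mirrored at its exact surface-crossing point (iterated until the step ends
inside). A hard reflecting
sphere is used rather than a harmonic tether because its stationary
distribution is exactly uniform in the ball, for which the closed-form
radius-of-confinement estimator is exact: per-axis variance R^2/5, so
Rc = sqrt(5/4 * (2*sigma^2 + dr0^2)) recovers R in the long-track limit.
That identity is the main test hook for parameter-recovery tests.

All generators draw from a single ``numpy.random.Generator`` seeded per
call; identical seed and config give bit-identical output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

#: Cq reported when a template is absent (complete digestion / cutting);
#: mirrors the cycle ceiling of a 40-cycle qPCR run.
CQ_CEILING = 40.0

QPCR_SITES = ("RS_0.7kb", "RS_5kb", "RS_10kb")
CONTROL_SITE = "control_ADH1"
HO_SITE = "HO_cut_site"


@dataclass
class GroundTruth:
    """Truth channel emitted alongside observations, for parameter-recovery tests."""

    confinement_radius: float | None = None  # um
    dsb_positions: np.ndarray | None = None  # (n_frames, 3) um, drift-free
    spb_positions: np.ndarray | None = None  # (n_frames, 3) um, drift-free
    drift: np.ndarray | None = None  # (n_frames, 3) um, shared random walk
    resection_fraction: dict | None = None  # {(site, timepoint): x}
    cut_fraction: dict | None = None  # {timepoint: f}
    extras: dict = field(default_factory=dict)


def _reflect_step(p0: np.ndarray, p1: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Mirror the step p0 -> p1 at the sphere surface until it ends inside.

    The segment's exit point through the sphere is found exactly and the
    remainder of the step is mirrored about the tangent plane there
    (specular reflection); multiple crossings within one step are iterated.
    This symmetrized scheme keeps the stationary distribution uniform in
    the ball to well below 1% even for per-frame steps of ~0.4 R, unlike
    radial mirroring whose bias is first order in the step size.
    """
    a0 = p0 - center
    a1 = p1 - center
    R2 = radius * radius
    for _ in range(16):
        if a1 @ a1 <= R2:
            return center + a1
        d = a1 - a0
        a = d @ d
        b = 2.0 * (a0 @ d)
        c = a0 @ a0 - R2
        disc = max(b * b - 4.0 * a * c, 0.0)
        t = min(max((-b + np.sqrt(disc)) / (2.0 * a), 0.0), 1.0)
        cross = a0 + t * d
        n = cross / np.linalg.norm(cross)
        rem = a1 - cross
        a0, a1 = cross, cross + rem - 2.0 * (rem @ n) * n
    return center + a1 / np.linalg.norm(a1) * radius  # pathological overshoot


def simulate_confined_track(
    cfg: SimulationConfig,
    center: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    rng: np.random.Generator | None = None,
    n_frames: int | None = None,
) -> np.ndarray:
    """Reflected Brownian motion inside a sphere.

    Returns an ``(n_frames, 3)`` array of positions in micrometres. The
    initial position is drawn uniformly from the ball (the stationary
    distribution), so the track is stationary from frame 0.
    """
    if cfg.confinement_radius <= 0:
        raise ValueError("confinement_radius must be positive")
    if cfg.diffusion_coeff < 0:
        raise ValueError("diffusion_coeff must be non-negative")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_frames if n_frames is None else int(n_frames)
    center = np.asarray(center, dtype=float)
    R = cfg.confinement_radius
    step_sd = np.sqrt(2.0 * cfg.diffusion_coeff * cfg.frame_interval)

    # uniform draw in the ball: direction * R * U^(1/3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    start = center + direction * R * rng.uniform() ** (1.0 / 3.0)

    out = np.empty((n, 3))
    out[0] = start
    if step_sd == 0.0:
        out[1:] = start
        # keep the stream position independent of D so D=0 stays comparable
        rng.normal(size=(n - 1, 3))
        return out
    steps = rng.normal(scale=step_sd, size=(n - 1, 3))
    pos = start
    for i in range(1, n):
        pos = _reflect_step(pos, pos + steps[i - 1], center, R)
        out[i] = pos
    return out


def simulate_cell(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """One cell: paired DSB and SPB observed tracks sharing nuclear drift.

    The confined DSB track and a fixed SPB position are both displaced by the
    same Gaussian random-walk drift (``drift_sd`` per frame per axis), so the
    channel difference cancels the drift exactly. Observed coordinates are
    emitted in pixel/slice units in the long-format track table used across
    the pipeline; optional localization noise (``cfg.localization_sd``, um)
    is added independently per channel.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_frames
    # place the confinement sphere at the volume centre
    center = np.array(
        [
            cfg.nx * cfg.pixel_size / 2000.0,
            cfg.ny * cfg.pixel_size / 2000.0,
            cfg.n_slices * cfg.z_step / 2000.0,
        ]
    )
    dsb = simulate_confined_track(cfg, center=center, rng=rng)
    spb = np.tile(center + np.asarray(cfg.spb_offset, dtype=float), (n, 1))

    drift = np.zeros((n, 3))
    if cfg.drift_sd > 0:
        drift[1:] = np.cumsum(rng.normal(scale=cfg.drift_sd, size=(n - 1, 3)), axis=0)

    truth = GroundTruth(
        confinement_radius=cfg.confinement_radius,
        dsb_positions=dsb.copy(),
        spb_positions=spb.copy(),
        drift=drift.copy(),
    )

    rows = []
    for channel, track in (("focus", dsb), ("fiducial", spb)):
        obs = track + drift
        if cfg.localization_sd > 0:
            obs = obs + rng.normal(scale=cfg.localization_sd, size=obs.shape)
        x_px = obs[:, 0] * 1000.0 / cfg.pixel_size
        y_px = obs[:, 1] * 1000.0 / cfg.pixel_size
        z_sl = obs[:, 2] * 1000.0 / cfg.z_step
        for f in range(n):
            rows.append(
                {
                    "cell_id": "cell_0",
                    "frame": f,
                    "t_s": f * cfg.frame_interval,
                    "channel": channel,
                    "x_px": x_px[f],
                    "y_px": y_px[f],
                    "z_slice": z_sl[f],
                    "intensity": 1.0,
                }
            )
    return pd.DataFrame(rows), truth


def simulate_cohort(
    cfg: SimulationConfig, condition: str = "WT", day_labels: list[str] | None = None
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """``n_cells`` independent cells under one condition.

    Each cell gets its own substream spawned from ``cfg.seed`` so cohorts are
    reproducible cell-by-cell. Day labels (for day-paired statistics) cycle
    through ``day_labels`` if given.
    """
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(cfg.n_cells)
    frames = []
    truths = []
    for i, stream in enumerate(streams):
        df, truth = simulate_cell(cfg, rng=stream)
        df = df.assign(cell_id=f"{condition}_cell_{i:03d}")
        if day_labels:
            df = df.assign(day=day_labels[i % len(day_labels)])
        frames.append(df)
        truths.append(truth)
    return pd.concat(frames, ignore_index=True), truths


def render_stack(
    tracks: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict]:
    """Render a two-channel image time series from a cell's track table.

    Axis order is ``(time, channel, z, y, x)`` with channel 0 = focus (GFP)
    and channel 1 = fiducial (mCherry); the order is recorded in the returned
    metadata dict. Each spot is a 3D Gaussian (sigma ``psf_sigma_xy`` px
    laterally, ``psf_sigma_z`` slices axially) scaled to ``photon_scale``
    peak photons on a ``background`` photon floor; Poisson photon noise and
    Gaussian read noise are applied when the noise model is non-zero.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_frames = int(tracks["frame"].max()) + 1
    channels = ("focus", "fiducial")
    stack = np.zeros((n_frames, 2, cfg.n_slices, cfg.ny, cfg.nx), dtype=np.float32)
    clipped = []

    zz = np.arange(cfg.n_slices, dtype=float)
    yy = np.arange(cfg.ny, dtype=float)
    xx = np.arange(cfg.nx, dtype=float)

    for ci, channel in enumerate(channels):
        sub = tracks[tracks["channel"] == channel]
        for _, row in sub.iterrows():
            f = int(row["frame"])
            x, y, z = float(row["x_px"]), float(row["y_px"]), float(row["z_slice"])
            inside = (0 <= x < cfg.nx) and (0 <= y < cfg.ny) and (0 <= z < cfg.n_slices)
            if not inside:
                warnings.warn(
                    f"spot at frame {f} channel {channel} outside rendered volume; clipped",
                    stacklevel=2,
                )
                clipped.append({"frame": f, "channel": channel})
            gz = np.exp(-0.5 * ((zz - z) / cfg.psf_sigma_z) ** 2)
            gy = np.exp(-0.5 * ((yy - y) / cfg.psf_sigma_xy) ** 2)
            gx = np.exp(-0.5 * ((xx - x) / cfg.psf_sigma_xy) ** 2)
            spot = cfg.noise.photon_scale * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
            stack[f, ci] += spot.astype(np.float32)

    stack += cfg.noise.background
    if cfg.noise.photon_scale > 0 and (cfg.noise.read_sd > 0 or cfg.noise.background > 0):
        stack = rng.poisson(stack).astype(np.float32)
        stack += rng.normal(scale=cfg.noise.read_sd, size=stack.shape).astype(np.float32)

    meta = {
        "axes": "TCZYX",
        "channels": list(channels),
        "pixel_size_nm": cfg.pixel_size,
        "z_step_nm": cfg.z_step,
        "frame_interval_s": cfg.frame_interval,
        "clipped_spots": clipped,
    }
    return stack, meta


def _delta_cq_for_fraction(x: float, f: float, e_rs: float) -> float:
    """Invert the resection-fraction equation for the restriction-site dCq.

    With the control-gene dCq at zero, x = 2/((E_RS**dCq + 1)*f) gives
    dCq = log(2/(x*f) - 1) / log(E_RS).
    """
    ratio = 2.0 / (x * f) - 1.0
    return float(np.log(ratio) / np.log(e_rs))


def simulate_qpcr(
    true_fraction_by_site_time: dict[tuple[str, float], float],
    f: float | dict[float, float],
    efficiencies: dict[str, float] | None = None,
    base_cq: float = 24.0,
    replicate_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    sample: str = "rep1",
    include_cutting: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Mock/digest Cq replicates consistent with chosen true resection fractions.

    For each (site, timepoint) the digest Cq is offset from the mock Cq by
    exactly the dCq that makes the resection-fraction equation return the
    requested true fraction at zero noise; the ADH1 control has zero expected
    dCq (no StyI dependence). ``f`` is the HO cut fraction, constant or per
    timepoint. A true fraction of 0 (no strand has passed the site) would
    need an infinite digest Cq; the digest Cq is set to ``CQ_CEILING`` and
    the row flagged. Gaussian noise of sd ``replicate_sd`` is added per
    replicate. When ``include_cutting`` is true, HO-cut-site rows implied by
    ``f`` are emitted so the fold-increase calculator can recover f.
    """
    rng = np.random.default_rng(seed)
    eff = dict(efficiencies or {})
    for site in QPCR_SITES:
        eff.setdefault(site, 2.0)
    eff.setdefault(CONTROL_SITE, 2.0)
    for site, e in eff.items():
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency for {site} must be in (1, 2], got {e}")

    timepoints = sorted({t for (_, t) in true_fraction_by_site_time})
    f_by_t = {t: (f[t] if isinstance(f, dict) else f) for t in timepoints}
    for t, ft in f_by_t.items():
        if not (0.0 < ft <= 1.0):
            raise ValueError(f"cut fraction f must be in (0, 1], got {ft} at t={t}")

    rows = []

    def emit(timepoint, site, treatment, mean_cq, flag=""):
        noise = rng.normal(scale=replicate_sd, size=n_reps) if replicate_sd > 0 else np.zeros(n_reps)
        for r in range(n_reps):
            rows.append(
                {
                    "sample": sample,
                    "timepoint_h": timepoint,
                    "site": site,
                    "treatment": treatment,
                    "replicate": r,
                    "cq": mean_cq + noise[r],
                    "flag": flag,
                }
            )

    for (site, t), x in sorted(true_fraction_by_site_time.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"true fraction must lie in [0, 1], got {x}")
        emit(t, site, "mock", base_cq)
        if x == 0.0:
            emit(t, site, "digest", CQ_CEILING, flag="complete_digestion")
        else:
            dcq = _delta_cq_for_fraction(x, f_by_t[t], eff[site])
            emit(t, site, "digest", base_cq + dcq)

    for t in timepoints:
        emit(t, CONTROL_SITE, "mock", base_cq)
        emit(t, CONTROL_SITE, "digest", base_cq)

    if include_cutting:
        for t in timepoints:
            intact = 1.0 - f_by_t[t] if t > min(timepoints) else 1.0
            if intact <= 0.0:
                emit(t, HO_SITE, "none", CQ_CEILING, flag="complete_cutting")
            else:
                emit(t, HO_SITE, "none", base_cq - np.log2(intact))
            emit(t, CONTROL_SITE, "none", base_cq)

    truth = GroundTruth(
        resection_fraction=dict(true_fraction_by_site_time),
        cut_fraction=dict(f_by_t),
    )
    return pd.DataFrame(rows), truth


def simulate_colonies(
    true_viability: float,
    n_plated: int = 100,
    n_plates: int = 3,
    seed: int = 0,
    condition: str = "WT",
) -> pd.DataFrame:
    """Binomial colony counts for paired selective/permissive plates.

    Every plated cell forms a colony on the permissive (YPD) plate; on the
    selective (galactose) plate each survives repair with probability
    ``true_viability``.
    """
    if not (0.0 <= true_viability <= 1.0):
        raise ValueError("viability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_plates):
        permissive = int(n_plated)
        selective = int(rng.binomial(permissive, true_viability))
        rows.append(
            {
                "condition": condition,
                "plate": p,
                "permissive_count": permissive,
                "selective_count": selective,
            }
        )
    return pd.DataFrame(rows)
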