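"""MSD and radius-of-confinement analysis of fiducial-corrected tracks.

The processing chain mirrors the standard workflow for chromosomal-locus
mobility in yeast: convert pixels/slices to micrometres, subtract the
spindle-pole-body fiducial from the focus coordinates frame by frame to
cancel whole-cell and nuclear motion, subtract the mean corrected position,
then compute the per-cell time-averaged MSD at 30 s lag multiples and the
closed-form radius of confinement

    Rc = sqrt( 5/4 * (2*sigma^2 + dr0^2) )

where ``sigma^2`` is the mean of the per-axis normal-fit variances
(unbiased, n-1 denominator, the ``normfit`` convention) of the
mean-centred x and y positions, and ``dr0^2 = dx0^2 + dy0^2`` is the
average squared deviation from the mean position (population, n
denominator). For positions uniform in a ball of radius R, each axis has
variance R^2/5, so sigma^2 = R^2/5 and dr0^2 = 2R^2/5 give Rc = R exactly:
the estimator reads off the radius of the explored sphere.

MSD and Rc use the lateral (x, y) coordinates by default; the formula above
names only the lateral axes even though acquisition is 3D, and the axial
localization is several-fold worse than lateral. Full 3D displacements are
available behind ``dims=3`` for sensitivity analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import PairedTracks


@dataclass
class RelativeTrack:
    """Focus-minus-fiducial coordinates in um, mean-centred per axis."""

    cell_id: str
    frames: np.ndarray  # int frame indices, strictly increasing
    t_s: np.ndarray  # seconds
    xyz: np.ndarray  # (n, 3) um; each retained axis has zero mean
    pixel_size_nm: float
    z_step_nm: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")


@dataclass
class MSDCurve:
    cell_id: str
    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray


@dataclass
class EnsembleMSD:
    lags_s: np.ndarray
    mean_msd_um2: np.ndarray
    sem_um2: np.ndarray
    n_cells: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": self.lags_s,
                "mean_msd_um2": self.mean_msd_um2,
                "sem_um2": self.sem_um2,
                "n_cells": self.n_cells,
            }
        )


@dataclass
class ConfinementResult:
    cell_id: str
    sigma2_um2: float  # mean of per-axis normal-fit variances (n-1)
    dr0_2_um2: float  # dx0^2 + dy0^2, population mean squared deviation (n)
    rc_um: float
    n_frames: int
    degenerate: bool = False  # all positions identical


def correct_coordinates(
    paired: PairedTracks,
    pixel_size_nm: float,
    z_step_nm: float,
    frame_interval_s: float = 30.0,
) -> RelativeTrack:
    """Fiducial subtraction, unit conversion, and mean-centering.

    Per shared frame: (focus - fiducial) in pixel/slice units, converted to
    micrometres with ``pixel_size_nm`` laterally and ``z_step_nm`` axially,
    then the per-axis mean over retained frames is subtracted. Any motion
    common to both channels (stage drift, nuclear translation) cancels in
    the subtraction, which is the entire point of the fiducial design.
    """
    if pixel_size_nm <= 0 or z_step_nm <= 0:
        raise ValueError("pixel_size_nm and z_step_nm must be positive")
    if len(paired.frames) < 2:
        raise ValueError(f"cell {paired.cell_id} rejected: fewer than 2 shared frames")
    diff = paired.focus - paired.fiducial
    xyz = np.empty_like(diff, dtype=float)
    xyz[:, 0] = diff[:, 0] * pixel_size_nm / 1000.0
    xyz[:, 1] = diff[:, 1] * pixel_size_nm / 1000.0
    xyz[:, 2] = diff[:, 2] * z_step_nm / 1000.0
    xyz -= xyz.mean(axis=0, keepdims=True)
    return RelativeTrack(
        cell_id=paired.cell_id,
        frames=np.asarray(paired.frames, dtype=int),
        t_s=np.asarray(paired.frames, dtype=float) * frame_interval_s,
        xyz=xyz,
        pixel_size_nm=pixel_size_nm,
        z_step_nm=z_step_nm,
    )


def relative_track_from_arrays(
    focus_um: np.ndarray,
    fiducial_um: np.ndarray,
    frame_interval_s: float = 30.0,
    cell_id: str = "cell_0",
    frames: np.ndarray | None = None,
) -> RelativeTrack:
    """Build a RelativeTrack from coordinates already in micrometres."""
    focus_um = np.atleast_2d(np.asarray(focus_um, dtype=float))
    fiducial_um = np.atleast_2d(np.asarray(fiducial_um, dtype=float))
    if focus_um.shape != fiducial_um.shape:
        raise ValueError("focus and fiducial arrays must have the same shape")
    if focus_um.shape[1] == 2:  # pad z for purely lateral input
        focus_um = np.column_stack([focus_um, np.zeros(len(focus_um))])
        fiducial_um = np.column_stack([fiducial_um, np.zeros(len(fiducial_um))])
    n = len(focus_um)
    if frames is None:
        frames = np.arange(n)
    xyz = focus_um - fiducial_um
    xyz = xyz - xyz.mean(axis=0, keepdims=True)
    return RelativeTrack(
        cell_id=cell_id,
        frames=np.asarray(frames, dtype=int),
        t_s=np.asarray(frames, dtype=float) * frame_interval_s,
        xyz=xyz,
        pixel_size_nm=np.nan,
        z_step_nm=np.nan,
    )


def compute_msd(
    track: RelativeTrack,
    max_lag_frames: int | None = None,
    dims: int = 2,
    overlapping: bool = True,
) -> MSDCurve:
    """Time-averaged MSD at multiples of the frame interval.

    For lag k, averages the squared displacement over every observed frame
    pair (i, i+k); pairs spanning gaps (missing frames) simply do not exist
    in the observed set and are therefore excluded. ``overlapping=False``
    restricts to non-overlapping windows (i = 0, k, 2k, ...) for
    sensitivity analysis; the default overlapping estimator uses all pairs.
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    frames = track.frames
    if len(frames) < 2:
        raise ValueError("track must have at least 2 frames")
    coords = track.xyz[:, :dims]
    span = int(frames[-1] - frames[0])
    if max_lag_frames is None:
        max_lag = span
    else:
        max_lag = int(max_lag_frames)
        if max_lag > span:
            warnings.warn(
                f"max_lag_frames={max_lag} exceeds track span {span}; curve truncated",
                stacklevel=2,
            )
            max_lag = span
    dt = float(np.median(np.diff(track.t_s) / np.diff(frames)))

    # place observed coordinates on the full frame grid; gaps stay NaN so
    # any pair spanning a missing frame endpoint drops out automatically
    full = np.full((span + 1, dims), np.nan)
    full[frames - frames[0]] = coords

    lags, msds, npairs = [], [], []
    for k in range(1, max_lag + 1):
        d = full[k:] - full[:-k]
        if not overlapping:
            d = d[::k]
        sq = np.einsum("ij,ij->i", d, d)
        valid = ~np.isnan(sq)
        if valid.any():
            lags.append(k * dt)
            msds.append(float(sq[valid].mean()))
            npairs.append(int(valid.sum()))
    return MSDCurve(
        cell_id=track.cell_id,
        lags_s=np.array(lags),
        msd_um2=np.array(msds),
        n_pairs=np.array(npairs, dtype=int),
    )


def ensemble_msd(curves: list[MSDCurve]) -> EnsembleMSD:
    """Across-cell mean and SEM of per-cell MSD curves, per lag.

    The SEM is over cells (sd across cells / sqrt(n_cells)), not over frame
    pairs: cells, not displacement pairs, are the independent replicates.
    With a single contributing cell the SEM is reported as 0.
    """
    if not curves:
        raise ValueError("ensemble_msd requires at least one curve")
    all_lags = np.unique(np.concatenate([c.lags_s for c in curves]))
    mean, sem, n = [], [], []
    for lag in all_lags:
        vals = [
            float(c.msd_um2[np.argmin(np.abs(c.lags_s - lag))])
            for c in curves
            if np.any(np.isclose(c.lags_s, lag))
        ]
        mean.append(float(np.mean(vals)))
        sem.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0)
        n.append(len(vals))
    return EnsembleMSD(
        lags_s=all_lags,
        mean_msd_um2=np.array(mean),
        sem_um2=np.array(sem),
        n_cells=np.array(n, dtype=int),
    )


def radius_of_confinement(track: RelativeTrack) -> ConfinementResult:
    """Closed-form radius of confinement from the lateral position scatter.

    sigma_x^2, sigma_y^2: unbiased (n-1) variances of the mean-centred x and
    y; sigma^2 is their mean. dx0^2, dy0^2: population (n) mean squared
    deviations; dr0^2 their sum. Rc = sqrt(5/4 * (2*sigma^2 + dr0^2)).
    A track with all positions identical yields Rc = 0 flagged degenerate.
    """
    n = len(track.frames)
    if n < 3:
        raise ValueError("radius_of_confinement requires at least 3 frames")
    x = track.xyz[:, 0] - track.xyz[:, 0].mean()
    y = track.xyz[:, 1] - track.xyz[:, 1].mean()
    sigma2 = float((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    dr0_2 = float(np.mean(x**2) + np.mean(y**2))
    rc = float(np.sqrt(1.25 * (2.0 * sigma2 + dr0_2)))
    return ConfinementResult(
        cell_id=track.cell_id,
        sigma2_um2=sigma2,
        dr0_2_um2=dr0_2,
        rc_um=rc,
        n_frames=n,
        degenerate=(sigma2 == 0.0 and dr0_2 == 0.0),
    )


@dataclass
class ConditionResult:
    condition: str
    per_cell: pd.DataFrame  # cell_id, n_frames, sigma2_um2, dr0_2_um2, rc_um
    ensemble: EnsembleMSD
    rejected: dict[str, str]  # cell_id -> reason

    @property
    def mean_rc(self) -> float:
        return float(self.per_cell["rc_um"].mean())

    @property
    def sem_rc(self) -> float:
        v = self.per_cell["rc_um"]
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0


def analyze_condition(
    tracks: list[RelativeTrack],
    condition: str = "condition",
    dims: int = 2,
    max_lag_frames: int | None = None,
    min_cells: int = 10,
) -> ConditionResult:
    """Per-cell MSD + Rc and the ensemble summary for one condition.

    Warns when fewer than ``min_cells`` cells survive (the conventional
    floor for across-day Rc comparisons is 10 cells); raises if none do,
    listing every rejection reason.
    """
    curves, rows, rejected = [], [], {}
    for tr in tracks:
        try:
            curve = compute_msd(tr, max_lag_frames=max_lag_frames, dims=dims)
            conf = radius_of_confinement(tr)
        except ValueError as exc:
            rejected[tr.cell_id] = str(exc)
            continue
        curves.append(curve)
        rows.append(
            {
                "condition": condition,
                "cell_id": tr.cell_id,
                "n_frames": conf.n_frames,
                "sigma2_um2": conf.sigma2_um2,
                "dr0_2_um2": conf.dr0_2_um2,
                "rc_um": conf.rc_um,
            }
        )
    if not rows:
        raise ValueError(f"no accepted cells for {condition}; rejections: {rejected}")
    if len(rows) < min_cells:
        warnings.warn(
            f"{condition}: only {len(rows)} cells (< {min_cells}); "
            "Rc comparisons are conventionally based on at least 10",
            stacklevel=2,
        )
    return ConditionResult(
        condition=condition,
        per_cell=pd.DataFrame(rows),
        ensemble=ensemble_msd(curves),
        rejected=rejected,
    )
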