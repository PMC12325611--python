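"""Spot detection and track linking for two-channel 3D time lapses.

The detector is deliberately simple and auditable: a difference-of-Gaussians
band-pass isolates diffraction-limited spots, candidates above a robust
noise threshold are taken at local maxima, and each is refined to subpixel /
subslice precision by an intensity-weighted centroid in a fixed window.
Linking is greedy nearest-neighbour frame to frame with a displacement gate
and bounded gaps; missing frames stay missing (no interpolation), so the
downstream MSD only ever sees observed positions. The interface accepts any
detector producing ``SpotDetection`` rows, leaving room for e.g. a Gaussian
MLE fitter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

CHANNELS = ("focus", "fiducial")


@dataclass(frozen=True)
class DetectionParams:
    sigma_small: float = 1.0  # px, DoG inner scale
    sigma_large: float = 3.0  # px, DoG outer scale
    sigma_small_z: float = 1.0  # slices
    sigma_large_z: float = 3.0  # slices
    threshold: float = 5.0  # in robust-noise (MAD) units of the filtered volume
    min_separation: float = 3.0  # px; closer maxima merge into one detection
    centroid_window: int = 2  # half-width of centroid refinement window, px
    saturation_level: float | None = None  # counts; detections at/above are flagged


@dataclass
class SpotDetection:
    frame: int
    channel: str
    x: float  # px
    y: float  # px
    z: float  # slices
    intensity: float
    quality: float
    saturated: bool = False


@dataclass
class SpotTrack:
    """One particle followed through a time lapse; at most one detection per frame."""

    cell_id: str
    channel: str
    detections: list[SpotDetection] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([[d.x, d.y, d.z] for d in self.detections], dtype=float)

    def coverage(self, n_frames: int) -> float:
        return len(self.detections) / n_frames if n_frames else 0.0

    def __len__(self) -> int:
        return len(self.detections)


def _robust_sd(volume: np.ndarray) -> float:
    """MAD-based noise scale, insensitive to the few bright spot voxels."""
    med = np.median(volume)
    return float(1.4826 * np.median(np.abs(volume - med)))


def detect_spots(
    stack: np.ndarray, channel: str, params: DetectionParams | None = None
) -> list[SpotDetection]:
    """Detect spots in every frame of one channel of a (T, C, Z, Y, X) stack.

    Returns detections sorted by descending quality within each frame; an
    empty frame simply contributes no detections.
    """
    params = params or DetectionParams()
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    ci = CHANNELS.index(channel)
    out: list[SpotDetection] = []
    n_frames = stack.shape[0]
    for f in range(n_frames):
        vol = stack[f, ci].astype(float)
        out.extend(_detect_in_volume(vol, f, channel, params))
    return out


def _detect_in_volume(
    vol: np.ndarray, frame: int, channel: str, p: DetectionParams
) -> list[SpotDetection]:
    lo = ndimage.gaussian_filter(vol, (p.sigma_small_z, p.sigma_small, p.sigma_small))
    hi = ndimage.gaussian_filter(vol, (p.sigma_large_z, p.sigma_large, p.sigma_large))
    dog = lo - hi
    # standardize per z-slice: the filter's reflect boundary inflates the
    # noise variance near the first/last slices, so a single global scale
    # over-detects there
    noise = np.array([max(_robust_sd(sl), 1e-12) for sl in dog])
    resp = dog / noise[:, None, None]
    size = max(3, int(round(2 * p.min_separation + 1)))
    maxf = ndimage.maximum_filter(resp, size=(3, size, size), mode="nearest")
    candidate = (resp == maxf) & (resp > p.threshold)
    # filter-boundary artifacts inflate the DoG variance at the volume edge;
    # exclude a one-outer-scale margin (spots that close to the edge cannot
    # be centroided reliably anyway)
    m = int(np.ceil(p.sigma_large))
    if candidate.shape[1] > 2 * m and candidate.shape[2] > 2 * m:
        candidate[:, :m, :] = candidate[:, -m:, :] = False
        candidate[:, :, :m] = candidate[:, :, -m:] = False
    peaks = np.argwhere(candidate)
    if peaks.size == 0:
        return []

    # suppress peaks closer than min_separation laterally, keeping the brighter
    order = np.argsort(-resp[tuple(peaks.T)])
    peaks = peaks[order]
    kept: list[np.ndarray] = []
    for pk in peaks:
        if all(np.hypot(pk[1] - q[1], pk[2] - q[2]) >= p.min_separation for q in kept):
            kept.append(pk)

    dets = []
    w = p.centroid_window
    nz, ny, nx = vol.shape
    for pk in kept:
        z0, y0, x0 = (int(v) for v in pk)
        zs = slice(max(0, z0 - w), min(nz, z0 + w + 1))
        ys = slice(max(0, y0 - w), min(ny, y0 + w + 1))
        xs = slice(max(0, x0 - w), min(nx, x0 + w + 1))
        win = vol[zs, ys, xs] - vol[zs, ys, xs].min()
        total = win.sum()
        if total <= 0:
            zc, yc, xc = float(z0), float(y0), float(x0)
        else:
            grid = np.mgrid[zs, ys, xs]
            zc = float((grid[0] * win).sum() / total)
            yc = float((grid[1] * win).sum() / total)
            xc = float((grid[2] * win).sum() / total)
        peak_val = float(vol[z0, y0, x0])
        saturated = p.saturation_level is not None and peak_val >= p.saturation_level
        quality = float(resp[z0, y0, x0])
        if saturated:
            quality = -abs(quality)  # flagged: saturated centroids are biased
        dets.append(
            SpotDetection(
                frame=frame,
                channel=channel,
                x=xc,
                y=yc,
                z=zc,
                intensity=peak_val,
                quality=quality,
                saturated=saturated,
            )
        )
    dets.sort(key=lambda d: -d.quality)
    return dets


def link_tracks(
    detections: list[SpotDetection],
    max_displacement: float = 6.0,
    max_gap: int = 2,
    cell_id: str = "cell_0",
) -> list[SpotTrack]:
    """Greedy nearest-neighbour linking of one channel's detections.

    Frame-to-frame assignments beyond ``max_displacement`` (lateral pixels,
    with z in slice units folded in) are rejected; a track survives up to
    ``max_gap`` consecutive empty frames and is then closed. Ties at equal
    distance are broken by higher intensity, then by detection order, so the
    result is deterministic.
    """
    if not detections:
        return []
    channel = detections[0].channel
    by_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    frames = sorted(by_frame)

    tracks: list[list[SpotDetection]] = []
    open_tracks: list[list[SpotDetection]] = []
    for f in frames:
        candidates = list(by_frame[f])
        # close tracks whose last detection is too old
        still_open = []
        for tr in open_tracks:
            if f - tr[-1].frame > max_gap + 1:
                tracks.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        assigned: set[int] = set()
        for tr in sorted(open_tracks, key=lambda t: -t[-1].quality):
            last = tr[-1]
            best = None
            best_key = None
            for i, d in enumerate(candidates):
                if i in assigned:
                    continue
                dist = float(np.sqrt((d.x - last.x) ** 2 + (d.y - last.y) ** 2 + (d.z - last.z) ** 2))
                if dist > max_displacement:
                    continue
                key = (dist, -d.intensity, i)
                if best_key is None or key < best_key:
                    best, best_key = i, key
            if best is not None:
                assigned.add(best)
                tr.append(candidates[best])
        for i, d in enumerate(candidates):
            if i not in assigned:
                open_tracks.append([d])
    tracks.extend(open_tracks)

    out = [SpotTrack(cell_id=cell_id, channel=channel, detections=tr) for tr in tracks if tr]
    out.sort(key=lambda t: (-len(t), t.detections[0].frame))
    return out


@dataclass
class PairedTracks:
    """Focus and fiducial observations restricted to their shared frames."""

    cell_id: str
    frames: np.ndarray  # shared frame indices
    focus: np.ndarray  # (n, 3) px/px/slice
    fiducial: np.ndarray  # (n, 3)


def pair_channels(
    focus_tracks: list[SpotTrack],
    fiducial_tracks: list[SpotTrack],
    n_frames: int,
    min_coverage: float = 0.8,
) -> PairedTracks:
    """Pair the focus track with the best fiducial track.

    With two spindle-pole bodies in view there are two fiducial tracks; the
    one sharing the most frames with the focus track wins, ties broken by
    mean proximity to the focus. Only frames present in both tracks are
    kept. Cells whose shared-frame coverage falls below ``min_coverage`` of
    ``n_frames`` are rejected (raises ``ValueError`` naming the reason) —
    they carry too little of the time lapse for a trustworthy MSD.
    """
    if not focus_tracks:
        raise ValueError("no focus track detected")
    if not fiducial_tracks:
        raise ValueError("no fiducial track detected")
    focus = max(focus_tracks, key=len)
    f_frames = {d.frame: d for d in focus.detections}

    def shared(tr: SpotTrack) -> list[int]:
        return [d.frame for d in tr.detections if d.frame in f_frames]

    def mean_dist(tr: SpotTrack) -> float:
        ds = []
        for d in tr.detections:
            if d.frame in f_frames:
                fd = f_frames[d.frame]
                ds.append(np.sqrt((d.x - fd.x) ** 2 + (d.y - fd.y) ** 2 + (d.z - fd.z) ** 2))
        return float(np.mean(ds)) if ds else np.inf

    best = max(fiducial_tracks, key=lambda tr: (len(shared(tr)), -mean_dist(tr)))
    frames = sorted(shared(best))
    coverage = len(frames) / n_frames
    if coverage < min_coverage:
        raise ValueError(
            f"cell {focus.cell_id} excluded: paired coverage {coverage:.2f} "
            f"below minimum {min_coverage:.2f}"
        )
    b_frames = {d.frame: d for d in best.detections}
    foc = np.array([[f_frames[f].x, f_frames[f].y, f_frames[f].z] for f in frames])
    fid = np.array([[b_frames[f].x, b_frames[f].y, b_frames[f].z] for f in frames])
    return PairedTracks(cell_id=focus.cell_id, frames=np.array(frames), focus=foc, fiducial=fid)


def detections_to_frame(detections: list[SpotDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": d.frame,
                "channel": d.channel,
                "x": d.x,
                "y": d.y,
                "z": d.z,
                "intensity": d.intensity,
                "quality": d.quality,
            }
            for d in detections
        ]
    )
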