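"""Readers and writers for the pipeline's interchange formats.

CSV is the interchange format between stages (human-auditable, diffable);
TIFF appears only at the imaging boundary. Track tables are validated
against a strict schema with line-numbered errors so malformed input fails
loudly before any analysis runs.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

TRACK_COLUMNS = ["cell_id", "frame", "t_s", "channel", "x_px", "y_px", "z_slice", "intensity"]
_TRACK_DTYPES = {
    "frame": int,
    "t_s": float,
    "x_px": float,
    "y_px": float,
    "z_slice": float,
    "intensity": float,
}
CQ_COLUMNS = ["sample", "timepoint_h", "site", "treatment", "replicate", "cq"]

AXES = "TCZYX"


def write_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    extra = [c for c in tracks.columns if c not in TRACK_COLUMNS and c != "day"]
    cols = TRACK_COLUMNS + (["day"] if "day" in tracks.columns else []) + extra
    tracks[cols].to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col, dtype in _TRACK_DTYPES.items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"  # +2: header and 1-based
            raise ValueError(f"{path}: line {row}, column {col!r}: {exc}") from exc
    bad_channel = ~df["channel"].isin(["focus", "fiducial"])
    if bad_channel.any():
        row = int(df.index[bad_channel][0]) + 2
        raise ValueError(f"{path}: line {row}: channel must be 'focus' or 'fiducial'")
    return df


def write_cq_csv(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    table.to_csv(path, index=False)


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if (df["cq"] <= 0).any():
        row = int(df.index[df["cq"] <= 0][0]) + 2
        raise ValueError(f"{path}: line {row}: cq must be positive")
    return df


def write_stack(stack: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Write a (T, C, Z, Y, X) stack as an ImageJ-style multi-dim TIFF."""
    if stack.ndim != 5:
        raise ValueError(f"expected a 5D (T, C, Z, Y, X) stack, got ndim={stack.ndim}")
    desc = json.dumps({"axes": AXES, **(meta or {})}, default=str)
    tifffile.imwrite(path, stack.astype(np.float32), metadata={"axes": AXES}, description=desc)


def read_stack(path: str | Path, axes: str | None = None) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack into (T, C, Z, Y, X) order.

    Axis order is taken from the TIFF series metadata; pass ``axes`` to
    override (e.g. ``"TZCYX"`` for stacks from other software). Ambiguous
    files without an override are an error rather than a guess.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            if not tf.series:
                raise ValueError(f"{path}: unreadable TIFF (no image series found)")
            series = tf.series[0]
            data = series.asarray()
            file_axes = series.axes
            desc = tf.pages[0].description
    except (tifffile.TiffFileError, OSError, IndexError) as exc:
        raise ValueError(f"{path}: unreadable TIFF ({exc})") from exc
    order = axes or file_axes
    order = order.replace("S", "C").replace("Q", "")
    if len(order) != data.ndim or set(order) - set(AXES):
        raise ValueError(
            f"{path}: cannot map axes {order!r} onto {AXES}; pass axes= to override"
        )
    # insert missing singleton axes, then permute into TCZYX
    for ax in AXES:
        if ax not in order:
            data = data[np.newaxis]
            order = ax + order
    data = np.transpose(data, [order.index(ax) for ax in AXES])
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return data, meta


def write_ground_truth(truths: list, path: str | Path) -> None:
    """JSON sidecar with the generator's truth channel."""

    def enc(t):
        d = {}
        for key in ("confinement_radius", "resection_fraction", "cut_fraction"):
            v = getattr(t, key, None)
            if isinstance(v, dict):
                v = {str(k): val for k, val in v.items()}
            d[key] = v
        for key in ("dsb_positions", "spb_positions", "drift"):
            v = getattr(t, key, None)
            d[key] = v.tolist() if v is not None else None
        return d

    with open(path, "w") as fh:
        json.dump([enc(t) for t in truths], fh)
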