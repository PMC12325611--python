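"""End-to-end orchestration: simulate -> (track) -> msd -> rc -> compare.

Every run writes the fully resolved configuration, the seed, and a log into
the output directory, and is bit-identical under the same seed and config.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, SimulationConfig
from .io import write_tracks_csv, write_ground_truth
from .mobility import analyze_condition, relative_track_from_arrays
from .stats import anova_dunnett, comparisons_to_frame, t_test_two_sided

log = logging.getLogger("dsbmotion")


def tracks_table_to_relative(
    tracks: pd.DataFrame,
    pixel_size_nm: float,
    z_step_nm: float,
    frame_interval_s: float = 30.0,
) -> list:
    """Convert a long-format two-channel track table into RelativeTracks.

    Pairs focus and fiducial rows per cell on their shared frames, converts
    to micrometres, subtracts the fiducial and mean-centres — the table
    analogue of the image-based pairing step.
    """
    out = []
    for cell_id, sub in tracks.groupby("cell_id", sort=True):
        foc = sub[sub["channel"] == "focus"].set_index("frame").sort_index()
        fid = sub[sub["channel"] == "fiducial"].set_index("frame").sort_index()
        shared = foc.index.intersection(fid.index)
        if len(shared) < 2:
            log.warning("cell %s skipped: fewer than 2 shared frames", cell_id)
            continue
        focus_um = np.column_stack(
            [
                foc.loc[shared, "x_px"] * pixel_size_nm / 1000.0,
                foc.loc[shared, "y_px"] * pixel_size_nm / 1000.0,
                foc.loc[shared, "z_slice"] * z_step_nm / 1000.0,
            ]
        )
        fid_um = np.column_stack(
            [
                fid.loc[shared, "x_px"] * pixel_size_nm / 1000.0,
                fid.loc[shared, "y_px"] * pixel_size_nm / 1000.0,
                fid.loc[shared, "z_slice"] * z_step_nm / 1000.0,
            ]
        )
        out.append(
            relative_track_from_arrays(
                focus_um,
                fid_um,
                frame_interval_s=frame_interval_s,
                cell_id=str(cell_id),
                frames=np.asarray(shared, dtype=int),
            )
        )
    return out


def _plot_ensembles(results: dict, path: Path) -> None:
    """Ensemble MSD (mean +/- SEM over cells) per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, res in sorted(results.items()):
        ens = res.ensemble
        ax.errorbar(ens.lags_s, ens.mean_msd_um2, yerr=ens.sem_um2,
                    label=f"{name} (n={len(res.per_cell)})", capsize=2)
    ax.set_xlabel("lag time (s)")
    ax.set_ylabel(r"MSD ($\mu m^2$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages on a two-condition synthetic cohort.

    Writes per-condition track CSVs, per-cell Rc CSVs, the ensemble MSD
    CSV, the comparison table, the resolved config, and a provenance log.
    Raises on the first failing stage with a stage-scoped message.
    """
    from .simulate import simulate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    cfg_hash = hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config sha256 %s seed %d stages %s", cfg_hash, config.seed, config.stages)
        sim = config.simulation
        conditions = config.stats.get("conditions", {"WT": sim.confinement_radius})
        day_labels = config.stats.get("day_labels", ["day1", "day2"])
        mobility_kw = {
            "dims": int(config.mobility.get("dims", 2)),
            "max_lag_frames": config.mobility.get("max_lag"),
        }

        results = {}
        all_tracks = {}
        for i, (name, radius) in enumerate(sorted(conditions.items())):
            cond_cfg = SimulationConfig.from_dict(
                {**sim.to_dict(), "confinement_radius": float(radius),
                 "seed": sim.seed + 1000 * (i + 1)}
            )
            tracks, truths = simulate_cohort(cond_cfg, condition=name, day_labels=day_labels)
            write_tracks_csv(tracks, out / f"tracks_{name}.csv")
            write_ground_truth(truths, out / f"truth_{name}.json")
            all_tracks[name] = tracks
            rel = tracks_table_to_relative(
                tracks, cond_cfg.pixel_size, cond_cfg.z_step, cond_cfg.frame_interval
            )
            res = analyze_condition(rel, condition=name, **mobility_kw)
            res.per_cell.to_csv(out / f"rc_{name}.csv", index=False)
            res.ensemble.to_frame().to_csv(out / f"msd_{name}.csv", index=False)
            results[name] = res
            log.info("condition %s: %d cells, mean Rc %.3f um", name, len(res.per_cell), res.mean_rc)
        _plot_ensembles(results, out / "msd_ensemble.png")

        if "compare" in config.stages and len(results) >= 2:
            per_cell = pd.concat([r.per_cell for r in results.values()], ignore_index=True)
            reference = config.stats.get("reference", sorted(results)[0])
            names = sorted(results)
            if len(names) == 2:
                a, b = names
                other = b if a == reference else a
                comp = t_test_two_sided(
                    per_cell.loc[per_cell["condition"] == other, "rc_um"],
                    per_cell.loc[per_cell["condition"] == reference, "rc_um"],
                    contrast=f"{other} vs {reference}",
                )
                table = comparisons_to_frame([comp])
            else:
                _, _, comps = anova_dunnett(per_cell, reference=reference, seed=config.seed)
                table = comparisons_to_frame(comps)
            table.to_csv(out / "comparisons.csv", index=False)
            log.info("comparisons written: %s", table["contrast"].tolist())
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
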