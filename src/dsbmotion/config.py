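"""Declarative configuration objects shared across the pipeline.

All lengths are micrometres and all times seconds once inside the library;
pixel/slice units appear only at the imaging boundary (rendering, detection)
and are converted exactly once, using ``pixel_size_nm`` and ``z_step_nm``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class NoiseModel:
    """Camera/photon noise for rendered stacks.

    photon_scale: expected photon count at the spot peak (Poisson).
    read_sd: Gaussian read noise, camera counts.
    background: uniform background level, photons.
    """

    photon_scale: float = 500.0
    read_sd: float = 2.0
    background: float = 20.0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_sd < 0 or self.background < 0:
            raise ValueError("noise model parameters must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated acquisition.

    Geometry follows a spinning-disk time lapse of a yeast nucleus: 15
    optical slices at a 0.3 um z-step, one volume every 30 s for 20 min
    (41 frames including t=0). The locus moves as reflected Brownian
    motion inside a sphere of radius ``confinement_radius``; the whole
    nucleus additionally drifts as a Gaussian random walk shared by the
    locus and the spindle-pole-body fiducial.
    """

    confinement_radius: float = 0.8  # um; reported Rc values span ~0.5-1.1 um
    diffusion_coeff: float = 2e-3  # um^2/s
    frame_interval: float = 30.0  # s
    n_frames: int = 41  # 20 min at 30 s, t=0 included
    n_cells: int = 20
    drift_sd: float = 0.05  # um per frame, per axis
    spb_offset: tuple[float, float, float] = (0.9, 0.7, 0.3)  # um
    pixel_size: float = 160.0  # nm/px (16 um EMCCD pixel, 100x objective)
    z_step: float = 300.0  # nm
    n_slices: int = 15
    ny: int = 48  # rendered image height, px
    nx: int = 48  # rendered image width, px
    psf_sigma_xy: float = 1.3  # px, lateral Gaussian PSF sigma
    psf_sigma_z: float = 1.5  # slices, axial Gaussian PSF sigma
    noise: NoiseModel = field(default_factory=NoiseModel)
    localization_sd: float = 0.0  # um, optional noise on emitted coordinates
    seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "confinement_radius": self.confinement_radius,
            "frame_interval": self.frame_interval,
            "pixel_size": self.pixel_size,
            "z_step": self.z_step,
            "psf_sigma_xy": self.psf_sigma_xy,
            "psf_sigma_z": self.psf_sigma_z,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be non-negative")
        if self.drift_sd < 0 or self.localization_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.n_cells < 1 or self.n_slices < 1 or self.ny < 4 or self.nx < 4:
            raise ValueError("counts/image dimensions out of range")

    @property
    def times_s(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["spb_offset"] = list(self.spb_offset)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        if "spb_offset" in d:
            d["spb_offset"] = tuple(d["spb_offset"])
        return cls(**d)


_RUN_SECTIONS = {"simulation", "detection", "mobility", "resection", "stats", "seed", "stages"}


@dataclass
class RunConfig:
    """Top-level pipeline configuration (``run`` subcommand).

    Sections map one-to-one onto pipeline stages; unknown keys anywhere are
    rejected before any compute so a typo cannot silently fall back to a
    default. The resolved config is serialized into every output directory.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: dict[str, Any] = field(default_factory=dict)
    mobility: dict[str, Any] = field(default_factory=dict)
    resection: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: ["simulate", "msd", "rc", "compare"])
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - _RUN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        sim = SimulationConfig.from_dict(d.get("simulation", {}))
        return cls(
            simulation=sim,
            detection=dict(d.get("detection", {})),
            mobility=dict(d.get("mobility", {})),
            resection=dict(d.get("resection", {})),
            stats=dict(d.get("stats", {})),
            stages=list(d.get("stages", ["simulate", "msd", "rc", "compare"])),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": self.simulation.to_dict(),
            "detection": self.detection,
            "mobility": self.mobility,
            "resection": self.resection,
            "stats": self.stats,
            "stages": self.stages,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
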