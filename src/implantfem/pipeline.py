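"""End-to-end orchestration: configuration, the full run, and the manifest.

A single YAML-serializable ``RunConfig`` holds every knob of the virtual
implant-therapy simulation with defaults reproducing the study conditions
(50 N occlusal load at 45 degrees to the tooth axis, fixed inferior
border, 3 diameters x 4 lengths = 12 designs, 0.39 mm voxels).  A run is a
pure function of the config (all randomness flows from its seed), so the
manifest — config echo, versions, timings, outputs — suffices to re-run
bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .synthetic_ct import (
    MandiblePhantomParams,
    generate_mandible_volume,
    segment_roi,
    write_volume,
)
from .implant_geometry import (
    enumerate_design_grid,
    DEFAULT_DIAMETERS_MM,
    DEFAULT_LENGTHS_MM,
)
from .material_model import MaterialTable
from .stress_post import run_sweep, StressSummary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_all"]

DEFAULT_BONE_THRESHOLD_HU = 300.0
DEFAULT_TOOTH_THRESHOLD_HU = 10300.0


@dataclass
class RunConfig:
    """All parameters of a full virtual implant-therapy run."""

    phantom: MandiblePhantomParams = field(default_factory=MandiblePhantomParams)
    material: MaterialTable = field(default_factory=MaterialTable)
    bone_threshold_hu: float = DEFAULT_BONE_THRESHOLD_HU
    tooth_threshold_hu: float = DEFAULT_TOOTH_THRESHOLD_HU
    diameters_mm: list[float] = field(
        default_factory=lambda: list(DEFAULT_DIAMETERS_MM)
    )
    lengths_mm: list[float] = field(default_factory=lambda: list(DEFAULT_LENGTHS_MM))
    supracrestal_height_mm: float = 8.0
    crown_radius_mm: float = 3.0
    cusp_offset_mm: float = 2.0
    load_magnitude_n: float = 50.0
    load_angle_deg: float = 45.0
    tooth_id: int = 1
    solver_method: str = "auto"
    seed: int = 2021
    outdir: str = "results/run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"] = self.phantom.to_dict()
        d["material"] = self.material.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["phantom"] = MandiblePhantomParams.from_dict(d["phantom"])
        d["material"] = MaterialTable.from_dict(d["material"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def design_grid(self):
        return enumerate_design_grid(
            self.diameters_mm,
            self.lengths_mm,
            supracrestal_height_mm=self.supracrestal_height_mm,
            crown_radius_mm=self.crown_radius_mm,
            cusp_offset_mm=self.cusp_offset_mm,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Invariant violations as messages naming field and constraint; [] if valid."""
    v: list[str] = []
    p = config.phantom
    if min(p.extents) < 20:
        v.append("phantom.extents: each axis must be at least 20 voxels")
    if p.spacing <= 0:
        v.append("phantom.spacing: must be positive")
    if not (p.cortical_hu > p.trabecular_hu > 0):
        v.append("phantom HU means: need cortical > trabecular > 0")
    if p.cortical_thickness_mm < p.spacing:
        v.append("phantom.cortical_thickness_mm: must be at least one voxel")
    if not config.tooth_threshold_hu > config.bone_threshold_hu:
        v.append("tooth_threshold_hu: must exceed bone_threshold_hu")
    if not config.diameters_mm or not config.lengths_mm:
        v.append("design grid: diameter and length lists must be non-empty")
    if any(d <= 0 for d in config.diameters_mm):
        v.append("diameters_mm: must be positive")
    if any(l <= 0 for l in config.lengths_mm):
        v.append("lengths_mm: must be positive")
    if config.load_magnitude_n <= 0:
        v.append("load_magnitude_n: must be positive")
    if not (0.0 <= config.load_angle_deg < 90.0):
        v.append("load_angle_deg: must lie in [0, 90)")
    if config.supracrestal_height_mm <= 0:
        v.append("supracrestal_height_mm: must be positive")
    m = config.material
    for name in ("nu_bone", "nu_tooth", "nu_implant"):
        nu = getattr(m, name)
        if not (0.0 < nu < 0.5):
            v.append(f"material.{name}: must lie in the open interval (0, 0.5)")
    return v


def run_all(config: RunConfig, write_volumes: bool = False) -> dict:
    """Execute generate -> segment -> extract -> sweep; return the manifest.

    Writes ``summary.csv``, ``manifest.json`` and the config echo under
    ``config.outdir``.  Identical config (including seed) reproduces the
    summary CSV byte-for-byte.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(violations))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    phantom_params = MandiblePhantomParams.from_dict(config.phantom.to_dict())
    phantom_params.seed = config.seed

    t0 = time.perf_counter()
    volume = generate_mandible_volume(phantom_params)
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    segmented = segment_roi(
        volume, config.bone_threshold_hu, config.tooth_threshold_hu
    )
    timings["segment"] = time.perf_counter() - t0
    if write_volumes:
        write_volume(segmented, outdir / "phantom_segmented.nii.gz")

    t0 = time.perf_counter()
    summary = run_sweep(
        segmented,
        config.design_grid(),
        table=config.material,
        load_magnitude_n=config.load_magnitude_n,
        load_angle_deg=config.load_angle_deg,
        tooth_id=config.tooth_id,
        solver_method=config.solver_method,
    )
    timings["sweep"] = time.perf_counter() - t0

    summary_path = outdir / "summary.csv"
    summary.to_csv(summary_path)
    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)

    manifest = {
        "package_version": __version__,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "material_constants": {
            "e_implant_mpa": config.material.e_implant,
            "nu_implant": config.material.nu_implant,
            "e_tooth_mpa": config.material.e_tooth,
            "nu_tooth": config.material.nu_tooth,
            "nu_bone": config.material.nu_bone,
        },
        "n_configurations": int(len(summary.table)),
        "timings_s": {k: round(t, 3) for k, t in timings.items()},
        "outputs": {"summary": str(summary_path), "config": str(config_path)},
        "configurations": summary.table.drop(
            columns=["peak_element"]
        ).to_dict(orient="records"),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    manifest["_summary"] = summary
    return manifest
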