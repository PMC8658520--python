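"""Virtual tooth extraction and parametric implant placement.

The design sweep places one-piece implants — a smooth intrabony cylinder
with a hemispherical apex plus a supracrestal abutment/crown cylinder —
into a refilled extraction socket, at the buccolingual centre of the ridge,
axially aligned (+z).  Threads are deliberately omitted: the quantities of
interest (peri-implant stress level and its diameter/length trends) are
set by the gross load-bearing geometry, not thread micro-features.

The supracrestal solid is congruent with the extracted tooth crown
(same radius and height) for every design, so the lever arm of the
oblique occlusal load is identical across the sweep: differences between
designs are purely intrabony, mirroring the clinical situation where a
longer or wider implant carries the same prosthetic crown.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .synthetic_ct import (
    VoxelVolume,
    LABEL_BACKGROUND,
    LABEL_BONE,
    LABEL_TOOTH,
    LABEL_IMPLANT,
)

__all__ = [
    "ImplantSpec",
    "PlacementFrame",
    "virtual_extraction",
    "place_implant",
    "enumerate_design_grid",
    "DEFAULT_DIAMETERS_MM",
    "DEFAULT_LENGTHS_MM",
]

DEFAULT_DIAMETERS_MM = (3.8, 4.3, 6.0)
DEFAULT_LENGTHS_MM = (9.0, 11.0, 13.0, 16.0)


@dataclass(frozen=True)
class ImplantSpec:
    """One implant design of the sweep.

    ``diameter_mm`` and ``length_mm`` are the intrabony dimensions; the
    supracrestal height and the buccal cusp offset of the load target are
    held constant across every design in a sweep (the crown the implant
    carries does not change with the fixture).
    """

    diameter_mm: float
    length_mm: float
    supracrestal_height_mm: float = 8.0
    crown_radius_mm: float = 3.0
    cusp_offset_mm: float = 2.0  # buccal (-y) offset of the load target

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("implant diameter and length must be positive")
        if self.supracrestal_height_mm <= 0:
            raise ValueError("supracrestal height must be positive")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    def solid_volume_mm3(self) -> float:
        """Analytic volume of the placed solid (body + hemispherical apex + crown)."""
        r = self.radius_mm
        body = np.pi * r**2 * (self.length_mm - r) + (2.0 / 3.0) * np.pi * r**3
        crown = np.pi * self.crown_radius_mm**2 * self.supracrestal_height_mm
        return float(body + crown)

    def label(self) -> str:
        return f"d{self.diameter_mm:g}_l{self.length_mm:g}"


@dataclass(frozen=True)
class PlacementFrame:
    """Where and how an implant enters the ridge.

    ``entry_point_mm`` sits on the bone crest surface at the buccolingual
    centre of the socket; ``axis`` is the (unit) implant axis, +z for an
    axially aligned placement.
    """

    entry_point_mm: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    tooth_id: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-9):
            raise ValueError("placement axis must be a unit vector")


def tooth_components(volume: VoxelVolume) -> tuple[np.ndarray, int]:
    """Connected components of the tooth label (6-connectivity); ids 1..n."""
    comp, n = ndimage.label(volume.labels == LABEL_TOOTH)
    return comp, int(n)


def frame_for_tooth(volume: VoxelVolume, tooth_id: int = 1) -> PlacementFrame:
    """Placement frame centred on a tooth: entry at its (x, y) centroid on the crest."""
    comp, n = tooth_components(volume)
    if not (1 <= tooth_id <= n):
        raise ValueError(f"unknown tooth_id {tooth_id}; volume has {n} teeth")
    idx = np.argwhere(comp == tooth_id)
    h = volume.spacing
    cx = float((idx[:, 0].mean() + 0.5) * h) + volume.origin[0]
    cy = float((idx[:, 1].mean() + 0.5) * h) + volume.origin[1]
    crest = crest_height_mm(volume)
    return PlacementFrame(entry_point_mm=(cx, cy, crest), tooth_id=tooth_id)


def crest_height_mm(volume: VoxelVolume) -> float:
    """Height of the bone crest surface (top of the highest bone voxel), mm."""
    zidx = np.argwhere(volume.labels == LABEL_BONE)[:, 2]
    if zidx.size == 0:
        raise ValueError("volume contains no bone")
    return volume.origin[2] + float(zidx.max() + 1) * volume.spacing


def virtual_extraction(
    volume: VoxelVolume,
    tooth_id: int = 1,
    shell_mm: float = 2.0,
    trabecular_hu_ceiling: float = 6000.0,
) -> VoxelVolume:
    """Remove one tooth and refill its socket with bone.

    All voxels of the tooth are relabelled bone and their CT values set to
    the mean CT of trabecular bone voxels within ``shell_mm`` of the socket
    (trabecular meaning bone below ``trabecular_hu_ceiling`` HU, which
    excludes the cortical plates the socket punches through).  Falls back to
    all shell bone voxels if the trabecular restriction empties the shell.
    """
    comp, n = tooth_components(volume)
    if n == 0:
        raise ValueError("volume contains no teeth")
    if not (1 <= tooth_id <= n):
        raise ValueError(f"unknown tooth_id {tooth_id}; volume has {n} teeth")
    socket = comp == tooth_id

    out = volume.copy()
    shell_vox = max(1, int(np.ceil(shell_mm / volume.spacing)))
    dilated = ndimage.binary_dilation(socket, iterations=shell_vox)
    shell = dilated & ~socket & (volume.labels == LABEL_BONE)
    shell_ct = volume.ct_values[shell]
    trab = shell_ct[shell_ct < trabecular_hu_ceiling]
    fill = float(trab.mean() if trab.size else shell_ct.mean())
    out.ct_values[socket] = fill
    out.labels[socket] = LABEL_BONE
    return out


def implant_solid_mask(
    volume: VoxelVolume, spec: ImplantSpec, frame: PlacementFrame
) -> np.ndarray:
    """Boolean mask of voxel centres inside the implant solid (any label)."""
    X, Y, Z = volume.voxel_centers_mm()
    ex, ey, ez = frame.entry_point_mm
    r = spec.radius_mm
    apex = ez - spec.length_mm
    r2d = (X - ex) ** 2 + (Y - ey) ** 2
    body = (r2d <= r**2) & (Z >= apex + r) & (Z <= ez)
    cap = (r2d + (Z - (apex + r)) ** 2 <= r**2) & (Z < apex + r)
    crown = (
        (r2d <= spec.crown_radius_mm**2)
        & (Z > ez)
        & (Z <= ez + spec.supracrestal_height_mm)
    )
    return body | cap | crown


def place_implant(
    volume: VoxelVolume,
    spec: ImplantSpec,
    frame: PlacementFrame,
    min_apical_clearance_mm: float = 1.2,
) -> VoxelVolume:
    """Label the implant solid into a refilled (post-extraction) volume.

    Only bone-labelled voxels are claimed (the socket has been refilled, so
    the whole solid — including the supracrestal portion, which occupies the
    former crown — lands on bone); background is never consumed and CT
    values are untouched, making placement idempotent.

    Raises an invalid-placement error, naming the overshoot in mm, if the
    apex would enter the inferior cortical border (the lowest
    ``min_apical_clearance_mm`` of bone).
    """
    ex, ey, ez = frame.entry_point_mm
    h = volume.spacing
    bone_zidx = np.argwhere(volume.labels == LABEL_BONE)[:, 2]
    if bone_zidx.size == 0:
        raise ValueError("volume contains no bone")
    bone_floor = volume.origin[2] + float(bone_zidx.min()) * h
    apex = ez - spec.length_mm
    overshoot = (bone_floor + min_apical_clearance_mm) - apex
    if overshoot > 0:
        raise ValueError(
            f"invalid placement: implant apex enters the inferior cortical "
            f"border by {overshoot:.2f} mm (spec {spec.label()})"
        )
    # lateral fit: the cylinder must stay inside the bone footprint
    nx, ny, _ = volume.shape
    r = spec.radius_mm
    if (ex - r < volume.origin[0]) or (ex + r > volume.origin[0] + nx * h) or (
        ey - r < volume.origin[1]
    ) or (ey + r > volume.origin[1] + ny * h):
        raise ValueError(f"invalid placement: implant exits the bone laterally "
                         f"(spec {spec.label()})")

    mask = implant_solid_mask(volume, spec, frame)
    out = volume.copy()
    claim = mask & (out.labels == LABEL_BONE)
    out.labels[claim] = LABEL_IMPLANT
    return out


def enumerate_design_grid(
    diameters_mm=DEFAULT_DIAMETERS_MM,
    lengths_mm=DEFAULT_LENGTHS_MM,
    **spec_kwargs,
) -> list[ImplantSpec]:
    """Cartesian product of diameters x lengths, diameter-major order."""
    diameters_mm = list(diameters_mm)
    lengths_mm = list(lengths_mm)
    if not diameters_mm or not lengths_mm:
        raise ValueError("diameter and length factor lists must be non-empty")
    return [
        ImplantSpec(diameter_mm=d, length_mm=l, **spec_kwargs)
        for d, l in itertools.product(diameters_mm, lengths_mm)
    ]
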