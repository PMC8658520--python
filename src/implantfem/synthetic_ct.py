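"""Synthetic mandibular-segment CT volumes and volume I/O.

The phantom is a straight rectangular-section prism standing in for a
posterior mandibular segment: a dense cortical shell on the buccal, lingual,
inferior and crestal faces, a noisy lower-attenuation trabecular interior,
and one or more tooth cylinders rooted in the bone and protruding above the
crest.  The mesiodistal (x) faces are treated as cut planes and carry no
shell.  Axes: x mesiodistal, y buccolingual (+y lingual), z inferosuperior
(+z superior); voxel indices are 0-based and all physical coordinates are mm.

HU defaults are chosen so that, under the package's linear HU->density
calibration, cortical bone lands in the high-density power branch of the
bone constitutive law, trabecular bone in the low branch, and the
cortical/trabecular transition plus the trabecular upper tail populate the
linear middle branch — so a default phantom exercises the whole law.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelVolume",
    "ToothSpec",
    "MandiblePhantomParams",
    "generate_mandible_volume",
    "segment_roi",
    "read_volume",
    "write_volume",
    "LABEL_BACKGROUND",
    "LABEL_BONE",
    "LABEL_TOOTH",
    "LABEL_IMPLANT",
]

LABEL_BACKGROUND = 0
LABEL_BONE = 1
LABEL_TOOTH = 2
LABEL_IMPLANT = 3
LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_BONE: "bone",
    LABEL_TOOTH: "tooth",
    LABEL_IMPLANT: "implant",
}


@dataclass
class VoxelVolume:
    """A CT-number grid with voxel spacing and a region label map.

    ``ct_values`` holds Hounsfield units, ``labels`` region codes
    (background/bone/tooth/implant).  Both arrays are indexed [x, y, z].
    ``spacing`` is the isotropic voxel edge length in mm and ``origin`` the
    position of the (0,0,0) voxel corner in mm.
    """

    ct_values: np.ndarray
    spacing: float = 0.39
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ct_values = np.asarray(self.ct_values, dtype=np.float64)
        if self.ct_values.ndim != 3:
            raise ValueError("ct_values must be a 3D array")
        if self.labels is None:
            self.labels = np.zeros(self.ct_values.shape, dtype=np.uint8)
        else:
            self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.ct_values.shape:
            raise ValueError("labels and ct_values must have identical dimensions")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct_values.shape

    def voxel_centers_mm(self):
        """Meshgrid of voxel-center coordinates (mm), one array per axis."""
        ax = [
            self.origin[k] + (np.arange(self.shape[k]) + 0.5) * self.spacing
            for k in range(3)
        ]
        return np.meshgrid(*ax, indexing="ij")

    def label_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=4)
        return {LABEL_NAMES[i]: int(counts[i]) for i in range(4)}

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(
            self.ct_values.copy(), self.spacing, tuple(self.origin), self.labels.copy()
        )


@dataclass
class ToothSpec:
    """A cylindrical tooth insert: root embedded in bone, crown above the crest."""

    center_x_mm: float
    center_y_mm: float
    radius_mm: float = 3.0
    root_depth_mm: float = 11.0     # depth below the bone crest
    crown_height_mm: float = 8.0    # protrusion above the bone crest


def _default_teeth() -> list[ToothSpec]:
    # one tooth at the segment centre (the first-molar site of the sweep)
    return [ToothSpec(center_x_mm=3.9, center_y_mm=5.07)]


@dataclass
class MandiblePhantomParams:
    """Parameters of the synthetic mandibular segment.

    Default extents give a 7.8 x 10.1 x 31.6 mm block at 0.39 mm voxels:
    23.4 mm of bone height (a 16 mm implant keeps ~6 mm of trabecular
    clearance above the inferior cortical plate) topped by the tooth crown /
    future abutment space.
    """

    extents: tuple[int, int, int] = (20, 26, 81)  # voxels (x, y, z)
    spacing: float = 0.39                         # mm
    bone_height_mm: float = 23.4                  # crest height above z=0
    cortical_thickness_mm: float = 1.2
    cortical_hu: float = 9000.0
    cortical_sd: float = 300.0
    trabecular_hu: float = 1600.0
    trabecular_sd: float = 500.0
    tooth_hu: float = 11000.0
    teeth: list[ToothSpec] = field(default_factory=_default_teeth)
    seed: int = 2021

    def __post_init__(self) -> None:
        if not (self.cortical_hu > self.trabecular_hu > 0):
            raise ValueError("need cortical HU mean > trabecular HU mean > 0")
        if self.cortical_thickness_mm < self.spacing:
            raise ValueError("cortical shell must be at least one voxel thick")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extents"] = list(self.extents)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MandiblePhantomParams":
        d = dict(d)
        d["extents"] = tuple(d["extents"])
        d["teeth"] = [
            t if isinstance(t, ToothSpec) else ToothSpec(**t) for t in d["teeth"]
        ]
        return cls(**d)


def generate_mandible_volume(params: MandiblePhantomParams) -> VoxelVolume:
    """Build the phantom volume; a pure function of the parameter set.

    The cortical shell wraps the buccal/lingual/inferior/crestal bone faces;
    teeth punch through the crestal shell as natural sockets.  Gaussian HU
    noise (per-tissue standard deviation) is drawn from a single seeded
    generator so identical params reproduce identical volumes bitwise.
    """
    nx, ny, nz = params.extents
    if min(nx, ny, nz) < 20:
        raise ValueError("extents must be at least 20 voxels per axis")
    h = params.spacing
    if params.cortical_thickness_mm > 0.5 * min(nx, ny, nz) * h:
        raise ValueError(
            "invalid geometry: cortical shell thickness exceeds half the smallest extent"
        )
    if params.bone_height_mm > nz * h:
        raise ValueError("invalid geometry: bone height exceeds the volume")

    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    crest = params.bone_height_mm
    t = params.cortical_thickness_mm
    bone = Z < crest
    cortical = bone & (
        (Z < t)                      # inferior border
        | (Z >= crest - t)           # crestal plate
        | (Y < t)                    # buccal plate
        | (Y >= ny * h - t)          # lingual plate
    )

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[bone] = LABEL_BONE

    tooth_mask = np.zeros_like(bone)
    for tooth in params.teeth:
        r2 = (X - tooth.center_x_mm) ** 2 + (Y - tooth.center_y_mm) ** 2
        inside = (
            (r2 <= tooth.radius_mm**2)
            & (Z >= crest - tooth.root_depth_mm)
            & (Z < crest + tooth.crown_height_mm)
        )
        tooth_mask |= inside
    labels[tooth_mask] = LABEL_TOOTH

    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(size=(nx, ny, nz))
    ct = np.zeros((nx, ny, nz), dtype=np.float64)
    trabecular = (labels == LABEL_BONE) & ~cortical
    cortical = (labels == LABEL_BONE) & cortical
    ct[trabecular] = params.trabecular_hu + params.trabecular_sd * noise[trabecular]
    ct[cortical] = params.cortical_hu + params.cortical_sd * noise[cortical]
    ct[tooth_mask] = params.tooth_hu

    volume = VoxelVolume(ct, spacing=h, labels=labels)
    _check_branch_coverage(volume)
    return volume


def _check_branch_coverage(volume: VoxelVolume) -> None:
    """Warn if the bone-voxel densities leave a constitutive branch empty."""
    from .material_model import hu_to_density, density_branch

    bone_ct = volume.ct_values[volume.labels == LABEL_BONE]
    if bone_ct.size == 0:
        warnings.warn("phantom contains no bone voxels")
        return
    branches = density_branch(hu_to_density(bone_ct))
    for b, name in ((1, "low power"), (2, "linear"), (3, "high power")):
        if not np.any(branches == b):
            warnings.warn(
                f"phantom bone densities leave the {name} branch of the "
                "constitutive law unpopulated"
            )


def segment_roi(
    volume: VoxelVolume, bone_threshold: float, tooth_threshold: float
) -> VoxelVolume:
    """Relabel the volume by CT thresholds (region-of-interest processing).

    Voxels at or above ``tooth_threshold`` become tooth, those in
    [bone_threshold, tooth_threshold) bone, the rest background.  CT values
    are untouched; a new volume is returned.
    """
    if not tooth_threshold > bone_threshold:
        raise ValueError("tooth_threshold must exceed bone_threshold")
    ct = volume.ct_values
    lo, hi = float(ct.min()), float(ct.max())
    if bone_threshold > hi or tooth_threshold < lo:
        logger.warning(
            "threshold(s) outside the volume's HU range [%g, %g]; "
            "an empty label class will result", lo, hi,
        )
    labels = np.full(ct.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[ct >= bone_threshold] = LABEL_BONE
    labels[ct >= tooth_threshold] = LABEL_TOOTH
    return VoxelVolume(ct.copy(), volume.spacing, tuple(volume.origin), labels)


# ---------------------------------------------------------------------------
# I/O: NIfTI (read/write), raw + JSON sidecar (read/write), DICOM series (read)
# ---------------------------------------------------------------------------

def write_volume(volume: VoxelVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume; ``format`` is 'nifti' or 'raw' (inferred from suffix).

    NIfTI stores CT values in ``<stem>.nii.gz`` and labels alongside in
    ``<stem>_labels.nii.gz``; raw writes float64/uint8 binaries plus a JSON
    sidecar describing shape, spacing and origin.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([volume.spacing] * 3 + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.ct_values, affine), str(path))
        nib.save(nib.Nifti1Image(volume.labels.astype(np.uint8), affine),
                 str(_labels_path(path)))
    elif fmt == "raw":
        stem = path.with_suffix("")
        ct_file = stem.with_suffix(".ct.raw")
        lab_file = stem.with_suffix(".labels.raw")
        volume.ct_values.astype("<f8").tofile(ct_file)
        volume.labels.astype(np.uint8).tofile(lab_file)
        sidecar = {
            "shape": list(volume.shape),
            "spacing": volume.spacing,
            "origin": list(volume.origin),
            "ct_dtype": "<f8",
            "labels_dtype": "u1",
            "ct_file": ct_file.name,
            "labels_file": lab_file.name,
        }
        path.write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported write format: {fmt}")
    return path


def read_volume(path: str | Path, format: str | None = None) -> VoxelVolume:
    """Read a volume from NIfTI, raw+JSON, or a DICOM series directory."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        spacing = float(img.header.get_zooms()[0])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        ct = np.asarray(img.dataobj, dtype=np.float64)
        lab_path = _labels_path(path)
        labels = None
        if lab_path.exists():
            labels = np.asarray(nib.load(str(lab_path)).dataobj).astype(np.uint8)
        return VoxelVolume(ct, spacing=spacing, origin=origin, labels=labels)
    if fmt == "raw":
        sidecar = json.loads(path.read_text())
        shape = tuple(sidecar["shape"])
        ct = np.fromfile(path.parent / sidecar["ct_file"],
                         dtype=sidecar["ct_dtype"]).reshape(shape)
        labels = np.fromfile(path.parent / sidecar["labels_file"],
                             dtype=sidecar["labels_dtype"]).reshape(shape)
        return VoxelVolume(ct, spacing=sidecar["spacing"],
                           origin=tuple(sidecar["origin"]), labels=labels)
    if fmt == "dicom":
        return _read_dicom_series(path)
    raise ValueError(f"unsupported read format: {fmt}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".json"):
        return "raw"
    if path.is_dir():
        return "dicom"
    raise ValueError(f"cannot infer volume format from {path}")


def _labels_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.lower().endswith(suf):
            return path.with_name(name[: -len(suf)] + "_labels" + suf)
    raise ValueError(f"not a NIfTI path: {path}")


def _read_dicom_series(directory: Path, spacing_rtol: float = 1e-3) -> VoxelVolume:
    """Stack a single-frame DICOM series into a volume (slices along z).

    Slices are ordered by their z position; a gap or duplicate (non-uniform
    slice spacing) is a hard error naming the offending slice file.
    """
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        zpos = float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2])
        slices.append((zpos, f, ds))
    slices.sort(key=lambda s: s[0])
    zs = np.array([s[0] for s in slices])
    if len(slices) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            k = int(np.flatnonzero(dz <= 0)[0])
            raise ValueError(
                f"duplicate slice position in DICOM series at slice "
                f"{slices[k + 1][1].name}"
            )
        ref = float(dz.min())  # a gap can only enlarge the step
        bad = np.flatnonzero(np.abs(dz - ref) > spacing_rtol * ref)
        if bad.size:
            raise ValueError(
                "inconsistent slice spacing in DICOM series at slice "
                f"{slices[bad[0] + 1][1].name}: spacing {dz[bad[0]]:.4f} mm "
                f"vs expected {ref:.4f} mm"
            )
    first = slices[0][2]
    px = [float(v) for v in first.PixelSpacing]
    spacing = px[0]
    planes = []
    for _, f, ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is (rows, cols) = (y, x); stack slices along z
    ct = np.stack(planes, axis=-1).transpose(1, 0, 2)
    origin = tuple(float(v) for v in getattr(first, "ImagePositionPatient", [0, 0, 0]))
    return VoxelVolume(ct, spacing=spacing, origin=origin)
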