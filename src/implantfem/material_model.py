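"""CT-value calibration and bone constitutive constants.

CT attenuation (Hounsfield units) is converted to apparent bone density
with the linear calibration rho = ct * 0.945e-4 (rho in gf/cc), and density
to Young's modulus with Keyak's piecewise power/linear law:

    E = 0.001 MPa                 rho = 0
    E = 33900 * rho**2.20  MPa    0   < rho <= 0.27
    E = 5507 * rho + 469   MPa    0.27 < rho <  0.6
    E = 10200 * rho**2.01  MPa    0.6 <= rho

Teeth and the titanium implant are homogeneous isotropic solids; bone is
heterogeneous isotropic with a per-element modulus from the local density.
All moduli are in MPa, densities in gf/cc, consistent with an mm-N-MPa
unit system throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING

import numpy as np

from .synthetic_ct import LABEL_BONE, LABEL_TOOTH, LABEL_IMPLANT

if TYPE_CHECKING:  # pragma: no cover
    from .meshing import TetMesh

__all__ = [
    "MaterialTable",
    "hu_to_density",
    "density_to_modulus",
    "assign_materials",
]

# Density interval edges of the piecewise bone law (gf/cc).
_RHO_LOW_HIGH = 0.27   # low power branch applies for 0 < rho <= 0.27
_RHO_MID_HIGH = 0.6    # linear branch applies for 0.27 < rho < 0.6


@dataclass(frozen=True)
class MaterialTable:
    """All constitutive constants plus the HU->density calibration slope.

    Defaults are the standard set for titanium implants in mandibular bone;
    edit a serialized copy (``to_dict``/``from_dict``) to explore other
    material assumptions.
    """

    hu_to_density_slope: float = 0.945e-4  # gf/cc per HU
    e_bone_floor: float = 0.001            # MPa, modulus at zero density
    bone_low_coeff: float = 33900.0        # MPa, E = c * rho**p, low branch
    bone_low_exp: float = 2.20
    bone_mid_slope: float = 5507.0         # MPa per gf/cc, linear mid branch
    bone_mid_intercept: float = 469.0      # MPa
    bone_high_coeff: float = 10200.0       # MPa, E = c * rho**p, high branch
    bone_high_exp: float = 2.01
    nu_bone: float = 0.4
    e_tooth: float = 4.80e4                # MPa
    nu_tooth: float = 0.23
    e_implant: float = 11.0e4              # MPa, titanium
    nu_implant: float = 0.29

    def __post_init__(self) -> None:
        for name in ("e_bone_floor", "e_tooth", "e_implant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("nu_bone", "nu_tooth", "nu_implant"):
            nu = getattr(self, name)
            if not (0.0 < nu < 0.5):
                raise ValueError(f"{name} must lie in the open interval (0, 0.5)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialTable":
        return cls(**d)


def hu_to_density(ct, table: MaterialTable | None = None):
    """Convert CT values (HU) to apparent bone density (gf/cc).

    Negative CT values (air, soft tissue below water) are clamped to zero
    density: the linear calibration would otherwise produce negative
    densities for which the constitutive law is undefined.
    """
    slope = (table or MaterialTable()).hu_to_density_slope
    ct = np.asarray(ct, dtype=float)
    if not np.all(np.isfinite(ct)):
        raise ValueError("CT values must be finite")
    rho = np.maximum(ct, 0.0) * slope
    return float(rho) if rho.ndim == 0 else rho


def density_to_modulus(rho, table: MaterialTable | None = None):
    """Young's modulus (MPa) from apparent density (gf/cc), piecewise.

    Exactly one branch applies to every density; the interval boundaries are
    assigned as the law is written (0.27 belongs to the low power branch,
    0.6 to the high power branch).
    """
    t = table or MaterialTable()
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    E = np.empty_like(rho)
    zero = rho == 0.0
    low = (rho > 0.0) & (rho <= _RHO_LOW_HIGH)
    mid = (rho > _RHO_LOW_HIGH) & (rho < _RHO_MID_HIGH)
    high = rho >= _RHO_MID_HIGH
    E[zero] = t.e_bone_floor
    E[low] = t.bone_low_coeff * rho[low] ** t.bone_low_exp
    E[mid] = t.bone_mid_slope * rho[mid] + t.bone_mid_intercept
    E[high] = t.bone_high_coeff * rho[high] ** t.bone_high_exp
    return float(E) if E.ndim == 0 else E


def density_branch(rho) -> np.ndarray:
    """Branch index of the bone law: 0 zero, 1 low power, 2 linear, 3 high power."""
    rho = np.asarray(rho, dtype=float)
    out = np.zeros(rho.shape, dtype=np.int8)
    out[(rho > 0.0) & (rho <= _RHO_LOW_HIGH)] = 1
    out[(rho > _RHO_LOW_HIGH) & (rho < _RHO_MID_HIGH)] = 2
    out[rho >= _RHO_MID_HIGH] = 3
    return out


def assign_materials(mesh: "TetMesh", table: MaterialTable | None = None) -> "TetMesh":
    """Populate per-element Young's modulus and Poisson ratio in place.

    Bone elements receive the density-derived modulus and nu_bone; tooth and
    implant elements the homogeneous constants of the table.  Returns the
    mesh for chaining.
    """
    t = table or MaterialTable()
    labels = mesh.labels
    known = np.isin(labels, (LABEL_BONE, LABEL_TOOTH, LABEL_IMPLANT))
    if not np.all(known):
        bad = np.flatnonzero(~known)
        raise ValueError(
            f"elements with unknown material label: ids {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else "")
        )
    E = np.empty(labels.shape, dtype=float)
    nu = np.empty(labels.shape, dtype=float)
    bone = labels == LABEL_BONE
    if np.any(bone):
        rho = mesh.density[bone]
        if np.any(~np.isfinite(rho)):
            raise ValueError("bone elements must carry a finite density")
        E[bone] = density_to_modulus(rho, t)
        nu[bone] = t.nu_bone
    tooth = labels == LABEL_TOOTH
    E[tooth] = t.e_tooth
    nu[tooth] = t.nu_tooth
    implant = labels == LABEL_IMPLANT
    E[implant] = t.e_implant
    nu[implant] = t.nu_implant
    mesh.E = E
    mesh.nu = nu
    return mesh
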