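"""Voxel volume to 4-node tetrahedral mesh conversion.

Each included voxel is split into 5 tetrahedra (four corner tets plus one
central tet, using only the 8 cube corners).  The decomposition exists in
two mirror forms; alternating them with voxel-index parity makes the
diagonals of shared faces agree, so the mesh conforms across neighbouring
voxels.  Nodes are exact lattice points and are merged by index, which is
bitwise-exact (tolerance 1e-9 mm is never exercised on the lattice).

Element label and density are inherited from the parent voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_ct import (
    VoxelVolume,
    LABEL_BONE,
    LABEL_TOOTH,
    LABEL_IMPLANT,
)
from .implant_geometry import ImplantSpec, PlacementFrame

__all__ = ["TetMesh", "voxel_to_tets", "select_fixed_nodes", "select_load_node"]

# unit-cube corners indexed by bits (bx, by, bz) -> k = 4*bx + 2*by + bz
_CORNERS = np.array(
    [[bx, by, bz] for bx in (0, 1) for by in (0, 1) for bz in (0, 1)], dtype=float
)

# 5-tet split: central tet on one tetrahedrally-arranged corner quadruple,
# corner tets on the complementary four corners.
_EVEN_RAW = [
    (0, 6, 5, 3),          # central
    (4, 0, 6, 5),
    (2, 0, 3, 6),
    (1, 0, 5, 3),
    (7, 6, 3, 5),
]
_ODD_RAW = [
    (4, 2, 1, 7),          # central
    (0, 4, 2, 1),
    (6, 4, 7, 2),
    (5, 4, 1, 7),
    (3, 2, 7, 1),
]


def _orient(patterns):
    """Fix each pattern to positive signed volume on the unit cube."""
    fixed = []
    for tet in patterns:
        p = _CORNERS[list(tet)]
        vol = np.linalg.det(p[1:] - p[0]) / 6.0
        fixed.append(tuple(tet) if vol > 0 else (tet[0], tet[1], tet[3], tet[2]))
    return np.array(fixed, dtype=np.int64)


_EVEN = _orient(_EVEN_RAW)
_ODD = _orient(_ODD_RAW)

MERGE_TOL_MM = 1e-9


@dataclass
class TetMesh:
    """Tet4 mesh with per-element label, density and (after assignment) E, nu."""

    nodes: np.ndarray                    # (n_nodes, 3) mm
    tets: np.ndarray                     # (n_elements, 4) node ids
    labels: np.ndarray                   # (n_elements,) region codes
    density: np.ndarray                  # (n_elements,) gf/cc (NaN for non-bone)
    spacing: float                       # parent voxel edge length, mm
    E: np.ndarray | None = None          # (n_elements,) MPa
    nu: np.ndarray | None = None         # (n_elements,)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def element_coords(self) -> np.ndarray:
        """(n_elements, 4, 3) nodal coordinates per element."""
        return self.nodes[self.tets]

    def element_volumes(self) -> np.ndarray:
        x = self.element_coords()
        d = x[:, 1:, :] - x[:, :1, :]
        return np.linalg.det(d) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)


def voxel_to_tets(
    volume: VoxelVolume,
    include_labels=(LABEL_BONE, LABEL_TOOTH, LABEL_IMPLANT),
) -> TetMesh:
    """Mesh every voxel whose label is in ``include_labels``.

    Raises if the selection is empty.  Shared lattice nodes are merged;
    every tetrahedron has strictly positive volume by construction.
    """
    from .material_model import hu_to_density

    sel = np.isin(volume.labels, list(include_labels))
    vox = np.argwhere(sel)
    if vox.shape[0] == 0:
        raise ValueError("no voxels carry an included label; nothing to mesh")

    nx, ny, nz = volume.shape
    sy, sz = (ny + 1) * (nz + 1), nz + 1

    # global lattice id of each voxel's 8 corners: (n_vox, 8)
    bx, by, bz = _CORNERS[:, 0].astype(np.int64), _CORNERS[:, 1].astype(np.int64), _CORNERS[:, 2].astype(np.int64)
    corner_ids = (
        (vox[:, 0:1] + bx) * sy + (vox[:, 1:2] + by) * sz + (vox[:, 2:3] + bz)
    )

    parity = (vox.sum(axis=1) % 2).astype(bool)
    pat = np.where(parity[:, None, None], _ODD[None, :, :], _EVEN[None, :, :])
    # elements in global lattice ids: (n_vox, 5, 4)
    elems = np.take_along_axis(
        corner_ids[:, None, :].repeat(5, axis=1), pat, axis=2
    ).reshape(-1, 4)

    used, tets = np.unique(elems, return_inverse=True)
    tets = tets.reshape(-1, 4).astype(np.int64)
    gi = used // sy
    gj = (used % sy) // sz
    gk = used % sz
    h = volume.spacing
    nodes = np.stack([gi, gj, gk], axis=1).astype(np.float64) * h
    nodes += np.asarray(volume.origin, dtype=np.float64)

    labels = np.repeat(volume.labels[sel.nonzero()], 5).astype(np.uint8)
    rho_vox = hu_to_density(volume.ct_values[sel.nonzero()])
    density = np.repeat(rho_vox, 5)
    density = np.where(np.repeat(volume.labels[sel.nonzero()], 5) == LABEL_BONE,
                       density, np.nan)

    mesh = TetMesh(nodes=nodes, tets=tets, labels=labels, density=density, spacing=h)
    vols = mesh.element_volumes()
    if np.any(vols <= 0):
        bad = int(np.flatnonzero(vols <= 0)[0])
        raise RuntimeError(f"inverted element produced at id {bad}")
    return mesh


def select_fixed_nodes(mesh: TetMesh) -> np.ndarray:
    """Nodes of the inferior border: the bottom voxel-layer node plane.

    Returns the sorted ids of all nodes within half a voxel of the lowest
    node, i.e. the z = z_min lattice plane (the discrete analogue of a
    completely fixed inferior surface).
    """
    if mesh.n_nodes == 0:
        raise ValueError("empty mesh")
    z = mesh.nodes[:, 2]
    return np.flatnonzero(z <= z.min() + 0.5 * mesh.spacing)


def select_load_node(
    mesh: TetMesh, frame: PlacementFrame, spec: ImplantSpec
) -> int:
    """Implant-crown node nearest the buccal-cusp target point.

    The target sits on the crown top face, offset buccally (-y) from the
    implant axis by the spec's cusp offset.  Ties are broken toward the
    lowest node id.
    """
    implant_elems = mesh.labels == LABEL_IMPLANT
    if not np.any(implant_elems):
        raise ValueError("mesh contains no implant elements")
    ids = np.unique(mesh.tets[implant_elems])
    ex, ey, ez = frame.entry_point_mm
    target = np.array(
        [ex, ey - spec.cusp_offset_mm, ez + spec.supracrestal_height_mm]
    )
    d2 = ((mesh.nodes[ids] - target) ** 2).sum(axis=1)
    return int(ids[np.argmin(d2)])  # argmin -> first (lowest) id on ties
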