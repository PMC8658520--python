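"""Linear static elasticity on tet4 meshes.

Constant-strain tetrahedra (exact one-point integration), sparse symmetric
assembly, Dirichlet conditions by system reduction, and a direct sparse
factorization (conjugate-gradient fallback for very large systems).  Units
are mm-N-MPa throughout.  Voigt ordering of strain/stress is
(xx, yy, zz, yz, xz, xy) with engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import TetMesh

__all__ = [
    "LoadCase",
    "DisplacementField",
    "StressState",
    "load_vector",
    "element_stiffness",
    "assemble",
    "solve",
    "recover_stress",
    "von_mises",
]

DIRECT_DOF_LIMIT = 200_000
SOLVE_RTOL = 1e-8


@dataclass
class LoadCase:
    """A concentrated nodal load plus the fixed (fully clamped) node set."""

    load_node: int
    force: np.ndarray                 # (3,) N
    fixed_nodes: np.ndarray           # node ids

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        if np.linalg.norm(self.force) == 0:
            raise ValueError("load magnitude must be positive")
        if self.fixed_nodes.size == 0:
            raise ValueError("fixed node set must be non-empty")
        if self.load_node in set(self.fixed_nodes.tolist()):
            raise ValueError("load node must not be fixed")

    def angle_to_axis_rad(self, axis=(0.0, 0.0, 1.0)) -> float:
        """Angle between the force and the (downward) implant-axis direction.

        An occlusal load acts downward along -axis; the configured
        inclination is measured from that direction.
        """
        a = -np.asarray(axis, dtype=float)
        c = float(self.force @ a / (np.linalg.norm(self.force) * np.linalg.norm(a)))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def load_vector(
    magnitude_n: float = 50.0,
    angle_deg: float = 45.0,
    axis=(0.0, 0.0, 1.0),
    lateral_dir=(0.0, 1.0, 0.0),
) -> np.ndarray:
    """Occlusal force vector: ``magnitude`` at ``angle`` to the tooth axis.

    The lateral component points along ``lateral_dir`` (buccal -> lingual,
    +y by the package's axis convention); the axial component presses
    downward (-axis).
    """
    if magnitude_n <= 0:
        raise ValueError("load magnitude must be positive")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    lat = np.asarray(lateral_dir, dtype=float)
    lat = lat - (lat @ a) * a
    lat = lat / np.linalg.norm(lat)
    th = np.deg2rad(angle_deg)
    return magnitude_n * (np.sin(th) * lat - np.cos(th) * a)


@dataclass
class DisplacementField:
    """Nodal displacements (mm), zero at fixed nodes."""

    u: np.ndarray                     # (n_nodes, 3)
    residual: float                   # ||K u - f|| / ||f|| on free DOFs
    reactions: np.ndarray             # (n_fixed, 3) N at the fixed nodes
    fixed_nodes: np.ndarray

    def equilibrium_error_n(self, applied: np.ndarray) -> float:
        """| sum of reactions + total applied load |, N."""
        return float(np.linalg.norm(self.reactions.sum(axis=0) + applied))


@dataclass
class StressState:
    """Per-element stress tensors (Voigt, MPa) and equivalent stress."""

    tensor: np.ndarray                # (n_elements, 6)
    vm: np.ndarray                    # (n_elements,)


def _elastic_matrix(E, nu):
    """Isotropic 6x6 stiffness in Voigt notation; batched over elements."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((E.size, 6, 6))
    for i in range(3):
        for j in range(3):
            C[:, i, j] = lam
        C[:, i, i] = lam + 2 * mu
        C[:, 3 + i, 3 + i] = mu
    return C


def _b_matrices(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices B (n, 6, 12) and volumes (n,) for tet4.

    Shape-function gradients come from the inverse of the 4x4 coordinate
    matrix [1 x y z] per element; strain is constant over each tetrahedron.
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    n = coords.shape[0]
    d = coords[:, 1:, :] - coords[:, :1, :]
    vol = np.linalg.det(d) / 6.0
    if np.any(vol <= 0):
        bad = int(np.flatnonzero(vol <= 0)[0])
        raise ValueError(f"inverted element (non-positive volume) at id {bad}")
    M = np.concatenate([np.ones((n, 4, 1)), coords], axis=2)   # (n, 4, 4)
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:4, :]                                     # (n, 3, 4): d N_a / d x_i
    B = np.zeros((n, 6, 12))
    gx, gy, gz = grads[:, 0, :], grads[:, 1, :], grads[:, 2, :]
    for a in range(4):
        c = 3 * a
        B[:, 0, c + 0] = gx[:, a]
        B[:, 1, c + 1] = gy[:, a]
        B[:, 2, c + 2] = gz[:, a]
        B[:, 3, c + 1] = gz[:, a]
        B[:, 3, c + 2] = gy[:, a]
        B[:, 4, c + 0] = gz[:, a]
        B[:, 4, c + 2] = gx[:, a]
        B[:, 5, c + 0] = gy[:, a]
        B[:, 5, c + 1] = gx[:, a]
    return (B[0], vol[0]) if single else (B, vol)


def element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of one constant-strain tetrahedron.

    Symmetric positive semidefinite with a 6-dimensional rigid-body
    nullspace.  ``coords`` is (4, 3) in mm; E in MPa.
    """
    if not (0.0 < nu < 0.5):
        raise ValueError("Poisson ratio must lie in (0, 0.5)")
    B, vol = _b_matrices(coords)
    C = _elastic_matrix(E, nu)[0]
    return vol * (B.T @ C @ B)


def assemble(mesh: TetMesh, chunk: int = 60_000) -> sp.csr_matrix:
    """Global sparse stiffness (3 n_nodes square) from per-element blocks."""
    if mesh.E is None or mesh.nu is None:
        raise ValueError("materials must be assigned before assembly")
    ndof = 3 * mesh.n_nodes
    K = sp.csr_matrix((ndof, ndof))
    coords = mesh.element_coords()
    for lo in range(0, mesh.n_elements, chunk):
        hi = min(lo + chunk, mesh.n_elements)
        B, vol = _b_matrices(coords[lo:hi])
        C = _elastic_matrix(mesh.E[lo:hi], mesh.nu[lo:hi])
        CB = C @ B
        Ke = vol[:, None, None] * np.matmul(B.transpose(0, 2, 1), CB)
        dof = (3 * mesh.tets[lo:hi, :, None] + np.arange(3)).reshape(hi - lo, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        K = K + sp.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(ndof, ndof)
        ).tocsr()
    return K


def _factor(Kff: sp.csc_matrix):
    try:
        return spla.splu(
            Kff,
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
    except RuntimeError as exc:
        raise RuntimeError(
            "singular constrained system; the fixed node set may not "
            "constrain all rigid-body modes"
        ) from exc


def _direct_solve(Kff: sp.csc_matrix, ff: np.ndarray, rtol: float) -> np.ndarray:
    """Mixed-precision direct solve: f32 LU + f64 iterative refinement."""
    fnorm = np.linalg.norm(ff)
    lu32 = _factor(Kff.astype(np.float32))
    uf = lu32.solve(ff.astype(np.float32)).astype(np.float64)
    res_prev = np.inf
    for _ in range(30):
        r = ff - Kff @ uf
        res = np.linalg.norm(r) / fnorm
        if res <= 0.01 * rtol:
            return uf
        if not np.isfinite(res) or (res > 0.5 * res_prev and res > rtol):
            break                      # refinement stalling above tolerance
        res_prev = res
        uf = uf + lu32.solve(r.astype(np.float32)).astype(np.float64)
    if np.isfinite(res) and res <= rtol:
        return uf
    lu = _factor(Kff)                  # full-precision fallback
    uf = lu.solve(ff)
    return uf + lu.solve(ff - Kff @ uf)


def _partition(ndof: int, fixed_nodes: np.ndarray):
    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    mask = np.ones(ndof, dtype=bool)
    mask[fixed_dofs] = False
    return np.flatnonzero(mask), fixed_dofs


def solve_system(
    K: sp.spmatrix,
    f: np.ndarray,
    fixed_dofs: np.ndarray,
    method: str = "auto",
    rtol: float = SOLVE_RTOL,
):
    """Solve K u = f with the listed DOFs held at zero.

    Returns (u, residual, constraint_forces) where ``constraint_forces`` is
    the full-length vector K u - f (zero at free DOFs up to the residual,
    reactions at constrained DOFs).  Direct sparse LU on the reduced system
    up to ``DIRECT_DOF_LIMIT`` free DOFs — the factorization is computed in
    single precision (halving time and memory) and polished to
    double-precision accuracy by iterative refinement against the
    double-precision matrix, with a full double-precision factorization as
    fallback.  Beyond the limit, Jacobi-preconditioned conjugate gradients.
    """
    ndof = K.shape[0]
    fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
    mask = np.ones(ndof, dtype=bool)
    mask[fixed_dofs] = False
    free = np.flatnonzero(mask)
    Kff = K[free][:, free].tocsc()
    ff = f[free]

    if method == "auto":
        method = "direct" if free.size <= DIRECT_DOF_LIMIT else "cg"
    if method == "direct":
        uf = _direct_solve(Kff, ff, rtol)
    elif method == "cg":
        Minv = sp.diags(1.0 / Kff.diagonal())
        uf, info = spla.cg(Kff, ff, M=Minv, rtol=rtol, maxiter=50_000)
        if info != 0:
            raise RuntimeError(f"conjugate gradients failed to converge (info={info})")
    else:
        raise ValueError(f"unknown solve method: {method}")

    residual = float(np.linalg.norm(Kff @ uf - ff) / np.linalg.norm(ff))
    if not np.all(np.isfinite(uf)):
        raise RuntimeError(
            "non-finite solution; the constrained system is singular or "
            "badly scaled — check that the fixed set removes all rigid modes"
        )
    if residual > 1e-6:
        raise RuntimeError(
            f"solver residual {residual:.2e} exceeds tolerance; system may be "
            "under-constrained"
        )
    u = np.zeros(ndof)
    u[free] = uf
    return u, residual, K @ u - f


def solve(
    K: sp.spmatrix,
    load: LoadCase,
    method: str = "auto",
    rtol: float = SOLVE_RTOL,
) -> DisplacementField:
    """Solve the load case with the fixed nodes fully clamped."""
    ndof = K.shape[0]
    f = np.zeros(ndof)
    f[3 * load.load_node: 3 * load.load_node + 3] = load.force
    _free, fixed_dofs = _partition(ndof, load.fixed_nodes)
    u, residual, r_full = solve_system(K, f, fixed_dofs, method, rtol)
    reactions = r_full[fixed_dofs].reshape(-1, 3)
    return DisplacementField(
        u=u.reshape(-1, 3),
        residual=residual,
        reactions=reactions,
        fixed_nodes=load.fixed_nodes.copy(),
    )


def recover_stress(mesh: TetMesh, displacements: DisplacementField) -> StressState:
    """Constant per-element stress from the displacement field."""
    if mesh.E is None or mesh.nu is None:
        raise ValueError("materials must be assigned before stress recovery")
    B, _vol = _b_matrices(mesh.element_coords())
    ue = displacements.u[mesh.tets].reshape(mesh.n_elements, 12)
    eps = np.einsum("eij,ej->ei", B, ue)
    C = _elastic_matrix(mesh.E, mesh.nu)
    sig = np.einsum("eij,ej->ei", C, eps)
    return StressState(tensor=sig, vm=von_mises(sig))


def von_mises(sig: np.ndarray) -> np.ndarray:
    """Equivalent stress from Voigt tensors (xx, yy, zz, yz, xz, xy)."""
    arr = np.atleast_2d(np.asarray(sig, dtype=float))
    sxx, syy, szz, syz, sxz, sxy = arr.T
    vm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (syz**2 + sxz**2 + sxy**2)
    )
    return float(vm[0]) if np.asarray(sig).ndim == 1 else vm
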