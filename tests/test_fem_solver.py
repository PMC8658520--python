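"""Element stiffness, assembly, solution and stress recovery verification."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

import implantfem as ifm
from implantfem.synthetic_ct import VoxelVolume, LABEL_BONE
from implantfem.meshing import TetMesh, voxel_to_tets
from implantfem import fem_solver
from implantfem.fem_solver import (
    LoadCase,
    element_stiffness,
    assemble,
    solve,
    solve_system,
    recover_stress,
    von_mises,
    load_vector,
)

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def homogeneous_mesh(nx, ny, nz, spacing=1.0, E=1000.0, nu=0.25, origin=(0, 0, 0)):
    ct = np.full((nx, ny, nz), 1000.0)
    labels = np.full((nx, ny, nz), LABEL_BONE, dtype=np.uint8)
    vol = VoxelVolume(ct, spacing=spacing, origin=origin, labels=labels)
    mesh = voxel_to_tets(vol)
    mesh.E = np.full(mesh.n_elements, float(E))
    mesh.nu = np.full(mesh.n_elements, float(nu))
    return mesh


def energy_oracle_stiffness(coords, E, nu):
    """Independent stiffness oracle from the strain-energy functional.

    Fits the affine displacement field interpolating the 4 nodal values,
    takes its symmetric gradient, and evaluates U = V/2 (lam tr(e)^2 +
    2 mu e:e); K_ij = U(e_i + e_j) - U(e_i) - U(e_j) for a quadratic U.
    """
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    vol = abs(np.linalg.det(coords[1:] - coords[0])) / 6.0
    A = np.hstack([np.ones((4, 1)), coords])  # affine basis at the nodes

    def energy(u12):
        coeff = np.linalg.solve(A, u12.reshape(4, 3))  # rows: const, d/dx, d/dy, d/dz
        grad = coeff[1:, :].T                          # grad[i, j] = d u_i / d x_j
        eps = 0.5 * (grad + grad.T)
        return vol * (0.5 * lam * np.trace(eps) ** 2 + mu * np.sum(eps * eps))

    K = np.zeros((12, 12))
    basis = np.eye(12)
    for i in range(12):
        for j in range(12):
            K[i, j] = (
                energy(basis[i] + basis[j]) - energy(basis[i]) - energy(basis[j])
            )
    return K


class TestElementStiffness:
    def test_symmetric(self):
        K = element_stiffness(UNIT_TET, 1.0, 0.25)
        assert np.array_equal(K, K.T) or np.allclose(K, K.T, atol=1e-15)

    def test_rigid_translations_in_nullspace(self):
        K = element_stiffness(UNIT_TET, 200.0, 0.3)
        for comp in range(3):
            u = np.zeros(12)
            u[comp::3] = 1.0
            assert np.linalg.norm(K @ u) <= 1e-9 * np.linalg.norm(K)

    def test_nullspace_dimension_is_six(self):
        rng = np.random.default_rng(0)
        coords = UNIT_TET + 0.1 * rng.standard_normal((4, 3))
        K = element_stiffness(coords, 50.0, 0.33)
        eig = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(eig) < 1e-9 * eig.max()) == 6
        assert np.all(eig > -1e-9 * eig.max())  # positive semidefinite

    @pytest.mark.parametrize("nu", [0.25, 0.4])
    def test_matches_energy_oracle(self, nu):
        rng = np.random.default_rng(42)
        for coords in (UNIT_TET, UNIT_TET + 0.2 * rng.standard_normal((4, 3))):
            K = element_stiffness(coords, 1.0, nu)
            K_oracle = energy_oracle_stiffness(coords, 1.0, nu)
            assert np.allclose(K, K_oracle, rtol=1e-9, atol=1e-12)

    def test_inverted_element_rejected(self):
        coords = UNIT_TET[[0, 2, 1, 3]]  # swapped -> negative volume
        with pytest.raises(ValueError, match="inverted"):
            element_stiffness(coords, 1.0, 0.25)


def dense_oracle_assembly(mesh):
    """Plain-python dense assembly, independent of the sparse scatter."""
    n = 3 * mesh.n_nodes
    K = np.zeros((n, n))
    for e in range(mesh.n_elements):
        Ke = element_stiffness(
            mesh.nodes[mesh.tets[e]], float(mesh.E[e]), float(mesh.nu[e])
        )
        dofs = []
        for a in mesh.tets[e]:
            dofs.extend([3 * a, 3 * a + 1, 3 * a + 2])
        for i, gi in enumerate(dofs):
            for j, gj in enumerate(dofs):
                K[gi, gj] += Ke[i, j]
    return K


class TestAssembly:
    def test_single_element_equals_element_block(self):
        mesh = TetMesh(
            nodes=UNIT_TET.copy(),
            tets=np.array([[0, 1, 2, 3]]),
            labels=np.array([LABEL_BONE], dtype=np.uint8),
            density=np.array([0.5]),
            spacing=1.0,
            E=np.array([100.0]),
            nu=np.array([0.3]),
        )
        K = assemble(mesh).toarray()
        assert np.allclose(K, element_stiffness(UNIT_TET, 100.0, 0.3), atol=1e-12)

    def test_disconnected_elements_block_diagonal(self):
        nodes = np.vstack([UNIT_TET, UNIT_TET + 10.0])
        mesh = TetMesh(
            nodes=nodes,
            tets=np.array([[0, 1, 2, 3], [4, 5, 6, 7]]),
            labels=np.array([LABEL_BONE, LABEL_BONE], dtype=np.uint8),
            density=np.array([0.5, 0.5]),
            spacing=1.0,
            E=np.array([100.0, 100.0]),
            nu=np.array([0.3, 0.3]),
        )
        K = assemble(mesh).toarray()
        assert np.all(K[:12, 12:] == 0)
        assert np.all(K[12:, :12] == 0)

    def test_matches_dense_oracle_on_voxel_block(self):
        mesh = homogeneous_mesh(2, 2, 2)
        K = assemble(mesh).toarray()
        assert np.allclose(K, dense_oracle_assembly(mesh), rtol=1e-12, atol=1e-9)

    def test_unassigned_material_rejected(self):
        mesh = homogeneous_mesh(1, 1, 1)
        mesh.E = None
        with pytest.raises(ValueError, match="assigned"):
            assemble(mesh)


def boundary_faces(mesh):
    """Faces appearing exactly once, with their (outward-area) node triples."""
    import itertools

    counts = {}
    for tet in mesh.tets:
        for tri in itertools.combinations(sorted(tet.tolist()), 3):
            counts[tri] = counts.get(tri, 0) + 1
    return [tri for tri, c in counts.items() if c == 1]


def consistent_face_loads(mesh, tris, traction):
    """Nodal forces equivalent to a uniform traction on the given triangles."""
    f = np.zeros(3 * mesh.n_nodes)
    for tri in tris:
        p = mesh.nodes[list(tri)]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        for a in tri:
            f[3 * a: 3 * a + 3] += traction * area / 3.0
    return f


class TestSolve:
    def test_bar_uniform_axial_stress(self):
        # 1x1x10 mm bar, roller-supported base, uniform tension on top:
        # constant-strain elements reproduce the homogeneous state exactly
        mesh = homogeneous_mesh(1, 1, 10, spacing=1.0, E=1000.0, nu=0.25)
        sigma = 2.0  # MPa applied traction
        top = [t for t in boundary_faces(mesh)
               if np.allclose(mesh.nodes[list(t)][:, 2], 10.0)]
        f = consistent_face_loads(mesh, top, np.array([0.0, 0.0, sigma]))
        z = mesh.nodes[:, 2]
        bottom = np.flatnonzero(z == 0.0)
        fixed = [3 * n + 2 for n in bottom]               # rollers: w = 0
        # order bottom nodes by (y, x): corner[0] = (0,0) pin; corner[1] =
        # (1,0) shares its y, so fixing v there stops rotation about z
        # without disturbing the Poisson contraction
        corner = bottom[np.lexsort((mesh.nodes[bottom, 0], mesh.nodes[bottom, 1]))]
        fixed += [3 * corner[0], 3 * corner[0] + 1]        # pin
        fixed += [3 * corner[1] + 1]
        u, residual, _ = solve_system(sp.csr_matrix(assemble(mesh)), f, np.array(fixed))
        stress = recover_stress(mesh, _fake_disp(mesh, u))
        assert np.allclose(stress.tensor[:, 2], sigma, rtol=1e-8)
        assert np.allclose(stress.tensor[:, [0, 1, 3, 4, 5]], 0.0, atol=1e-8 * sigma)
        assert np.allclose(stress.vm, sigma, rtol=1e-8)

    def test_cantilever_tip_deflection(self):
        # 1x1x10 mm cantilever, 8 elements through the thickness: tip
        # deflection within 5% of the Euler-Bernoulli value F L^3 / (3 E I)
        n = 8
        mesh = homogeneous_mesh(n, n, 10 * n, spacing=1.0 / n, E=1000.0, nu=0.25)
        z = mesh.nodes[:, 2]
        fixed = np.flatnonzero(z <= 1e-12)
        tip = np.flatnonzero(np.abs(z - 10.0) <= 1e-12)
        F = 1.0
        f = np.zeros(3 * mesh.n_nodes)
        f[3 * tip] = F / len(tip)
        fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel()
        u, residual, _ = solve_system(assemble(mesh), f, fixed_dofs)
        tip_defl = u.reshape(-1, 3)[tip, 0].mean()
        expected = F * 10.0**3 / (3.0 * 1000.0 * (1.0 / 12.0))
        assert abs(tip_defl - expected) / expected < 0.05

    def test_matches_dense_oracle_small_mesh(self):
        # <= 300 DOF: sparse path vs brute-force dense linear solve
        mesh = homogeneous_mesh(2, 2, 2, E=500.0, nu=0.3)
        assert 3 * mesh.n_nodes <= 300
        fixed = ifm.select_fixed_nodes(mesh)
        load_node = int(np.argmax(mesh.nodes[:, 2] + mesh.nodes[:, 0]))
        case = LoadCase(load_node, np.array([3.0, -2.0, -5.0]), fixed)
        disp = solve(assemble(mesh), case)

        Kd = dense_oracle_assembly(mesh)
        f = np.zeros(3 * mesh.n_nodes)
        f[3 * load_node: 3 * load_node + 3] = case.force
        fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel()
        free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed_dofs)
        u_oracle = np.zeros(3 * mesh.n_nodes)
        u_oracle[free] = np.linalg.solve(Kd[np.ix_(free, free)], f[free])
        assert np.allclose(
            disp.u.ravel(), u_oracle, rtol=1e-8, atol=1e-12 * np.abs(u_oracle).max()
        )

    def test_fixed_dofs_zero_and_equilibrium(self):
        mesh = homogeneous_mesh(2, 2, 3)
        fixed = ifm.select_fixed_nodes(mesh)
        case = LoadCase(int(mesh.n_nodes - 1), load_vector(50.0, 45.0), fixed)
        disp = solve(assemble(mesh), case)
        assert np.all(disp.u[fixed] == 0.0)
        assert disp.residual <= 1e-8
        assert disp.equilibrium_error_n(case.force) <= 1e-6

    def test_linearity_in_load(self):
        mesh = homogeneous_mesh(2, 2, 3)
        fixed = ifm.select_fixed_nodes(mesh)
        node = int(mesh.n_nodes - 1)
        K = assemble(mesh)
        base = solve(K, LoadCase(node, load_vector(50.0, 45.0), fixed))
        s_base = recover_stress(mesh, base)
        for alpha in (0.5, 2.0):
            scaled = solve(K, LoadCase(node, alpha * load_vector(50.0, 45.0), fixed))
            s_scaled = recover_stress(mesh, scaled)
            assert np.allclose(scaled.u, alpha * base.u, rtol=1e-7, atol=1e-15)
            assert np.allclose(s_scaled.vm, alpha * s_base.vm, rtol=1e-7, atol=1e-12)

    def test_stiffness_scaling(self):
        # multiplying every modulus by beta leaves stresses unchanged and
        # divides displacements by beta
        beta = 3.0
        mesh_a = homogeneous_mesh(2, 2, 3, E=1000.0)
        mesh_b = homogeneous_mesh(2, 2, 3, E=1000.0 * beta)
        fixed = ifm.select_fixed_nodes(mesh_a)
        node = int(mesh_a.n_nodes - 1)
        case = LoadCase(node, load_vector(50.0, 45.0), fixed)
        da = solve(assemble(mesh_a), case)
        db = solve(assemble(mesh_b), case)
        assert np.allclose(db.u, da.u / beta, rtol=1e-7, atol=1e-15)
        assert np.allclose(
            recover_stress(mesh_b, db).vm,
            recover_stress(mesh_a, da).vm,
            rtol=1e-7,
        )

    def test_underconstrained_system_raises(self):
        mesh = homogeneous_mesh(1, 1, 2)
        K = assemble(mesh)
        # fixing a single node leaves rotational rigid modes about it
        case = LoadCase(
            int(mesh.n_nodes - 1), np.array([1.0, 0, 0]), np.array([0])
        )
        with pytest.raises(RuntimeError):
            solve(K, case)


def _fake_disp(mesh, u):
    return fem_solver.DisplacementField(
        u=u.reshape(-1, 3),
        residual=0.0,
        reactions=np.zeros((1, 3)),
        fixed_nodes=np.array([0]),
    )


class TestStressRecovery:
    def test_rigid_motion_gives_zero_stress(self):
        mesh = homogeneous_mesh(2, 2, 2)
        t = np.array([0.5, -1.0, 2.0])
        w = np.array([0.01, -0.02, 0.005])  # infinitesimal rotation
        u = t + np.cross(np.broadcast_to(w, mesh.nodes.shape), mesh.nodes)
        stress = recover_stress(mesh, _fake_disp(mesh, u.ravel()))
        assert np.allclose(stress.vm, 0.0, atol=1e-10)

    @pytest.mark.parametrize(
        "voigt, expected",
        [
            ([10.0, 0, 0, 0, 0, 0], 10.0),           # uniaxial
            ([0, 0, 0, 0, 0, 1.0], np.sqrt(3.0)),    # pure shear
            ([5.0, 5.0, 5.0, 0, 0, 0], 0.0),         # hydrostatic
        ],
    )
    def test_von_mises_closed_forms(self, voigt, expected):
        assert von_mises(np.array(voigt)) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_von_mises_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.standard_normal((3, 3))
        sig = 0.5 * (s + s.T)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rot = q @ sig @ q.T
        def voigt(m):
            return np.array([m[0, 0], m[1, 1], m[2, 2], m[1, 2], m[0, 2], m[0, 1]])
        assert von_mises(voigt(rot)) == pytest.approx(
            von_mises(voigt(sig)), rel=1e-9, abs=1e-12
        )


class TestLoadVector:
    def test_magnitude_and_angle(self):
        F = load_vector(50.0, 45.0)
        assert np.linalg.norm(F) == pytest.approx(50.0, rel=1e-12)
        case = LoadCase(1, F, np.array([0]))
        assert case.angle_to_axis_rad() == pytest.approx(np.deg2rad(45.0), abs=1e-9)

    def test_buccal_to_lingual_compressive(self):
        F = load_vector(50.0, 45.0)
        assert F[1] > 0     # lateral component toward lingual (+y)
        assert F[2] < 0     # axial component presses into the bone

    def test_zero_load_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(1, np.zeros(3), np.array([0]))
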