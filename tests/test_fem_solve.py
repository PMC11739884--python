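"""Static solver verification against closed-form elasticity oracles."""

import numpy as np
import pytest

from seg2fem.fem_build import Material, reference_node
from seg2fem.fem_solve import (
    assemble_stiffness,
    coupling_transform,
    solve_linear_static,
    von_mises,
    write_vtu,
)
from seg2fem.tetmesh import TetMesh, structured_box_mesh, to_quadratic

MAT = Material(youngs_modulus=1000.0, poisson_ratio=1e-6)


def single_tet(order="linear"):
    tm = TetMesh(nodes=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                                dtype=float),
                 elements=np.array([[0, 1, 2, 3]]))
    return to_quadratic(tm) if order == "quadratic" else tm


def bar_fixture(n_axial=8):
    """2x2x10 mm prism, quadratic tets; returns mesh, end node sets."""
    tm = to_quadratic(structured_box_mesh((2.0, 2.0, 10.0), (2, 2, n_axial)))
    bottom = np.flatnonzero(np.abs(tm.nodes[:, 2]) < 1e-12)
    top = np.flatnonzero(np.abs(tm.nodes[:, 2] - 10.0) < 1e-12)
    return tm, bottom, top


class TestAssembly:
    @pytest.mark.parametrize("order", ["linear", "quadratic"])
    def test_operator_symmetric_with_six_rigid_modes(self, order):
        tm = single_tet(order)
        k = assemble_stiffness(tm, MAT).toarray()
        assert np.abs(k - k.T).max() < 1e-9 * np.abs(k).max()
        w = np.linalg.eigvalsh(k)
        assert (np.abs(w) < 1e-9 * np.abs(w).max()).sum() == 6

    def test_linear_in_youngs_modulus(self):
        tm = single_tet()
        k1 = assemble_stiffness(tm, Material(1000.0, 0.3)).toarray()
        k2 = assemble_stiffness(tm, Material(2000.0, 0.3)).toarray()
        assert np.allclose(k2, 2 * k1)

    def test_rigid_modes_annihilated(self):
        tm = to_quadratic(structured_box_mesh((1, 1, 1), (2, 2, 2)))
        k = assemble_stiffness(tm, MAT)
        scale = np.abs(k).max()
        for t in np.eye(3):
            mode = np.tile(t, tm.n_nodes)
            assert np.abs(k @ mode).max() < 1e-9 * scale
        for axis in np.eye(3):
            mode = np.cross(axis, tm.nodes).ravel()
            assert np.abs(k @ mode).max() < 1e-9 * scale

    def test_inverted_element_named(self):
        tm = TetMesh(nodes=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
                                    dtype=float),
                     elements=np.array([[0, 2, 1, 3]]))  # negative volume
        from seg2fem.fem_solve import AssemblyError
        with pytest.raises(AssemblyError):
            assemble_stiffness(tm, MAT)


class TestCoupling:
    def test_prescribed_rotation_moves_nodes_by_theta_cross_r(self):
        tm, _, top = bar_fixture(4)
        ref = reference_node(tm, top)
        t, _, ref_cols = coupling_transform(tm, top, ref)
        q = np.zeros(t.shape[1])
        theta = 1e-3
        q[ref_cols[5]] = theta  # rotation about z
        u = (t @ q).reshape(-1, 3)
        r = tm.nodes[top] - tm.nodes[ref]
        expected = np.cross([0, 0, theta], r)
        assert np.allclose(u[top], expected, atol=1e-15)

    def test_reduced_operator_stays_symmetric(self):
        tm, _, top = bar_fixture(2)
        ref = reference_node(tm, top)
        k = assemble_stiffness(tm, MAT)
        t, _, _ = coupling_transform(tm, top, ref)
        kq = (t.T @ k @ t).toarray()
        assert np.abs(kq - kq.T).max() < 1e-9 * np.abs(kq).max()

    def test_restraining_a_coupled_node_rejected(self):
        tm, bottom, top = bar_fixture(2)
        with pytest.raises(ValueError):
            solve_linear_static(
                tm, MAT, fixed={int(top[0]): np.zeros(3)},
                coupling=(reference_node(tm, top), top),
                ref_load=np.zeros(6))


class TestStaticSolve:
    def test_zero_load_zero_displacement(self):
        tm, bottom, _ = bar_fixture(2)
        res = solve_linear_static(tm, MAT, fixed={int(n): np.zeros(3) for n in bottom})
        assert res.converged
        assert np.abs(res.displacements).max() == 0.0

    def test_bar_matches_axial_closed_form(self):
        tm, bottom, top = bar_fixture()
        F, L, A = 100.0, 10.0, 4.0
        res = solve_linear_static(
            tm, MAT, fixed={int(n): np.zeros(3) for n in bottom},
            coupling=(reference_node(tm, top), top),
            ref_load=np.array([0, 0, F, 0, 0, 0]))
        exact = F * L / (MAT.youngs_modulus * A)
        assert res.ref_node_motion[2] == pytest.approx(exact, rel=0.01)
        assert res.element_von_mises.mean() == pytest.approx(F / A, rel=0.01)

    def test_beam_matches_bending_closed_form(self):
        tm, bottom, top = bar_fixture()
        M, L = 50.0, 10.0
        inertia = 2.0 ** 4 / 12.0
        res = solve_linear_static(
            tm, MAT, fixed={int(n): np.zeros(3) for n in bottom},
            coupling=(reference_node(tm, top), top),
            ref_load=np.array([0, 0, 0, M, 0, 0]))
        exact = M * L / (MAT.youngs_modulus * inertia)
        assert res.ref_node_motion[3] == pytest.approx(exact, rel=0.05)

    def test_restrained_nodes_exactly_zero(self):
        tm, bottom, top = bar_fixture(4)
        res = solve_linear_static(
            tm, MAT, fixed={int(n): np.zeros(3) for n in bottom},
            coupling=(reference_node(tm, top), top),
            ref_load=np.array([0, 0, 0, 1000.0, 0, 0]))
        assert np.abs(res.displacements[bottom]).max() == 0.0

    def test_reaction_balances_applied_moment(self):
        tm, bottom, top = bar_fixture(4)
        moment = 7.5 * 1000.0  # the standard flexion moment in N*mm
        ref = reference_node(tm, top)
        res = solve_linear_static(
            tm, MAT, fixed={int(n): np.zeros(3) for n in bottom},
            coupling=(ref, top),
            ref_load=np.array([0, 0, 0, moment, 0, 0]))
        lever = tm.nodes - tm.nodes[ref]
        reaction_moment = np.cross(lever[bottom], res.reactions[bottom]).sum(axis=0)
        assert reaction_moment[0] == pytest.approx(-moment, rel=1e-8)
        # forces balance too
        assert np.abs(res.reactions[bottom].sum(axis=0)).max() < 1e-8 * moment

    def test_coupled_set_motion_consistent_with_rigid_map(self):
        tm, bottom, top = bar_fixture(4)
        ref = reference_node(tm, top)
        res = solve_linear_static(
            tm, MAT, fixed={int(n): np.zeros(3) for n in bottom},
            coupling=(ref, top),
            ref_load=np.array([0, 0, 0, 500.0, 0, 0]))
        u_t, theta = res.ref_node_motion[:3], res.ref_node_motion[3:]
        r = tm.nodes[top] - tm.nodes[ref]
        expected = u_t + np.cross(theta, r)
        diameter = np.linalg.norm(tm.nodes[top].max(0) - tm.nodes[top].min(0))
        resid = np.abs(res.displacements[top] - expected).max()
        assert resid < 1e-8 * diameter

    def test_mesh_convergence_monotone_under_refinement(self):
        # linear elements under bending converge from below; quadratic are
        # already exact, so the h-refinement study uses linear tets
        M, L = 50.0, 10.0
        inertia = 2.0 ** 4 / 12.0
        exact = M * L / (MAT.youngs_modulus * inertia)
        errors = []
        for n in (4, 8, 16):
            tm = structured_box_mesh((2.0, 2.0, L), (2, 2, n))
            bottom = np.flatnonzero(np.abs(tm.nodes[:, 2]) < 1e-12)
            top = np.flatnonzero(np.abs(tm.nodes[:, 2] - L) < 1e-12)
            res = solve_linear_static(
                tm, MAT, fixed={int(i): np.zeros(3) for i in bottom},
                coupling=(reference_node(tm, top), top),
                ref_load=np.array([0, 0, 0, M, 0, 0]))
            errors.append(abs(res.ref_node_motion[3] - exact) / exact)
        assert errors[0] > errors[1] > errors[2]

    @pytest.mark.parametrize("order", ["linear", "quadratic"])
    def test_patch_test_reproduces_linear_field(self, order):
        tm = structured_box_mesh((1, 1, 1), (2, 2, 2))
        if order == "quadratic":
            tm = to_quadratic(tm)
        grad = np.array([[1e-3, 2e-4, 0.0], [2e-4, -5e-4, 1e-4], [0.0, 1e-4, 2e-3]])
        on_boundary = np.any(np.abs(tm.nodes) < 1e-12, axis=1) | \
            np.any(np.abs(tm.nodes - 1.0) < 1e-12, axis=1)
        fixed = {int(i): grad @ tm.nodes[i] for i in np.flatnonzero(on_boundary)}
        res = solve_linear_static(tm, Material(1000.0, 0.3), fixed=fixed)
        exact = tm.nodes @ grad.T
        err = np.abs(res.displacements - exact).max() / np.abs(exact).max()
        assert err < 1e-8
        # constant stress state: all elements agree
        spread = res.element_von_mises.std() / res.element_von_mises.mean()
        assert spread < 1e-8


class TestVonMises:
    def test_uniaxial_shear_hydrostatic_closed_forms(self):
        assert von_mises(np.diag([5.0, 0, 0])) == pytest.approx(5.0)
        tau = np.zeros((3, 3))
        tau[0, 1] = tau[1, 0] = 3.0
        assert von_mises(tau) == pytest.approx(np.sqrt(3) * 3.0)
        assert von_mises(np.eye(3) * 7.0) == pytest.approx(0.0, abs=1e-12)


class TestExports:
    def test_vtu_written_with_fields(self, tmp_path):
        tm = to_quadratic(structured_box_mesh((1, 1, 1), (1, 1, 1)))
        path = tmp_path / "out.vtu"
        write_vtu(path, tm,
                  point_data={"displacement": np.zeros((tm.n_nodes, 3))},
                  cell_data={"von_mises": np.zeros(tm.n_elements)})
        text = path.read_text()
        assert "UnstructuredGrid" in text and "von_mises" in text
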