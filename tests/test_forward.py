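import numpy as np
import pytest

from headbem import (
    BemOperator,
    Dipole,
    EEGSample,
    HeadModel,
    UniformFieldSource,
    apply_operator,
    electrode_voltages,
    fibonacci_layout,
    icosphere,
    impressed_field,
    impressed_potential,
    project_to_skin,
    secondary_field,
    solve_charges,
    surface_potential,
)

Q = 1e-8  # A·m
SIG = 0.3  # S/m


def single_interface(subdiv=2, sigma_in=SIG, sigma_out=0.0, radius=0.09):
    return HeadModel(
        interfaces=(icosphere(radius, subdiv),), names=("s",),
        sigma_in=(sigma_in,), sigma_out=(sigma_out,), refinable=(True,),
    )


class TestImpressedField:
    def test_on_axis_closed_forms(self):
        d = 0.03
        dip = Dipole([0, 0, 0], [0, 0, Q], SIG)
        phi = impressed_potential(dip, [[0, 0, d]])
        assert phi[0] == pytest.approx(Q / (4 * np.pi * SIG * d**2))
        E = impressed_field(dip, [[0, 0, d]])
        assert np.linalg.norm(E[0]) == pytest.approx(
            2 * Q / (4 * np.pi * SIG * d**3)
        )

    def test_equatorial_antisymmetry(self):
        dip = Dipole([0, 0, 0], [0, 0, Q], SIG)
        v = np.array([0.01, 0.02, 0.015])
        phi_p = impressed_potential(dip, [v])
        phi_m = impressed_potential(dip, [[v[0], v[1], -v[2]]])
        assert phi_p[0] == pytest.approx(-phi_m[0], rel=1e-12)

    def test_inverse_cube_decay(self):
        dip = Dipole([0, 0, 0], [0, 0, Q], SIG)
        E1 = impressed_field(dip, [[0, 0, 0.02]])
        E2 = impressed_field(dip, [[0, 0, 0.04]])
        assert np.linalg.norm(E2) / np.linalg.norm(E1) == pytest.approx(1 / 8)

    def test_singularity_guard(self):
        dip = Dipole([0, 0, 0.01], [0, 0, Q], SIG)
        with pytest.raises(ValueError, match="coincides"):
            impressed_field(dip, [[0, 0, 0.01]])

    def test_gradient_consistency(self):
        """E = -grad(phi) by central differences."""
        dip = Dipole([0.002, -0.001, 0.0], [Q, -Q / 2, Q / 3], SIG)
        p = np.array([0.02, 0.015, -0.01])
        h = 1e-7
        num = np.array([
            (impressed_potential(dip, [p + h * e])[0]
             - impressed_potential(dip, [p - h * e])[0]) / (2 * h)
            for e in np.eye(3)
        ])
        np.testing.assert_allclose(impressed_field(dip, [p])[0], -num, rtol=1e-6)


class TestOperator:
    def test_zero_contrast_reduces_to_half_identity(self):
        m = single_interface(sigma_in=SIG, sigma_out=SIG)  # K = 0
        rng = np.random.default_rng(0)
        rho = rng.normal(size=m.n_facets)
        np.testing.assert_allclose(apply_operator(m, rho), rho / 2, rtol=1e-14)

    def test_zero_input(self):
        m = single_interface()
        assert np.all(apply_operator(m, np.zeros(m.n_facets)) == 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_operator(single_interface(), np.zeros(3))

    def test_dense_matches_matvec_and_transpose(self):
        m = single_interface(1, sigma_in=0.4, sigma_out=1.2)
        for deflate in (False, True):
            op = BemOperator(m, deflate=deflate)
            A = op.dense()
            rng = np.random.default_rng(1)
            x = rng.normal(size=m.n_facets)
            np.testing.assert_allclose(op.matvec(x), A @ x, rtol=1e-11, atol=1e-13)
            np.testing.assert_allclose(op.rmatvec(x), A.T @ x, rtol=1e-11, atol=1e-13)


class TestSolve:
    def test_uniform_conductivity_interior_interfaces_silent(self):
        sig = [0.3] * 5
        radii = [0.092, 0.086, 0.080, 0.078, 0.070]
        m = HeadModel(
            interfaces=tuple(icosphere(r, 1) for r in radii),
            names=tuple("abcde"), sigma_in=tuple(sig),
            sigma_out=(0.0, *sig[:-1]), refinable=(False,) + (True,) * 4,
        )
        dip = Dipole([0, 0, 0.074], [Q, 0, 0], 0.3)
        sol = solve_charges(m, dip)
        interior = sol.rho[m.interface_slice(1).start:]
        skin = sol.rho[m.interface_slice(0)]
        assert np.abs(interior).max() <= 1e-10 * np.abs(skin).max()

    def test_sphere_in_uniform_field_interior(self):
        si, so, E0 = 0.2, 1.0, 2.0
        m = single_interface(3, sigma_in=si, sigma_out=so)
        sol = solve_charges(m, UniformFieldSource([0, 0, E0]), tol=1e-8)
        pts = np.array([[0, 0, 0], [0.02, 0.01, -0.01], [0, -0.03, 0.02]])
        E = np.array([0, 0, E0]) + secondary_field(sol, pts)
        expect = 3 * so / (si + 2 * so) * E0
        np.testing.assert_allclose(E[:, 2], expect, rtol=0.02)
        assert np.abs(E[:, :2]).max() < 0.02 * expect

    def test_central_dipole_surface_potential(self):
        R = 0.09
        m = single_interface(3, radius=R)
        dip = Dipole([0, 0, 0], [0, 0, Q], SIG)
        sol = solve_charges(m, dip)
        pts = m.interfaces[0].facet_centroid
        pts = pts / np.linalg.norm(pts, axis=1)[:, None] * R
        phi = surface_potential(sol, pts)
        expect = 3 * Q * (pts[:, 2] / R) / (4 * np.pi * SIG * R**2)
        assert np.abs(phi - expect).max() <= 0.05 * np.abs(expect).max()

    def test_charge_neutrality_invariant(self):
        m = single_interface(2)
        dip = Dipole([0, 0, 0.05], [Q, 0, Q], SIG)
        sol = solve_charges(m, dip)
        A = m.facet_areas
        assert abs(sol.rho @ A) <= 1e-6 * (np.abs(sol.rho) @ A)
        assert sol.solver_stats["residual"] <= 1e-6

    def test_invalid_tolerance(self):
        m = single_interface(1)
        with pytest.raises(ValueError):
            solve_charges(m, Dipole([0, 0, 0], [0, 0, Q], SIG), tol=0.5)


@pytest.fixture(scope="module")
def setup():
    m = single_interface(2)
    el = project_to_skin(fibonacci_layout(32, 0.65), m.interfaces[0])
    return m, el


class TestPotentialAndVoltages:

    def test_zero_charges_gives_impressed_potential(self, setup):
        m, _ = setup
        from headbem.forward import ChargeSolution

        dip = Dipole([0, 0, 0.02], [Q, 0, 0], SIG)
        sol = ChargeSolution(m, np.zeros(m.n_facets), dip)
        pts = np.array([[0.2, 0.1, 0.3]])
        assert surface_potential(sol, pts)[0] == pytest.approx(
            impressed_potential(dip, pts)[0]
        )

    def test_neutral_distribution_decays_faster_than_monopole(self, setup):
        m, _ = setup
        dip = Dipole([0, 0, 0.03], [0, 0, Q], SIG)
        sol = solve_charges(m, dip)
        far1 = surface_potential(sol, [[0, 0, 0.9]])[0]
        far2 = surface_potential(sol, [[0, 0, 1.8]])[0]
        assert abs(far2) <= abs(far1) / 4 * 1.1  # at least dipolar (r^-2)

    def test_voltage_linearity_in_moment(self, setup):
        m, el = setup
        pos = [0.01, -0.005, 0.03]
        cols = []
        for e in np.eye(3):
            sol = solve_charges(m, Dipole(pos, Q * e, SIG), tol=1e-9)
            cols.append(electrode_voltages(sol, el).voltages)
        L = np.column_stack(cols)
        q = np.array([0.3, -1.2, 0.7])
        sol = solve_charges(m, Dipole(pos, Q * q, SIG), tol=1e-9)
        V = electrode_voltages(sol, el).voltages
        assert np.abs(L @ q - V).max() <= 1e-7 * np.abs(V).max()

    def test_moment_flip_negates_voltages(self, setup):
        m, el = setup
        pos = [0, 0.01, 0.04]
        s1 = solve_charges(m, Dipole(pos, [Q, 0, Q], SIG))
        s2 = solve_charges(m, Dipole(pos, [-Q, 0, -Q], SIG))
        v1 = electrode_voltages(s1, el).voltages
        v2 = electrode_voltages(s2, el).voltages
        np.testing.assert_allclose(v2, -v1, rtol=1e-6)

    def test_average_reference_sums_to_zero_and_idempotent(self, setup):
        m, el = setup
        sol = solve_charges(m, Dipole([0, 0, 0.03], [Q, 0, 0], SIG))
        v = electrode_voltages(sol, el, reference="average")
        assert abs(v.voltages.sum()) <= 1e-12 * np.linalg.norm(v.voltages)
        again = v.average_reference()
        np.testing.assert_allclose(again.voltages, v.voltages, atol=1e-18)

    def test_bad_facet_assignment_rejected(self, setup):
        m, el = setup
        from dataclasses import replace as dc_replace

        sol = solve_charges(m, Dipole([0, 0, 0.03], [Q, 0, 0], SIG))
        bad = dc_replace(el, facet_index=el.facet_index + m.n_facets)
        with pytest.raises(ValueError, match="skin"):
            electrode_voltages(sol, bad)

    def test_electrode_count_matches_layout(self, setup):
        m, _ = setup
        el256 = project_to_skin(fibonacci_layout(256, 0.65), m.interfaces[0])
        sol = solve_charges(m, Dipole([0, 0, 0.03], [Q, 0, 0], SIG))
        assert len(electrode_voltages(sol, el256).voltages) == 256


def test_eeg_sample_length_mismatch():
    with pytest.raises(ValueError):
        EEGSample(np.zeros(3), ("a", "b"))
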