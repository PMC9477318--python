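"""Elastica solver: oracles, equilibrium, frictionless contact, sweeps."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from whiskmap.elastica import (RodModel, SolverOptions, base_reactions,
                               deflect_to_point, reachable_space)
from whiskmap.errors import ParameterError
from whiskmap.geometry import (ContactPoint, MaterialParams, WhiskerShape,
                               spherical_to_cartesian)
from whiskmap.mapping import build_grid

E_UN = 3.0e9  # 3 GPa in μN/mm²


def straight_tapered(n=100, L=20.0, taper=15.0):
    nodes = np.column_stack([np.linspace(0, L, n), np.zeros(n), np.zeros(n)])
    arcs = np.linspace(0, L, n)
    mat = MaterialParams(taper_ratio=taper)
    radii = mat.base_radius_um - (mat.base_radius_um - mat.tip_radius_um) * arcs / L
    return WhiskerShape(nodes, arcs, radii, mat)


class TestBaseReactions:
    def test_hand_example(self):
        bl = base_reactions([0.0, 1.0, 0.0], [10.0, 0.0, 0.0])
        assert (bl.Fx, bl.Fy, bl.Fz) == (0.0, 1.0, 0.0)
        assert (bl.Mx, bl.My, bl.Mz) == (0.0, 0.0, 10.0)

    def test_zero_force(self):
        bl = base_reactions(np.zeros(3), [5.0, 1.0, 2.0])
        assert all(getattr(bl, k) == 0.0 for k in
                   ("Fx", "Fy", "Fz", "Mx", "My", "Mz"))

    def test_moment_magnitude_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(-10, 10, 3)
            F = rng.uniform(-5, 5, 3)
            bl = base_reactions(F, p)
            M = np.array([bl.Mx, bl.My, bl.Mz])
            cosang = np.dot(p, F) / (np.linalg.norm(p) * np.linalg.norm(F))
            sinang = np.sqrt(max(0.0, 1 - cosang ** 2))
            expected = np.linalg.norm(p) * np.linalg.norm(F) * sinang
            assert np.linalg.norm(M) == pytest.approx(expected, rel=1e-9,
                                                      abs=1e-9)


class TestEulerBernoulliOracle:
    def test_cylinder_tip_deflection(self, straight_cylinder):
        """δ = FL³/(3EI): 20 μN transverse tip load moves the tip 0.226 mm."""
        rod = RodModel(straight_cylinder)
        F = 20.0
        res = rod.deflect_under_force([0.0, F, 0.0], 20.0)
        assert res.converged
        I = np.pi * 0.1 ** 4 / 4.0
        delta = F * 20.0 ** 3 / (3.0 * E_UN * I)
        assert delta == pytest.approx(0.22635, rel=1e-3)
        assert res.deflected_nodes[-1, 1] == pytest.approx(delta, rel=0.01)


class TestPlanarLargeDeflectionOracle:
    def _oracle_shape(self, whisker, F2, s_c, n=4000):
        """Independent planar elastica: continuous ODE, dense RK integration.

        θ'(s) = M(s)/EI(s) with M(s) the z-moment of the point load about
        arc position s; the contact position enters implicitly and is solved
        by fixed-point iteration.
        """
        L = whisker.total_arc_length
        mat = whisker.material
        rb, rt = mat.base_radius_um * 1e-3, mat.tip_radius_um * 1e-3

        def EI(s):
            r = rb - (rb - rt) * s / L
            return E_UN * np.pi * r ** 4 / 4.0

        pc = np.array([s_c, 0.0])
        for _ in range(80):
            def rhs(s, y):
                x, yy, th = y
                if s < s_c:
                    M = (pc[0] - x) * F2[1] - (pc[1] - yy) * F2[0]
                else:
                    M = 0.0
                return [np.cos(th), np.sin(th), M / EI(s)]

            sol = solve_ivp(rhs, (0, L), [0.0, 0.0, 0.0], rtol=1e-10,
                            atol=1e-12, dense_output=True, max_step=L / 200)
            new_pc = sol.sol(s_c)[:2]
            if np.linalg.norm(new_pc - pc) < 1e-10:
                pc = new_pc
                break
            pc = 0.5 * pc + 0.5 * new_pc
        return pc, sol

    def test_contact_solution_matches_ode_oracle(self):
        w = straight_tapered()
        target = spherical_to_cartesian(ContactPoint(10.0, 5.0, 0.0))
        res = deflect_to_point(w, target)
        assert res.converged
        F2 = res.applied_force[:2]
        assert abs(res.applied_force[2]) < 1e-9
        pc, _ = self._oracle_shape(w, F2, res.contact_arc_length)
        # the oracle, fed the solver's force and contact arc, reaches the
        # same contact point
        deflection = np.linalg.norm(target[:2] - np.array([10.0, 0.0]))
        err = np.linalg.norm(pc - target[:2])
        assert err < 0.01 * max(deflection, 1.0)
        # base bending moment agreement
        mb_oracle = abs(pc[0] * F2[1] - pc[1] * F2[0])
        mb_solver = abs(res.base_loads.Mz)
        assert mb_solver == pytest.approx(mb_oracle, rel=0.01)


class TestContactSolver:
    def test_null_deflection_on_whisker(self, gamma_whisker, gamma_rod):
        node = gamma_whisker.nodes[60]
        res = gamma_rod.deflect(node)
        assert res.converged
        assert np.linalg.norm(res.applied_force) == 0.0
        np.testing.assert_allclose(res.deflected_nodes, gamma_whisker.nodes)

    def test_target_reached_and_frictionless(self, gamma_rod):
        res = gamma_rod.deflect(spherical_to_cartesian(
            ContactPoint(12.0, 2.0, 8.0)))
        assert res.converged
        target = spherical_to_cartesian(ContactPoint(12.0, 2.0, 8.0))
        assert np.linalg.norm(res.contact_location - target) < 1e-4
        f = res.applied_force
        assert abs(np.dot(f, res.contact_tangent)) / np.linalg.norm(f) < 1e-6

    def test_static_equilibrium_closure(self, gamma_rod):
        res = gamma_rod.deflect(spherical_to_cartesian(
            ContactPoint(10.0, 18.0, -6.0)))
        assert res.converged
        F, M = res.base_loads.as_arrays()
        np.testing.assert_allclose(F, res.applied_force, rtol=1e-12)
        np.testing.assert_allclose(
            M, np.cross(res.contact_location, res.applied_force), rtol=1e-12)

    def test_linearity_in_youngs_modulus(self, small_whisker):
        target = spherical_to_cartesian(ContactPoint(11.0, 6.0, 5.0))
        res1 = deflect_to_point(small_whisker, target)
        mat2 = MaterialParams(youngs_modulus_gpa=6.0)
        w2 = small_whisker.with_material(mat2)
        res2 = deflect_to_point(w2, target)
        assert res1.converged and res2.converged
        F1, M1 = res1.base_loads.as_arrays()
        F2, M2 = res2.base_loads.as_arrays()
        np.testing.assert_allclose(F2, 2.0 * F1, rtol=1e-6)
        np.testing.assert_allclose(M2, 2.0 * M1, rtol=1e-6)
        np.testing.assert_allclose(res2.deflected_nodes, res1.deflected_nodes,
                                   atol=1e-6)

    def test_planar_closure(self, planar_whisker):
        """In-plane contacts on a planar whisker: Fz, Mx, My all vanish."""
        for theta in (-20.0, -5.0, 12.0, 25.0):
            res = deflect_to_point(planar_whisker,
                                   spherical_to_cartesian(
                                       ContactPoint(10.0, theta, 0.0)))
            assert res.converged
            bl = res.base_loads
            scale = max(1.0, abs(bl.Fy))
            assert abs(bl.Fz) < 1e-8 * scale
            assert abs(bl.Mx) < 1e-7 * scale
            assert abs(bl.My) < 1e-7 * scale

    def test_small_deflection_moment_balance(self):
        """Base bending moment -> force × contact arc length for tiny pushes."""
        w = straight_tapered()
        s = 10.0
        d = s * np.tan(np.deg2rad(1.0))
        res = deflect_to_point(w, np.array([s, d, 0.0]))
        assert res.converged
        f = np.linalg.norm(res.applied_force)
        assert abs(res.base_loads.Mz) == pytest.approx(f * s, rel=0.01)

    def test_unreachable_target_discarded(self, gamma_rod):
        res = gamma_rod.deflect(np.array([25.0, 5.0, 0.0]))
        assert not res.converged
        assert res.reason == "unreachable"

    def test_solver_options_validated(self):
        with pytest.raises(ParameterError):
            SolverOptions(tol_pos_mm=-1.0)
        with pytest.raises(ParameterError):
            SolverOptions(max_newton=0)


class TestReachableSpace:
    def test_on_whisker_grid_zero_loads(self, small_whisker):
        pts = small_whisker.nodes[[20, 30, 40]]
        import pandas as pd

        from whiskmap.geometry import cartesian_to_spherical

        grid = pd.DataFrame([{
            "r_mm": cartesian_to_spherical(p).r_mm,
            "theta_deg": cartesian_to_spherical(p).theta_deg,
            "phi_deg": cartesian_to_spherical(p).phi_deg} for p in pts])
        table = reachable_space(small_whisker, grid)
        assert table.df["converged"].all()
        assert np.abs(table.df[["Fx", "Fy", "Fz", "Mx", "My", "Mz"]]
                      .to_numpy()).max() < 1e-9
        assert table.df["excluded_small_deflection"].all()

    def test_far_grid_point_discarded(self, small_whisker):
        grid = build_grid((30.0, 30.0), 1.0, (0.0, 0.0), 1.0, (0.0, 0.0), 1.0)
        table = reachable_space(small_whisker, grid)
        assert not table.df["converged"].any()
        assert (table.df["discard_reason"] != "").all()

    def test_converged_cloud_single_component(self, reduced_table):
        """Reachable points form one connected cloud around the whisker."""
        from scipy import ndimage

        df = reduced_table.df
        rv = np.sort(df["r_mm"].unique())
        tv = np.sort(df["theta_deg"].unique())
        pv = np.sort(df["phi_deg"].unique())
        cube = np.zeros((len(rv), len(tv), len(pv)), bool)
        cube[np.searchsorted(rv, df["r_mm"]),
             np.searchsorted(tv, df["theta_deg"]),
             np.searchsorted(pv, df["phi_deg"])] = df["converged"]
        _, n = ndimage.label(cube, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_mx_grows_with_elevation(self, reduced_table):
        """|Mx| increases with |φ| at fixed (r, θ): twist from out-of-plane."""
        from scipy.stats import spearmanr

        d = reduced_table.df
        d = d[d["converged"]]
        rhos = []
        for (r, th), grp in d.groupby(["r_mm", "theta_deg"]):
            if len(grp) >= 8:
                rho = spearmanr(np.abs(grp["phi_deg"]),
                                np.abs(grp["Mx"])).statistic
                if np.isfinite(rho):
                    rhos.append(rho)
        assert len(rhos) > 50
        assert np.median(rhos) > 0.5
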