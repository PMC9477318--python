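"""Whisker geometry: shapes, frames, and spherical coordinates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from whiskmap.errors import (DomainError, GeometryError, InputError,
                             ParameterError)
from whiskmap.geometry import (ContactPoint, MaterialParams, WhiskerShape,
                               align_to_whisker_frame,
                               build_gamma_like_whisker,
                               cartesian_to_spherical, load_whisker_points,
                               resample_polyline, save_whisker_points,
                               spherical_to_cartesian)


def _rot(rx, ry, rz):
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", [rx, ry, rz]).as_matrix()


class TestMaterialParams:
    def test_tip_radius_from_taper(self):
        m = MaterialParams(base_radius_um=100.0, taper_ratio=15.0)
        assert m.tip_radius_um == pytest.approx(6.67, abs=0.005)

    @pytest.mark.parametrize("kwargs", [
        {"youngs_modulus_gpa": -1.0}, {"poisson_ratio": 0.6},
        {"poisson_ratio": 0.0}, {"base_radius_um": 0.0},
        {"taper_ratio": 0.5},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            MaterialParams(**kwargs)


class TestGammaLikeWhisker:
    def test_planar_limit(self):
        w = build_gamma_like_whisker(oop_cubic_coeff=0.0)
        assert np.abs(w.nodes[:, 2]).max() < 1e-9

    def test_default_shape_is_near_planar_proximally(self, gamma_whisker):
        w = gamma_whisker
        L = w.total_arc_length
        prox = np.abs(w.nodes[w.arc_lengths <= 0.7 * L, 2]).max()
        dist = np.abs(w.nodes[w.arc_lengths > 0.7 * L, 2]).max()
        assert prox < 0.05 * L
        assert dist > prox

    def test_linear_taper_formula(self, gamma_whisker):
        w = gamma_whisker
        rb, rt = w.material.base_radius_um, w.material.tip_radius_um
        expected = rb - (rb - rt) * w.arc_lengths / w.total_arc_length
        np.testing.assert_allclose(w.radii_um, expected, rtol=1e-9)
        assert w.radii_um[0] / w.radii_um[-1] == pytest.approx(15.0, rel=1e-6)

    def test_arc_length_and_frame_conventions(self, gamma_whisker):
        w = gamma_whisker
        assert w.total_arc_length == pytest.approx(20.0, rel=1e-3)
        assert np.linalg.norm(w.nodes[0]) < 1e-12
        # proximal direction along +x
        chord = w.nodes[5] - w.nodes[0]
        assert chord[0] / np.linalg.norm(chord) > 0.99
        assert w.nodes[-1, 1] > 0  # tip toward +y

    @pytest.mark.parametrize("kwargs", [
        {"arc_length_mm": 0.0}, {"taper_ratio": 1.0}, {"n_nodes": 10},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ParameterError):
            build_gamma_like_whisker(**kwargs)


class TestFrameAlignment:
    def test_idempotent(self, gamma_whisker):
        once = align_to_whisker_frame(gamma_whisker.nodes)
        twice = align_to_whisker_frame(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_flips_parabola_opening_down(self):
        x = np.linspace(0, 10, 60)
        pts = np.column_stack([x, -0.05 * x ** 2, np.zeros_like(x)])
        out = align_to_whisker_frame(pts)
        assert out[-1, 1] > 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(-np.pi, np.pi) for _ in range(3)]),
           st.tuples(*[st.floats(-30, 30) for _ in range(3)]))
    def test_rigid_motion_invariance(self, angles, shift):
        base = build_gamma_like_whisker(n_nodes=40)
        moved = base.nodes @ _rot(*angles).T + np.asarray(shift)
        recovered = align_to_whisker_frame(moved)
        np.testing.assert_allclose(recovered, base.nodes, atol=1e-6)

    def test_degenerate_geometry(self):
        with pytest.raises(GeometryError):
            align_to_whisker_frame(np.zeros((20, 3)))


class TestSphericalCoordinates:
    @pytest.mark.parametrize("cp,expected", [
        (ContactPoint(10, 0, 0), [10, 0, 0]),
        (ContactPoint(10, 90, 0), [0, 10, 0]),
        (ContactPoint(5, 0, 90 - 1e-9), [0, 0, 5]),
    ])
    def test_axis_points(self, cp, expected):
        np.testing.assert_allclose(spherical_to_cartesian(cp), expected,
                                   atol=1e-7)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(-179, 179), st.floats(-89, 89))
    def test_round_trip(self, r, theta, phi):
        cp = ContactPoint(r, theta, phi)
        back = cartesian_to_spherical(spherical_to_cartesian(cp))
        assert back.r_mm == pytest.approx(r, abs=1e-9 * max(1, r))
        assert back.theta_deg == pytest.approx(theta, abs=1e-7)
        assert back.phi_deg == pytest.approx(phi, abs=1e-7)

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            cartesian_to_spherical([0.0, 0.0, 0.0])

    def test_contact_point_domain(self):
        with pytest.raises(DomainError):
            ContactPoint(-1.0, 0.0, 0.0)
        with pytest.raises(DomainError):
            ContactPoint(1.0, 0.0, 95.0)


class TestPointFiles:
    def test_collinear_points_straight_whisker(self, tmp_path):
        x = np.linspace(0, 12, 100)
        path = tmp_path / "w.csv"
        path.write_text("x_mm,y_mm,z_mm\n" +
                        "\n".join(f"{xi},0,0" for xi in x))
        w = load_whisker_points(path)
        assert w.total_arc_length == pytest.approx(12.0, rel=1e-9)
        assert np.abs(w.nodes[:, 1:]).max() < 1e-12

    def test_save_load_round_trip(self, tmp_path, small_whisker):
        path = tmp_path / "w.csv"
        save_whisker_points(small_whisker, path)
        back = load_whisker_points(path, small_whisker.material,
                                   n_nodes=small_whisker.n_nodes)
        np.testing.assert_allclose(back.nodes, small_whisker.nodes, atol=1e-6)

    def test_arc_length_matches_quadrature(self, tmp_path):
        a = 0.03
        x = np.linspace(0, 15, 50)
        pts = np.column_stack([x, a * x ** 2, np.zeros_like(x)])
        path = tmp_path / "q.csv"
        path.write_text("x_mm,y_mm,z_mm\n" +
                        "\n".join(f"{p[0]},{p[1]},{p[2]}" for p in pts))
        w = load_whisker_points(path, n_nodes=400)
        exact, _ = quad(lambda t: np.sqrt(1 + (2 * a * t) ** 2), 0, 15)
        # chord-length arc of the 50-point polyline, refined by resampling
        assert w.total_arc_length == pytest.approx(exact, rel=1e-3)

    @pytest.mark.parametrize("body", [
        "x_mm,y_mm,z_mm\n1,0,0\n2,0,0",          # too few points
        "x_mm,y_mm\n" + "\n".join(f"{i},0" for i in range(20)),  # bad columns
        "x_mm,y_mm,z_mm\n" + "\n".join("1,1,1" for _ in range(20)),  # dupes
    ])
    def test_input_errors(self, tmp_path, body):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(InputError):
            load_whisker_points(path)

    def test_resample_preserves_arc_length(self, gamma_whisker):
        res = resample_polyline(gamma_whisker.nodes, 250)
        seg = np.linalg.norm(np.diff(res, axis=0), axis=1).sum()
        assert seg == pytest.approx(gamma_whisker.total_arc_length, rel=1e-3)


def test_whisker_shape_invariants_enforced():
    nodes = np.column_stack([np.linspace(0, 10, 20), np.zeros(20), np.zeros(20)])
    arcs = np.linspace(0, 10, 20)
    radii_up = np.linspace(50, 100, 20)  # increasing: violates taper
    with pytest.raises(GeometryError):
        WhiskerShape(nodes, arcs, radii_up, MaterialParams())
    with pytest.raises(GeometryError):
        WhiskerShape(nodes + [1, 0, 0], arcs,
                     np.linspace(100, 6.67, 20), MaterialParams())
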