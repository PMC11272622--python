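"""Cross-section geometry: girth, curvature, radial indentation, I/O."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from ctpress.leg_geometry import (
    MAX_CURVATURE_RADIUS,
    CrossSection,
    LegModel,
    apply_radial_displacement,
    circle_section,
    ellipse_section,
    girth,
    girth_change_from_displacement,
    local_radius,
    read_leg_csv,
    write_leg_csv,
    write_obj,
)


def ellipse_perimeter(a, b):
    """Independent quadrature oracle for the ellipse perimeter."""
    integrand = lambda t: math.hypot(a * math.sin(t), b * math.cos(t))
    val, _ = quad(integrand, 0.0, 2.0 * math.pi, limit=200)
    return val


class TestGirth:
    def test_unit_circle(self):
        c = circle_section(1.0, n=360)
        assert girth(c) == pytest.approx(2.0 * math.pi, rel=1e-4)

    def test_ellipse_matches_quadrature_oracle(self):
        e = ellipse_section(0.06, 0.04, n=720)
        assert girth(e) == pytest.approx(ellipse_perimeter(0.06, 0.04), rel=1e-4)

    @given(st.floats(min_value=0.5, max_value=4.0))
    def test_homogeneous_under_scaling(self, s):
        c = circle_section(0.05, n=128)
        scaled = CrossSection(z=c.z, points=c.points * s)
        assert girth(scaled) == pytest.approx(s * girth(c), rel=1e-12)


class TestLocalRadius:
    def test_circle_radius_recovered_everywhere(self):
        c = circle_section(0.04, n=256)
        for frac in (0.0, 0.17, 0.5, 0.83):
            assert local_radius(c, frac) == pytest.approx(0.04, rel=1e-6)

    def test_ellipse_major_axis_curvature(self):
        # radius of curvature at the end of the major axis is b^2 / a
        e = ellipse_section(0.06, 0.04, n=720)
        assert local_radius(e, 0.0) == pytest.approx(0.04**2 / 0.06, rel=1e-3)

    def test_collinear_triple_clips_to_maximum(self):
        # a square boundary: collinear triples on the flat sides hit the clip
        s = np.linspace(-1, 1, 16, endpoint=False)
        pts = np.concatenate([
            np.column_stack([s, np.full_like(s, -1.0)]),          # bottom, left->right
            np.column_stack([np.full_like(s, 1.0), s]),           # right, up
            np.column_stack([-s, np.full_like(s, 1.0)]),          # top, right->left
            np.column_stack([np.full_like(s, -1.0), -s]),         # left, down
        ])
        sq = CrossSection(z=0.0, points=pts * 0.05)
        radii = [local_radius(sq, f) for f in np.linspace(0, 0.99, 40)]
        assert max(radii) == MAX_CURVATURE_RADIUS


class TestRadialDisplacement:
    def test_zero_displacement_is_identity(self):
        c = circle_section(0.05, n=128)
        d = apply_radial_displacement(c, 0.0)
        np.testing.assert_allclose(d.points, c.points)

    @pytest.mark.parametrize(
        "w_mm,delta_cm", [(3.61, 2.27), (11.06, 6.95)]
    )
    def test_circle_girth_drop_matches_reported_circumference_change(self, w_mm, delta_cm):
        # indentation depths map to circumference deltas through dC = 2 pi w
        c = circle_section(0.05, n=720)
        d = apply_radial_displacement(c, w_mm * 1e-3)
        assert (girth(c) - girth(d)) * 100 == pytest.approx(delta_cm, abs=5e-3)

    @given(st.floats(min_value=1e-4, max_value=0.02))
    def test_circle_girth_drop_equals_2_pi_w(self, w):
        c = circle_section(0.05, n=2048)
        d = apply_radial_displacement(c, w)
        assert girth(d) == pytest.approx(girth(c) - 2 * math.pi * w, rel=1e-6)

    def test_ellipse_agrees_with_reperimeter_oracle(self):
        e = ellipse_section(0.06, 0.04, n=720)
        w = 2e-3
        d = apply_radial_displacement(e, w)
        # eroding an ellipse by w shrinks the perimeter by ~2 pi w
        assert girth(d) == pytest.approx(girth(e) - 2 * math.pi * w, rel=1e-3)

    def test_composition_on_circles(self):
        c = circle_section(0.05, n=512)
        both = apply_radial_displacement(apply_radial_displacement(c, 0.004), 0.006)
        once = apply_radial_displacement(c, 0.010)
        np.testing.assert_allclose(both.points, once.points, atol=1e-12)

    def test_composition_on_convex_sections(self):
        e = ellipse_section(0.06, 0.045, n=720)
        both = apply_radial_displacement(apply_radial_displacement(e, 0.002), 0.003)
        once = apply_radial_displacement(e, 0.005)
        assert girth(both) == pytest.approx(girth(once), rel=1e-4)

    def test_oversized_displacement_rejected(self):
        c = circle_section(0.05, n=128)
        with pytest.raises(ValueError, match="inscribed"):
            apply_radial_displacement(c, 0.06)

    @pytest.mark.parametrize("w_mm,delta_cm", [(3.61, 2.27), (11.06, 6.95), (0.0, 0.0)])
    def test_scalar_identity(self, w_mm, delta_cm):
        assert girth_change_from_displacement(w_mm * 1e-3) * 100 == pytest.approx(
            delta_cm, abs=5e-3
        )


class TestLegModelAndIO:
    def _leg(self):
        sections = tuple(
            circle_section(r, z=z, n=64, label=lab)
            for r, z, lab in [(0.035, 0.04, "B"), (0.042, 0.12, "B1"),
                              (0.055, 0.24, "C"), (0.054, 0.35, "D")]
        )
        return LegModel(sections=sections, rigidity="rigid")

    def test_unsorted_heights_rejected(self):
        secs = [circle_section(0.03, z=0.3, n=32, label="B"),
                circle_section(0.05, z=0.1, n=32, label="D")]
        with pytest.raises(ValueError, match="increasing"):
            LegModel(sections=tuple(secs), rigidity="rigid")

    def test_csv_round_trip_preserves_girths_bitwise(self, tmp_path):
        leg = self._leg()
        path = tmp_path / "leg.csv"
        write_leg_csv(leg, path)
        back = read_leg_csv(path)
        for s1, s2 in zip(leg.sections, back.sections):
            assert s1.label == s2.label
            assert girth(s1) == girth(s2)
            np.testing.assert_array_equal(s1.points, s2.points)

    def test_missing_label_column_tolerated(self, tmp_path, caplog):
        leg = self._leg()
        path = tmp_path / "leg.csv"
        write_leg_csv(leg, path)
        lines = path.read_text().splitlines()
        stripped = [",".join(ln.split(",")[:4]) for ln in lines]
        path.write_text("\n".join(stripped))
        with pytest.warns(UserWarning):  # leg misses B/D labels
            back = read_leg_csv(path)
        assert all(s.label is None for s in back.sections)

    def test_malformed_row_names_row_number(self, tmp_path):
        leg = self._leg()
        path = tmp_path / "leg.csv"
        write_leg_csv(leg, path)
        lines = path.read_text().splitlines()
        lines[5] = lines[5].replace(lines[5].split(",")[2], "oops", 1)
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="row 6"):
            read_leg_csv(path)

    def test_descending_sections_named_by_row(self, tmp_path):
        leg = self._leg()
        path = tmp_path / "leg.csv"
        write_leg_csv(leg, path)
        lines = path.read_text().splitlines()
        header, rows = lines[0], lines[1:]
        path.write_text("\n".join([header] + rows[64:128] + rows[:64] + rows[128:]))
        with pytest.raises(ValueError, match="not sorted"):
            read_leg_csv(path)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="16"):
            CrossSection(z=0.0, points=np.array([[0, 0], [1, 0], [0, 1]], float))

    def test_obj_export_writes_mesh(self, tmp_path):
        leg = self._leg()
        path = tmp_path / "leg.obj"
        write_obj(leg, path)
        text = path.read_text()
        assert text.count("v ") == 4 * 64
        assert text.count("f ") == 3 * 64 * 2
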