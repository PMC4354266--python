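"""Glyph element geometry against independent numeric oracles."""

import math

import numpy as np
import pytest

from phenoglyph import geometry as G
from phenoglyph.scene import Style

ST = Style()


def arc_length(primitive, n=4096):
    pts = np.asarray(primitive.sample(n))
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def polygon_area(points):
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


class TestBorderFill:
    def test_endpoints(self):
        assert G.geom_border_fill(0.0, 0, 0, 0.3, 0.2, ST, ()) is None
        full = G.geom_border_fill(1.0, 0, 0, 0.3, 0.2, ST, ())
        assert full.u1 == pytest.approx(2 * math.pi)

    def test_half_circle_has_semicircular_length(self):
        r = 0.25
        arc = G.geom_border_fill(0.5, 0, 0, r, r, ST, ())
        assert arc_length(arc) == pytest.approx(math.pi * r, rel=0.01)

    def test_quarter_on_eccentric_ellipse_is_arc_length_not_angle(self):
        a, b = 0.3, 0.15  # 2:1 ellipse
        perimeter = G.ellipse_perimeter(a, b)
        arc = G.geom_border_fill(0.25, 0, 0, a, b, ST, ())
        assert arc_length(arc) == pytest.approx(perimeter / 4, rel=0.01)
        # away from the symmetry points an angular sweep would disagree:
        # 1/8 of the arc length is NOT at 1/8 of the parameter sweep
        eighth = G.geom_border_fill(0.125, 0, 0, a, b, ST, ())
        assert abs(eighth.u1 - math.pi / 4) > 0.05
        assert arc_length(eighth) == pytest.approx(perimeter / 8, rel=0.01)

    @pytest.mark.parametrize("frac", np.arange(0.05, 1.0, 0.05))
    def test_fraction_accuracy_on_grid(self, frac):
        a, b = 0.3, 0.18
        perimeter = G.ellipse_perimeter(a, b)
        arc = G.geom_border_fill(float(frac), 0, 0, a, b, ST, ())
        assert arc_length(arc) / perimeter == pytest.approx(frac, abs=0.02)


class TestAreaFill:
    def test_endpoints_and_counts(self):
        sites = G.hex_lattice(0, 0, 0.25, 0.18, 0.05)
        assert G.geom_area_fill(0.0, 0, 0, 0.25, 0.18, "x", ST, ()) == []
        assert len(G.geom_area_fill(1.0, 0, 0, 0.25, 0.18, "x", ST, ())) \
            == len(sites)
        half = G.geom_area_fill(0.5, 0, 0, 0.25, 0.18, "x", ST, ())
        assert len(half) == round(0.5 * len(sites))

    def test_fills_bottom_up(self):
        placed = G.geom_area_fill(0.4, 0, 0, 0.25, 0.18, "x", ST, ())
        ys = [p.y for p in placed]
        sites = G.hex_lattice(0, 0, 0.25, 0.18, 0.05)
        unplaced_ys = [y for _, y in sites[len(placed):]]
        assert max(ys) <= min(unplaced_ys) + 1e-12

    def test_deterministic(self):
        a = G.geom_area_fill(0.37, 0, 0, 0.25, 0.18, "x", ST, ())
        b = G.geom_area_fill(0.37, 0, 0, 0.25, 0.18, "x", ST, ())
        assert a == b


class TestSpikes:
    def test_degenerate_empty(self):
        assert G.geom_spikes(0.0, 1.0, 0, 0, 0.3, 0.2, ST, ()) == []
        assert G.geom_spikes(0.5, 0.0, 0, 0, 0.3, 0.2, ST, ()) == []

    def test_full_fraction_rings_the_perimeter(self):
        spikes = G.geom_spikes(1.0, 1.0, 0, 0, 0.3, 0.2, ST, ())
        assert len(spikes) == G.SPIKE_SLOTS

    def test_half_fraction_spans_half_perimeter_within_one_pitch(self):
        a, b = 0.3, 0.15
        spikes = G.geom_spikes(0.5, 1.0, 0, 0, a, b, ST, ())
        perimeter = G.ellipse_perimeter(a, b)
        # base endpoints all lie on the ellipse; accumulated base arc
        base_len = 0.0
        for s in spikes:
            p0, _, p1 = s.points
            base_len += math.hypot(p1[0] - p0[0], p1[1] - p0[1])
        # chord sum slightly under arc length; one pitch tolerance
        pitch = perimeter / G.SPIKE_SLOTS
        assert abs(base_len - perimeter / 2) < pitch

    def test_height_scales_with_minor_axis(self):
        a, b = 0.3, 0.2
        spikes = G.geom_spikes(0.1, 1.0, 0, 0, a, b, ST, ())
        apex = spikes[0].points[1]
        p0, _, p1 = spikes[0].points
        mid = ((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2)
        h = math.hypot(apex[0] - mid[0], apex[1] - mid[1])
        assert h == pytest.approx(G.SPIKE_HEIGHT_FACTOR * b, rel=0.05)


class TestSubcircles:
    def test_zero_and_one(self):
        assert G.geom_subcircles(0, 0, 0, 0.2, 0.15, ST, ()) == []
        (one,) = G.geom_subcircles(1, 0, 0, 0.2, 0.15, ST, ())
        assert (one.cx, one.cy) == (0, 0)

    @pytest.mark.parametrize("count", [2, 3, 5, 7, 13])
    def test_nonoverlapping_and_inside(self, count):
        a, b = 0.12, 0.1
        circles = G.geom_subcircles(count, 0, 0, a, b, ST, ())
        assert len(circles) == count
        for i, ci in enumerate(circles):
            assert (ci.cx / a) ** 2 + (ci.cy / b) ** 2 <= 1.0 + 1e-9
            for cj in circles[i + 1:]:
                d = math.hypot(ci.cx - cj.cx, ci.cy - cj.cy)
                assert d >= ci.r + cj.r - 1e-12

    def test_deterministic(self):
        assert G.geom_subcircles(2, 0, 0, 0.2, 0.15, ST, ()) \
            == G.geom_subcircles(2, 0, 0, 0.2, 0.15, ST, ())


class TestProtrusion:
    def test_absent_at_zero(self):
        assert G.geom_protrusion(0.0, 0, 0, 0.25, 0.2, ST, ()) == []

    @pytest.mark.parametrize("rel", [0.25, 0.5, 1.0])
    def test_major_dimension_proportional(self, rel):
        a = 0.25
        arc, base = G.geom_protrusion(rel, 0, 0, a, 0.2, ST, ())
        assert arc.a == pytest.approx(rel * a)
        # height fixed at half its own major dimension
        assert arc.b == pytest.approx(arc.a)
        (x0, _), (x1, _) = base.points
        assert x1 - x0 == pytest.approx(2 * rel * a)


class TestOrganelles:
    def test_empty_and_full(self):
        empty = G.geom_organelle(0.0, "rectangle", 0, 0, 0.2, ST,
                                 Style(stroke="none", fill="k"), ())
        assert len(empty) == 1  # outline only
        full = G.geom_organelle(1.0, "rectangle", 0, 0, 0.2, ST,
                                Style(stroke="none", fill="k"), ())
        outline, fill = full
        assert polygon_area(fill.points) == pytest.approx(
            polygon_area(outline.points))

    def test_rectangle_half_value_fills_half_area(self):
        outline, fill = G.geom_organelle(0.5, "rectangle", 0, 0, 0.2, ST,
                                         Style(stroke="none", fill="k"), ())
        assert polygon_area(fill.points) == pytest.approx(
            0.5 * polygon_area(outline.points))

    def test_ellipse_half_value_fills_half_disc(self):
        # at mid height the circular segment is exactly half the disc
        prims = G.geom_organelle(0.5, "ellipse", 0, 0, 0.2, ST,
                                 Style(stroke="none", fill="k"), ())
        circle, fill = prims
        assert polygon_area(fill.points) == pytest.approx(
            math.pi * circle.r ** 2 / 2, rel=1e-3)

    def test_ellipse_height_not_area_is_proportional(self):
        prims = G.geom_organelle(0.25, "ellipse", 0, 0, 0.2, ST,
                                 Style(stroke="none", fill="k"), ())
        _, fill = prims
        top = max(p[1] for p in fill.points)
        assert top == pytest.approx(-0.1 + 0.25 * 0.2, abs=1e-6)
        # segment area at quarter height is NOT a quarter of the disc
        r = 0.1
        seg = polygon_area(fill.points)
        assert abs(seg - math.pi * r ** 2 / 4) > 0.1 * math.pi * r ** 2 / 4


def test_membrane_process_length_proportional():
    a, b = 0.25, 0.2
    stalk_half, _ = G.geom_membrane_process(0.5, 0, 0, a, b, ST, ())
    stalk_full, _ = G.geom_membrane_process(1.0, 0, 0, a, b, ST, ())
    len_half = stalk_half.points[1][0] - stalk_half.points[0][0]
    len_full = stalk_full.points[1][0] - stalk_full.points[0][0]
    assert len_full == pytest.approx(2 * len_half)
    assert G.geom_membrane_process(0.0, 0, 0, a, b, ST, ()) == []
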