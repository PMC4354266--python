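"""Geometric constructions for the individual glyph elements.

All constructions are deterministic functions of their arguments; no
randomness is used anywhere in rendering.  Coordinates are glyph-local
(y up) with the main ellipse centred at the origin.

Conventions (design choices where the visual language leaves freedom):

* Border filling is *arc-length* proportional, not angle proportional:
  the thickened arc starts at 12 o'clock and runs clockwise until its
  arc length equals ``fraction`` of the full elliptic perimeter.  On an
  eccentric ellipse an angular sweep would over-represent the flat ends.
* Area filling places symbols on a fixed hexagonal lattice inside the
  region, filled from the bottom upward, so partial fills read as a
  rising level.
* Spikes sit on a contiguous arc starting at 12 o'clock, clockwise;
  maximal spike height is 25% of the minor semi-axis.
* Sub-circles are packed centre-first, then on concentric rings.
* The protrusion half-ellipse sits on top of the cell; its major
  dimension is ``rel_area`` times the main major dimension and its
  height is half its own major dimension.
* Organelles fill bottom-up; the fill *height* is proportional to the
  value (for the ellipse organelle the filled area is then the circular
  segment below the chord at that height).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .scene import Circle, EllipseArc, Polygon, Polyline, Style, Symbol

logger = logging.getLogger(__name__)

#: Spikes never exceed this fraction of the minor semi-axis.
SPIKE_HEIGHT_FACTOR = 0.25
#: Number of spike pitches around a full perimeter.
SPIKE_SLOTS = 24


# ---------------------------------------------------------------------------
# ellipse arc-length machinery

def ellipse_point(cx: float, cy: float, a: float, b: float, u: float):
    """Point on the ellipse at clock parameter ``u`` (0 = top, clockwise)."""
    return cx + a * math.sin(u), cy + b * math.cos(u)


def ellipse_perimeter(a: float, b: float, n: int = 4096) -> float:
    """Perimeter by dense quadrature of the speed ``|dP/du|``."""
    u = np.linspace(0.0, 2.0 * math.pi, n)
    speed = np.hypot(a * np.cos(u), b * np.sin(u))
    return float(np.trapezoid(speed, u))


def _cumulative_arc(a: float, b: float, n: int = 4096):
    """Clockwise-from-top parameter grid and cumulative arc length."""
    u = np.linspace(0.0, 2.0 * math.pi, n)
    speed = np.hypot(a * np.cos(u), b * np.sin(u))
    ds = np.diff(u) * 0.5 * (speed[:-1] + speed[1:])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    return u, s


def param_at_arc_fraction(a: float, b: float, fraction: float) -> float:
    """Clock parameter u where the clockwise arc length reaches
    ``fraction`` of the perimeter."""
    u, s = _cumulative_arc(a, b)
    target = fraction * s[-1]
    return float(np.interp(target, s, u))


# ---------------------------------------------------------------------------
# element constructions

def geom_border_fill(fraction: float, cx: float, cy: float, a: float, b: float,
                     style: Style, groups: tuple[str, ...]) -> EllipseArc | None:
    """Thickened border arc whose arc length is ``fraction`` of the perimeter."""
    if fraction <= 0.0:
        return None
    u1 = 2.0 * math.pi if fraction >= 1.0 else param_at_arc_fraction(a, b, fraction)
    return EllipseArc(cx, cy, a, b, 0.0, u1, style=style, groups=groups)


def hex_lattice(cx: float, cy: float, a: float, b: float,
                spacing: float) -> list[tuple[float, float]]:
    """Hexagonal lattice points strictly inside the ellipse, bottom-up order.

    Rows are ``spacing * sqrt(3)/2`` apart, odd rows offset by half a
    spacing; sites within 90% of the boundary are kept so symbols stay
    clear of the outline.
    """
    dy = spacing * math.sqrt(3.0) / 2.0
    pts: list[tuple[float, float]] = []
    n_rows = int(math.floor(2.0 * b / dy)) + 1
    y0 = cy - dy * (n_rows - 1) / 2.0
    for j in range(n_rows):
        y = y0 + j * dy
        x_off = (spacing / 2.0) if (j % 2) else 0.0
        n_cols = int(math.floor(2.0 * a / spacing)) + 1
        xs = [cx + x_off + (i - n_cols // 2) * spacing for i in range(n_cols + 1)]
        for x in xs:
            if ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 0.9 ** 2:
                pts.append((x, y))
    pts.sort(key=lambda p: (p[1], p[0]))
    return pts


def geom_area_fill(fraction: float, cx: float, cy: float, a: float, b: float,
                   symbol: str, style: Style, groups: tuple[str, ...],
                   spacing: float | None = None) -> list[Symbol]:
    """Fill the ellipse interior bottom-up with symbols on a hex lattice.

    The number of placed sites is ``round(fraction * lattice_size)``, so
    the covered-lattice fraction tracks the value exactly up to the
    rounding grain.
    """
    if spacing is None:
        spacing = max(a, b) / 5.0
    sites = hex_lattice(cx, cy, a, b, spacing)
    n = int(round(max(0.0, min(1.0, fraction)) * len(sites)))
    size = spacing * 0.55
    return [Symbol(x, y, size, marker=symbol, style=style, groups=groups)
            for x, y in sites[:n]]


def geom_spikes(fraction: float, height: float, cx: float, cy: float,
                a: float, b: float, style: Style,
                groups: tuple[str, ...]) -> list[Polygon]:
    """Outward triangular spikes along a contiguous arc from 12 o'clock.

    The spike bases tile the clockwise arc covering ``fraction`` of the
    perimeter at a pitch of 1/24 of the perimeter; spike height is
    ``height * 0.25 * minor semi-axis``.
    """
    if fraction <= 0.0 or height <= 0.0:
        return []
    u_grid, s_grid = _cumulative_arc(a, b)
    perimeter = s_grid[-1]
    pitch = perimeter / SPIKE_SLOTS
    n_spikes = max(1, int(round(min(1.0, fraction) * SPIKE_SLOTS)))
    h = height * SPIKE_HEIGHT_FACTOR * min(a, b)
    spikes = []
    for i in range(n_spikes):
        s0, s1 = i * pitch, (i + 1) * pitch
        u0 = float(np.interp(s0, s_grid, u_grid))
        u1 = float(np.interp(s1, s_grid, u_grid))
        um = float(np.interp((s0 + s1) / 2.0, s_grid, u_grid))
        p0 = ellipse_point(cx, cy, a, b, u0)
        p1 = ellipse_point(cx, cy, a, b, u1)
        # outward normal at the midpoint
        nx, ny = math.sin(um) / a, math.cos(um) / b
        norm = math.hypot(nx, ny)
        mx, my = ellipse_point(cx, cy, a, b, um)
        apex = (mx + h * nx / norm, my + h * ny / norm)
        spikes.append(Polygon((p0, apex, p1), style=style, groups=groups))
    return spikes


def _ring_allocation(count: int) -> list[int]:
    """Centre-then-rings allocation: 1, then 6, 12, 18, ... per ring."""
    alloc, remaining, ring = [], count, 0
    while remaining > 0:
        cap = 1 if ring == 0 else 6 * ring
        take = min(cap, remaining)
        alloc.append(take)
        remaining -= take
        ring += 1
    return alloc


def geom_subcircles(count: int, cx: float, cy: float, a: float, b: float,
                    style: Style, groups: tuple[str, ...],
                    r_floor: float = 0.02) -> list[Circle]:
    """``count`` non-overlapping circles packed inside the ellipse.

    Packing is deterministic: one circle at the centre, the rest on
    concentric rings (first slot at 12 o'clock, clockwise).  The circle
    radius shrinks as rings are added; below ``r_floor`` (relative to
    the minor semi-axis) the radius is clamped and a warning logged.
    """
    if count <= 0:
        return []
    rin = min(a, b) * 0.92        # pack inside the inscribed circle
    alloc = _ring_allocation(count)
    n_rings = len(alloc) - 1
    if count == 1:
        return [Circle(cx, cy, rin * 0.45, style=style, groups=groups)]
    d = rin / (n_rings + 0.45)    # radial ring spacing
    r = 0.45 * d
    if r < r_floor * min(a, b):
        logger.warning("subcircle count %d exceeds comfortable packing; "
                       "radius clamped", count)
        r = r_floor * min(a, b)
    circles = []
    for ring, n_on_ring in enumerate(alloc):
        if ring == 0:
            circles.append(Circle(cx, cy, r, style=style, groups=groups))
            continue
        rr = ring * d
        for k in range(n_on_ring):
            ang = 2.0 * math.pi * k / n_on_ring   # clockwise from top
            circles.append(Circle(cx + rr * math.sin(ang),
                                  cy + rr * math.cos(ang), r,
                                  style=style, groups=groups))
    return circles


def geom_protrusion(rel_area: float, cx: float, cy: float, a: float, b: float,
                    style: Style, groups: tuple[str, ...]) -> list:
    """Half-ellipse on top of the cell; major dimension = rel_area * 2a."""
    if rel_area <= 0.0:
        return []
    ap = rel_area * a          # protrusion semi-major
    hp = ap                    # height = half its major dimension (2*ap/2)
    base_y = cy + b
    arc = EllipseArc(cx, base_y, ap, hp, -math.pi / 2.0, math.pi / 2.0,
                     style=style, groups=groups)
    base = Polyline(((cx - ap, base_y), (cx + ap, base_y)),
                    style=style, groups=groups)
    return [arc, base]


def geom_membrane_process(value: float, cx: float, cy: float,
                          a: float, b: float, style: Style,
                          groups: tuple[str, ...],
                          max_len: float | None = None) -> list:
    """Stalk-like process on the glyph's right side, length ∝ value."""
    if value <= 0.0:
        return []
    if max_len is None:
        max_len = 0.7 * a
    x0 = cx + a
    x1 = x0 + value * max_len
    stalk = Polyline(((x0, cy), (x1, cy)), style=style, groups=groups)
    knob = Circle(x1, cy, 0.04 * min(a, b) + 0.015 * a, style=style,
                  groups=groups)
    return [stalk, knob]


def circular_segment_polygon(cx: float, cy: float, r: float,
                             level: float, n: int = 96):
    """Polygon of the disc region below the horizontal line y = level."""
    lo, hi = cy - r, cy + r
    level = max(lo, min(hi, level))
    if level <= lo:
        return None
    s = (level - cy) / r
    phi = math.asin(max(-1.0, min(1.0, s)))
    # boundary from right chord end, clockwise along the bottom, to left end
    angles = np.linspace(phi, -math.pi - phi, n)
    pts = [(cx + r * math.cos(t), cy + r * math.sin(t)) for t in angles]
    return Polygon(tuple(pts), style=Style(stroke="none", fill="black"))


def geom_organelle(value: float, shape: str, cx: float, cy: float,
                   height: float, style: Style, fill_style: Style,
                   groups: tuple[str, ...]) -> list:
    """Organelle outline with its lower portion filled to value * height.

    ``shape`` is one of ``line``, ``ellipse``, ``rectangle``; ``cy`` is
    the organelle centre, ``height`` its full vertical extent.
    """
    value = max(0.0, min(1.0, value))
    lo = cy - height / 2.0
    level = lo + value * height
    prims: list = []
    if shape == "line":
        prims.append(Polyline(((cx, lo), (cx, lo + height)), style=style,
                              groups=groups))
        if value > 0:
            thick = Style(stroke=fill_style.fill if fill_style.fill != "none"
                          else style.stroke,
                          stroke_width=style.stroke_width * 3.5)
            prims.append(Polyline(((cx, lo), (cx, level)), style=thick,
                                  groups=groups))
    elif shape == "rectangle":
        w = height * 0.6
        outline = ((cx - w / 2, lo), (cx + w / 2, lo),
                   (cx + w / 2, lo + height), (cx - w / 2, lo + height))
        prims.append(Polygon(outline, style=style, groups=groups))
        if value > 0:
            filled = ((cx - w / 2, lo), (cx + w / 2, lo),
                      (cx + w / 2, level), (cx - w / 2, level))
            prims.append(Polygon(filled, style=fill_style, groups=groups))
    elif shape == "ellipse":
        r = height / 2.0
        prims.append(Circle(cx, cy, r, style=style, groups=groups))
        if value > 0:
            seg = circular_segment_polygon(cx, cy, r, level)
            if seg is not None:
                prims.append(Polygon(seg.points, style=fill_style,
                                     groups=groups))
    else:
        raise ValueError(f"unknown organelle shape: {shape!r}")
    return prims
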