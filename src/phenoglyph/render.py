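"""Glyph rendering: scaled feature row + spec -> Scene.

The glyph lives in a unit bounding box centred on its anchor.  The main
ellipse semi-axes are ``0.25 * scaled length`` and ``0.25 * scaled
width``, which guarantees that even a maximal protrusion (height equal
to the main semi-major axis) or maximal spikes stay inside the box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from . import geometry as G
from .elements import Family, element_by_name
from .glyphspec import GlyphSpec
from .scene import Scene, Style, EllipseArc, Text
from .table import FeatureTable

logger = logging.getLogger(__name__)

#: Main-ellipse semi-axis per unit of scaled dimensional value.
AX = 0.25
#: Default colour map for colour-bound elements (perceptually uniform).
DEFAULT_CMAP = "viridis"

_OUTLINE = Style(stroke="black", stroke_width=0.004)
_THICK = Style(stroke="black", stroke_width=0.016)
_FILL = Style(stroke="none", fill="#444444")


@dataclass(frozen=True)
class GlyphGeometry:
    """Semi-axes of the three concentric ellipses of one glyph."""

    main: tuple[float, float]
    inner: tuple[float, float] | None
    peri: tuple[float, float] | None


def _pair_value(values: dict[str, float], spec: GlyphSpec,
                length_el: str, width_el: str) -> tuple[float, float] | None:
    by_el = {b.element: values[b.feature] for b in spec.bindings}
    if length_el not in by_el:
        return None
    return by_el[length_el], by_el[width_el]


def build_geometry(values: dict[str, float], spec: GlyphSpec) -> GlyphGeometry:
    """Derive ellipse semi-axes from the bound dimensional values.

    Unbound ellipses that other bound elements need (e.g. an area fill
    without explicit dimensions) fall back to fixed default sizes.  The
    inner and perinuclear ellipses are rescaled (and a warning logged)
    if they would not fit inside the main ellipse.
    """
    bound = set(spec.elements)

    main = _pair_value(values, spec, "main-ellipse-length", "main-ellipse-width")
    if main is None:
        main = (0.8, 0.8)
    a, b = AX * main[0], AX * main[1]

    inner = _pair_value(values, spec, "inner-ellipse-length", "inner-ellipse-width")
    needs_inner = bound & {"inner-ellipse-area-fill", "inner-ellipse-colour",
                           "inner-subcircle-count"}
    if inner is not None:
        ai, bi = AX * inner[0], AX * inner[1]
    elif needs_inner:
        ai, bi = 0.45 * a, 0.45 * b
    else:
        ai = bi = None
    if ai is not None and (ai > 0.8 * a or bi > 0.8 * b):
        f = min(0.8 * a / ai, 0.8 * b / bi)
        logger.warning("inner ellipse rescaled by %.3f to fit the cell body", f)
        ai, bi = ai * f, bi * f

    peri = _pair_value(values, spec, "perinuclear-ellipse-length",
                       "perinuclear-ellipse-width")
    needs_peri = bound & {"perinuclear-ellipse-area-fill",
                          "perinuclear-ellipse-colour"}
    if peri is not None:
        ap, bp = AX * peri[0], AX * peri[1]
    elif needs_peri:
        ap, bp = 0.65 * a, 0.65 * b
    else:
        ap = bp = None
    if ap is not None and (ap > 0.92 * a or bp > 0.92 * b):
        f = min(0.92 * a / ap, 0.92 * b / bp)
        logger.warning("perinuclear ellipse rescaled by %.3f to fit", f)
        ap, bp = ap * f, bp * f

    return GlyphGeometry(
        main=(a, b),
        inner=None if ai is None else (ai, bi),
        peri=None if ap is None else (ap, bp),
    )


def _colour(value: float, cmap_name: str) -> str:
    rgba = colormaps[cmap_name](float(np.clip(value, 0.0, 1.0)))
    return "#{:02x}{:02x}{:02x}".format(*(int(round(c * 255)) for c in rgba[:3]))


def render_glyph(row, spec: GlyphSpec, anchor: tuple[float, float] = (0.0, 0.0),
                 size: float = 1.0, cmap: str = DEFAULT_CMAP) -> Scene:
    """Render one scaled feature row into a Scene.

    ``row`` is a mapping (dict / pandas Series) from the spec's feature
    names to scaled values.  Values outside the element's domain are
    clipped with a warning.  Output is deterministic: identical inputs
    produce identical primitive lists.
    """
    values: dict[str, float] = {}
    for b in spec.bindings:
        if b.feature not in row:
            raise KeyError(f"row lacks bound feature {b.feature!r}")
        v = float(row[b.feature])
        desc = element_by_name(b.element)
        if desc.value_domain.value == "count":
            values[b.feature] = max(0, int(round(v)))
        else:
            lo = 0.1 if desc.value_domain.value == "dimensional" else 0.0
            if v < lo or v > 1.0:
                logger.warning("value %.4g for %r outside [%g, 1]; clipped",
                               v, b.feature, lo)
                v = min(1.0, max(lo, v))
            values[b.feature] = v

    geom = build_geometry(values, spec)
    a, b_ = geom.main
    scene = Scene()
    by_el = {bd.element: bd for bd in spec.bindings}

    def groups_of(*els: str) -> tuple[str, ...]:
        return tuple(e for e in els if e in by_el)

    def val(el: str) -> float:
        return values[by_el[el].feature]

    # --- main ellipse outline (shared by the length/width bindings) ---
    main_groups = groups_of("main-ellipse-length", "main-ellipse-width")
    main_fill = "none"
    if "main-ellipse-colour" in by_el:
        main_fill = _colour(val("main-ellipse-colour"),
                            by_el["main-ellipse-colour"].style.get("cmap", cmap))
        main_groups = main_groups + ("main-ellipse-colour",)
    scene.add(EllipseArc(0.0, 0.0, a, b_, 0.0, 2.0 * np.pi,
                         style=Style(stroke="black", stroke_width=0.004,
                                     fill=main_fill),
                         groups=main_groups, closed=True))

    # --- perinuclear ellipse ---
    if geom.peri is not None:
        ap, bp = geom.peri
        peri_groups = groups_of("perinuclear-ellipse-length",
                                "perinuclear-ellipse-width")
        peri_fill = "none"
        if "perinuclear-ellipse-colour" in by_el:
            peri_fill = _colour(val("perinuclear-ellipse-colour"), cmap)
            peri_groups = peri_groups + ("perinuclear-ellipse-colour",)
        scene.add(EllipseArc(0.0, 0.0, ap, bp, 0.0, 2.0 * np.pi,
                             style=Style(stroke="black", stroke_width=0.003,
                                         fill=peri_fill, dash="0.01,0.006"),
                             groups=peri_groups, closed=True))
        if "perinuclear-ellipse-area-fill" in by_el:
            g = ("perinuclear-ellipse-area-fill",)
            scene.add(*G.geom_area_fill(val("perinuclear-ellipse-area-fill"),
                                        0.0, 0.0, ap, bp, "dot",
                                        Style(stroke="black", fill="black",
                                              stroke_width=0.002), g))

    # --- inner (nuclear) ellipse ---
    if geom.inner is not None:
        ai, bi = geom.inner
        inner_groups = groups_of("inner-ellipse-length", "inner-ellipse-width")
        inner_fill = "none"
        if "inner-ellipse-colour" in by_el:
            inner_fill = _colour(val("inner-ellipse-colour"),
                                 by_el["inner-ellipse-colour"].style.get("cmap",
                                                                         cmap))
            inner_groups = inner_groups + ("inner-ellipse-colour",)
        scene.add(EllipseArc(0.0, 0.0, ai, bi, 0.0, 2.0 * np.pi,
                             style=Style(stroke="black", stroke_width=0.004,
                                         fill=inner_fill),
                             groups=inner_groups, closed=True))
        if "inner-ellipse-area-fill" in by_el:
            g = ("inner-ellipse-area-fill",)
            scene.add(*G.geom_area_fill(val("inner-ellipse-area-fill"),
                                        0.0, 0.0, ai, bi, "x",
                                        Style(stroke="black",
                                              stroke_width=0.002), g))
        if "inner-subcircle-count" in by_el:
            g = ("inner-subcircle-count",)
            scene.add(*G.geom_subcircles(int(val("inner-subcircle-count")),
                                         0.0, 0.0, ai, bi,
                                         Style(stroke="black",
                                               stroke_width=0.002), g))

    # --- main-ellipse fills ---
    if "main-ellipse-area-fill" in by_el:
        g = ("main-ellipse-area-fill",)
        # exclude the nucleus region visually by using a coarser lattice
        scene.add(*G.geom_area_fill(val("main-ellipse-area-fill"),
                                    0.0, 0.0, a, b_, "x",
                                    Style(stroke="black", stroke_width=0.002),
                                    g))
    if "main-ellipse-border-fill" in by_el:
        g = ("main-ellipse-border-fill",)
        scene.add(G.geom_border_fill(val("main-ellipse-border-fill"),
                                     0.0, 0.0, a, b_, _THICK, g))

    # --- protrusion, spikes, membrane process ---
    if "protrusion" in by_el:
        scene.add(*G.geom_protrusion(val("protrusion"), 0.0, 0.0, a, b_,
                                     _OUTLINE, ("protrusion",)))
    if "spikes-fraction" in by_el or "spikes-height" in by_el:
        frac = val("spikes-fraction") if "spikes-fraction" in by_el else 1.0
        height = val("spikes-height") if "spikes-height" in by_el else 1.0
        g = groups_of("spikes-fraction", "spikes-height")
        scene.add(*G.geom_spikes(frac, height, 0.0, 0.0, a, b_,
                                 Style(stroke="black", stroke_width=0.002,
                                       fill="black"), g))
    if "membrane-process" in by_el:
        scene.add(*G.geom_membrane_process(val("membrane-process"),
                                           0.0, 0.0, a, b_,
                                           Style(stroke="black",
                                                 stroke_width=0.006),
                                           ("membrane-process",)))

    # --- organelles at three fixed slots in the lower cytoplasm ---
    organelle_h = 0.35 * b_
    slot_y = -0.62 * b_
    slots = {"line-organelle": (-0.45 * a, "line"),
             "ellipse-organelle": (0.0, "ellipse"),
             "rectangle-organelle": (0.45 * a, "rectangle")}
    for el, (sx, shape) in slots.items():
        if el in by_el:
            scene.add(*G.geom_organelle(val(el), shape, sx, slot_y, organelle_h,
                                        Style(stroke="black",
                                              stroke_width=0.002),
                                        _FILL, (el,)))

    out = scene.scaled(size)
    return out.translated(anchor[0], anchor[1])


# ---------------------------------------------------------------------------
# legend


def render_legend(spec: GlyphSpec, entry_height: float = 0.1,
                  cmap: str = DEFAULT_CMAP) -> Scene:
    """Automatic legend: one miniature element at mid value + the feature
    name, per binding, in binding order (top to bottom)."""
    scene = Scene()
    for i, binding in enumerate(spec.bindings):
        y = -i * entry_height
        mini = _legend_miniature(binding.element, cmap)
        scene.extend(mini.scaled(entry_height * 0.8).translated(0.05, y))
        scene.add(Text(0.14, y, binding.feature, size=entry_height * 0.4,
                       anchor="start", groups=(binding.element,)))
    return scene


def _legend_miniature(element: str, cmap: str) -> Scene:
    """Miniature of one element drawn at mid value in a unit box."""
    desc = element_by_name(element)
    s = Scene()
    g = (element,)
    thin = Style(stroke="black", stroke_width=0.02)
    if desc.family in (Family.MAIN_ELLIPSE_DIM, Family.INNER_ELLIPSE_DIM,
                       Family.PERINUCLEAR_ELLIPSE_DIM):
        s.add(EllipseArc(0, 0, 0.45, 0.28, 0, 2 * np.pi, style=thin, groups=g))
    elif desc.family is Family.COLOUR:
        s.add(EllipseArc(0, 0, 0.4, 0.4, 0, 2 * np.pi,
                         style=Style(stroke="black", stroke_width=0.02,
                                     fill=_colour(0.5, cmap)), groups=g))
    elif desc.family is Family.AREA_FILL:
        s.add(EllipseArc(0, 0, 0.45, 0.3, 0, 2 * np.pi, style=thin, groups=g))
        s.add(*G.geom_area_fill(0.5, 0, 0, 0.45, 0.3, "x",
                                Style(stroke="black", stroke_width=0.01), g))
    elif desc.family is Family.BORDER_FILL:
        s.add(EllipseArc(0, 0, 0.45, 0.3, 0, 2 * np.pi, style=thin, groups=g))
        s.add(G.geom_border_fill(0.5, 0, 0, 0.45, 0.3,
                                 Style(stroke="black", stroke_width=0.06), g))
    elif desc.family in (Family.SPIKES_FRACTION, Family.SPIKES_HEIGHT):
        s.add(EllipseArc(0, 0, 0.4, 0.3, 0, 2 * np.pi, style=thin, groups=g))
        s.add(*G.geom_spikes(0.5, 1.0, 0, 0, 0.4, 0.3,
                             Style(stroke="black", stroke_width=0.01,
                                   fill="black"), g))
    elif desc.family is Family.SUBCIRCLE_COUNT:
        s.add(EllipseArc(0, 0, 0.45, 0.3, 0, 2 * np.pi, style=thin, groups=g))
        s.add(*G.geom_subcircles(2, 0, 0, 0.45, 0.3, thin, g))
    elif desc.family is Family.PROTRUSION:
        s.add(EllipseArc(0, -0.2, 0.45, 0.22, 0, 2 * np.pi, style=thin, groups=g))
        s.add(*G.geom_protrusion(0.5, 0, -0.2, 0.45, 0.22, thin, g))
    elif desc.family is Family.MEMBRANE_PROCESS:
        s.add(EllipseArc(-0.15, 0, 0.3, 0.22, 0, 2 * np.pi, style=thin, groups=g))
        s.add(*G.geom_membrane_process(0.7, -0.15, 0, 0.3, 0.22, thin, g))
    elif desc.family is Family.ORGANELLE_LINE:
        s.add(*G.geom_organelle(0.5, "line", 0, 0, 0.8, thin, _FILL, g))
    elif desc.family is Family.ORGANELLE_ELLIPSE:
        s.add(*G.geom_organelle(0.5, "ellipse", 0, 0, 0.8, thin, _FILL, g))
    elif desc.family is Family.ORGANELLE_RECTANGLE:
        s.add(*G.geom_organelle(0.5, "rectangle", 0, 0, 0.8, thin, _FILL, g))
    return s


# ---------------------------------------------------------------------------
# layout


def layout(n: int, mode: str = "grid",
           coords: np.ndarray | None = None,
           canvas: tuple[float, float] = (1.0, 1.0),
           margin: float = 0.08,
           min_separation: float = 1.5):
    """Anchor positions (and glyph size) for ``n`` glyphs.

    ``grid`` mode lays glyphs on a row-major grid with uniform spacing.
    ``coordinates`` mode rescales the given xy (e.g. the first two
    principal components) onto the canvas and chooses the glyph size so
    the median nearest-neighbour distance is at least ``min_separation``
    glyph widths.

    Returns ``(anchors, size)`` with anchors an ``(n, 2)`` array.
    """
    w, h = canvas
    if mode == "grid":
        ncols = int(np.ceil(np.sqrt(n)))
        nrows = int(np.ceil(n / ncols))
        cell = min(w / ncols, h / nrows)
        anchors = []
        for i in range(n):
            r, c = divmod(i, ncols)
            anchors.append(((c + 0.5) * cell, h - (r + 0.5) * cell))
        return np.asarray(anchors), cell * 0.9
    if mode != "coordinates":
        raise ValueError(f"unknown layout mode: {mode!r}")
    coords = np.asarray(coords, dtype=float)
    if coords is None or coords.shape != (n, 2):
        raise ValueError(f"coordinates mode needs one xy per row; "
                         f"got {None if coords is None else coords.shape}")
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span[span == 0] = 1.0
    unit = (coords - lo) / span
    anchors = np.empty_like(unit)
    anchors[:, 0] = margin + unit[:, 0] * (w - 2 * margin)
    anchors[:, 1] = margin + unit[:, 1] * (h - 2 * margin)
    if n >= 2:
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(anchors))
        np.fill_diagonal(d, np.inf)
        med_nn = float(np.median(d.min(axis=1)))
        size = min(0.2 * min(w, h), med_nn / min_separation)
    else:
        size = 0.2 * min(w, h)
    return anchors, size


def render_panel(table: FeatureTable, spec: GlyphSpec, mode: str = "grid",
                 coords: np.ndarray | None = None,
                 canvas: tuple[float, float] = (1.0, 1.0),
                 cmap: str = DEFAULT_CMAP,
                 labels: bool = True) -> Scene:
    """Render every row of a scaled table as a glyph on a shared canvas."""
    if table.scaling_state != "scaled":
        raise ValueError("table must be scaled before rendering")
    n = len(table.data)
    anchors, size = layout(n, mode=mode, coords=coords, canvas=canvas)
    scene = Scene()
    for (x, y), (rid, row) in zip(anchors, table.data.iterrows()):
        scene.extend(render_glyph(row, spec, anchor=(x, y), size=size,
                                  cmap=cmap))
        if labels:
            scene.add(Text(x, y - 0.55 * size, str(rid), size=0.12 * size,
                           anchor="middle"))
    return scene
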