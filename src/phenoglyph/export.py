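"""Scene export to SVG 1.1 and PNG.

SVG output writes every primitive as a path (arcs are densely sampled,
which keeps the writer trivial and the output deterministic); PNG goes
through matplotlib at a caller-chosen DPI.
"""

from __future__ import annotations

import math
from pathlib import Path

from .scene import (Circle, EllipseArc, Polygon, Polyline, Scene, Symbol,
                    Text)

_ARC_SAMPLES = 128


def _fmt(x: float) -> str:
    return f"{x:.5f}"


def _style_attrs(style, extra_fill: str | None = None) -> str:
    fill = extra_fill if extra_fill is not None else style.fill
    parts = [f'stroke="{style.stroke}"',
             f'stroke-width="{_fmt(style.stroke_width)}"',
             f'fill="{fill}"']
    if style.dash:
        parts.append(f'stroke-dasharray="{style.dash}"')
    return " ".join(parts)


def _path(points, closed: bool) -> str:
    d = "M " + " L ".join(f"{_fmt(x)} {_fmt(y)}" for x, y in points)
    return d + (" Z" if closed else "")


def _symbol_svg(p: Symbol) -> str:
    s = p.size / 2
    attrs = _style_attrs(p.style, extra_fill="none")
    if p.marker == "x":
        return (f'<path d="M {_fmt(p.x - s)} {_fmt(p.y - s)} '
                f'L {_fmt(p.x + s)} {_fmt(p.y + s)} '
                f'M {_fmt(p.x - s)} {_fmt(p.y + s)} '
                f'L {_fmt(p.x + s)} {_fmt(p.y - s)}" {attrs}/>')
    if p.marker == "plus":
        return (f'<path d="M {_fmt(p.x - s)} {_fmt(p.y)} '
                f'L {_fmt(p.x + s)} {_fmt(p.y)} '
                f'M {_fmt(p.x)} {_fmt(p.y - s)} '
                f'L {_fmt(p.x)} {_fmt(p.y + s)}" {attrs}/>')
    # dot
    return (f'<circle cx="{_fmt(p.x)}" cy="{_fmt(p.y)}" r="{_fmt(s * 0.6)}" '
            f'stroke="none" fill="{p.style.fill if p.style.fill != "none" else p.style.stroke}"/>')


def scene_to_svg(scene: Scene, pad: float = 0.05,
                 pixels_per_unit: float = 600.0) -> str:
    """Serialize a scene to an SVG 1.1 document string (y flipped to
    screen convention)."""
    x0, y0, x1, y1 = scene.bbox()
    x0 -= pad
    y0 -= pad
    x1 += pad
    y1 += pad
    w, h = x1 - x0, y1 - y0
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w * pixels_per_unit)}" height="{_fmt(h * pixels_per_unit)}" '
        f'viewBox="{_fmt(x0)} {_fmt(-y1)} {_fmt(w)} {_fmt(h)}">',
        f'<g transform="scale(1,-1)">',
    ]
    for p in scene:
        if isinstance(p, EllipseArc):
            closed = p.closed or abs((p.u1 - p.u0) - 2 * math.pi) < 1e-12
            lines.append(f'<path d="{_path(p.sample(_ARC_SAMPLES), closed)}" '
                         f'{_style_attrs(p.style)}/>')
        elif isinstance(p, Circle):
            lines.append(f'<circle cx="{_fmt(p.cx)}" cy="{_fmt(p.cy)}" '
                         f'r="{_fmt(p.r)}" {_style_attrs(p.style)}/>')
        elif isinstance(p, Polygon):
            lines.append(f'<path d="{_path(p.points, True)}" '
                         f'{_style_attrs(p.style)}/>')
        elif isinstance(p, Polyline):
            lines.append(f'<path d="{_path(p.points, False)}" '
                         f'{_style_attrs(p.style)}/>')
        elif isinstance(p, Symbol):
            lines.append(_symbol_svg(p))
        elif isinstance(p, Text):
            anchor = {"start": "start", "middle": "middle", "end": "end"}[p.anchor]
            lines.append(
                f'<text x="{_fmt(p.x)}" y="{_fmt(-p.y)}" '
                f'transform="scale(1,-1)" font-size="{_fmt(p.size)}" '
                f'text-anchor="{anchor}" fill="black" '
                f'font-family="sans-serif">{_escape(p.text)}</text>')
        else:
            raise TypeError(f"cannot export primitive {type(p)}")
    lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines)


def _escape(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))


def save_svg(scene: Scene, path: str | Path, **kwargs) -> None:
    Path(path).write_text(scene_to_svg(scene, **kwargs))


def save_png(scene: Scene, path: str | Path, dpi: int = 150,
             size_inches: float = 6.0) -> None:
    """Rasterize through matplotlib at the requested DPI."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon
    from matplotlib.lines import Line2D

    x0, y0, x1, y1 = scene.bbox()
    pad = 0.05
    fig, ax = plt.subplots(figsize=(size_inches, size_inches *
                                    max(1e-6, (y1 - y0 + 2 * pad)) /
                                    max(1e-6, (x1 - x0 + 2 * pad))))
    ax.set_xlim(x0 - pad, x1 + pad)
    ax.set_ylim(y0 - pad, y1 + pad)
    ax.set_aspect("equal")
    ax.axis("off")
    lw_scale = 72.0 * size_inches / max(1e-6, x1 - x0 + 2 * pad)

    def lw(style):
        return max(0.3, style.stroke_width * lw_scale)

    for p in scene:
        if isinstance(p, (EllipseArc, Polygon, Polyline)):
            pts = p.sample(_ARC_SAMPLES) if isinstance(p, EllipseArc) else p.points
            closed = isinstance(p, Polygon) or (
                isinstance(p, EllipseArc)
                and (p.closed or abs((p.u1 - p.u0) - 2 * math.pi) < 1e-12))
            if p.style.fill != "none":
                ax.add_patch(MplPolygon(pts, closed=True,
                                        facecolor=p.style.fill,
                                        edgecolor="none"))
            if p.style.stroke != "none":
                xs = [q[0] for q in pts] + ([pts[0][0]] if closed else [])
                ys = [q[1] for q in pts] + ([pts[0][1]] if closed else [])
                ax.add_line(Line2D(xs, ys, color=p.style.stroke,
                                   linewidth=lw(p.style)))
        elif isinstance(p, Circle):
            circ = plt.Circle((p.cx, p.cy), p.r,
                              facecolor=p.style.fill if p.style.fill != "none"
                              else "none",
                              edgecolor=p.style.stroke if p.style.stroke != "none"
                              else "none",
                              linewidth=lw(p.style))
            ax.add_patch(circ)
        elif isinstance(p, Symbol):
            marker = {"x": "x", "plus": "+", "dot": "."}.get(p.marker, "x")
            ax.plot([p.x], [p.y], marker=marker, color=p.style.stroke,
                    markersize=max(1.0, p.size * lw_scale * 0.8),
                    linestyle="none",
                    markeredgewidth=max(0.3, p.style.stroke_width * lw_scale))
        elif isinstance(p, Text):
            ha = {"start": "left", "middle": "center", "end": "right"}[p.anchor]
            ax.text(p.x, p.y, p.text, fontsize=max(2.0, p.size * lw_scale / 2),
                    ha=ha, va="center")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
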