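"""Resolution-independent drawing primitives.

A :class:`Scene` is an ordered list of primitives in glyph-local
coordinates (y up).  Every primitive carries the names of the visual
element(s) that generated it in ``groups``, so a scene can be audited
element by element.  Primitive order is deterministic for identical
input; no randomness enters rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Style:
    stroke: str = "black"
    stroke_width: float = 0.004
    fill: str = "none"
    dash: str | None = None


@dataclass(frozen=True)
class EllipseArc:
    """Elliptic arc in 'clock' parameterization.

    Point at parameter u is ``(cx + a*sin(u), cy + b*cos(u))``: u = 0 is
    12 o'clock and u increases clockwise.  A full ellipse spans
    ``[0, 2*pi]``.
    """

    cx: float
    cy: float
    a: float
    b: float
    u0: float
    u1: float
    style: Style = Style()
    groups: tuple[str, ...] = ()
    closed: bool = False

    def sample(self, n: int = 256) -> list[tuple[float, float]]:
        us = [self.u0 + (self.u1 - self.u0) * i / (n - 1) for i in range(n)]
        return [(self.cx + self.a * math.sin(u), self.cy + self.b * math.cos(u))
                for u in us]

    def bbox(self) -> tuple[float, float, float, float]:
        pts = self.sample(128)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        w = self.style.stroke_width / 2
        return min(xs) - w, min(ys) - w, max(xs) + w, max(ys) + w


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float
    style: Style = Style()
    groups: tuple[str, ...] = ()

    def bbox(self) -> tuple[float, float, float, float]:
        w = self.style.stroke_width / 2
        return (self.cx - self.r - w, self.cy - self.r - w,
                self.cx + self.r + w, self.cy + self.r + w)


@dataclass(frozen=True)
class Polygon:
    points: tuple[tuple[float, float], ...]
    style: Style = Style()
    groups: tuple[str, ...] = ()

    def bbox(self) -> tuple[float, float, float, float]:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        w = self.style.stroke_width / 2
        return min(xs) - w, min(ys) - w, max(xs) + w, max(ys) + w


@dataclass(frozen=True)
class Polyline:
    points: tuple[tuple[float, float], ...]
    style: Style = Style()
    groups: tuple[str, ...] = ()

    def bbox(self) -> tuple[float, float, float, float]:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        w = self.style.stroke_width / 2
        return min(xs) - w, min(ys) - w, max(xs) + w, max(ys) + w


@dataclass(frozen=True)
class Symbol:
    """Small marker (cross / dot / plus) used for area filling."""

    x: float
    y: float
    size: float
    marker: str = "x"
    style: Style = Style()
    groups: tuple[str, ...] = ()

    def bbox(self) -> tuple[float, float, float, float]:
        s = self.size / 2
        return self.x - s, self.y - s, self.x + s, self.y + s


@dataclass(frozen=True)
class Text:
    x: float
    y: float
    text: str
    size: float = 0.03
    anchor: str = "start"  # start | middle | end
    style: Style = Style(fill="black", stroke="none")
    groups: tuple[str, ...] = ()

    def bbox(self) -> tuple[float, float, float, float]:
        # conservative estimate; text extent depends on the font
        w = self.size * 0.6 * len(self.text)
        x0 = {"start": self.x, "middle": self.x - w / 2, "end": self.x - w}[self.anchor]
        return x0, self.y - self.size / 2, x0 + w, self.y + self.size / 2

Primitive = EllipseArc | Circle | Polygon | Polyline | Symbol | Text


@dataclass
class Scene:
    """Ordered, deterministic list of drawing primitives."""

    primitives: list[Primitive] = field(default_factory=list)

    def add(self, *prims: Primitive | None) -> None:
        for p in prims:
            if p is not None:
                self.primitives.append(p)

    def extend(self, other: "Scene") -> None:
        self.primitives.extend(other.primitives)

    def __iter__(self) -> Iterator[Primitive]:
        return iter(self.primitives)

    def __len__(self) -> int:
        return len(self.primitives)

    def group_names(self) -> list[str]:
        """Distinct group tags in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.primitives:
            for g in p.groups:
                seen.setdefault(g)
        return list(seen)

    def by_group(self, group: str) -> list[Primitive]:
        return [p for p in self.primitives if group in p.groups]

    def bbox(self) -> tuple[float, float, float, float]:
        if not self.primitives:
            return 0.0, 0.0, 0.0, 0.0
        boxes = [p.bbox() for p in self.primitives]
        return (min(b[0] for b in boxes), min(b[1] for b in boxes),
                max(b[2] for b in boxes), max(b[3] for b in boxes))

    def translated(self, dx: float, dy: float) -> "Scene":
        return Scene([_moved(p, dx, dy) for p in self.primitives])

    def scaled(self, s: float) -> "Scene":
        return Scene([_scaled(p, s) for p in self.primitives])


def _moved(p: Primitive, dx: float, dy: float) -> Primitive:
    if isinstance(p, (EllipseArc, Circle)):
        return replace(p, cx=p.cx + dx, cy=p.cy + dy)
    if isinstance(p, (Polygon, Polyline)):
        return replace(p, points=tuple((x + dx, y + dy) for x, y in p.points))
    if isinstance(p, (Symbol, Text)):
        return replace(p, x=p.x + dx, y=p.y + dy)
    raise TypeError(type(p))


def _scaled(p: Primitive, s: float) -> Primitive:
    st = replace(p.style, stroke_width=p.style.stroke_width * s)
    if isinstance(p, EllipseArc):
        return replace(p, cx=p.cx * s, cy=p.cy * s, a=p.a * s, b=p.b * s, style=st)
    if isinstance(p, Circle):
        return replace(p, cx=p.cx * s, cy=p.cy * s, r=p.r * s, style=st)
    if isinstance(p, (Polygon, Polyline)):
        return replace(p, points=tuple((x * s, y * s) for x, y in p.points), style=st)
    if isinstance(p, Symbol):
        return replace(p, x=p.x * s, y=p.y * s, size=p.size * s, style=st)
    if isinstance(p, Text):
        return replace(p, x=p.x * s, y=p.y * s, size=p.size * s, style=st)
    raise TypeError(type(p))
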