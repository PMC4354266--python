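"""Registry of the visual elements a glyph can encode.

A glyph is a cell-like pictogram: the cell body, nucleus and perinuclear
region are drawn as ellipses whose major/minor dimensions, colour and
proportional filling each encode one measured feature.  Proportional
filling encodes a value in [0, 1] as the filled fraction of a closed
outline (thickened border arc, symbol fill, or fill height of a small
organelle shape), relying on visual closure for readout.

The registry is fixed: 21 elements, of which exactly 8 use proportional
filling.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Family(str, Enum):
    """Geometry family of a visual element."""

    MAIN_ELLIPSE_DIM = "main-ellipse-dim"
    INNER_ELLIPSE_DIM = "inner-ellipse-dim"
    PERINUCLEAR_ELLIPSE_DIM = "perinuclear-ellipse-dim"
    COLOUR = "colour"
    AREA_FILL = "area-fill"
    BORDER_FILL = "border-fill"
    SPIKES_FRACTION = "spikes-fraction"
    SPIKES_HEIGHT = "spikes-height"
    SUBCIRCLE_COUNT = "subcircle-count"
    PROTRUSION = "protrusion"
    MEMBRANE_PROCESS = "membrane-process"
    ORGANELLE_LINE = "organelle-line"
    ORGANELLE_ELLIPSE = "organelle-ellipse"
    ORGANELLE_RECTANGLE = "organelle-rectangle"


class ValueDomain(str, Enum):
    UNIT = "unit"              # [0, 1]
    DIMENSIONAL = "dimensional"  # [0.1, 1], jointly scaled lengths/widths
    COUNT = "count"            # non-negative integer


@dataclass(frozen=True)
class ElementDescriptor:
    """One registered visual element.

    Attributes
    ----------
    name:
        Stable identifier used in glyph-spec bindings.
    family:
        Geometry family driving the renderer dispatch.
    proportional_fill:
        Whether the element encodes its value as a filled fraction of a
        closed outline.
    colour_dependent:
        Whether reading the element requires colour vision (most elements
        are deliberately colour independent).
    value_domain:
        Domain the bound (scaled) feature must lie in.
    """

    name: str
    family: Family
    proportional_fill: bool
    colour_dependent: bool
    value_domain: ValueDomain


def _d(name, family, prop=False, colour=False, domain=ValueDomain.UNIT):
    return ElementDescriptor(name, family, prop, colour, domain)


_REGISTRY: tuple[ElementDescriptor, ...] = (
    _d("main-ellipse-length", Family.MAIN_ELLIPSE_DIM, domain=ValueDomain.DIMENSIONAL),
    _d("main-ellipse-width", Family.MAIN_ELLIPSE_DIM, domain=ValueDomain.DIMENSIONAL),
    _d("main-ellipse-colour", Family.COLOUR, colour=True),
    _d("main-ellipse-area-fill", Family.AREA_FILL, prop=True),
    _d("main-ellipse-border-fill", Family.BORDER_FILL, prop=True),
    _d("inner-ellipse-length", Family.INNER_ELLIPSE_DIM, domain=ValueDomain.DIMENSIONAL),
    _d("inner-ellipse-width", Family.INNER_ELLIPSE_DIM, domain=ValueDomain.DIMENSIONAL),
    _d("inner-ellipse-colour", Family.COLOUR, colour=True),
    _d("inner-ellipse-area-fill", Family.AREA_FILL, prop=True),
    _d("inner-subcircle-count", Family.SUBCIRCLE_COUNT, domain=ValueDomain.COUNT),
    _d("perinuclear-ellipse-length", Family.PERINUCLEAR_ELLIPSE_DIM,
       domain=ValueDomain.DIMENSIONAL),
    _d("perinuclear-ellipse-width", Family.PERINUCLEAR_ELLIPSE_DIM,
       domain=ValueDomain.DIMENSIONAL),
    _d("perinuclear-ellipse-colour", Family.COLOUR, colour=True),
    _d("perinuclear-ellipse-area-fill", Family.AREA_FILL, prop=True),
    _d("protrusion", Family.PROTRUSION),
    _d("spikes-fraction", Family.SPIKES_FRACTION, prop=True),
    _d("spikes-height", Family.SPIKES_HEIGHT),
    _d("membrane-process", Family.MEMBRANE_PROCESS),
    _d("line-organelle", Family.ORGANELLE_LINE, prop=True),
    _d("ellipse-organelle", Family.ORGANELLE_ELLIPSE, prop=True),
    _d("rectangle-organelle", Family.ORGANELLE_RECTANGLE, prop=True),
)

# Pairs of dimensional elements that must be bound together: a length
# without its width (or vice versa) would leave the ellipse undefined.
DIMENSIONAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("main-ellipse-length", "main-ellipse-width"),
    ("inner-ellipse-length", "inner-ellipse-width"),
    ("perinuclear-ellipse-length", "perinuclear-ellipse-width"),
)


def element_registry() -> list[ElementDescriptor]:
    """Return the fixed 21-element registry in stable order."""
    return list(_REGISTRY)


def element_by_name(name: str) -> ElementDescriptor:
    """Look up a descriptor; raise ``KeyError`` with the offending name."""
    for desc in _REGISTRY:
        if desc.name == name:
            return desc
    raise KeyError(f"unknown glyph element: {name!r}")


assert len(_REGISTRY) == 21
assert sum(d.proportional_fill for d in _REGISTRY) == 8
assert len({d.name for d in _REGISTRY}) == 21
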