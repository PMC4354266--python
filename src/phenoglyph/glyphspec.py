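"""Glyph specifications: validated feature-to-element bindings."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .elements import DIMENSIONAL_PAIRS, element_by_name
from .table import FeatureTable

logger = logging.getLogger(__name__)


class SpecValidationError(ValueError):
    """A glyph-spec binding violates the registry contract."""


@dataclass(frozen=True)
class Binding:
    feature: str
    element: str
    style: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class GlyphSpec:
    """Validated ordered mapping from feature names to element names."""

    bindings: tuple[Binding, ...]
    palette: dict = field(default_factory=dict, compare=False)

    @property
    def features(self) -> list[str]:
        return [b.feature for b in self.bindings]

    @property
    def elements(self) -> list[str]:
        return [b.element for b in self.bindings]

    def element_for(self, feature: str) -> str:
        for b in self.bindings:
            if b.feature == feature:
                return b.element
        raise KeyError(feature)

    def legend_labels(self) -> list[str]:
        return self.features


def validate_spec(
    raw: dict[str, str | dict],
    table: FeatureTable | None = None,
    palette: dict | None = None,
) -> GlyphSpec:
    """Validate a raw feature->element mapping against the registry.

    ``raw`` maps feature names to element names, or to dicts of the form
    ``{"element": name, **style}``.  Checks: every element exists in the
    registry, each element is bound at most once, each feature at most
    once (dict keys guarantee that), dimensional length/width pairs are
    bound together, and bound features exist in ``table`` when given.
    Unreferenced table columns are ignored with a logged warning.
    """
    bindings: list[Binding] = []
    seen_elements: set[str] = set()
    for feature, target in raw.items():
        if isinstance(target, dict):
            try:
                element = target["element"]
            except KeyError:
                raise SpecValidationError(
                    f"binding for {feature!r} lacks an 'element' key")
            style = {k: v for k, v in target.items() if k != "element"}
        else:
            element, style = str(target), {}
        try:
            element_by_name(element)
        except KeyError:
            raise SpecValidationError(
                f"feature {feature!r} bound to unknown element {element!r}")
        if element in seen_elements:
            raise SpecValidationError(
                f"element {element!r} bound more than once (feature {feature!r})")
        seen_elements.add(element)
        bindings.append(Binding(feature, element, style))

    for length, width in DIMENSIONAL_PAIRS:
        if (length in seen_elements) != (width in seen_elements):
            missing = width if length in seen_elements else length
            present = length if length in seen_elements else width
            raise SpecValidationError(
                f"{present!r} bound without its pair {missing!r}")

    if table is not None:
        table_cols = set(table.columns)
        for b in bindings:
            if b.feature not in table_cols:
                raise SpecValidationError(
                    f"bound feature {b.feature!r} not in table columns")
        unused = table_cols - {b.feature for b in bindings}
        if unused:
            logger.warning("table columns not bound to any element: %s",
                           sorted(unused))

    return GlyphSpec(bindings=tuple(bindings), palette=dict(palette or {}))


#: The 15-variable demo configuration matching the published example
#: panel: the main ellipse (length, width, area fill and border fill),
#: the inner sub-ellipse (length, width, fill, colour), relative
#: protrusion area, spikes (fraction and height), membrane process and
#: the three organelles.
FIG1B_ELEMENTS: tuple[str, ...] = (
    "main-ellipse-length",
    "main-ellipse-width",
    "main-ellipse-area-fill",
    "main-ellipse-border-fill",
    "inner-ellipse-length",
    "inner-ellipse-width",
    "inner-ellipse-area-fill",
    "inner-ellipse-colour",
    "protrusion",
    "spikes-fraction",
    "spikes-height",
    "membrane-process",
    "line-organelle",
    "ellipse-organelle",
    "rectangle-organelle",
)


def demo_spec(feature_names: list[str] | None = None) -> GlyphSpec:
    """The 15-variable demo spec; default feature names mirror elements."""
    if feature_names is None:
        feature_names = [e.replace("-", "_") for e in FIG1B_ELEMENTS]
    if len(feature_names) != len(FIG1B_ELEMENTS):
        raise SpecValidationError(
            f"demo spec needs {len(FIG1B_ELEMENTS)} feature names")
    return validate_spec(dict(zip(feature_names, FIG1B_ELEMENTS)))
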