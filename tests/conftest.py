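"""Shared fixtures: synthetic images and their extracted tables.

The expensive full-pipeline extraction runs once per session and is
shared by the unit and acceptance tests.
"""

import numpy as np
import pytest

from phenoglyph.images import extract_feature_table
from phenoglyph.synthetic import (CellBlueprint, SynthImageSpec,
                                  demo_image_spec, synth_cell_image)


@pytest.fixture(scope="session")
def demo_image():
    """Noisy 5-cell two-channel fixture with a touching pair."""
    return synth_cell_image(demo_image_spec(seed=11))


@pytest.fixture(scope="session")
def demo_table(demo_image):
    return extract_feature_table(demo_image["nuclear"],
                                 demo_image["cell_body"])


@pytest.fixture(scope="session")
def clean_image():
    """Noise-free fixture with equal nuclear plateaus: isolated cells,
    one with a genuine protrusion ring, for segmentation-recovery checks."""
    blueprints = tuple(
        CellBlueprint(center=c, cell_axes=ax, nucleus_axes=nx,
                      core_fraction=cf, nucleus_intensity=100.0)
        for c, ax, nx, cf in [
            ((60, 60), (24, 20), (10, 8), 1.0),
            ((60, 180), (22, 21), (9, 9), 1.0),
            ((180, 60), (26, 17), (9, 7), 0.75),
            ((185, 185), (23, 23), (10, 10), 0.85),
        ])
    return synth_cell_image(SynthImageSpec(blueprints=blueprints,
                                           noise_sd=0.0, seed=0))


def match_to_truth(pred_labels: np.ndarray, truth_labels: np.ndarray,
                   truth_label: int) -> np.ndarray:
    """Mask of the predicted object that best overlaps a truth object."""
    tm = truth_labels == truth_label
    labs, cnt = np.unique(pred_labels[tm], return_counts=True)
    if (labs > 0).sum() == 0:
        return np.zeros_like(tm)
    best = labs[np.argmax(np.where(labs > 0, cnt, 0))]
    return pred_labels == best


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 0.0
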