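"""Ground-truth generators: synthetic two-channel cell images and
archetype feature tables.

Both generators are pure functions of their specs (RNG seed included),
so every pipeline stage can be tested against known truth without any
external data.

The image generator renders ellipsoidal cells with a bright "core"
plateau and a dimmer peripheral plateau (the protrusion), a nucleus in
the nuclear channel, optional texture (speckle or grating) in the core,
and additive Gaussian pixel noise.  It returns the truth the extraction
pipeline should recover: label masks, relative protrusion areas, and
neighbour fractions from mask adjacency.

The table generator emulates the study design that motivates the
downstream analysis: five morphological archetypes over the nine
plotted features (a round high-contact archetype, a ruffly / textured /
protrusive one, a spread smooth one, an intermediate highly textured
one, and a compact smooth one), with Gaussian scatter around each
archetype mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import LabeledImage, neighbour_fraction
from .table import FeatureTable

#: The nine per-population features shown on glyphs.
PROFILE_FEATURES = (
    "cell_length", "cell_width", "nucleus_length", "nucleus_width",
    "neighbour_fraction", "relative_protrusion_area", "ruffliness",
    "nuc_texture_index", "cell_texture_index",
)


# ---------------------------------------------------------------------------
# image generator


@dataclass(frozen=True)
class CellBlueprint:
    """One planted cell: geometry, intensity plateaus and texture."""

    center: tuple[float, float]            # (row, col)
    cell_axes: tuple[float, float]         # semi-axes (row, col), px
    nucleus_axes: tuple[float, float]
    core_fraction: float = 1.0             # area fraction of the bright core
    cell_intensity: float = 100.0          # core plateau
    protrusion_intensity: float = 50.0     # peripheral plateau
    nucleus_intensity: float = 100.0
    texture: str = "none"                  # none | speckle | grating
    touching: bool = False                 # may share a border with others


@dataclass(frozen=True)
class SynthImageSpec:
    shape: tuple[int, int] = (256, 256)
    blueprints: tuple[CellBlueprint, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0


def _ellipse_q(shape, center, axes) -> np.ndarray:
    """Normalized squared ellipse distance; q <= 1 is inside."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2)


def synth_cell_image(spec: SynthImageSpec) -> dict:
    """Render a two-channel image with per-cell ground truth.

    Returns a dict with ``nuclear`` and ``cell_body`` float images,
    ``cell_labels`` / ``nucleus_labels`` truth matrices, and ``truth``: a
    list of per-cell dicts (mask areas, relative protrusion area, NF
    from mask adjacency).  Raises if blueprints overlap without both
    carrying the ``touching`` flag.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    n = len(spec.blueprints)
    qs = np.stack([_ellipse_q(shape, b.center, b.cell_axes)
                   for b in spec.blueprints]) if n else np.empty((0, *shape))
    inside = qs <= 1.0
    n_owners = inside.sum(axis=0)
    if (n_owners > 1).any():
        owners = np.where(inside[:, n_owners > 1].any(axis=1))[0]
        bad = [i for i in owners if not spec.blueprints[i].touching]
        if bad:
            raise ValueError(
                f"blueprints {bad} overlap without the touching flag")
    # each contested pixel goes to the nearest cell (smallest q)
    cell_labels = np.zeros(shape, dtype=np.int32)
    if n:
        nearest = np.argmin(np.where(inside, qs, np.inf), axis=0)
        cell_labels[n_owners > 0] = nearest[n_owners > 0] + 1

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nuclear = np.zeros(shape, dtype=float)
    cell_body = np.zeros(shape, dtype=float)
    truth: list[dict] = []
    for i, b in enumerate(spec.blueprints):
        lab = i + 1
        cmask = cell_labels == lab
        core_axes = (b.cell_axes[0] * np.sqrt(b.core_fraction),
                     b.cell_axes[1] * np.sqrt(b.core_fraction))
        core = cmask & (_ellipse_q(shape, b.center, core_axes) <= 1.0)
        prot = cmask & ~core
        cell_body[prot] = b.protrusion_intensity
        core_img = np.full(shape, b.cell_intensity)
        if b.texture == "speckle":
            core_img = core_img * (1.0 + 0.3 * rng.standard_normal(shape))
        elif b.texture == "grating":
            cc = np.arange(shape[1])[None, :]
            core_img = core_img * (1.0 + 0.3 * np.sin(2 * np.pi * cc / 6.0))
        cell_body[core] = core_img[core]
        nmask = _ellipse_q(shape, b.center, b.nucleus_axes) <= 1.0
        nmask &= cmask
        nucleus_labels[nmask] = lab
        nuclear[nmask] = b.nucleus_intensity
        truth.append({
            "label": lab,
            "cell_area_px": int(cmask.sum()),
            "nucleus_area_px": int(nmask.sum()),
            "core_area_px": int(core.sum()),
            "relative_protrusion_area": float(prot.sum()) / max(1, cmask.sum()),
        })
    nf = neighbour_fraction(LabeledImage(cell_labels))
    for t in truth:
        t["neighbour_fraction"] = nf.get(t["label"], 0.0)
    if spec.noise_sd > 0:
        nuclear = nuclear + spec.noise_sd * rng.standard_normal(shape)
        cell_body = cell_body + spec.noise_sd * rng.standard_normal(shape)
        np.clip(nuclear, 0.0, None, out=nuclear)
        np.clip(cell_body, 0.0, None, out=cell_body)
    return {"nuclear": nuclear, "cell_body": cell_body,
            "cell_labels": cell_labels, "nucleus_labels": nucleus_labels,
            "truth": truth}


def demo_image_spec(seed: int = 0, touching: bool = True) -> SynthImageSpec:
    """Standard 5-cell fixture: three isolated cells (one textured, one
    protrusive) and, when ``touching``, a touching pair for non-zero NF.

    Nuclear plateau intensities are deliberately staggered (90..110) so
    the per-image mitotic cut (median + 3 MAD) has a meaningful scale
    and none of the planted cells is flagged.
    """
    pair_sep = 40 if touching else 60
    blueprints = (
        CellBlueprint(center=(60, 64), cell_axes=(24, 20),
                      nucleus_axes=(9, 7), nucleus_intensity=90.0,
                      touching=touching),
        CellBlueprint(center=(60, 64 + pair_sep), cell_axes=(22, 21),
                      nucleus_axes=(8, 8), nucleus_intensity=110.0,
                      touching=touching),
        CellBlueprint(center=(70, 190), cell_axes=(26, 17),
                      nucleus_axes=(9, 6), nucleus_intensity=100.0,
                      core_fraction=0.75),
        CellBlueprint(center=(180, 70), cell_axes=(20, 26),
                      nucleus_axes=(7, 9), nucleus_intensity=95.0,
                      texture="speckle"),
        CellBlueprint(center=(185, 185), cell_axes=(23, 23),
                      nucleus_axes=(8, 8), nucleus_intensity=105.0,
                      core_fraction=0.85, texture="grating"),
    )
    return SynthImageSpec(shape=(256, 256), blueprints=blueprints,
                          noise_sd=1.0, seed=seed)


def two_plateau_cell(n_core: int = 80, n_prot: int = 20,
                     hi: float = 100.0, lo: float = 10.0) -> dict:
    """Exact two-plateau cell for the core/protrusion split arithmetic.

    A rectangular cell of ``n_core + n_prot`` pixels with ``n_core``
    pixels at intensity ``hi`` and ``n_prot`` at ``lo``, embedded with a
    2-px background margin.  With the defaults the mean is 82, the 70%
    threshold 57.4, and the true relative protrusion area 0.2.
    """
    width = 10
    rows_core = n_core // width
    rows_prot = n_prot // width
    assert rows_core * width == n_core and rows_prot * width == n_prot
    h = rows_core + rows_prot
    mask = np.zeros((h + 4, width + 4), dtype=bool)
    channel = np.zeros((h + 4, width + 4), dtype=float)
    mask[2:2 + h, 2:2 + width] = True
    channel[2:2 + rows_core, 2:2 + width] = hi
    channel[2 + rows_core:2 + h, 2:2 + width] = lo
    return {"mask": mask, "channel": channel,
            "true_relative_protrusion_area": n_prot / (n_core + n_prot)}


# ---------------------------------------------------------------------------
# archetype feature tables


#: Archetype means over PROFILE_FEATURES (lengths/widths in micrometres,
#: NF / protrusion / texture indices on [0, 1], ruffliness unitless).
ARCHETYPE_MEANS: dict[str, tuple[float, ...]] = {
    "round_high_nf":      (32.0, 29.0, 14.0, 13.0, 0.70, 0.03, 0.10, 0.20, 0.20),
    "ruffly_protrusive":  (85.0, 40.0, 20.0, 16.0, 0.10, 0.50, 0.90, 0.80, 0.85),
    "spread_smooth":      (80.0, 55.0, 20.0, 17.0, 0.40, 0.15, 0.25, 0.35, 0.30),
    "intermediate_textured": (55.0, 35.0, 17.0, 15.0, 0.35, 0.30, 0.50, 0.90, 0.90),
    "compact_smooth":     (55.0, 45.0, 18.0, 16.0, 0.45, 0.10, 0.20, 0.30, 0.25),
}

#: Per-feature scatter (sd) around the archetype means.
ARCHETYPE_SDS: tuple[float, ...] = (3.0, 3.0, 1.0, 1.0, 0.05, 0.04, 0.06,
                                    0.06, 0.06)

#: Value domains used to clip the Gaussian draws.
_DOMAINS = ((1.0, None), (1.0, None), (1.0, None), (1.0, None),
            (0.0, 1.0), (0.0, 1.0), (0.0, None), (0.0, 1.0), (0.0, 1.0))


@dataclass(frozen=True)
class ArchetypeSpec:
    samples_per_archetype: int = 20
    sds: tuple[float, ...] = ARCHETYPE_SDS
    means: dict = field(default_factory=lambda: dict(ARCHETYPE_MEANS))
    seed: int = 0


def synth_feature_table(spec: ArchetypeSpec) -> tuple[FeatureTable, pd.Series]:
    """Gaussian draws around the archetype means, clipped to domains.

    Returns the raw feature table (dimensional columns flagged) and the
    planted archetype labels.
    """
    rng = np.random.default_rng(spec.seed)
    rows, labels, ids = [], [], []
    for name, means in spec.means.items():
        means = np.asarray(means, dtype=float)
        if means.shape != (len(PROFILE_FEATURES),):
            raise ValueError(f"archetype {name!r} needs "
                             f"{len(PROFILE_FEATURES)} means")
        draws = means + np.asarray(spec.sds) * rng.standard_normal(
            (spec.samples_per_archetype, len(means)))
        for j, (lo, hi) in enumerate(_DOMAINS):
            draws[:, j] = np.clip(draws[:, j], lo, hi)
        for i in range(spec.samples_per_archetype):
            rows.append(draws[i])
            labels.append(name)
            ids.append(f"{name}_{i:03d}")
    df = pd.DataFrame(rows, columns=list(PROFILE_FEATURES), index=ids)
    table = FeatureTable(df, dimensional_set=frozenset(
        {"cell_length", "cell_width", "nucleus_length", "nucleus_width"}))
    return table, pd.Series(labels, index=ids, name="archetype")


#: Fixed loading pattern used to expand a texture index into a
#: correlated 20-column block (first PC then recovers the index).
_BLOCK_LOADINGS = np.array(
    [1.0, 0.9, 0.8, 1.1, 0.7, 0.95, 1.05, 0.85, 0.6, 1.2,
     0.75, 0.9, 1.0, 0.8, 1.1, 0.65, 0.95, 0.7, 1.15, 0.85])


def expand_texture_blocks(table: FeatureTable, noise_sd: float = 0.03,
                          seed: int = 0) -> FeatureTable:
    """Replace the two texture-index columns with 20-column blocks.

    Each block column is the index times a fixed positive loading plus
    Gaussian noise, so compressing the block back through its first
    principal component recovers (up to noise) the planted index.  Used
    to exercise the texture-compression stage end to end.
    """
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    for prefix in ("nuc", "cell"):
        idx = df.pop(f"{prefix}_texture_index").to_numpy(dtype=float)
        block = (idx[:, None] * _BLOCK_LOADINGS[None, :]
                 + noise_sd * rng.standard_normal((len(idx),
                                                   len(_BLOCK_LOADINGS))))
        for j in range(block.shape[1]):
            df[f"{prefix}_texture_{j:02d}"] = block[:, j]
    return FeatureTable(df, dimensional_set=table.dimensional_set,
                        scaling_state=table.scaling_state)
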