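"""Profile analysis: texture-index compression, normalization,
hierarchical clustering and PCA layout coordinates.

The 20 texture features of each region are compressed to a single
texture index — the score on the first principal component of the
scaled texture block.  For clustering and PCA the assembled profiles
are z-scored per feature (so all features are on the same scale) and
grouped by agglomerative clustering with Euclidean distance and average
linkage (UPGMA).  Glyph plotting uses the 0.1–1 / 0–1 scaled features,
not the z-scores: the two normalizations coexist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


class ConstantColumnError(ValueError):
    pass


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column standardization (x - mean) / sd, sample sd (ddof=1)."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples to z-score")
    out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ConstantColumnError(f"constant column: {col!r}")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=matrix.index)


def _first_pc(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Scores, loadings and explained-variance share of the first PC."""
    centred = block - block.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] == 0:
        raise ConstantColumnError("block has no variance; PC undefined")
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    share = float(s[0] ** 2 / (s ** 2).sum())
    return scores, loadings, share


def texture_index(texture_block: pd.DataFrame) -> pd.Series:
    """Compress a scaled 20-column texture block to its first-PC score.

    The sign is fixed so the index correlates positively with the mean
    texture magnitude of each sample (PCA signs are otherwise
    arbitrary).
    """
    if len(texture_block) < 2:
        raise ValueError("need at least 2 samples")
    block = texture_block.to_numpy(dtype=float)
    scores, _, _ = _first_pc(block)
    magnitude = block.mean(axis=1)
    if np.std(magnitude) > 0 and np.corrcoef(scores, magnitude)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=texture_block.index, name="texture_index")


@dataclass
class ClusterResult:
    """UPGMA tree, flat assignment at k, and per-cluster mean profiles."""

    linkage: np.ndarray
    assignments: pd.Series      # sample -> cluster id in 1..k
    k: int

    def cluster_ids(self) -> list[int]:
        return sorted(self.assignments.unique())


def hcluster(profiles: pd.DataFrame, k: int) -> ClusterResult:
    """Hierarchical clustering: Euclidean distance, average linkage, cut
    at ``k`` flat clusters.  Deterministic (scipy's linkage applies a
    fixed merge order under ties)."""
    n = len(profiles)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    z = hierarchy.linkage(pdist(profiles.to_numpy(dtype=float)),
                          method="average")
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(linkage=z,
                         assignments=pd.Series(flat, index=profiles.index,
                                               name="cluster"),
                         k=k)


def pca_project(profiles: pd.DataFrame) -> pd.DataFrame:
    """Scores on the first two principal components.

    Sign convention: for each PC, the loading with the largest absolute
    value is made positive, so layouts are reproducible run to run.
    Requires at least 3 samples and a data matrix of rank >= 2.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 samples")
    x = profiles.to_numpy(dtype=float)
    centred = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if (s > max(x.shape) * np.finfo(float).eps * s[0]).sum() < 2:
        raise ValueError("profile matrix has rank < 2; cannot project")
    coords = np.empty((len(profiles), 2))
    for j in range(2):
        load = vt[j]
        sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
        coords[:, j] = sign * u[:, j] * s[j]
    return pd.DataFrame(coords, index=profiles.index, columns=["pc1", "pc2"])


def cluster_profile_means(result: ClusterResult,
                          profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster column means of the given (plot-scaled) profiles.

    Intended for glyph rendering of cluster averages, so callers pass
    the 0.1–1 / 0–1 scaled features rather than z-scores.
    """
    if not result.assignments.index.equals(profiles.index):
        raise ValueError("assignment index does not match profiles")
    grouped = profiles.groupby(result.assignments).mean()
    grouped.index.name = "cluster"
    return grouped
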