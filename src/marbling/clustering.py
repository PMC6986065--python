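"""Hierarchical clustering of expression and correlation profiles.

Profiles (tissue columns, gene panels, or correlation vectors) are compared
by correlation distance d = 1 - Pearson r, so perfectly co-varying profiles
sit at distance 0 and perfectly anti-correlated ones at 2 — clustering "on
positive relationships only".  Trees are average-linkage (UPGMA) merge
trees; gene subsampling makes genome-scale column clustering cheap and
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from marbling.io import ExpressionMatrix


@dataclass
class Dendrogram:
    """Binary merge tree: leaf labels plus a SciPy linkage matrix."""

    labels: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.linkage = np.asarray(self.linkage, dtype=float)
        expect = max(len(self.labels) - 1, 0)
        if self.linkage.shape not in ((expect, 4), (0,)) and expect > 0:
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """Ordered (node, node, height) merge list; leaves are 0..n-1."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2] if self.linkage.size else np.array([])

    def leaves_under(self, node: int) -> frozenset[str]:
        """Leaf labels in the subtree rooted at an internal or leaf node id."""
        n = self.n_leaves
        if node < n:
            return frozenset([self.labels[node]])
        a, b = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
        return self.leaves_under(a) | self.leaves_under(b)

    def first_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """The bipartition of leaves at the root (the last merge)."""
        if self.n_leaves < 2:
            raise ValueError("tree has no split")
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return self.leaves_under(a), self.leaves_under(b)


def subsample_genes(matrix: ExpressionMatrix, count: int, seed: int) -> ExpressionMatrix:
    """Uniform random sample of ``count`` probes without replacement."""
    n = matrix.values.shape[0]
    if count > n:
        raise ValueError(f"cannot sample {count} of {n} probes")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=count, replace=False))
    return ExpressionMatrix(matrix.values.iloc[keep], matrix.samples)


def correlation_distance(profiles: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Pairwise d = 1 - Pearson r between profiles.

    ``axis='columns'`` compares columns (e.g. tissues over genes);
    ``axis='rows'`` compares rows.  Profiles need >= 3 observations and
    nonzero variance.
    """
    if axis not in ("columns", "rows"):
        raise ValueError("axis must be 'columns' or 'rows'")
    data = profiles if axis == "columns" else profiles.T
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations per profile")
    sd = data.std(axis=0, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance profiles: {flat[:5]}")
    r = np.corrcoef(data.to_numpy(), rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=data.columns, columns=data.columns)


def agglomerate(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Average-linkage (UPGMA) merge tree from a square distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    labels = list(dist.columns) if isinstance(dist, pd.DataFrame) else [
        str(i) for i in range(d.shape[0])
    ]
    if d.shape[0] == 1:
        return Dendrogram(labels, np.empty((0, 4)))
    condensed = squareform(d, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(labels, z)


def cluster_profiles(profiles: pd.DataFrame, axis: str = "columns") -> Dendrogram:
    """Correlation-distance UPGMA clustering in one call."""
    return agglomerate(correlation_distance(profiles, axis=axis))


def treatment_mean_columns(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-(breed, tissue) mean columns, as used for depot dendrograms.

    Columns are labelled ``breed_tissue`` and average the replicate samples
    of that breed-by-tissue group.
    """
    groups = matrix.samples.groupby(["breed", "tissue"], sort=True).groups
    cols = {}
    for (breed, tissue), ids in groups.items():
        cols[f"{breed}_{tissue}"] = matrix.values[list(ids)].mean(axis=1)
    return pd.DataFrame(cols)
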