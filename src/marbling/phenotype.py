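"""Metabolite-phenotype correlation analysis.

Pearson correlations between plasma metabolite levels and carcass
phenotypes over a small set of animals (n = 8 in the reference design),
with two-sided significance from the exact t transform
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom and flagging at a
raw alpha (no multiplicity correction, matching the source analysis).  At
n = 8 the two-sided 0.05 threshold corresponds to |r| > ~0.707.

Correlation profiles of metabolites and phenotypes can then be jointly
clustered ("correlations of correlations"): variables whose vectors of
correlations to everything else co-vary end up in the same clade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from marbling.clustering import Dendrogram, agglomerate


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p for paired observations (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_table(
    metabolites: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All metabolite x phenotype Pearson correlations over shared animals.

    Both tables are animals x variables; rows are aligned on the shared
    animal index (complete cases per pair).  Returns a tidy frame with one
    row per pair: metabolite, phenotype, n, r, p, significant (at raw
    ``alpha``).
    """
    shared = metabolites.index.intersection(phenotypes.index)
    if len(shared) == 0:
        raise ValueError("metabolite and phenotype tables share no animals")
    met = metabolites.loc[shared]
    phe = phenotypes.loc[shared]
    rows = []
    for m in met.columns:
        for f in phe.columns:
            pair = pd.concat([met[m], phe[f]], axis=1).dropna()
            r, p = pearson_with_p(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            rows.append(
                {
                    "metabolite": m,
                    "phenotype": f,
                    "n": len(pair),
                    "r": r,
                    "p": p,
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def correlation_matrix(
    metabolites: pd.DataFrame, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Full Pearson correlation matrix among all variables (both tables)."""
    shared = metabolites.index.intersection(phenotypes.index)
    if len(shared) == 0:
        raise ValueError("metabolite and phenotype tables share no animals")
    joint = pd.concat([metabolites.loc[shared], phenotypes.loc[shared]], axis=1)
    r = np.corrcoef(joint.to_numpy(), rowvar=False)
    return pd.DataFrame(r, index=joint.columns, columns=joint.columns)


def cluster_correlation_profiles(
    metabolites: pd.DataFrame, phenotypes: pd.DataFrame
) -> Dendrogram:
    """Joint UPGMA tree of metabolites and phenotypes.

    Each variable's profile is its row of the joint correlation matrix;
    profiles are compared by 1 - Pearson r of those rows (correlations of
    correlations), so only positively co-varying relationship patterns
    cluster tightly.
    """
    corr = correlation_matrix(metabolites, phenotypes)
    r2 = np.corrcoef(corr.to_numpy())
    d = np.clip(1.0 - r2, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    dist = pd.DataFrame(d, index=corr.columns, columns=corr.columns)
    return agglomerate(dist)
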