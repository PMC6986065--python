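"""Threshold queries that separate adipocyte signal from muscle contamination.

Dissected intramuscular fat (IMF) unavoidably carries some longissimus dorsi
(LD) muscle, so genes highly expressed in muscle masquerade as IMF-regulated.
Rather than model the admixture, the procedure here ANDs together strict
fold-change criteria on depot means — e.g. "higher in IMF than LD" with
"more than 2-fold higher in IMF than SC" — so that a gene only survives if
its IMF signal cannot be explained by the contaminant.  All thresholds are
log2 differences and all comparisons are strict; "by any amount" is encoded
as threshold 0.

For each AND-combination the report gives probe- and unique-gene-level
counts and the fold enrichment or depletion of the observed intersection
relative to independence (expected = nA * nB / N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

# The canonical single criteria: (left, right, log2 threshold, relation).
# 4-fold = 2.0 log2, 2-fold = 1.0, 1.68-fold = 0.75, 1.32-fold = 0.4;
# the log2 values, not the rounded folds, are primary.
OTHER_FAT_DEPOTS = ("SC", "Inter", "Kid", "Omen")

SINGLE_QUERIES: dict[str, tuple] = {
    "LD_gt_4x_SC": ("LD", "SC", 2.0, "greater"),
    "IMF_gt_1.32x_otherfat": ("IMF", OTHER_FAT_DEPOTS, 0.4, "greater"),
    "IMF_gt_1.68x_otherfat": ("IMF", OTHER_FAT_DEPOTS, 0.75, "greater"),
    "IMF_gt_2x_SC": ("IMF", "SC", 1.0, "greater"),
    "IMF_lt_1.32x_SC": ("IMF", "SC", 0.4, "less"),
    "IMF_gt_2x_LD": ("IMF", "LD", 1.0, "greater"),
    "IMF_gt_LD": ("IMF", "LD", 0.0, "greater"),
    "IMF_lt_LD": ("IMF", "LD", 0.0, "less"),
}

# AND-combinations: name -> component single-query names.
AND_QUERIES: dict[str, tuple[str, str]] = {
    "q2_IMF_adipocyte_vs_fat_1": ("IMF_gt_1.32x_otherfat", "IMF_gt_2x_LD"),
    "q3_IMF_adipocyte_vs_fat_2": ("IMF_gt_1.68x_otherfat", "IMF_gt_LD"),
    "q4_IMF_adipocyte_vs_SC": ("IMF_gt_2x_SC", "IMF_gt_LD"),
    "q5_IMF_down_not_muscle": ("IMF_lt_1.32x_SC", "IMF_lt_LD"),
}


@dataclass(frozen=True)
class CriterionSpec:
    """One strict threshold comparison between two expression summaries.

    ``left`` and ``right`` are either a tissue name or a tuple of tissue
    names (resolved to the unweighted mean of those depot means).  The gene
    passes when ``left - right`` exceeds (relation 'greater') or falls below
    minus (relation 'less') the log2 ``threshold``, strictly.
    """

    left: object
    right: object
    threshold: float
    relation: str = "greater"

    def __post_init__(self) -> None:
        if self.relation not in ("greater", "less"):
            raise ValueError("relation must be 'greater' or 'less'")
        if not math.isfinite(self.threshold) or self.threshold < 0:
            raise ValueError("threshold must be finite and >= 0")


def _resolve(means: pd.DataFrame, selector) -> pd.Series:
    if isinstance(selector, str):
        if selector not in means.columns:
            raise KeyError(
                f"tissue {selector!r} not in mean table; have {list(means.columns)}"
            )
        return means[selector]
    tissues = list(selector)
    missing = [t for t in tissues if t not in means.columns]
    if missing:
        raise KeyError(f"tissues {missing} not in mean table")
    return means[tissues].mean(axis=1)


def apply_criterion(means: pd.DataFrame, spec: CriterionSpec) -> pd.Index:
    """Probe ids passing one strict threshold criterion on depot means."""
    diff = _resolve(means, spec.left) - _resolve(means, spec.right)
    if spec.relation == "greater":
        mask = diff > spec.threshold
    else:
        mask = diff < -spec.threshold
    return means.index[mask]


def combine_and(sets, probe_map: pd.Series | None = None) -> dict:
    """Intersect >=2 probe sets; report probe- and gene-level counts."""
    sets = [pd.Index(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to combine")
    inter = sets[0]
    for s in sets[1:]:
        inter = inter.intersection(s)
    genes = None
    if probe_map is not None:
        genes = sorted(set(probe_map.reindex(inter).dropna()))
    return {
        "probes": inter,
        "probe_count": len(inter),
        "genes": genes,
        "unique_gene_count": len(genes) if genes is not None else None,
    }


def independence_ratio(n_a: int, n_b: int, background: int, observed: int) -> dict:
    """Fold enrichment/depletion of an intersection versus independence.

    expected = nA * nB / N.  When observed >= expected the ratio is
    observed/expected (enrichment); otherwise expected/observed (depletion).
    An observed count of 0 with nonzero expectation reports infinite
    depletion.
    """
    if background <= 0:
        raise ValueError("background count must be positive")
    if not (0 <= n_a <= background and 0 <= n_b <= background):
        raise ValueError("marginal counts must lie in [0, background]")
    if observed > min(n_a, n_b):
        raise ValueError("observed exceeds the smaller marginal count")
    expected = n_a * n_b / background
    if observed >= expected:
        mode = "enrichment"
        ratio = observed / expected if expected > 0 else math.inf
    else:
        mode = "depletion"
        ratio = expected / observed if observed > 0 else math.inf
    return {"expected": expected, "ratio": ratio, "mode": mode}


def run_named_queries(
    means: pd.DataFrame,
    probe_map: pd.Series | None = None,
    background: pd.Index | None = None,
) -> pd.DataFrame:
    """Execute the canonical single and AND threshold queries.

    ``means`` must contain the tissues IMF, SC, LD, Inter, Kid, Omen.  The
    report has one row per query with probe and unique-gene counts, percent
    of background, and (for AND rows) the expected overlap under
    independence plus the enrichment/depletion ratio computed on probe-level
    counts against the full probe background.
    """
    if background is None:
        background = means.index
    else:
        background = pd.Index(background)
    means = means.loc[means.index.intersection(background)]
    n_bg = len(background)
    if n_bg == 0:
        return pd.DataFrame(
            columns=[
                "query", "kind", "probe_count", "unique_gene_count",
                "percent_of_background", "expected", "ratio", "mode", "genes",
            ]
        )

    singles: dict[str, pd.Index] = {}
    rows = []
    for name, (left, right, thr, rel) in SINGLE_QUERIES.items():
        hits = apply_criterion(means, CriterionSpec(left, right, thr, rel))
        singles[name] = hits
        genes = (
            sorted(set(probe_map.reindex(hits).dropna())) if probe_map is not None else None
        )
        rows.append(
            {
                "query": name,
                "kind": "single",
                "probe_count": len(hits),
                "unique_gene_count": len(genes) if genes is not None else None,
                "percent_of_background": 100.0 * len(hits) / n_bg,
                "expected": np.nan,
                "ratio": np.nan,
                "mode": "",
                "genes": genes,
            }
        )
    for name, (a, b) in AND_QUERIES.items():
        combo = combine_and([singles[a], singles[b]], probe_map)
        ind = independence_ratio(
            len(singles[a]), len(singles[b]), n_bg, combo["probe_count"]
        )
        rows.append(
            {
                "query": name,
                "kind": "and",
                "probe_count": combo["probe_count"],
                "unique_gene_count": combo["unique_gene_count"],
                "percent_of_background": 100.0 * combo["probe_count"] / n_bg,
                "expected": ind["expected"],
                "ratio": ind["ratio"],
                "mode": ind["mode"],
                "genes": combo["genes"],
            }
        )
    return pd.DataFrame(rows)


def contamination_colour(m_imf_vs_ld, clip: float = 2.0):
    """Continuous colour score in [0, 1] from the IMF-minus-LD log2 contrast.

    Genes higher in IMF than in the contaminant muscle (M > 0) score above
    0.5 and are credibly expressed by the marbling adipocytes themselves;
    the map is linear in M, clipped at +/-``clip`` log2 units.
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    m = np.clip(np.asarray(m_imf_vs_ld, dtype=float), -clip, clip)
    out = (m + clip) / (2.0 * clip)
    return float(out) if out.ndim == 0 else out
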