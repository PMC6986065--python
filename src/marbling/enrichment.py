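"""Hypergeometric gene-set over-representation with BH q-values.

This is the verification instrument for the contamination filters: a target
list still carrying muscle contamination lights up a "muscle system
process"-like annotation set; a clean list does not.  Testing is at gene
(not probe) level, annotation sets are intersected with the supplied
background before testing, and the BH denominator m is the number of sets
with nonzero background intersection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from marbling.io import GeneSetCollection


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_upper_tail(k: int, set_size: int, target_size: int, background: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=background, K=set_size, n=target_size).

    Exact summation of the pmf in log space over the attainable overlap
    values; no normal approximation.
    """
    if not (0 <= set_size <= background and 0 <= target_size <= background):
        raise ValueError("set and target sizes must lie in [0, background]")
    if not 0 <= k <= min(set_size, target_size):
        raise ValueError("k must lie in [0, min(set_size, target_size)]")
    lo = max(k, set_size + target_size - background)
    hi = min(set_size, target_size)
    if lo > hi:
        return 0.0
    i = np.arange(lo, hi + 1)
    log_terms = (
        _log_binom(set_size, i)
        + _log_binom(background - set_size, target_size - i)
        - _log_binom(background, target_size)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_i = min over j with p_j >= p_i of (m / rank_j) * p_j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(target, background, sets: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of each annotation set in a target gene list.

    ``target`` must be a subset of ``background`` (both upper-case
    normalized here).  Sets are intersected with the background first; sets
    with empty intersection are not tested.  Returns one row per tested set
    with overlap k, set size K, target size n, background size N, the exact
    hypergeometric upper-tail p, and the BH q over the tested sets, ranked
    by p.
    """
    bg = frozenset(str(g).upper() for g in background)
    tgt = frozenset(str(g).upper() for g in target)
    stray = tgt - bg
    if stray:
        raise ValueError(f"target genes missing from background: {sorted(stray)[:5]}")
    n_bg, n_tgt = len(bg), len(tgt)
    rows = []
    for name, members in sets.sets.items():
        in_bg = members & bg
        if not in_bg:
            continue
        k = len(in_bg & tgt)
        p = hypergeometric_upper_tail(k, len(in_bg), n_tgt, n_bg)
        rows.append({"set": name, "k": k, "K": len(in_bg), "n": n_tgt, "N": n_bg, "p": p})
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(result):
        result["q"] = bh_qvalues(result["p"].to_numpy())
        result = result.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    return result
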