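"""Per-gene summarization and scoring between fat depots.

The central statistic is the Phenotypic Impact Factor (PIF): the log2
differential expression M between two depots multiplied by the average log2
abundance A across them.  PIF de-emphasizes lowly expressed, noisy probes
relative to ranking on M alone.  PIF values are z-scored across the table
and passed through the standard-normal upper tail to give one-tailed
p-values; differential expression is additionally tested with a classical
pooled-variance two-sample t-test on the replicate samples.

Scoring happens at probe level; :func:`collapse_probes` then keeps, for
every gene, the probe with the largest |PIF|, which is how a one-row-per-
gene ranking is produced on a platform where most genes have several probes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from marbling.io import ExpressionMatrix

SCORE_COLUMNS = [
    "probe",
    "gene",
    "mean_a",
    "mean_b",
    "M",
    "A",
    "signed_fc",
    "t_p",
    "pif",
    "pif_z",
    "pif_p",
]


def depot_means(matrix: ExpressionMatrix, tissue: str) -> pd.Series:
    """Arithmetic mean log2 expression per probe over all samples of a depot.

    Replicates are pooled across breeds with equal weight per sample (12
    samples in the reference design: 3 breeds x 4 replicates).
    """
    cols = matrix.samples_for(tissue)
    if not cols:
        raise KeyError(
            f"tissue {tissue!r} not present; available: {matrix.tissues}"
        )
    if len(cols) < 2:
        raise ValueError(f"tissue {tissue!r} has fewer than 2 samples")
    return matrix.values[cols].mean(axis=1).rename(tissue)


def depot_mean_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Probe x tissue table of depot means for every tissue in the matrix."""
    return pd.concat([depot_means(matrix, t) for t in matrix.tissues], axis=1)


def ma_transform(mean_a, mean_b):
    """MA coordinates: M = mean_a - mean_b, A = (mean_a + mean_b) / 2."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    m = mean_a - mean_b
    a = (mean_a + mean_b) / 2.0
    if m.ndim == 0:
        return float(m), float(a)
    return m, a


def signed_fold_change(m):
    """Linear fold change with the signed table convention.

    ``+2**M`` for M >= 0 and ``-2**(-M)`` for M < 0, so a gene 2.2-fold
    lower in the first depot reports -2.20 rather than 0.45.
    """
    m = np.asarray(m, dtype=float)
    fc = np.where(m >= 0, np.exp2(m), -np.exp2(-m))
    return float(fc) if fc.ndim == 0 else fc


def equal_variance_t_test(group_a, group_b):
    """Two-sided pooled-variance t-test p-value(s).

    Accepts 1-D groups (one test) or 2-D arrays (probes x replicates, one
    test per row).  Degenerate rows with zero pooled variance return p = 1
    when the means are equal and p = 0 when they differ; both are
    conventions for data with no within-group spread.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean(axis=1) - b.mean(axis=1)
    p = np.empty(a.shape[0])
    zero = pooled <= 0
    p[zero] = np.where(diff[zero] == 0, 1.0, 0.0)
    ok = ~zero
    if ok.any():
        se = np.sqrt(pooled[ok] * (1.0 / na + 1.0 / nb))
        t = diff[ok] / se
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    return float(p[0]) if np.asarray(group_a).ndim == 1 else p


def pif(m, mean_a, mean_b):
    """Phenotypic Impact Factor: M times the average abundance A."""
    m = np.asarray(m, dtype=float)
    a = (np.asarray(mean_a, dtype=float) + np.asarray(mean_b, dtype=float)) / 2.0
    out = m * a
    return float(out) if out.ndim == 0 else out


def pif_significance(pif_values):
    """z-score PIF over the table; one-tailed standard-normal p per entry.

    z = (PIF - mean) / sd over the supplied vector (sample sd, ddof=1);
    p = P(Z > |z|), i.e. extremeness regardless of sign, so both strongly
    up- and strongly down-regulated genes earn small p-values.
    """
    v = np.asarray(pif_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 PIF values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("PIF values have zero spread")
    z = (v - v.mean()) / sd
    p = stats.norm.sf(np.abs(z))
    return z, p


def score_table(
    matrix: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    probe_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Full probe-level score table for the ``tissue_a`` vs ``tissue_b`` contrast.

    Columns: probe, gene, mean_a, mean_b, M, A, signed_fc, t_p, pif, pif_z,
    pif_p.  PIF z-scoring is performed over the complete probe-level table,
    before any collapse to genes.
    """
    mean_a = depot_means(matrix, tissue_a)
    mean_b = depot_means(matrix, tissue_b)
    m, a = ma_transform(mean_a.to_numpy(), mean_b.to_numpy())
    vals_a = matrix.values[matrix.samples_for(tissue_a)].to_numpy()
    vals_b = matrix.values[matrix.samples_for(tissue_b)].to_numpy()
    t_p = equal_variance_t_test(vals_a, vals_b)
    pif_v = m * a
    z, p1 = pif_significance(pif_v)
    table = pd.DataFrame(
        {
            "probe": matrix.probe_ids.astype(str),
            "gene": (
                probe_map.reindex(matrix.probe_ids).to_numpy()
                if probe_map is not None
                else matrix.probe_ids.astype(str)
            ),
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "M": m,
            "A": a,
            "signed_fc": signed_fold_change(m),
            "t_p": t_p,
            "pif": pif_v,
            "pif_z": z,
            "pif_p": p1,
        }
    )
    if probe_map is not None and table["gene"].isna().any():
        missing = table.loc[table["gene"].isna(), "probe"].tolist()
        raise KeyError(f"probes missing from probe map: {missing[:5]}")
    return table.reset_index(drop=True)


def collapse_probes(table: pd.DataFrame, probe_map: pd.Series | None = None) -> pd.DataFrame:
    """One row per gene: keep the probe with maximal |PIF|.

    Ties are broken by lexicographic probe id so the result is
    deterministic.  If ``probe_map`` is given it overrides/defines the
    table's gene column; every probe must be mapped.
    """
    t = table.copy()
    if probe_map is not None:
        genes = probe_map.reindex(t["probe"])
        if genes.isna().any():
            missing = list(genes.index[genes.isna()])
            raise KeyError(f"probes missing from probe map: {missing[:5]}")
        t["gene"] = genes.to_numpy()
    if "gene" not in t.columns:
        raise ValueError("table has no gene column and no probe map given")
    t = t.assign(_abs_pif=t["pif"].abs()).sort_values(
        ["gene", "_abs_pif", "probe"], ascending=[True, False, True]
    )
    out = t.drop_duplicates("gene", keep="first").drop(columns="_abs_pif")
    return out.reset_index(drop=True)


def select_extreme(table: pd.DataFrame, fraction: float, direction: str) -> pd.DataFrame:
    """The most extreme ``fraction`` of records by PIF, up- or down-regulated.

    The subset size is round-half-up(fraction * N): 1% of 14,476 records is
    145 and 5% is 724.  ``direction='up'`` takes the largest PIF values,
    ``'down'`` the most negative.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    n = len(table)
    count = int(math.floor(fraction * n + 0.5))
    ordered = table.sort_values(
        ["pif", "probe"] if "probe" in table.columns else "pif",
        ascending=[direction == "down", True] if "probe" in table.columns else (direction == "down"),
    )
    return ordered.head(count).reset_index(drop=True)


def tabulate_panel(
    gene_list,
    means: pd.DataFrame,
    scores: pd.DataFrame,
    decimals: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Report table for a curated gene panel.

    For each resolvable gene: the per-tissue log2 means, signed fold change,
    M, and the t-test and PIF p-values, rounded to ``decimals``.  ``scores``
    must be a gene-level (collapsed) table; ``means`` a probe x tissue
    table.  Genes absent from the score table (e.g. not expressed on the
    platform) are returned in the side list, not treated as fatal.
    """
    wanted = [str(g).upper() for g in gene_list]
    idx = scores.set_index(scores["gene"].astype(str).str.upper())
    rows, missing = [], []
    for gene in wanted:
        if gene not in idx.index:
            missing.append(gene)
            continue
        rec = idx.loc[gene]
        probe = rec["probe"]
        row = {"gene": gene, "probe": probe}
        for tissue in means.columns:
            row[tissue] = round(float(means.at[probe, tissue]), decimals)
        row["signed_fc"] = round(float(rec["signed_fc"]), decimals)
        row["M"] = round(float(rec["M"]), decimals)
        row["t_p"] = float(rec["t_p"])
        row["pif_p"] = float(rec["pif_p"])
        rows.append(row)
    columns = ["gene", "probe", *means.columns, "signed_fc", "M", "t_p", "pif_p"]
    report = pd.DataFrame(rows, columns=columns)
    return report, missing
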