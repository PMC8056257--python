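"""Expression-based validation statistics.

Two statistics validate candidate genes against tissue expression data:

* a two-sided Wilcoxon rank-sum test comparing a gene's expression between
  two groups (e.g. vastus lateralis muscle biopsies from 16 young vs 12 old
  adults), exact by full enumeration of rank assignments when the total
  sample size is small and tie-free, otherwise a normal approximation with
  mid-ranks, tie correction and continuity correction;
* the correlation (Pearson by default, Spearman optional) of a gene's
  expression with a continuous trait (e.g. whole-body BMD across 84 iliac
  bone biopsies), with a two-sided t-distribution p-value.

No multiple-testing correction is applied by default — per-gene p < 0.05 is
reported as nominal significance — but Benjamini-Hochberg across genes is
available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 20  # full-enumeration rank-sum path bound

METHOD_EXACT = "exact"
METHOD_NORMAL = "normal-approx"
METHOD_CORR = "correlation"


@dataclass
class ValidationResult:
    gene: str
    statistic: float | None
    p_value: float | None
    n: tuple
    method: str
    undefined: bool = False
    note: str = ""


@lru_cache(maxsize=None)
def _ranksum_pmf(n_a: int, n_total: int):
    """Exact null pmf of the group-A rank sum W over all C(n_total, n_a)
    equally likely assignments of ranks 1..n_total (no ties).

    Dynamic programming over ranks: table[k][s] = number of k-subsets of the
    ranks seen so far with sum s.  Returns (support offset = min W, counts).
    """
    max_sum = n_total * (n_total + 1) // 2
    table = np.zeros((n_a + 1, max_sum + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(n_a, r), 0, -1):
            table[k, r:] += table[k - 1, : max_sum + 1 - r]
    counts = table[n_a]
    total = counts.sum()
    return counts / total


def exact_ranksum_p(w: float, n_a: int, n_total: int) -> float:
    """Two-sided exact p-value for rank sum ``w`` of a group of size ``n_a``:
    twice the smaller inclusive tail, capped at 1."""
    pmf = _ranksum_pmf(n_a, n_total)
    w = int(round(w))
    lower = pmf[: w + 1].sum()
    upper = pmf[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def rank_sum_test(group_a, group_b, gene: str = "") -> ValidationResult:
    """Two-sided Wilcoxon rank-sum test between two expression groups.

    Exact enumeration when total n <= 20 with no ties; otherwise mid-ranks
    with the normal approximation (tie + continuity corrected, via
    scipy.stats.mannwhitneyu).  The reported statistic is the group-A rank
    sum W; the method tag records which path ran.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    n_a, n_total = a.size, combined.size
    ranks = stats.rankdata(combined)
    w = float(ranks[:n_a].sum())
    has_ties = np.unique(combined).size < n_total

    if n_total <= EXACT_MAX_N and not has_ties:
        p = exact_ranksum_p(w, n_a, n_total)
        method = METHOD_EXACT
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
        p = float(min(1.0, p))
        method = METHOD_NORMAL
    return ValidationResult(gene=gene, statistic=w, p_value=p,
                            n=(int(n_a), int(b.size)), method=method)


def trait_correlation(expression, trait, method: str = "pearson",
                      gene: str = "") -> ValidationResult:
    """Correlation of per-sample expression with a continuous trait.

    Pairwise-complete observations are used; the two-sided p comes from the
    t distribution with n-2 degrees of freedom.  Zero variance in either
    vector yields a flagged undefined result rather than NaN propagation.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and trait must be aligned")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("correlation requires at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ValidationResult(gene=gene, statistic=None, p_value=None,
                                n=(int(x.size),), method=METHOD_CORR,
                                undefined=True, note="zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return ValidationResult(gene=gene, statistic=float(r), p_value=float(p),
                            n=(int(x.size),), method=f"{METHOD_CORR}-{method}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata
    (group label and/or continuous trait)."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    metadata: pd.DataFrame  # index = sample ids; columns may include group, trait

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")


def read_expression(values_path, metadata_path) -> ExpressionMatrix:
    """Read genes-x-samples TSV and a metadata TSV (sample, group, trait)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, metadata=metadata)


def validate_genes(
    expr: ExpressionMatrix,
    genes=None,
    group_col: str = "group",
    trait_col: str | None = None,
    correlation_method: str = "pearson",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene validation over an expression matrix.

    With ``group_col`` present in the metadata, runs the rank-sum test
    between the two group labels; with ``trait_col`` given, adds the
    expression-trait correlation.  ``bh_adjust=True`` appends
    Benjamini-Hochberg adjusted p-values across the tested genes.
    """
    gene_list = list(genes) if genes is not None else list(expr.values.index)
    present = [g for g in gene_list if g in expr.values.index]
    meta = expr.metadata.loc[list(expr.values.columns)]

    group_split = None
    if group_col in meta.columns:
        labels = meta[group_col].dropna().unique()
        if len(labels) != 2:
            raise ValueError(f"rank-sum validation needs exactly 2 groups, got {list(labels)}")
        ga = meta.index[meta[group_col] == labels[0]]
        gb = meta.index[meta[group_col] == labels[1]]
        group_split = (labels, ga, gb)

    rows = []
    for g in present:
        v = expr.values.loc[g]
        rec = {"gene": g, "detected": True}
        if group_split is not None:
            labels, ga, gb = group_split
            res = rank_sum_test(v[ga], v[gb], gene=g)
            rec.update(ranksum_W=res.statistic, ranksum_p=res.p_value,
                       ranksum_method=res.method, n_a=res.n[0], n_b=res.n[1])
        if trait_col is not None and trait_col in meta.columns:
            res = trait_correlation(v.to_numpy(), meta[trait_col].to_numpy(),
                                    method=correlation_method, gene=g)
            rec.update(corr_r=res.statistic, corr_p=res.p_value,
                       corr_method=res.method, corr_undefined=res.undefined)
        rows.append(rec)
    for g in gene_list:
        if g not in expr.values.index:
            rows.append({"gene": g, "detected": False})
    out = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["gene", "detected"])
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        for col in ("ranksum_p", "corr_p"):
            if col in out.columns:
                mask = out[col].notna()
                adj = np.full(len(out), np.nan)
                if mask.any():
                    adj[mask.to_numpy()] = multipletests(
                        out.loc[mask, col], method="fdr_bh"
                    )[1]
                out[col + "_bh"] = adj
    return out
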