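"""Conditional and conjunction FDR from paired GWAS p-values.

For SNP i with principal-trait p-value p_i and conditional-trait p-value
q_i, the empirical-count conditional FDR estimator is

    cFDR_i = min(1, p_i * #{j: q_j <= q_i} / #{j: p_j <= p_i and q_j <= q_i})

i.e. the nominal p-value rescaled by the empirical conditional CDF ratio
F(q) / F(p, q), with the null proportion conservatively set to 1.  Counts
are inclusive of SNP i itself, so the denominator is never zero and tied
p-values share the largest qualifying count.  With every conditional
p-value equal to 1 this reduces exactly to the unconditional
Benjamini-Hochberg-style estimator p * N / rank.

The conjunction ccFDR — the estimated probability that a SNP is associated
with *neither* trait — is the elementwise maximum of the two
conditioning-direction cFDRs.

The joint counts are 2-D dominance counts, computed in O(N log N) with a
Fenwick (binary indexed) tree; a numba-compiled kernel is used when numba
is importable, with an identical pure-Python fallback.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "conditional_fdr",
    "compute_cfdr",
    "compute_ccfdr",
    "unconditional_fdr",
    "cfdr_table",
    "manhattan_table",
]


def _joint_count_kernel(p_sorted, qr_sorted, n_qranks):
    """counts[k] = #{j: p_j <= p_k, q_j <= q_k} for entries given in
    nondecreasing p order; qr_sorted are 1-based dense q ranks."""
    n = p_sorted.shape[0]
    tree = np.zeros(n_qranks + 1, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j < n and p_sorted[j] == p_sorted[i]:
            j += 1
        for k in range(i, j):  # insert the whole tie group first (counts inclusive)
            idx = qr_sorted[k]
            while idx <= n_qranks:
                tree[idx] += 1
                idx += idx & (-idx)
        for k in range(i, j):
            idx = qr_sorted[k]
            s = 0
            while idx > 0:
                s += tree[idx]
                idx -= idx & (-idx)
            out[k] = s
        i = j
    return out


try:  # optional acceleration; the fallback is the same code path
    from numba import njit

    _joint_count_fast = njit(cache=False)(_joint_count_kernel)
except Exception:  # pragma: no cover - numba present in the supported env
    _joint_count_fast = _joint_count_kernel


def _validate_p(p, name):
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError(f"empty {name} array")
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        raise ValueError(f"{name} values must lie in (0, 1]")
    return p


def joint_counts(p, q) -> np.ndarray:
    """#{j: p_j <= p_i and q_j <= q_i} for each i (inclusive of i)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    uq = np.unique(q)
    qr = (np.searchsorted(uq, q) + 1).astype(np.int64)
    order = np.argsort(p, kind="mergesort")
    counts_sorted = _joint_count_fast(p[order], qr[order], len(uq))
    out = np.empty_like(counts_sorted)
    out[order] = counts_sorted
    return out


def conditional_fdr(p, q) -> np.ndarray:
    """Per-SNP cFDR of the principal p-values ``p`` given conditional ``q``.

    Both arrays must be aligned by SNP and lie in (0, 1].  Output is in
    (0, 1], aligned with the input order.
    """
    p = _validate_p(p, "principal p")
    q = _validate_p(q, "conditional p")
    if p.shape != q.shape:
        raise ValueError("principal and conditional p arrays must be aligned")
    q_counts = np.searchsorted(np.sort(q), q, side="right")
    denom = joint_counts(p, q)
    return np.minimum(1.0, p * q_counts / denom)


def compute_cfdr(merged, principal: int = 1) -> np.ndarray:
    """cFDR over a merged pair table, conditioning on the other trait.

    ``principal`` selects which trait's p-values are rescaled (1 -> p1|p2,
    2 -> p2|p1).  Accepts a MergedPairTable or a DataFrame with p1/p2.
    """
    df = merged.df if hasattr(merged, "df") else merged
    if principal not in (1, 2):
        raise ValueError("principal must be 1 or 2")
    p, q = (df["p1"], df["p2"]) if principal == 1 else (df["p2"], df["p1"])
    return conditional_fdr(p, q)


def compute_ccfdr(cfdr_a, cfdr_b) -> np.ndarray:
    """Conjunction ccFDR: elementwise maximum of the two aligned cFDR arrays."""
    a = np.asarray(cfdr_a, dtype=float)
    b = np.asarray(cfdr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("cFDR arrays must have equal length")
    return np.maximum(a, b)


def unconditional_fdr(p) -> np.ndarray:
    """Single-trait baseline: FDR_i = min(1, p_i * N / rank_i), rank inclusive
    of ties (equals :func:`conditional_fdr` with all conditional p = 1)."""
    p = _validate_p(p, "p")
    rank = np.searchsorted(np.sort(p), p, side="right")
    return np.minimum(1.0, p * p.size / rank)


def monotonize(values, p) -> np.ndarray:
    """Optional lookup-table semantics: enforce cFDR non-decreasing in the
    principal p-value via suffix minima over the p-sorted order."""
    values = np.asarray(values, dtype=float)
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="mergesort")
    v = values[order]
    v = np.minimum.accumulate(v[::-1])[::-1]
    out = np.empty_like(v)
    out[order] = v
    return out


def cfdr_table(merged, threshold: float = 0.05, monotone: bool = False) -> pd.DataFrame:
    """Full per-SNP result: both conditioning directions, ccFDR and
    significance calls at the (strict) threshold.

    Returns a DataFrame with snp_id/chrom/pos/p1/p2, cfdr_1_given_2,
    cfdr_2_given_1, ccfdr and boolean sig_* columns.
    """
    df = merged.df if hasattr(merged, "df") else merged
    if len(df) == 0:
        raise ValueError("empty merged table")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    c12 = conditional_fdr(df["p1"], df["p2"])
    c21 = conditional_fdr(df["p2"], df["p1"])
    if monotone:
        c12 = monotonize(c12, df["p1"].to_numpy())
        c21 = monotonize(c21, df["p2"].to_numpy())
    cc = compute_ccfdr(c12, c21)
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].values if "snp_id" in df else np.arange(len(df)),
            "chrom": df["chrom"].values if "chrom" in df else "",
            "pos": df["pos"].values if "pos" in df else 0,
            "p1": np.asarray(df["p1"], dtype=float),
            "p2": np.asarray(df["p2"], dtype=float),
            "cfdr_1_given_2": c12,
            "cfdr_2_given_1": c21,
            "ccfdr": cc,
            "sig_1_given_2": c12 < threshold,
            "sig_2_given_1": c21 < threshold,
            "sig_conjunction": cc < threshold,
        }
    )
    return out


def manhattan_table(values, threshold: float = 0.05, snps: pd.DataFrame | None = None):
    """Manhattan-plot data: y = -log10(value), flagged against the reference
    line at -log10(threshold) rounded to one decimal (1.3 for 0.05).

    Returns (DataFrame with y/above_line, line_height).
    """
    v = np.asarray(values, dtype=float)
    if (v <= 0).any() or (v > 1).any():
        raise ValueError("values must lie in (0, 1]")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    line = round(-np.log10(threshold), 1)
    df = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].values if snps is not None else np.arange(v.size),
            "chrom": snps["chrom"].values if snps is not None else "",
            "pos": snps["pos"].values if snps is not None else 0,
            "value": v,
            "y": -np.log10(v),
            "above_line": v < threshold,
        }
    )
    return df, line
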