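"""Conditional (stratified) Q-Q curves and a scalar pleiotropic-enrichment
summary.

Each stratum is the subset of SNPs whose conditional-trait p-value falls at
or below a cutoff; within a stratum the principal-trait p-values are plotted
as nominal -log10(p) (y) against empirical quantiles -log10(k/(n+1)) (x).
Under pleiotropic enrichment the curves for stricter conditional cutoffs
deviate upward/leftward from the all-SNPs curve; the deflection area between
a stratum's curve and the reference curve quantifies that visual pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)


@dataclass
class QQStratum:
    """One conditional stratum's Q-Q curve (points sorted by x ascending)."""

    threshold: float
    points: pd.DataFrame  # columns x, y
    n: int


def stratified_qq(
    merged,
    principal: int = 1,
    thresholds=DEFAULT_THRESHOLDS,
    quantile: str = "k/(n+1)",
) -> list[QQStratum]:
    """Build conditional Q-Q curves, one per conditional-trait cutoff.

    The k-th smallest principal p in a stratum of size n gets empirical
    quantile k/(n+1) by default ((k-0.5)/n available via ``quantile``),
    which keeps -log10 finite at the extreme order statistic.  Empty
    strata are omitted with a warning.
    """
    df = merged.df if hasattr(merged, "df") else merged
    if len(df) == 0:
        raise ValueError("empty merged table")
    thresholds = [float(t) for t in thresholds]
    if any(t <= 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if principal not in (1, 2):
        raise ValueError("principal must be 1 or 2")
    p = np.asarray(df["p1" if principal == 1 else "p2"], dtype=float)
    q = np.asarray(df["p2" if principal == 1 else "p1"], dtype=float)

    strata = []
    for t in sorted(thresholds, reverse=True):
        sel = np.sort(p[q <= t])
        n = sel.size
        if n == 0:
            warnings.warn(f"stratified_qq: stratum q<={t:g} is empty, omitted")
            continue
        k = np.arange(1, n + 1)
        if quantile == "k/(n+1)":
            eq = k / (n + 1)
        elif quantile == "(k-0.5)/n":
            eq = (k - 0.5) / n
        else:
            raise ValueError(f"unknown quantile convention {quantile!r}")
        pts = pd.DataFrame({"x": -np.log10(eq), "y": -np.log10(sel)})
        pts = pts.sort_values("x", kind="mergesort").reset_index(drop=True)
        strata.append(QQStratum(threshold=t, points=pts, n=n))
    return strata


def strata_to_frame(strata: list[QQStratum]) -> pd.DataFrame:
    """Long-format table (stratum_threshold, x, y, n) for writing/plotting."""
    frames = [
        s.points.assign(stratum_threshold=s.threshold, n=s.n) for s in strata
    ]
    return pd.concat(frames, ignore_index=True)[["stratum_threshold", "x", "y", "n"]]


def enrichment_area(
    strata: list[QQStratum], reference: float = 1.0, grid_size: int = 200
) -> pd.DataFrame:
    """Signed deflection area of each stratum's curve relative to the
    reference (all-SNPs) curve.

    Curves are linearly interpolated onto a common grid over the overlapping
    -log10(q) range; the trapezoidal integral of (y_stratum - y_reference)
    is positive when the stratum lies above the reference (enrichment).
    Strata with fewer than 2 points get a NaN deflection and are flagged.
    """
    by_t = {s.threshold: s for s in strata}
    if reference not in by_t:
        raise ValueError(f"reference stratum {reference!r} not present")
    ref = by_t[reference]
    rows = []
    for s in strata:
        if len(s.points) < 2 or len(ref.points) < 2:
            rows.append((s.threshold, np.nan, s.n, True))
            continue
        lo = max(s.points["x"].min(), ref.points["x"].min())
        hi = min(s.points["x"].max(), ref.points["x"].max())
        if hi <= lo:
            rows.append((s.threshold, np.nan, s.n, True))
            continue
        grid = np.linspace(lo, hi, grid_size)
        ys = np.interp(grid, s.points["x"], s.points["y"])
        yr = np.interp(grid, ref.points["x"], ref.points["y"])
        rows.append((s.threshold, float(np.trapezoid(ys - yr, grid)), s.n, False))
    return pd.DataFrame(rows, columns=["stratum_threshold", "deflection", "n", "undefined"])
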