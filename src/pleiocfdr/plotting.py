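"""Thin optional rendering layer: stratified Q-Q curves and Manhattan plots.

All statistics are emitted as data tables elsewhere; these helpers only
draw them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def qq_plot(strata_by_tag: dict, path, figsize=(10, 4.5)) -> None:
    """One panel per conditioning direction; one curve per conditional
    cutoff, plus the identity line expected under the null."""
    n_panels = len(strata_by_tag)
    fig, axes = plt.subplots(1, n_panels, figsize=figsize, squeeze=False)
    for ax, (tag, strata) in zip(axes[0], strata_by_tag.items()):
        lim = 0.0
        for s in strata:
            ax.plot(s.points["x"], s.points["y"], lw=1,
                    label=f"q ≤ {s.threshold:g} (n={s.n})")
            lim = max(lim, s.points["x"].max())
        ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="expected")
        ax.set_xlabel(r"empirical $-\log_{10}(q)$")
        ax.set_ylabel(r"nominal $-\log_{10}(p)$")
        ax.set_title(tag)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def manhattan_plot(mh, line: float, path, title: str = "", figsize=(10, 3.5)) -> None:
    """Manhattan plot of -log10 cFDR/ccFDR with the significance reference
    line (1.3 for the 0.05 threshold)."""
    fig, ax = plt.subplots(figsize=figsize)
    chroms = list(dict.fromkeys(mh["chrom"]))
    offset = 0
    ticks = []
    for i, c in enumerate(chroms):
        sub = mh[mh["chrom"] == c]
        x = offset + np.arange(len(sub))
        ax.scatter(x, sub["y"], s=4, color="C0" if i % 2 == 0 else "C2",
                   rasterized=True)
        ticks.append((offset + len(sub) / 2, str(c)))
        offset += len(sub)
    ax.axhline(line, color="red", lw=1)
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([l for _, l in ticks], fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}$ value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
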