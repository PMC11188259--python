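"""Manhattan-style plots for the two GWAS stages."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["manhattan"]


def manhattan(
    frame: pd.DataFrame,
    threshold: float | None = None,
    path=None,
    title: str = "",
):
    """Plot -log10(p) against cumulative genome position.

    ``frame`` needs columns chrom, pos and neg_log10_p.  Chromosomes are
    laid out in sorted label order with alternating shades; an optional
    horizontal significance line marks the Bonferroni threshold.
    Returns the matplotlib figure (saved to ``path`` when given).
    """
    frame = frame.copy()
    frame["chrom"] = frame["chrom"].astype(str)
    chroms = sorted(frame["chrom"].unique(), key=lambda c: (len(c), c))
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, chrom in enumerate(chroms):
        sub = frame[frame["chrom"] == chrom].sort_values("pos")
        x = offset + sub["pos"].to_numpy()
        ax.scatter(x, sub["neg_log10_p"], s=6,
                   color="#444444" if i % 2 else "#1f77b4")
        ticks.append(offset + sub["pos"].mean() if len(sub) else offset)
        labels.append(chrom)
        offset = x.max() + 1 if len(sub) else offset
    if threshold is not None:
        ax.axhline(threshold, color="red", ls="--", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
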