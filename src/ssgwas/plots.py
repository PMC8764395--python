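"""Convenience plots over the result tables (the TSVs are the contract)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan_plot(results: pd.DataFrame, thresholds=None, ax=None):
    """Manhattan plot from a per-SNP results table (chrom, pos_bp, p)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for chrom, grp in results.dropna(subset=["p"]).groupby("chrom"):
        x = grp["pos_bp"] + offset
        ax.scatter(x, -np.log10(grp["p"]), s=4,
                   color="steelblue" if chrom % 2 else "darkorange")
        ticks.append((offset + grp["pos_bp"].max() / 2, str(chrom)))
        offset += grp["pos_bp"].max()
    if thresholds is not None:
        ax.axhline(thresholds.significant_logp, ls="--", color="red", lw=0.8)
        ax.axhline(-np.log10(thresholds.suggestive_p), ls=":", color="gray", lw=0.8)
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([c for _, c in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    return ax


def qq_plot(p_values: np.ndarray, ax=None):
    """Observed vs expected quantiles of -log10 p under the uniform null."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    p = np.sort(np.asarray(p_values)[~np.isnan(p_values)])
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    ax.scatter(exp, -np.log10(p), s=4, color="black")
    ax.plot([0, exp.max()], [0, exp.max()], color="red", lw=0.8)
    ax.set_xlabel("expected " + r"$-\log_{10}(p)$")
    ax.set_ylabel("observed " + r"$-\log_{10}(p)$")
    return ax


def ld_decay_plot(summary: pd.DataFrame, ax=None):
    """Mean r^2 per distance bin from ``ld_decay_summary`` output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(summary["dist_mb_low"], summary["r2_mean"], marker="o", ms=3)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.set_ylim(0, None)
    return ax
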