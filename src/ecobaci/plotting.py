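"""Minimal plotting helper: BACI effects with error bars on an asinh scale."""

from __future__ import annotations

import numpy as np

from .baci import BACIResult, asinh_scale


def plot_baci(result: BACIResult, path=None, ax=None):
    """Point-and-error-bar chart of per-taxon BACI effects.

    Effects and their +/- 1 SE intervals are transformed with the inverse
    hyperbolic sine so that taxa spanning orders of magnitude share one axis;
    the mean abundance of each taxon is annotated above its point.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    eff = result.effect
    se = result.se.fillna(0.0)
    x = np.arange(len(eff))
    y = asinh_scale(eff.to_numpy())
    lo = asinh_scale((eff - se).to_numpy())
    hi = asinh_scale((eff + se).to_numpy())
    ax.errorbar(x, y, yerr=[y - lo, hi - y], fmt="o", color="k", capsize=2)
    ax.axhline(0.0, color="grey", lw=0.8)
    mean_ab = result.category_means.mean(axis=0)
    for xi, taxon in zip(x, eff.index):
        ax.annotate(
            f"{mean_ab[taxon]:.0f}", (xi, ax.get_ylim()[1]),
            ha="center", fontsize=7, annotation_clip=False,
        )
    ax.set_xticks(x)
    ax.set_xticklabels(eff.index, rotation=90, fontsize=8)
    ax.set_ylabel("BACI effect (asinh scale)")
    ax.set_title(
        f"{result.sample_type or ''} {'/'.join(result.occasion_pair)}".strip()
    )
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
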