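"""Before-After-Control-Impact effects and category summaries.

The BACI effect for a taxon is the change in the treated-minus-control
difference of mean abundance across the spray:
``(treated_after - control_after) - (treated_before - control_before)``.
It is computed on pooled-sample cell means within each (location, habitat)
replicate; the overall effect is the mean over replicates and its standard
error the sample SD over replicates divided by sqrt(n).  No per-taxon
p-values are attached: with ~20 orders, unadjusted tests would be expected
to flag one by chance, while multiplicity corrections would mask modest but
real shifts, so effects are reported with uncertainty only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TaxonCountMatrix

logger = logging.getLogger(__name__)

__all__ = ["BACIResult", "baci_effect", "category_summary", "asinh_scale"]


def asinh_scale(x):
    """Inverse hyperbolic sine, log(x + sqrt(x^2 + 1)): a signed log-like
    scale that is linear near 0 — used for plotting effects spanning orders
    of magnitude in both signs."""
    return np.arcsinh(x)


@dataclass
class BACIResult:
    """Per-taxon BACI effects with replicate-based uncertainty."""

    effect: pd.Series
    se: pd.Series
    replicate_effects: pd.DataFrame  # (location, habitat) x taxa
    category_means: pd.DataFrame  # (period, treatment) x taxa
    category_ses: pd.DataFrame
    occasion_pair: tuple[str, str]
    sample_type: str | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_effects)

    def as_frame(self) -> pd.DataFrame:
        """Supplementary-table layout: taxon, mean abundance, effect, SE."""
        return pd.DataFrame(
            {
                "taxon": self.effect.index,
                "mean_abundance": self.category_means.mean(axis=0).to_numpy(),
                "baci_effect": self.effect.to_numpy(),
                "baci_se": self.se.to_numpy(),
                "occasion_pair": "/".join(self.occasion_pair),
                "sample_type": self.sample_type or "",
            }
        )


def baci_effect(m: TaxonCountMatrix, occasion_pair: tuple[str, str]) -> BACIResult:
    """BACI effect and SE per taxon from (location, habitat) replicates.

    ``occasion_pair`` is (pre-occasion, post-occasion), e.g. ``("pre",
    "post1")``.  Replicates missing any of the four treatment x period cells
    are dropped with a warning; with fewer than two complete replicates the
    SE is undefined (NaN).
    """
    pre, post = occasion_pair
    sub = m.restrict_occasions((pre, post))
    cells = sub.counts.groupby(
        [sub.meta["location"], sub.meta["habitat"], sub.meta["treatment"], sub.meta["period"]],
        observed=True,
    ).mean()

    reps = []
    index = []
    for (loc, hab), grp in cells.groupby(level=[0, 1], observed=True):
        grp = grp.droplevel([0, 1])
        needed = [("treated", "after"), ("control", "after"),
                  ("treated", "before"), ("control", "before")]
        if not all(key in grp.index for key in needed):
            logger.warning("dropping incomplete BACI replicate (%s, %s)", loc, hab)
            continue
        val = (
            grp.loc[("treated", "after")] - grp.loc[("control", "after")]
            - (grp.loc[("treated", "before")] - grp.loc[("control", "before")])
        )
        reps.append(val)
        index.append((loc, hab))
    if not reps:
        raise ValueError("no complete (location, habitat) replicate for the BACI effect")
    replicate_effects = pd.DataFrame(
        reps, index=pd.MultiIndex.from_tuples(index, names=["location", "habitat"])
    )
    effect = replicate_effects.mean(axis=0)
    n = len(replicate_effects)
    if n >= 2:
        se = replicate_effects.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = pd.Series(np.nan, index=effect.index)

    cat = category_summary(sub)
    means = cat["mean"].unstack(level=["period", "treatment"]).T
    ses = cat["se"].unstack(level=["period", "treatment"]).T
    stypes = sub.meta["sample_type"].unique()
    return BACIResult(
        effect=effect.rename("baci_effect"),
        se=se.rename("baci_se"),
        replicate_effects=replicate_effects,
        category_means=means,
        category_ses=ses,
        occasion_pair=occasion_pair,
        sample_type=stypes[0] if len(stypes) == 1 else None,
    )


def category_summary(m: TaxonCountMatrix) -> pd.DataFrame:
    """Mean and SE of abundance per taxon per (period, treatment) category.

    Rows are a MultiIndex (taxon, period, treatment); a category with one
    sample has SE NaN.  A companion per-(occasion, treatment) table is
    available via ``occasion_summary``.
    """
    return _grouped_summary(m, ["period", "treatment"])


def occasion_summary(m: TaxonCountMatrix) -> pd.DataFrame:
    """Mean and SE per taxon per (occasion, treatment) — trajectory view."""
    return _grouped_summary(m, ["occasion", "treatment"])


def _grouped_summary(m: TaxonCountMatrix, keys: list[str]) -> pd.DataFrame:
    grouped = m.counts.groupby([m.meta[k] for k in keys], observed=True)
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    count = grouped.count()
    se = sd / np.sqrt(count)
    out = pd.concat(
        {"mean": mean.stack(), "se": se.stack()}, axis=1
    )
    out.index = out.index.set_names(keys + ["taxon"])
    return out.reorder_levels(["taxon"] + keys).sort_index()
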