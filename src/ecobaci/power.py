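"""Bootstrap power analysis driven by the AIC model-comparison decision rule.

Power here is operational: the fraction of bootstrap replicates in which the
model including treatment attains a lower AIC than the nested null.  Each
replicate resamples whole pooled-sample rows with replacement (unstratified,
metadata travelling with each row, preserving cross-taxon correlation), then
multiplies the counts of treated rows in the after period by a reduction
factor and rounds half-up, and fits both models.

Two modes:

* retrospective — the resample has the observed size; the question is the
  smallest abundance reduction the realised design detects with >= 80% power.
* prospective — the resample is an integer multiple of the observed size;
  the question is the sample-size multiplier needed to reach 80% power for a
  25% or 50% reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TaxonCountMatrix
from .model import ModelSpec, build_design, fit_nb_glm

logger = logging.getLogger(__name__)

__all__ = [
    "PowerGrid",
    "retrospective_power",
    "prospective_power",
    "RETRO_FACTOR_GRID",
    "BULK_MULTIPLIERS",
    "PITFALL_MULTIPLIERS",
]

#: The retrospective reduction-factor grid: 0.1 to 0.9 in steps of 0.05.
RETRO_FACTOR_GRID = tuple(np.round(np.arange(0.10, 0.91, 0.05), 2))
#: Prospective sample-size multipliers for the two sample types.
BULK_MULTIPLIERS = tuple(range(1, 21))
PITFALL_MULTIPLIERS = tuple(range(10, 101, 10))
#: Prospective reduction factors, i.e. 25% and 50% abundance reductions.
PROSPECTIVE_FACTORS = (0.75, 0.5)

POWER_LEVEL = 0.80


@dataclass
class PowerGrid:
    """Power estimates over a (reduction factor, sample-size multiplier) grid."""

    table: pd.DataFrame  # factor, multiplier, n_reps, power, mc_se, n_redraws
    mode: str
    occasion_pair: tuple[str, str]
    sample_type: str | None
    seed: int | None
    null_spec: ModelSpec = field(default_factory=ModelSpec.null)
    alt_spec: ModelSpec = field(default_factory=ModelSpec.alternative)

    def power_at(self, factor: float, multiplier: int = 1) -> float:
        t = self.table
        row = t[(np.isclose(t["factor"], factor)) & (t["multiplier"] == multiplier)]
        if row.empty:
            raise KeyError(f"no grid cell (factor={factor}, multiplier={multiplier})")
        return float(row["power"].iloc[0])

    def smallest_detectable_reduction(self, level: float = POWER_LEVEL) -> float | None:
        """Smallest reduction 1 - factor with power >= level (retrospective)."""
        t = self.table[self.table["power"] >= level]
        if t.empty:
            return None
        return float(np.round(1.0 - t["factor"].max(), 10))

    def required_multiplier(self, factor: float, level: float = POWER_LEVEL) -> int | None:
        """Smallest sample-size multiplier reaching power >= level, or None."""
        t = self.table[np.isclose(self.table["factor"], factor)]
        t = t[t["power"] >= level]
        if t.empty:
            return None
        return int(t["multiplier"].min())

    def summary(self) -> dict:
        out = {
            "mode": self.mode,
            "occasion_pair": list(self.occasion_pair),
            "sample_type": self.sample_type,
            "seed": self.seed,
            "power_level": POWER_LEVEL,
        }
        if self.mode == "retrospective":
            out["smallest_detectable_reduction"] = self.smallest_detectable_reduction()
        else:
            out["required_multiplier"] = {
                str(f): self.required_multiplier(f)
                for f in sorted(self.table["factor"].unique(), reverse=True)
            }
        return out


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


class _BootstrapEngine:
    """Precomputed template for fast repeated resample-and-refit cycles."""

    def __init__(self, m: TaxonCountMatrix, null_spec: ModelSpec, alt_spec: ModelSpec):
        if not null_spec.is_nested_in(alt_spec):
            raise ValueError(f"{null_spec} is not nested in {alt_spec}")
        self.Y = m.counts.to_numpy(dtype=float)
        self.X_null, _ = build_design(m.meta, null_spec)
        self.X_alt, _ = build_design(m.meta, alt_spec)
        self.treated_after = (
            (m.meta["treatment"] == "treated") & (m.meta["period"] == "after")
        ).to_numpy()
        # factor level codes per row, for the degenerate-resample check
        self.level_codes = []
        for term in alt_spec.terms:
            codes, uniq = pd.factorize(m.meta[term], sort=True)
            self.level_codes.append((codes, len(uniq)))
        self.n = len(m)

    def valid(self, idx: np.ndarray) -> bool:
        for codes, k in self.level_codes:
            if len(np.unique(codes[idx])) < k:
                return False
        return True

    def draw(self, rng: np.random.Generator, size: int, max_redraws: int = 1000):
        redraws = 0
        while True:
            idx = rng.integers(0, self.n, size=size)
            if self.valid(idx):
                return idx, redraws
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("could not draw a non-degenerate resample")

    def alt_wins(self, idx: np.ndarray, factor: float) -> bool:
        """One bootstrap replicate: does the treatment model win on AIC?"""
        y = self.Y[idx].copy()
        mask = self.treated_after[idx]
        if factor != 1.0:
            y[mask] = _round_half_up(y[mask] * factor)
        Xn, Xa = self.X_null[idx], self.X_alt[idx]
        aic_null = aic_alt = 0.0
        for j in range(y.shape[1]):
            fn = fit_nb_glm(y[:, j], Xn)
            fa = fit_nb_glm(y[:, j], Xa)
            aic_null += -2.0 * fn.llf + 2.0 * fn.n_params
            aic_alt += -2.0 * fa.llf + 2.0 * fa.n_params
        return aic_alt - aic_null < -1e-9


def _power_run(
    m: TaxonCountMatrix,
    occasion_pair: tuple[str, str],
    grid: list[tuple[float, int]],
    n_reps: int,
    seed: int | None,
    null_spec: ModelSpec,
    alt_spec: ModelSpec,
    mode: str,
) -> PowerGrid:
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a usable power estimate")
    sub = m.restrict_occasions(occasion_pair)
    engine = _BootstrapEngine(sub, null_spec, alt_spec)
    rng = np.random.default_rng(seed)
    rows = []
    for factor, mult in grid:
        if not 0.0 < factor <= 1.0:
            raise ValueError(f"reduction factor must be in (0, 1], got {factor}")
        wins = 0
        redraws = 0
        for _ in range(n_reps):
            idx, r = engine.draw(rng, size=mult * engine.n)
            redraws += r
            wins += engine.alt_wins(idx, factor)
        p = wins / n_reps
        rows.append(
            {
                "factor": factor,
                "multiplier": mult,
                "n_reps": n_reps,
                "power": p,
                "mc_se": np.sqrt(p * (1.0 - p) / n_reps),
                "n_redraws": redraws,
            }
        )
        if redraws:
            logger.warning(
                "%d degenerate resample(s) redrawn at factor=%.2f multiplier=%d",
                redraws, factor, mult,
            )
    stypes = sub.meta["sample_type"].unique()
    return PowerGrid(
        table=pd.DataFrame(rows),
        mode=mode,
        occasion_pair=occasion_pair,
        sample_type=stypes[0] if len(stypes) == 1 else None,
        seed=seed,
        null_spec=null_spec,
        alt_spec=alt_spec,
    )


def retrospective_power(
    m: TaxonCountMatrix,
    occasion_pair: tuple[str, str],
    factors: tuple[float, ...] = RETRO_FACTOR_GRID,
    n_reps: int = 500,
    seed: int | None = None,
    null_spec: ModelSpec | None = None,
    alt_spec: ModelSpec | None = None,
) -> PowerGrid:
    """Detectability of abundance reductions with the realised design.

    ``factor`` multiplies treated-after counts; the corresponding abundance
    reduction is ``1 - factor``.  With ``factor = 1`` the estimate is the
    AIC rule's false-selection rate (no true effect).
    """
    return _power_run(
        m, occasion_pair, [(f, 1) for f in factors], n_reps, seed,
        null_spec or ModelSpec.null(), alt_spec or ModelSpec.alternative(),
        "retrospective",
    )


def prospective_power(
    m: TaxonCountMatrix,
    occasion_pair: tuple[str, str],
    reductions: tuple[float, ...] = PROSPECTIVE_FACTORS,
    multipliers: tuple[int, ...] = BULK_MULTIPLIERS,
    n_reps: int = 200,
    seed: int | None = None,
    null_spec: ModelSpec | None = None,
    alt_spec: ModelSpec | None = None,
) -> PowerGrid:
    """Sample size needed for target power, by resampling m-fold datasets."""
    if any(int(m_) != m_ or m_ < 1 for m_ in multipliers):
        raise ValueError("multipliers must be positive integers")
    grid = [(f, int(mult)) for f in reductions for mult in multipliers]
    return _power_run(
        m, occasion_pair, grid, n_reps, seed,
        null_spec or ModelSpec.null(), alt_spec or ModelSpec.alternative(),
        "prospective",
    )
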