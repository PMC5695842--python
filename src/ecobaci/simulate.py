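"""Synthetic raw/pooled count datasets with the field experiment's structure.

The generator inverts the analysis model: for every design cell
(location x plot treatment x habitat x occasion x sample type) a pooled-count
mean is formed on the log scale from a taxon baseline, a before/after period
effect, a habitat effect, a location effect shared by the paired plots, and a
treatment multiplier acting only on treated plots after the spray.  Raw
component samples (lawn cores, forest soil and litter, paired pitfall traps)
are drawn so that their within-cell sum is exactly negative binomial with the
cell mean and the taxon's dispersion ``Phi`` (Var = mu + mu^2/Phi); the raw
table is then pooled through :func:`ecobaci.data.pool_samples` like real data.

Defaults emulate the study's layout: 13 locations of paired 8x8 m plots in
lawn and forest, bulk samples at three occasions (468 raw components, one
forest-litter sample lost), pitfall traps at 7 locations for two occasions
plus 3 locations at a late occasion (136 raw traps, 7 unsortable), ~20
arthropod orders with two hyper-abundant ones (mites and springtails) whose
bulk counts come from an extrapolated 15% subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import SUBSAMPLE_FRACTION, PoolingPlan, TaxonCountMatrix, pool_samples

__all__ = ["SyntheticConfig", "simulate_dataset", "dispersion_check", "DEFAULT_TAXA"]

#: Ground-dwelling arthropod orders typical of temperate lawn/forest soil;
#: the first two are the hyper-abundant, subsample-counted ones.
DEFAULT_TAXA = (
    "acari", "collembola", "araneae", "blattodea", "chilopoda", "coleoptera",
    "dermaptera", "diplopoda", "diplura", "diptera", "hemiptera", "hymenoptera",
    "isopoda", "lepidoptera", "orthoptera", "pauropoda", "protura",
    "psocoptera", "symphyla", "thysanoptera",
)

_COMPONENTS = {
    ("bulk", "lawn"): ("lawn_core", "lawn_core"),
    ("bulk", "forest"): ("forest_soil", "forest_soil", "forest_litter", "forest_litter"),
    ("pitfall", "lawn"): ("pitfall", "pitfall"),
    ("pitfall", "forest"): ("pitfall", "pitfall"),
}


@dataclass
class SyntheticConfig:
    """Parameters of the generating model and of the sampling layout.

    Per-taxon vectors (``intercepts`` on the log pooled-count scale,
    ``habitat_effects`` for forest vs lawn, ``period_effects`` for after vs
    before, ``dispersions`` Phi) and per-location effects default to ``None``
    and are then drawn once from the config's seed, with the first two taxa
    dominant (pooled-cell means around 500 and 150 vs ~1 for the median
    taxon, matching the observed skew).  ``treatment_multiplier`` scales the
    mean of treated-plot cells after the spray; 1 means no effect, and a
    per-taxon vector is accepted.
    """

    n_locations: int = 13
    n_taxa: int = 20
    seed: int = 0
    occasions_bulk: tuple[str, ...] = ("pre", "post1", "post2")
    n_pitfall_locations: int = 7
    pitfall_occasions: tuple[str, ...] = ("pre", "post1")
    n_pitfall_late_locations: int = 3
    pitfall_late_occasion: str = "post2"
    taxa: tuple[str, ...] | None = None
    intercepts: np.ndarray | None = None
    habitat_effects: np.ndarray | None = None
    period_effects: np.ndarray | None = None
    location_effects: np.ndarray | None = None
    sigma_location: float = 0.5
    dispersions: np.ndarray | None = None
    treatment_multiplier: float | np.ndarray = 1.0
    #: "baci": the multiplier hits treated plots only after the spray (the
    #: field reality); "main": it hits every treated row, i.e. data generated
    #: exactly under the alternative model's main-effect form (used for
    #: parameter-recovery checks).
    treatment_mode: str = "baci"
    pitfall_log_offset: float = -3.0
    subsample_fraction: float = SUBSAMPLE_FRACTION
    n_extrapolated: int = 2
    n_lost_bulk: int = 1
    n_dirty_pitfall: int = 7

    def resolve(self) -> "SyntheticConfig":
        """Fill in any unspecified parameter vectors, reproducibly from seed."""
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0xC0FFEE)))
        J, L = self.n_taxa, self.n_locations
        taxa = self.taxa
        if taxa is None:
            taxa = tuple(DEFAULT_TAXA[:J]) + tuple(
                f"taxon_{i:02d}" for i in range(len(DEFAULT_TAXA), J)
            )
        if len(taxa) != J:
            raise ValueError(f"{len(taxa)} taxon labels for n_taxa={J}")
        intercepts = self.intercepts
        if intercepts is None:
            intercepts = rng.normal(0.3, 1.0, size=J)
            if J >= 1:
                intercepts[0] = np.log(500.0)
            if J >= 2:
                intercepts[1] = np.log(150.0)
        habitat = self.habitat_effects
        if habitat is None:
            habitat = rng.normal(0.0, 0.7, size=J)
        period = self.period_effects
        if period is None:
            period = rng.normal(0.0, 0.4, size=J)
        location = self.location_effects
        if location is None:
            location = rng.normal(0.0, self.sigma_location, size=L)
        disp = self.dispersions
        if disp is None:
            disp = rng.uniform(0.3, 2.0, size=J)
        disp = np.asarray(disp, dtype=float)
        if np.any(disp <= 0):
            raise ValueError("dispersions must be positive")
        mult = np.broadcast_to(np.asarray(self.treatment_multiplier, dtype=float), (J,))
        if np.any(mult < 0):
            raise ValueError("treatment multiplier must be >= 0")
        return replace(
            self,
            taxa=tuple(taxa),
            intercepts=np.asarray(intercepts, float),
            habitat_effects=np.asarray(habitat, float),
            period_effects=np.asarray(period, float),
            location_effects=np.asarray(location, float),
            dispersions=disp,
            treatment_multiplier=np.array(mult),
        )

    @property
    def location_labels(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_locations)]


def _cell_frame(cfg: SyntheticConfig) -> pd.DataFrame:
    """One row per pooled design cell, with location index and occasion."""
    rows = []
    locs = cfg.location_labels
    for l, loc in enumerate(locs):
        for treatment in ("control", "treated"):
            for habitat in ("lawn", "forest"):
                for occ in cfg.occasions_bulk:
                    rows.append((loc, l, treatment, habitat, occ, "bulk"))
                occs = list(cfg.pitfall_occasions) if l < cfg.n_pitfall_locations else []
                if l < cfg.n_pitfall_late_locations:
                    occs.append(cfg.pitfall_late_occasion)
                for occ in occs:
                    rows.append((loc, l, treatment, habitat, occ, "pitfall"))
    return pd.DataFrame(
        rows,
        columns=["location", "loc_index", "treatment", "habitat", "occasion", "sample_type"],
    )


def expected_cell_means(cfg: SyntheticConfig, cells: pd.DataFrame) -> np.ndarray:
    """Pooled-count mean per cell x taxon: exp of the model's linear predictor."""
    cfg = cfg if cfg.intercepts is not None else cfg.resolve()
    lp = np.tile(cfg.intercepts, (len(cells), 1))
    lp += np.where(cells["habitat"].to_numpy()[:, None] == "forest", cfg.habitat_effects, 0.0)
    lp += np.where(cells["occasion"].to_numpy()[:, None] != "pre", cfg.period_effects, 0.0)
    lp += cfg.location_effects[cells["loc_index"].to_numpy()][:, None]
    lp += np.where(cells["sample_type"].to_numpy()[:, None] == "pitfall", cfg.pitfall_log_offset, 0.0)
    hit = cells["treatment"].to_numpy() == "treated"
    if cfg.treatment_mode == "baci":
        hit = hit & (cells["occasion"].to_numpy() != "pre")
    elif cfg.treatment_mode != "main":
        raise ValueError(f"unknown treatment_mode {cfg.treatment_mode!r}")
    with np.errstate(divide="ignore"):
        lp += np.where(hit[:, None], np.log(cfg.treatment_multiplier), 0.0)
    return np.exp(lp)


def simulate_dataset(
    cfg: SyntheticConfig | None = None,
) -> tuple[TaxonCountMatrix, TaxonCountMatrix]:
    """Draw one raw dataset and its pooled counterpart.

    Returns ``(raw, pooled)``.  Raw component counts within a cell are NB
    with mean ``mu/k`` and size ``Phi/k`` (k components), so the pooled sum
    is exactly NB(mu, Phi).  For the extrapolated taxa, each raw bulk value
    is a binomially thinned 15% subsample scaled back up (mean-preserving,
    variance-inflating), mirroring the counting protocol.  Everything is a
    deterministic function of the config, including which samples are lost.
    """
    cfg = (cfg or SyntheticConfig()).resolve()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xDA7A)))
    cells = _cell_frame(cfg)
    mu = expected_cell_means(cfg, cells)
    taxa = list(cfg.taxa)
    extrapolated = tuple(taxa[: cfg.n_extrapolated])

    meta_rows = []
    count_rows = []
    for i in range(len(cells)):
        cell = cells.iloc[i]
        comps = _COMPONENTS[(cell["sample_type"], cell["habitat"])]
        k = len(comps)
        size = cfg.dispersions / k
        mean = mu[i] / k
        for c, comp in enumerate(comps):
            p = size / (size + np.maximum(mean, 1e-12))
            y = rng.negative_binomial(size, p).astype(float)
            if cell["sample_type"] == "bulk" and cfg.subsample_fraction < 1.0:
                for j in range(cfg.n_extrapolated):
                    sub = rng.binomial(int(y[j]), cfg.subsample_fraction)
                    y[j] = sub / cfg.subsample_fraction
            meta_rows.append(
                {
                    "sample_id": f"{cell['location']}|{cell['treatment']}|{cell['habitat']}"
                    f"|{cell['occasion']}|{cell['sample_type']}|{comp}{c}",
                    "location": cell["location"],
                    "treatment": cell["treatment"],
                    "habitat": cell["habitat"],
                    "occasion": cell["occasion"],
                    "sample_type": cell["sample_type"],
                    "component": comp,
                    "stratum": "edge" if c % 2 == 0 else "interior",
                }
            )
            count_rows.append(y)

    meta = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(np.vstack(count_rows), columns=taxa)

    # sample losses, as in the field: lost litter samples, unsortable pitfalls
    drop = np.zeros(len(meta), dtype=bool)
    litter = np.flatnonzero((meta["component"] == "forest_litter").to_numpy())
    if cfg.n_lost_bulk:
        drop[rng.choice(litter, size=min(cfg.n_lost_bulk, len(litter)), replace=False)] = True
    # dirty pitfalls never empty a whole cell (every pooled cell keeps >=1
    # usable trap), so the pooled row count stays at the design's 68
    pits = np.flatnonzero((meta["component"] == "pitfall").to_numpy())
    if cfg.n_dirty_pitfall and len(pits):
        cell_of = meta.iloc[pits][
            ["location", "treatment", "habitat", "occasion"]
        ].astype(str).agg("|".join, axis=1).to_numpy()
        cells_unique = np.unique(cell_of)
        dirty_cells = rng.choice(
            cells_unique, size=min(cfg.n_dirty_pitfall, len(cells_unique)), replace=False
        )
        for cell in dirty_cells:
            members = pits[cell_of == cell]
            drop[rng.choice(members)] = True
    raw = TaxonCountMatrix(counts.loc[~drop], meta.loc[~drop], extrapolated)
    pooled = pool_samples(raw, PoolingPlan())
    return raw, pooled


def dispersion_check(m: TaxonCountMatrix) -> pd.Series:
    """Per-taxon variance/mean ratio (1 for Poisson, >1 when overdispersed).

    Undefined ratios (all-zero or constant columns) are returned as NaN.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    mean = m.counts.mean()
    var = m.counts.var(ddof=1)
    ratio = var / mean
    ratio[(var == 0) | (mean == 0)] = np.nan
    return ratio.rename("var_mean_ratio")
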