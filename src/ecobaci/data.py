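"""Count-table data model, CSV I/O, subsample extrapolation and pooling.

A :class:`TaxonCountMatrix` holds a samples x taxa matrix of non-negative
counts together with one metadata record per sample (location, treatment,
habitat, occasion, sample type, and for raw samples the component within the
plot, e.g. a lawn core or a forest litter sample).  Raw component samples are
pooled into one row per (location, treatment, habitat, occasion, sample type)
cell, the unit at which the models operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required metadata column is missing or mis-mapped."""


class ValidationError(ValueError):
    """Counts or metadata violate the data model's invariants."""


#: Canonical metadata columns, in file order.
META_COLUMNS = (
    "sample_id",
    "location",
    "treatment",
    "habitat",
    "occasion",
    "sample_type",
)
#: Optional metadata columns preserved when present.
OPTIONAL_META_COLUMNS = ("component", "stratum")

FACTOR_LEVELS = {
    "treatment": ("control", "treated"),
    "habitat": ("lawn", "forest"),
    "occasion": ("pre", "post1", "post2"),
    "sample_type": ("bulk", "pitfall"),
    "period": ("before", "after"),
    "stratum": ("edge", "interior"),
}

#: Study-design constants of the paired-plot layout: 13 locations, each with
#: one treated 8 m x 8 m plot (and a paired control plot of the same size).
N_LOCATIONS = 13
PLOT_SIDE_M = 8.0

#: Fraction of each bulk sample counted for the two hyper-abundant orders.
SUBSAMPLE_FRACTION = 0.15


def treated_area_m2(n_locations: int = N_LOCATIONS, plot_side_m: float = PLOT_SIDE_M) -> float:
    """Total treated area: one square plot of side ``plot_side_m`` per location."""
    return n_locations * plot_side_m**2


def period_from_occasion(occasion: pd.Series) -> pd.Series:
    """Derive the before/after period: ``before`` iff occasion is ``pre``."""
    return pd.Series(
        np.where(occasion.to_numpy() == "pre", "before", "after"),
        index=occasion.index,
        name="period",
    )


def extrapolate_subsample(subcount: float, fraction: float = SUBSAMPLE_FRACTION) -> float:
    """Estimate a sample total from a counted fraction: ``subcount / fraction``.

    With the study's 15% subsample this is (100/15) x subsample count.
    ``fraction`` must lie in (0, 1].
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"subsample fraction must be in (0, 1], got {fraction}")
    if subcount < 0:
        raise ValueError("subsample count must be non-negative")
    return subcount / fraction


class TaxonCountMatrix:
    """Samples x taxa count matrix with per-sample design metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative counts, columns = taxon labels.
    meta
        DataFrame aligned row-for-row with ``counts``; must carry the
        canonical metadata columns.  A ``period`` column is derived from
        ``occasion`` if absent.
    extrapolated_taxa
        Taxa whose counts were scaled up from a counted subsample (their
        raw values may be non-integer).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        meta: pd.DataFrame,
        extrapolated_taxa: tuple[str, ...] = (),
    ) -> None:
        counts = counts.reset_index(drop=True)
        meta = meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        if len(counts) != len(meta):
            raise ValidationError(
                f"counts has {len(counts)} rows but meta has {len(meta)}"
            )
        if meta["sample_id"].duplicated().any():
            dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        arr = counts.to_numpy(dtype=float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise ValidationError("counts must be non-negative and non-missing")
        for col, levels in FACTOR_LEVELS.items():
            if col in meta.columns:
                observed = set(meta[col].dropna().unique())
                unknown = observed - set(levels)
                if unknown:
                    raise ValidationError(
                        f"unknown {col} level(s): {sorted(unknown)}; "
                        f"allowed: {list(levels)}"
                    )
        if "period" not in meta.columns:
            meta = meta.copy()
            meta["period"] = period_from_occasion(meta["occasion"])
        else:
            expected = period_from_occasion(meta["occasion"])
            if not meta["period"].equals(expected):
                raise ValidationError("period must be 'before' iff occasion is 'pre'")
        unknown_taxa = set(extrapolated_taxa) - set(counts.columns)
        if unknown_taxa:
            raise ValidationError(f"extrapolated taxa not in matrix: {sorted(unknown_taxa)}")
        self.counts = counts.astype(float)
        self.meta = meta
        self.extrapolated_taxa = tuple(sorted(extrapolated_taxa))

    # -- basic protocol ----------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return len(self.counts)

    def __len__(self) -> int:
        return self.n_samples

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonCountMatrix):
            return NotImplemented
        a, b = self.sorted(), other.sorted()
        return (
            a.extrapolated_taxa == b.extrapolated_taxa
            and a.counts.equals(b.counts)
            and a.meta[list(META_COLUMNS)].equals(b.meta[list(META_COLUMNS)])
        )

    def sorted(self) -> "TaxonCountMatrix":
        """Canonical ordering: rows by sample_id, columns by taxon label."""
        order = self.meta["sample_id"].argsort(kind="stable").to_numpy()
        return TaxonCountMatrix(
            self.counts.iloc[order].reindex(sorted(self.counts.columns), axis=1),
            self.meta.iloc[order],
            self.extrapolated_taxa,
        )

    def select(self, mask: np.ndarray | pd.Series) -> "TaxonCountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return TaxonCountMatrix(
            self.counts.loc[mask], self.meta.loc[mask], self.extrapolated_taxa
        )

    def restrict_occasions(self, occasions: tuple[str, ...]) -> "TaxonCountMatrix":
        present = set(self.meta["occasion"].unique())
        absent = set(occasions) - present
        if absent:
            raise ValidationError(
                f"occasion(s) {sorted(absent)} not present in data (has {sorted(present)})"
            )
        return self.select(self.meta["occasion"].isin(occasions).to_numpy())


@dataclass(frozen=True)
class PoolingPlan:
    """How raw component samples collapse into pooled analysis samples.

    ``expected_components`` maps (sample_type, habitat) to the component
    labels a complete cell should contain; cells missing some components are
    still pooled over what exists (a warning is logged), matching the study's
    handling of the lost litter sample and the unsortable pitfalls.
    """

    keys: tuple[str, ...] = ("location", "treatment", "habitat", "occasion", "sample_type")
    expected_components: dict = field(
        default_factory=lambda: {
            ("bulk", "lawn"): ("lawn_core",),
            ("bulk", "forest"): ("forest_soil", "forest_litter"),
            ("pitfall", "lawn"): ("pitfall",),
            ("pitfall", "forest"): ("pitfall",),
        }
    )
    round_to_int: bool = True


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def pool_samples(raw: TaxonCountMatrix, plan: PoolingPlan | None = None) -> TaxonCountMatrix:
    """Sum raw component counts within each design cell.

    One pooled row is produced per distinct combination of the plan's grouping
    keys that has at least one usable raw sample.  Counts are summed and, by
    default, rounded half-up to integers so the negative-binomial likelihood
    is defined on the result (only extrapolated taxa can be non-integer).
    """
    plan = plan or PoolingPlan()
    missing = [k for k in plan.keys if k not in raw.meta.columns]
    if missing:
        raise SchemaError(f"pooling keys absent from metadata: {missing}")
    keys = list(plan.keys)
    grouped = raw.counts.groupby([raw.meta[k] for k in keys], observed=True, sort=True)
    pooled_counts = grouped.sum()
    n_components = grouped.size()

    meta = pooled_counts.index.to_frame(index=False)
    meta["sample_id"] = [
        "|".join(str(v) for v in key) for key in pooled_counts.index
    ]
    if "component" in raw.meta.columns:
        for key, sub in raw.meta.groupby(keys, observed=True):
            expected = plan.expected_components.get(
                (sub["sample_type"].iloc[0], sub["habitat"].iloc[0])
            )
            if expected is not None:
                present = sub["component"].dropna()
                lacking = set(expected) - set(present)
                if lacking:
                    logger.warning(
                        "pooled cell %s missing component(s) %s; summed over %d sample(s)",
                        key, sorted(lacking), len(sub),
                    )
    counts = pooled_counts.reset_index(drop=True)
    if plan.round_to_int:
        counts = pd.DataFrame(
            _round_half_up(counts.to_numpy(dtype=float)),
            columns=counts.columns,
        )
    out = TaxonCountMatrix(counts, meta, raw.extrapolated_taxa)
    logger.info(
        "pooled %d raw samples into %d rows (components per cell: min %d, max %d)",
        raw.n_samples, out.n_samples, n_components.min(), n_components.max(),
    )
    return out.sorted()


# -- CSV I/O ---------------------------------------------------------------

_EXTRA_COL = "extrapolated_taxa"


def write_count_table(m: TaxonCountMatrix, path) -> None:
    """Write a wide CSV: metadata columns, then one column per taxon.

    Rows are ordered by sample_id and columns by taxon label so output is
    bit-stable.  The set of extrapolated taxa is carried in a repeated
    ``extrapolated_taxa`` column (semicolon-joined).
    """
    m = m.sorted()
    meta_cols = [c for c in META_COLUMNS + OPTIONAL_META_COLUMNS if c in m.meta.columns]
    out = m.meta[meta_cols].copy()
    if m.extrapolated_taxa:
        out[_EXTRA_COL] = ";".join(m.extrapolated_taxa)
    for taxon in m.taxa:
        out[taxon] = m.counts[taxon].to_numpy()
    out.to_csv(path, index=False)


def read_count_table(path, schema: dict[str, str] | None = None) -> TaxonCountMatrix:
    """Read a count table from CSV (wide or long layout).

    A long layout is recognised by ``taxon`` and ``count`` columns (one row
    per sample x taxon; duplicates are an error).  ``schema`` optionally maps
    file column names onto the canonical metadata names.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {missing}")

    extrapolated: tuple[str, ...] = ()
    if _EXTRA_COL in df.columns:
        vals = df[_EXTRA_COL].dropna().unique()
        if len(vals) > 1:
            raise ValidationError(f"inconsistent {_EXTRA_COL} column")
        if len(vals) == 1 and str(vals[0]):
            extrapolated = tuple(str(vals[0]).split(";"))
        df = df.drop(columns=[_EXTRA_COL])

    meta_cols = [c for c in META_COLUMNS + OPTIONAL_META_COLUMNS if c in df.columns]
    if {"taxon", "count"} <= set(df.columns):  # long layout
        if df.duplicated(subset=["sample_id", "taxon"]).any():
            raise ValidationError("duplicated (sample_id, taxon) rows in long layout")
        counts = df.pivot(index="sample_id", columns="taxon", values="count").fillna(0.0)
        meta = df[meta_cols].drop_duplicates("sample_id").set_index("sample_id")
        meta = meta.loc[counts.index].reset_index()
        counts = counts.reset_index(drop=True)
        counts.columns.name = None
    else:
        taxa = [c for c in df.columns if c not in meta_cols and c != "period"]
        if not taxa:
            raise SchemaError("no taxon columns found")
        meta = df[meta_cols]
        try:
            counts = df[taxa].astype(float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric count value: {exc}") from exc
    return TaxonCountMatrix(counts, meta, extrapolated).sorted()
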