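"""Core density estimators.

Calling-male density on a plot is a habitat-stratified extrapolation of the
per-site best counts: within each of the four strata (small, medium, large
waterbodies, ditches) the summed count ``C`` is scaled by the ratio of total
to surveyed habitat ``Pt/Ps``, summed across strata and divided by plot
area.  Minimum adult density divides that by the product of the behavioural
detection proportions ``ma·mp·ms``, yielding a deliberate lower bound on
the true adult density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .core_data import (
    Dataset,
    DatasetError,
    TaxonParameters,
    WaterbodyCategory,
    WaterbodyRecord,
)
from .survey_metrics import select_best_year, site_best_counts

__all__ = [
    "CategoryTally",
    "DensityEstimate",
    "sampled_length",
    "tally_categories",
    "extrapolated_counts",
    "compute_dc",
    "compute_mafd",
    "category_contributions",
    "adjust_operational_sex_ratio",
    "estimate_density",
    "estimate_density_table",
    "summarize_density",
]

#: Reduction applied to published operational male proportions in terrestrial
#: taxa to approximate the whole-population sex ratio.
OPERATIONAL_SEX_RATIO_REDUCTION = 0.15


@dataclass(frozen=True)
class CategoryTally:
    """Counts and habitat totals for one stratum on one plot.

    ``pt`` and ``ps`` share units within the stratum: number of waterbodies
    for the small class, metres of shoreline/channel for the linear classes.
    """

    category: WaterbodyCategory
    c: float
    pt: float
    ps: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"{self.category.value}: calling-male score must be >= 0")
        if not self.pt >= self.ps >= 0:
            raise ValueError(
                f"{self.category.value}: need pt >= ps >= 0, got pt={self.pt}, ps={self.ps}"
            )
        if self.c > 0 and self.ps == 0:
            raise DatasetError(
                f"{self.category.value}: calling males recorded but no habitat surveyed"
            )


@dataclass(frozen=True)
class DensityEstimate:
    """Densities for one plot × taxon in its best survey year."""

    plot_id: str
    taxon: str
    year: int
    dc: float
    mafd: float
    plot_area_km2: float
    category_counts: dict[WaterbodyCategory, float] = field(default_factory=dict)
    category_mafd: dict[WaterbodyCategory, float] = field(default_factory=dict)


def sampled_length(
    record: WaterbodyRecord, hearing_distance_m: float, n_listening_points: int = 1
) -> float:
    """Metres of linear habitat within the observer's hearing range.

    An explicit ``sampled_length_m`` measurement on the record is honoured;
    otherwise the default rule is 2 × hearing distance per listening point,
    capped at the total habitat length.  Only meaningful for medium/large
    waterbodies and ditches (small waterbodies are treated as whole units).
    """
    if not record.category.is_linear:
        raise ValueError(
            f"waterbody {record.waterbody_id!r}: sampled length undefined for "
            f"{record.category.value} waterbodies"
        )
    total = record.habitat_length_m
    if total is None:
        raise DatasetError(f"waterbody {record.waterbody_id!r}: missing perimeter/length")
    if record.sampled_length_m is not None:
        return record.sampled_length_m
    return min(total, 2.0 * hearing_distance_m * n_listening_points)


def tally_categories(
    ds: Dataset,
    plot_id: str,
    taxon: str,
    year: int,
    params: TaxonParameters,
    site_counts: dict[str, float] | None = None,
) -> dict[WaterbodyCategory, CategoryTally]:
    """Per-stratum calling-male scores and habitat totals for one plot-year.

    ``site_counts`` overrides the per-site best counts (used by the visual
    correction to re-run the estimate on augmented counts).
    """
    if site_counts is None:
        site_counts = site_best_counts(ds, plot_id, taxon, year)
    tallies: dict[WaterbodyCategory, CategoryTally] = {}
    for cat in WaterbodyCategory:
        c = pt = ps = 0.0
        for wb in ds.plot_waterbodies(plot_id):
            if wb.category is not cat:
                continue
            if cat is WaterbodyCategory.SMALL:
                pt += 1.0
                if wb.surveyed:
                    ps += 1.0
            else:
                pt += wb.habitat_length_m or 0.0
                if wb.surveyed:
                    ps += sampled_length(wb, params.hearing_distance_m)
            if wb.surveyed:
                c += site_counts.get(wb.waterbody_id, 0.0)
        tallies[cat] = CategoryTally(category=cat, c=c, pt=pt, ps=ps)
    return tallies


def extrapolated_counts(
    tallies: dict[WaterbodyCategory, CategoryTally]
) -> dict[WaterbodyCategory, float]:
    """Per-stratum calling males extrapolated to all plot habitat: C·Pt/Ps.

    A stratum with habitat but no surveyed portion (and no counts, which
    would be inconsistent) contributes zero with a warning — the minimum
    density convention for an unsampled stratum.
    """
    out: dict[WaterbodyCategory, float] = {}
    for cat, t in tallies.items():
        if t.ps == 0:
            if t.pt > 0:
                warnings.warn(
                    f"{cat.value}: habitat present but none surveyed; stratum contributes 0",
                    stacklevel=2,
                )
            out[cat] = 0.0
        else:
            out[cat] = t.c * t.pt / t.ps
    return out


def compute_dc(
    tallies: dict[WaterbodyCategory, CategoryTally], plot_area_km2: float
) -> float:
    """Calling-male density (males/km²): Σ over strata of C·Pt/Ps, over plot area."""
    if not plot_area_km2 > 0:
        raise ValueError(f"plot area must be positive, got {plot_area_km2}")
    return sum(extrapolated_counts(tallies).values()) / plot_area_km2


def compute_mafd(
    tallies_or_dc: dict[WaterbodyCategory, CategoryTally] | float,
    params: TaxonParameters,
    plot_area_km2: float | None = None,
) -> float:
    """Minimum adult frog density (adults/km²).

    For scalar sex-ratio taxa this is ``dc / (ma·mp·ms)`` and a plain
    calling-male density may be passed directly.  For the water-frog
    complex the division is applied per stratum with the stratum-specific
    sex ratio, so the full tallies (plus plot area) are required.
    """
    if isinstance(tallies_or_dc, (int, float)):
        if params.ms_large is not None:
            raise ValueError(
                f"{params.taxon}: stratum tallies are required for taxa with "
                "stratum-specific sex ratios"
            )
        return float(tallies_or_dc) / (params.ma * params.mp * params.ms)
    if plot_area_km2 is None or not plot_area_km2 > 0:
        raise ValueError("plot_area_km2 must be positive when passing tallies")
    counts = extrapolated_counts(tallies_or_dc)
    return sum(
        n / (params.ma * params.mp * params.ms_for_category(cat)) for cat, n in counts.items()
    ) / plot_area_km2


def _category_mafd(
    tallies: dict[WaterbodyCategory, CategoryTally],
    params: TaxonParameters,
    plot_area_km2: float,
) -> dict[WaterbodyCategory, float]:
    counts = extrapolated_counts(tallies)
    return {
        cat: n / (params.ma * params.mp * params.ms_for_category(cat)) / plot_area_km2
        for cat, n in counts.items()
    }


def category_contributions(estimate: DensityEstimate) -> dict[WaterbodyCategory, float] | None:
    """Fraction of the adult-density estimate contributed by each stratum.

    Sums to 1; equals the calling-male density shares for scalar sex-ratio
    taxa.  Undefined (``None``) when the estimate is zero.
    """
    if estimate.mafd <= 0:
        return None
    return {cat: v / estimate.mafd for cat, v in estimate.category_mafd.items()}


def adjust_operational_sex_ratio(operational_male_proportion: float) -> float:
    """Convert an operational (breeding-site) male proportion to a population one.

    Applies the standard 15% reduction used for terrestrial taxa, where
    many females skip breeding in a given year.  This is a config-preparation
    helper for user-supplied ratios; the shipped defaults are already
    adjusted.
    """
    if not 0 < operational_male_proportion <= 1:
        raise ValueError(
            f"operational male proportion must be in (0, 1], got {operational_male_proportion}"
        )
    return (1.0 - OPERATIONAL_SEX_RATIO_REDUCTION) * operational_male_proportion


def estimate_density(
    ds: Dataset,
    plot_id: str,
    taxon: str,
    params: TaxonParameters,
    year: int | None = None,
    site_counts: dict[str, float] | None = None,
) -> DensityEstimate | None:
    """Density estimate for one plot × taxon; ``None`` if the taxon was never recorded."""
    if year is None:
        year = select_best_year(ds, plot_id, taxon)
    if year is None:
        return None
    s = ds.plot_area_km2(plot_id)
    tallies = tally_categories(ds, plot_id, taxon, year, params, site_counts=site_counts)
    cat_mafd = _category_mafd(tallies, params, s)
    return DensityEstimate(
        plot_id=plot_id,
        taxon=taxon,
        year=year,
        dc=compute_dc(tallies, s),
        mafd=sum(cat_mafd.values()),
        plot_area_km2=s,
        category_counts=extrapolated_counts(tallies),
        category_mafd=cat_mafd,
    )


def estimate_density_table(
    ds: Dataset, params_by_taxon: dict[str, TaxonParameters], taxa: list[str] | None = None
) -> pd.DataFrame:
    """Per-plot-taxon density table (dc, mafd, stratum contributions)."""
    taxa = taxa if taxa is not None else [t for t in ds.taxa if t in params_by_taxon]
    rows = []
    for plot_id in ds.plot_ids:
        for taxon in taxa:
            est = estimate_density(ds, plot_id, taxon, params_by_taxon[taxon])
            if est is None:
                continue
            contrib = category_contributions(est)
            rows.append(
                {
                    "plot_id": est.plot_id,
                    "taxon": est.taxon,
                    "year": est.year,
                    "dc": est.dc,
                    "mafd": est.mafd,
                    "plot_area_km2": est.plot_area_km2,
                    **{
                        f"contribution_{cat.value}": (contrib[cat] if contrib else None)
                        for cat in WaterbodyCategory
                    },
                }
            )
    return pd.DataFrame(
        rows,
        columns=["plot_id", "taxon", "year", "dc", "mafd", "plot_area_km2"]
        + [f"contribution_{cat.value}" for cat in WaterbodyCategory],
    )


def summarize_density(table: pd.DataFrame) -> pd.DataFrame:
    """Taxon-level mean ± SD and median of dc/mafd plus mean stratum contributions."""
    rows = []
    for taxon, g in table.groupby("taxon"):
        row: dict[str, object] = {"taxon": taxon, "n_plots": int(len(g))}
        for col in ("dc", "mafd"):
            row[f"{col}_mean"] = float(g[col].mean())
            row[f"{col}_sd"] = float(g[col].std(ddof=1)) if len(g) > 1 else None
            row[f"{col}_median"] = float(g[col].median())
        for cat in WaterbodyCategory:
            vals = g[f"contribution_{cat.value}"].dropna()
            row[f"contribution_{cat.value}_mean"] = float(vals.mean()) if len(vals) else None
        rows.append(row)
    return pd.DataFrame(rows)
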