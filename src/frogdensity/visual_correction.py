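"""Correction of audial density estimates with visual observation records.

Visual adult counts and egg-mass counts are inflated by class-specific
detection probabilities into an estimate of males present, converted via
the peak calling proportion into "virtual calling males", and used to
floor the recorded counts.  Re-running the density estimators on the
augmented counts yields a corrected density; the ratio of the original to
the corrected estimate measures the fraction of the population that the
audial-only estimate covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_data import (
    Dataset,
    DatasetError,
    TaxonParameters,
    VisibilityClass,
    VisualRecord,
    WaterbodyCategory,
)
from .density import estimate_density
from .survey_metrics import select_best_year, site_best_counts

__all__ = [
    "DetectionProbabilityTable",
    "CorrectionResult",
    "estimate_present_males",
    "virtual_calling_males",
    "augmented_site_counts",
    "compute_nde",
    "correction_table",
    "summarize_corrections",
]

#: Minimum fraction of surveyed waterbodies with visual records for a plot ×
#: taxon × year to be eligible for the corrected estimate.
MIN_VISUAL_COVERAGE = 0.75


@dataclass(frozen=True)
class DetectionProbabilityTable:
    """Visual detection probabilities by observation condition."""

    clear_active: float = 0.75
    clear_inactive: float = 0.50
    obstructed: float = 0.20
    casual: float = 0.10
    egg_mass: float = 0.90

    def __post_init__(self) -> None:
        for name in ("clear_active", "clear_inactive", "obstructed", "casual", "egg_mass"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"detection probability {name} must be in (0, 1], got {v}")

    def for_class(self, visibility_class: VisibilityClass) -> float:
        return getattr(self, visibility_class.value)


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected density and audial coverage for one plot × taxon × year."""

    plot_id: str
    taxon: str
    year: int
    mafd: float
    nde: float | None
    fraction_covered: float | None
    eligible: bool
    visual_coverage: float


def estimate_present_males(
    record: VisualRecord,
    params: TaxonParameters,
    dp: DetectionProbabilityTable | None = None,
    category: WaterbodyCategory | None = None,
    combine: str = "max",
) -> float:
    """Estimate the number of males present at a waterbody from visual evidence.

    The adult component inflates the seen count by the visibility-class
    detection probability, multiplied by the sex ratio when the sex of the
    observed adults is unknown.  The egg component treats each mass as one
    breeding female, inflates by the egg detection probability and converts
    females to males via ``ms / (1 - ms)``.  The two components are two
    noisy views of the same male pool, so by default the larger one is
    taken (``combine='sum'`` adds them instead).
    """
    dp = dp or DetectionProbabilityTable()
    ms = params.ms_for_category(category) if category is not None else params.ms
    adults_component = 0.0
    if record.adults_seen > 0:
        if record.visibility_class is None:
            raise DatasetError(
                f"visual record at {record.waterbody_id!r}: visibility class missing"
            )
        adults_component = record.adults_seen / dp.for_class(record.visibility_class)
        if not record.sex_known:
            adults_component *= ms
    egg_component = 0.0
    if record.egg_masses > 0:
        if ms >= 1:
            raise ValueError(f"{params.taxon}: egg-mass conversion undefined for ms = 1")
        females = record.egg_masses / dp.egg_mass
        egg_component = females * ms / (1.0 - ms)
    if combine == "sum":
        return adults_component + egg_component
    if combine == "max":
        return max(adults_component, egg_component)
    raise ValueError(f"combine must be 'max' or 'sum', got {combine!r}")


def virtual_calling_males(present_males: float, ma: float, recorded_calling: float) -> float:
    """Count augmented with undetected virtual calling males.

    Visually inferred present males are converted to virtual calling males
    with the peak calling proportion; the recorded count is raised to that
    level when it falls short and kept otherwise.
    """
    if present_males < 0 or recorded_calling < 0:
        raise ValueError("inputs must be non-negative")
    virtual = present_males * ma
    return recorded_calling + max(0.0, virtual - recorded_calling)


def augmented_site_counts(
    ds: Dataset,
    plot_id: str,
    taxon: str,
    year: int,
    params: TaxonParameters,
    dp: DetectionProbabilityTable | None = None,
    combine: str = "max",
) -> dict[str, float]:
    """Per-site best counts floored by visually inferred virtual calling males."""
    dp = dp or DetectionProbabilityTable()
    counts = dict(site_best_counts(ds, plot_id, taxon, year))
    plot_wbs = {w.waterbody_id: w for w in ds.plot_waterbodies(plot_id) if w.surveyed}
    for v in ds.visual_records:
        wb = plot_wbs.get(v.waterbody_id)
        if wb is None or v.taxon != taxon or v.year != year:
            continue
        if v.adults_seen == 0 and v.egg_masses == 0:
            continue
        present = estimate_present_males(v, params, dp, category=wb.category, combine=combine)
        recorded = counts.get(v.waterbody_id, 0.0)
        counts[v.waterbody_id] = virtual_calling_males(present, params.ma, recorded)
    return counts


def _visual_coverage(ds: Dataset, plot_id: str, taxon: str, year: int) -> float:
    surveyed = [w.waterbody_id for w in ds.plot_waterbodies(plot_id) if w.surveyed]
    if not surveyed:
        return 0.0
    covered = {
        v.waterbody_id
        for v in ds.visual_records
        if v.taxon == taxon and v.year == year and v.waterbody_id in set(surveyed)
    }
    return len(covered) / len(surveyed)


def compute_nde(
    ds: Dataset,
    plot_id: str,
    taxon: str,
    params: TaxonParameters,
    year: int | None = None,
    dp: DetectionProbabilityTable | None = None,
    combine: str = "max",
    min_coverage: float = MIN_VISUAL_COVERAGE,
) -> CorrectionResult | None:
    """Corrected density estimate for one plot × taxon.

    Eligibility requires visual records at ``min_coverage`` of the surveyed
    waterbodies in the year; ineligible plots return a flagged result with
    the coverage fraction but no corrected value.  Returns ``None`` when
    the taxon has no audial data on the plot at all.
    """
    if year is None:
        year = select_best_year(ds, plot_id, taxon)
    if year is None:
        return None
    base = estimate_density(ds, plot_id, taxon, params, year=year)
    assert base is not None
    coverage = _visual_coverage(ds, plot_id, taxon, year)
    if coverage < min_coverage:
        return CorrectionResult(
            plot_id=plot_id, taxon=taxon, year=year, mafd=base.mafd,
            nde=None, fraction_covered=None, eligible=False, visual_coverage=coverage,
        )
    augmented = augmented_site_counts(ds, plot_id, taxon, year, params, dp, combine=combine)
    corrected = estimate_density(ds, plot_id, taxon, params, year=year, site_counts=augmented)
    assert corrected is not None
    nde = corrected.mafd
    fraction = base.mafd / nde if nde > 0 else None
    return CorrectionResult(
        plot_id=plot_id, taxon=taxon, year=year, mafd=base.mafd,
        nde=nde, fraction_covered=fraction, eligible=True, visual_coverage=coverage,
    )


def correction_table(
    ds: Dataset,
    params_by_taxon: dict[str, TaxonParameters],
    dp: DetectionProbabilityTable | None = None,
    taxa: list[str] | None = None,
    combine: str = "max",
) -> pd.DataFrame:
    """Per-plot-taxon corrected-density rows for the whole dataset."""
    taxa = taxa if taxa is not None else [t for t in ds.taxa if t in params_by_taxon]
    rows = []
    for plot_id in ds.plot_ids:
        for taxon in taxa:
            r = compute_nde(ds, plot_id, taxon, params_by_taxon[taxon], dp=dp, combine=combine)
            if r is not None:
                rows.append(vars(r))
    return pd.DataFrame(
        rows,
        columns=["plot_id", "taxon", "year", "mafd", "nde", "fraction_covered",
                 "eligible", "visual_coverage"],
    )


def summarize_corrections(table: pd.DataFrame) -> pd.DataFrame:
    """Taxon-level mean ± SD and median of the covered-population fraction."""
    rows = []
    for taxon, g in table.groupby("taxon"):
        vals = g.loc[g["eligible"] == True, "fraction_covered"].dropna()  # noqa: E712
        rows.append(
            {
                "taxon": taxon,
                "fraction_covered_mean": float(vals.mean()) if len(vals) else None,
                "fraction_covered_sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                "fraction_covered_median": float(vals.median()) if len(vals) else None,
                "n_plots": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
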