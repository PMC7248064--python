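"""Survey-quality and fidelity metrics computed per plot × taxon.

Best-year selection, waterbody detection probability (WDP), inter-year
breeding-site fidelity (IYF), the contribution of the most productive
survey (CMPS), and per-plot occupancy summaries.  All ratios are set-based
and undefined values are returned as ``None`` (reported as missing), never
as NaN surprises downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_data import Dataset

__all__ = [
    "PlotTaxonMetrics",
    "best_site_count",
    "site_best_counts",
    "select_best_year",
    "compute_wdp",
    "compute_iyf",
    "compute_cmps",
    "summarize_plot",
    "compute_metrics_table",
    "summarize_taxa",
]


@dataclass(frozen=True)
class PlotTaxonMetrics:
    """Quality metrics for one taxon on one plot (best year unless noted)."""

    plot_id: str
    taxon: str
    best_year: int | None
    wdp: float | None
    iyf: float | None
    cmps: float | None
    mean_calling_males_per_occupied_waterbody: float | None
    fraction_waterbodies_with_audial_records: float | None

    def __post_init__(self) -> None:
        for name in ("wdp", "iyf", "cmps", "fraction_waterbodies_with_audial_records"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0, 1]: {v}")


def best_site_count(counts: Iterable[float]) -> float | None:
    """Largest number of simultaneously counted males over the visits to a site.

    Returns ``None`` for a site with no recorded visits (excluded downstream).
    """
    counts = list(counts)
    if not counts:
        return None
    return max(counts)


def site_best_counts(ds: Dataset, plot_id: str, taxon: str, year: int) -> dict[str, float]:
    """Per-site best (maximum simultaneous) counts for a plot, taxon and year.

    Sites appear only if at least one count row (including explicit zeros)
    was recorded for them in that year.
    """
    survey_ids = {s.survey_id for s in ds.plot_surveys(plot_id, year)}
    per_site: dict[str, list[float]] = {}
    for c in ds.call_counts:
        if c.taxon == taxon and c.survey_id in survey_ids:
            per_site.setdefault(c.waterbody_id, []).append(c.count)
    return {wb: max(v) for wb, v in per_site.items()}


def select_best_year(ds: Dataset, plot_id: str, taxon: str) -> int | None:
    """Year whose plot total of per-site maxima is largest (ties → earliest year).

    Data from different years are never pooled; all density estimation uses
    this single best year.  Returns ``None`` when the taxon was never
    recorded on the plot.
    """
    totals: dict[int, float] = {}
    for year in ds.plot_years(plot_id):
        best = site_best_counts(ds, plot_id, taxon, year)
        if best:
            totals[year] = sum(best.values())
    if not totals:
        return None
    top = max(totals.values())
    return min(y for y, t in totals.items() if t == top)


def _audial_sites(ds: Dataset, plot_id: str, taxon: str, year: int) -> set[str]:
    return {wb for wb, c in site_best_counts(ds, plot_id, taxon, year).items() if c > 0}


def _visual_evidence_sites(ds: Dataset, plot_id: str, taxon: str, year: int) -> set[str]:
    plot_wbs = {w.waterbody_id for w in ds.plot_waterbodies(plot_id)}
    return {
        v.waterbody_id
        for v in ds.visual_records
        if v.taxon == taxon and v.year == year and v.waterbody_id in plot_wbs and v.any_evidence
    }


def compute_wdp(ds: Dataset, plot_id: str, taxon: str, year: int) -> float | None:
    """Waterbody detection probability for audial surveys.

    Ratio of waterbodies with calling-male records to waterbodies with any
    evidence of adult presence (audial, adults seen, spawn, tadpoles or
    metamorphs) in the given year.  ``None`` when no evidence exists.
    """
    audial = _audial_sites(ds, plot_id, taxon, year)
    evidence = audial | _visual_evidence_sites(ds, plot_id, taxon, year)
    if not evidence:
        return None
    return len(audial) / len(evidence)


def compute_iyf(ds: Dataset, plot_id: str, taxon: str) -> float | None:
    """Inter-year fidelity in breeding-waterbody use.

    Ratio of waterbodies with a call record in the most productive year to
    waterbodies with a call record in the pooled data for all years.
    Undefined (``None``) for plots with fewer than two survey years; true
    breeding-site shifts and detection failures are deliberately conflated.
    """
    years = ds.plot_years(plot_id)
    if len(years) < 2:
        return None
    best_year = select_best_year(ds, plot_id, taxon)
    if best_year is None:
        return None
    pooled: set[str] = set()
    for y in years:
        pooled |= _audial_sites(ds, plot_id, taxon, y)
    if not pooled:
        return None
    return len(_audial_sites(ds, plot_id, taxon, best_year)) / len(pooled)


def compute_cmps(ds: Dataset, plot_id: str, taxon: str, year: int) -> float | None:
    """Contribution of the most productive survey.

    Largest single-survey plot total divided by the year's total calling
    male score (the sum over sites of per-site maxima — the best survey is
    often most productive only for part of the individual sites).  Low
    values indicate that more surveys per breeding period are desirable.
    """
    survey_totals: dict[str, float] = {}
    survey_ids = {s.survey_id for s in ds.plot_surveys(plot_id, year)}
    for c in ds.call_counts:
        if c.taxon == taxon and c.survey_id in survey_ids:
            survey_totals[c.survey_id] = survey_totals.get(c.survey_id, 0.0) + c.count
    denom = sum(site_best_counts(ds, plot_id, taxon, year).values())
    if denom <= 0 or not survey_totals:
        return None
    return max(survey_totals.values()) / denom


def summarize_plot(
    ds: Dataset, plot_id: str, taxon: str, year: int | None = None
) -> PlotTaxonMetrics:
    """Full metric summary for one plot × taxon (defaults to the best year).

    The mean calling-male count is computed only over occupied waterbodies
    (those with a positive best count); the occupancy fraction is over all
    surveyed waterbodies on the plot.
    """
    if year is None:
        year = select_best_year(ds, plot_id, taxon)
    if year is None:
        return PlotTaxonMetrics(plot_id, taxon, None, None, None, None, None, None)
    best = site_best_counts(ds, plot_id, taxon, year)
    occupied = [c for c in best.values() if c > 0]
    n_surveyed = sum(1 for w in ds.plot_waterbodies(plot_id) if w.surveyed)
    return PlotTaxonMetrics(
        plot_id=plot_id,
        taxon=taxon,
        best_year=year,
        wdp=compute_wdp(ds, plot_id, taxon, year),
        iyf=compute_iyf(ds, plot_id, taxon),
        cmps=compute_cmps(ds, plot_id, taxon, year),
        mean_calling_males_per_occupied_waterbody=(
            sum(occupied) / len(occupied) if occupied else None
        ),
        fraction_waterbodies_with_audial_records=(
            len(occupied) / n_surveyed if n_surveyed else None
        ),
    )


def compute_metrics_table(ds: Dataset, taxa: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-plot-taxon metrics table for the whole dataset."""
    taxa = list(taxa) if taxa is not None else ds.taxa
    rows = []
    for plot_id in ds.plot_ids:
        for taxon in taxa:
            m = summarize_plot(ds, plot_id, taxon)
            rows.append(vars(m))
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id", "taxon", "best_year", "wdp", "iyf", "cmps",
            "mean_calling_males_per_occupied_waterbody",
            "fraction_waterbodies_with_audial_records",
        ],
    )


def summarize_taxa(metrics: pd.DataFrame) -> pd.DataFrame:
    """Taxon-level mean ± SD (n) summary of the plot metrics table.

    Plots where the taxon was never recorded contribute only to the
    plot-presence fraction; each metric is averaged over the plots where it
    is defined, mirroring per-column sample sizes.
    """
    out = []
    for taxon, g in metrics.groupby("taxon"):
        present = g["best_year"].notna()
        row: dict[str, object] = {
            "taxon": taxon,
            "fraction_plots_with_audial_records": float(present.mean()) if len(g) else None,
        }
        for col in (
            "mean_calling_males_per_occupied_waterbody",
            "fraction_waterbodies_with_audial_records",
            "wdp", "iyf", "cmps",
        ):
            vals = g[col].dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else None
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else None
            row[f"{col}_n"] = int(len(vals))
        out.append(row)
    return pd.DataFrame(out)
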