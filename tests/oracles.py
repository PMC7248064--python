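"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the production code paths in ``density`` and
``survey_metrics``: best counts, habitat totals and extrapolation are all
recomputed with plain per-waterbody loops from the raw record containers.
"""

from __future__ import annotations

from frogdensity.core_data import Dataset, TaxonParameters, WaterbodyCategory


def naive_site_best_counts(ds: Dataset, plot_id: str, taxon: str, year: int) -> dict[str, float]:
    best: dict[str, float] = {}
    for c in ds.call_counts:
        sv = ds.surveys[c.survey_id]
        if c.taxon != taxon or sv.plot_id != plot_id or sv.year != year:
            continue
        if c.waterbody_id not in best or c.count > best[c.waterbody_id]:
            best[c.waterbody_id] = c.count
    return best


def _naive_sampled_length(wb, hearing_m: float) -> float:
    total = wb.length_m if wb.category is WaterbodyCategory.DITCH else wb.perimeter_m
    if wb.sampled_length_m is not None:
        return wb.sampled_length_m
    return total if total < 2.0 * hearing_m else 2.0 * hearing_m


def naive_dc(
    ds: Dataset, plot_id: str, taxon: str, year: int, params: TaxonParameters
) -> float:
    """Per-waterbody loop evaluation of the stratified density."""
    best = naive_site_best_counts(ds, plot_id, taxon, year)
    s = ds.plot_area_km2(plot_id)
    total = 0.0
    for cat in WaterbodyCategory:
        pt = ps = 0.0
        for wb in ds.waterbodies.values():
            if wb.plot_id != plot_id or wb.category is not cat:
                continue
            if cat is WaterbodyCategory.SMALL:
                pt += 1.0
                if wb.surveyed:
                    ps += 1.0
            else:
                length = wb.length_m if cat is WaterbodyCategory.DITCH else wb.perimeter_m
                pt += length or 0.0
                if wb.surveyed:
                    ps += _naive_sampled_length(wb, params.hearing_distance_m)
        if ps == 0:
            continue
        for wb in ds.waterbodies.values():
            if wb.plot_id == plot_id and wb.category is cat and wb.surveyed:
                total += best.get(wb.waterbody_id, 0.0) * pt / ps
    return total / s


def naive_mafd(
    ds: Dataset, plot_id: str, taxon: str, year: int, params: TaxonParameters
) -> float:
    """Per-waterbody loop with the stratum sex ratio applied to each site."""
    best = naive_site_best_counts(ds, plot_id, taxon, year)
    s = ds.plot_area_km2(plot_id)
    total = 0.0
    for cat in WaterbodyCategory:
        pt = ps = 0.0
        for wb in ds.waterbodies.values():
            if wb.plot_id != plot_id or wb.category is not cat:
                continue
            if cat is WaterbodyCategory.SMALL:
                pt += 1.0
                if wb.surveyed:
                    ps += 1.0
            else:
                length = wb.length_m if cat is WaterbodyCategory.DITCH else wb.perimeter_m
                pt += length or 0.0
                if wb.surveyed:
                    ps += _naive_sampled_length(wb, params.hearing_distance_m)
        if ps == 0:
            continue
        if params.ms_large is None:
            ms = params.ms
        elif cat is WaterbodyCategory.LARGE:
            ms = params.ms_large
        elif cat is WaterbodyCategory.MEDIUM:
            ms = (params.ms + params.ms_large) / 2.0
        else:
            ms = params.ms
        for wb in ds.waterbodies.values():
            if wb.plot_id == plot_id and wb.category is cat and wb.surveyed:
                total += (
                    best.get(wb.waterbody_id, 0.0) * pt / ps / (params.ma * params.mp * ms)
                )
    return total / s
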