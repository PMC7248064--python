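"""Synthetic survey generator with known truth.

The generative model is a binomial thinning chain that mirrors the
estimator's detection decomposition exactly: adults are allocated to
waterbodies proportionally to habitat, males are a binomial draw with the
sex ratio, presence at a survey thins by ``mp`` × seasonal activity, and
calling thins by ``ma`` × the daily modifier.  Counts are recorded only at
surveyed sites and, for linear habitat, only within the hearing range.
Because estimation inverts this chain, parameter recovery is a fair
end-to-end test of the whole pipeline.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .core_data import (
    CallCount,
    Dataset,
    SurveyEvent,
    TaxonParameters,
    VisibilityClass,
    VisualRecord,
    WaterbodyCategory,
    WaterbodyRecord,
    classify_waterbody,
)
from .density import estimate_density_table

__all__ = [
    "TaxonTruth",
    "SimulationConfig",
    "simulate_dataset",
    "truth_parameters",
    "recovery_experiment",
    "seasonal_activity",
]


class TaxonTruth(BaseModel):
    """Generative truth for one taxon."""

    density: float = Field(ge=0, description="true adult density, individuals/km²")
    ma: float = Field(gt=0, le=1)
    mp: float = Field(gt=0, le=1)
    ms: float = Field(gt=0, le=1)
    ms_large: float | None = Field(default=None, gt=0, le=1)
    hearing_distance_m: float = Field(default=100.0, gt=0)
    breeding_profile: Literal["lek", "explosive"] = "lek"
    peak_day: float = 14.0
    season_width_days: float = Field(default=10.0, gt=0)
    rise_days: float = Field(default=3.0, gt=0)
    #: SD (days) of per-site shifts of the activity curve — different local
    #: populations breed at slightly different times
    site_peak_jitter_days: float = Field(default=0.0, ge=0)
    nocturnal: bool = False

    def ms_for_category(self, category: WaterbodyCategory) -> float:
        if self.ms_large is None:
            return self.ms
        if category is WaterbodyCategory.LARGE:
            return self.ms_large
        if category is WaterbodyCategory.MEDIUM:
            return (self.ms + self.ms_large) / 2.0
        return self.ms


class SimulationConfig(BaseModel):
    """Full description of a synthetic survey campaign."""

    n_plots: int = Field(default=5, ge=1)
    plot_area_km2: float = Field(default=25.0, gt=0)
    seed: int = 0
    # waterbody inventory per plot
    mean_small: float = Field(default=12.0, ge=0)
    mean_medium: float = Field(default=2.0, ge=0)
    mean_large: float = Field(default=0.4, ge=0)
    mean_ditch: float = Field(default=4.0, ge=0)
    ditch_length_range_m: tuple[float, float] = (500.0, 3000.0)
    # fraction of habitat units surveyed per stratum
    surveyed_fraction: dict[str, float] = Field(
        default_factory=lambda: {"small": 0.27, "medium": 0.49, "large": 0.57, "ditch": 0.5}
    )
    # how adults split across strata (renormalised over strata present on a plot)
    category_shares: dict[str, float] = Field(
        default_factory=lambda: {"small": 0.75, "medium": 0.15, "large": 0.02, "ditch": 0.08}
    )
    years: list[int] = Field(default_factory=lambda: [2016])
    onset_day_of_year: int = 97
    survey_rel_days: list[float] = Field(default_factory=lambda: [14.0])
    survey_rel_daytimes: list[float] = Field(default_factory=lambda: [0.5])
    sunset_time_hours: float = 21.0
    site_fidelity: float = Field(default=1.0, ge=0, le=1)
    visual_coverage: float = Field(default=0.0, ge=0, le=1)
    visual_detection: float = Field(default=0.75, gt=0, le=1)
    taxa: dict[str, TaxonTruth]

    @field_validator("surveyed_fraction", "category_shares")
    @classmethod
    def _check_probs(cls, v: dict[str, float]) -> dict[str, float]:
        for k, val in v.items():
            if k not in (c.value for c in WaterbodyCategory):
                raise ValueError(f"unknown waterbody category {k!r}")
            if not 0 <= val <= 1 and k in ("small", "medium", "large", "ditch"):
                if val < 0:
                    raise ValueError(f"{k}: value must be >= 0")
        return v


def seasonal_activity(truth: TaxonTruth, rel_day: float) -> float:
    """Calling-activity multiplier in [0, 1] as a function of days since onset.

    Lek breeders follow a scaled Gaussian around the peak; explosive
    breeders rise linearly over ``rise_days`` to the peak and then decay
    exponentially with scale ``season_width_days``.
    """
    if truth.breeding_profile == "lek":
        z = (rel_day - truth.peak_day) / truth.season_width_days
        return math.exp(-0.5 * z * z)
    if rel_day < truth.peak_day - truth.rise_days:
        return 0.0
    if rel_day < truth.peak_day:
        return 1.0 - (truth.peak_day - rel_day) / truth.rise_days
    return math.exp(-(rel_day - truth.peak_day) / truth.season_width_days)


def _daily_modifier(truth: TaxonTruth, rel_daytime: float) -> float:
    if not truth.nocturnal:
        return 1.0
    # smooth ramp-up towards sunset for strictly nocturnal callers
    return 1.0 / (1.0 + math.exp(-8.0 * (rel_daytime - 0.85)))


def _circleish_perimeter_m(area_ha: float, rng: np.random.Generator) -> float:
    # shoreline of a mildly irregular waterbody: circle perimeter × shape factor
    area_m2 = area_ha * 1e4
    return 2.0 * math.sqrt(math.pi * area_m2) * rng.uniform(1.1, 1.5)


def _generate_waterbodies(cfg: SimulationConfig, rng: np.random.Generator) -> Dataset:
    ds = Dataset()
    for p in range(cfg.n_plots):
        plot_id = f"P{p + 1:03d}"
        ds.plot_areas[plot_id] = cfg.plot_area_km2
        specs: list[tuple[WaterbodyCategory, float | None, float | None, float | None]] = []
        n_small = max(1, int(rng.poisson(cfg.mean_small)))
        for _ in range(n_small):
            specs.append((WaterbodyCategory.SMALL, float(rng.uniform(0.05, 0.45)), None, None))
        for _ in range(int(rng.poisson(cfg.mean_medium))):
            a = float(rng.uniform(0.6, 9.5))
            specs.append((WaterbodyCategory.MEDIUM, a, _circleish_perimeter_m(a, rng), None))
        for _ in range(int(rng.poisson(cfg.mean_large))):
            a = float(rng.uniform(11.0, 30.0))
            specs.append((WaterbodyCategory.LARGE, a, _circleish_perimeter_m(a, rng), None))
        for _ in range(int(rng.poisson(cfg.mean_ditch))):
            lo, hi = cfg.ditch_length_range_m
            specs.append((WaterbodyCategory.DITCH, None, None, float(rng.uniform(lo, hi))))

        surveyed_by_cat: dict[WaterbodyCategory, list[int]] = {c: [] for c in WaterbodyCategory}
        flags = []
        for i, (cat, _, _, _) in enumerate(specs):
            surveyed = bool(rng.random() < cfg.surveyed_fraction.get(cat.value, 0.5))
            flags.append(surveyed)
            if surveyed:
                surveyed_by_cat[cat].append(i)
        # guarantee at least one surveyed site in every stratum present on the
        # plot, so no stratum with adults is left entirely unsampled
        for cat in WaterbodyCategory:
            idxs = [i for i, s in enumerate(specs) if s[0] is cat]
            if idxs and not surveyed_by_cat[cat]:
                flags[idxs[int(rng.integers(len(idxs)))]] = True

        for i, ((cat, area, perim, length), surveyed) in enumerate(zip(specs, flags)):
            if area is not None:
                assert classify_waterbody(area) is cat
            wb = WaterbodyRecord(
                waterbody_id=f"{plot_id}-W{i + 1:03d}",
                plot_id=plot_id,
                category=cat,
                area_ha=area,
                perimeter_m=perim,
                length_m=length,
                surveyed=surveyed,
            )
            ds.waterbodies[wb.waterbody_id] = wb
    return ds


def _allocation_probs(
    wbs: list[WaterbodyRecord], cfg: SimulationConfig
) -> np.ndarray:
    cats_present = {w.category for w in wbs}
    share = {c: cfg.category_shares.get(c.value, 0.0) for c in cats_present}
    total_share = sum(share.values())
    if total_share == 0:
        share = {c: 1.0 for c in cats_present}
        total_share = float(len(cats_present))
    unit_totals: dict[WaterbodyCategory, float] = {}
    for w in wbs:
        u = 1.0 if w.category is WaterbodyCategory.SMALL else (w.habitat_length_m or 0.0)
        unit_totals[w.category] = unit_totals.get(w.category, 0.0) + u
    probs = np.zeros(len(wbs))
    for i, w in enumerate(wbs):
        u = 1.0 if w.category is WaterbodyCategory.SMALL else (w.habitat_length_m or 0.0)
        probs[i] = (share[w.category] / total_share) * (u / unit_totals[w.category])
    return probs / probs.sum()


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, dict]:
    """Generate one dataset plus a truth record of every latent quantity.

    Deterministic under a fixed ``config.seed``.  The truth record stores,
    per plot × taxon × year, the adults and males allocated to each
    waterbody and the present/calling/counted chain for each survey, plus
    realized per-taxon densities over the whole campaign.
    """
    rng = np.random.default_rng(config.seed)
    ds = _generate_waterbodies(config, rng)
    noon = 12.0

    truth: dict = {
        "seed": config.seed,
        "taxa": {},
        "plots": {},
    }
    onset_by_year = {
        y: dt.date(y, 1, 1) + dt.timedelta(days=config.onset_day_of_year - 1)
        for y in config.years
    }

    # survey calendar (same schedule on every plot)
    for plot_id in ds.plot_ids:
        for year in config.years:
            for k, rel_day in enumerate(config.survey_rel_days):
                rdt = config.survey_rel_daytimes[k % len(config.survey_rel_daytimes)]
                ev = SurveyEvent(
                    survey_id=f"{plot_id}-Y{year}-S{k + 1}",
                    plot_id=plot_id,
                    year=year,
                    calendar_date=onset_by_year[year] + dt.timedelta(days=round(rel_day)),
                    mid_time_hours=noon + rdt * (config.sunset_time_hours - noon),
                    sunset_time_hours=config.sunset_time_hours,
                    earliest_season_date=onset_by_year[year],
                    noon_time_hours=noon,
                )
                ds.surveys[ev.survey_id] = ev

    total_adults = {taxon: 0 for taxon in config.taxa}
    for plot_id in ds.plot_ids:
        wbs = sorted(ds.plot_waterbodies(plot_id), key=lambda w: w.waterbody_id)
        probs = _allocation_probs(wbs, config)
        truth["plots"][plot_id] = {}
        for taxon, tt in config.taxa.items():
            ptruth: dict = {"adults": {}, "males": {}, "surveys": {}}
            truth["plots"][plot_id][taxon] = ptruth
            prev_adults: np.ndarray | None = None
            for year in config.years:
                n_adults = int(rng.poisson(tt.density * config.plot_area_km2))
                if prev_adults is None:
                    adults = rng.multinomial(n_adults, probs)
                else:
                    # inter-year site fidelity: each site keeps its allocation
                    # with probability φ, the remainder is reshuffled
                    keep = rng.random(len(wbs)) < config.site_fidelity
                    kept = np.where(keep, prev_adults, 0)
                    adults = kept + rng.multinomial(int(n_adults - kept.sum()), probs) \
                        if n_adults > kept.sum() else kept
                    adults = np.asarray(adults)
                prev_adults = adults
                total_adults[taxon] += int(adults.sum())
                ms_vec = np.array([tt.ms_for_category(w.category) for w in wbs])
                males = rng.binomial(adults, ms_vec)
                peak_shift = (
                    rng.normal(0.0, tt.site_peak_jitter_days, len(wbs))
                    if tt.site_peak_jitter_days > 0
                    else np.zeros(len(wbs))
                )
                ptruth["adults"][str(year)] = {
                    w.waterbody_id: int(a) for w, a in zip(wbs, adults)
                }
                ptruth["males"][str(year)] = {
                    w.waterbody_id: int(m) for w, m in zip(wbs, males)
                }
                for ev in ds.plot_surveys(plot_id, year):
                    act = np.array(
                        [
                            seasonal_activity(tt, ev.relative_date - shift)
                            for shift in peak_shift
                        ]
                    )
                    day_mod = _daily_modifier(tt, ev.relative_daytime)
                    p_present = np.minimum(1.0, tt.mp * act)
                    p_calling = min(1.0, tt.ma * day_mod)
                    present = rng.binomial(males, p_present)
                    calling = rng.binomial(present, p_calling)
                    srec: dict = {}
                    for w, pres, call in zip(wbs, present, calling):
                        counted = None
                        if w.surveyed:
                            if w.category is WaterbodyCategory.SMALL:
                                counted = int(call)
                            else:
                                length = w.habitat_length_m or 0.0
                                frac = min(1.0, 2.0 * tt.hearing_distance_m / length) \
                                    if length > 0 else 0.0
                                counted = int(rng.binomial(call, frac))
                            ds.call_counts.append(
                                CallCount(
                                    survey_id=ev.survey_id,
                                    waterbody_id=w.waterbody_id,
                                    taxon=taxon,
                                    count=float(counted),
                                )
                            )
                        srec[w.waterbody_id] = {
                            "present": int(pres),
                            "calling": int(call),
                            "counted": counted,
                        }
                    ptruth["surveys"][ev.survey_id] = srec
                if config.visual_coverage > 0:
                    _simulate_visual(ds, config, rng, wbs, taxon, tt, year, males)

    area_total = config.n_plots * config.plot_area_km2
    for taxon, tt in config.taxa.items():
        truth["taxa"][taxon] = {
            "true_density": tt.density,
            "total_adults": total_adults[taxon],
            "realized_density": total_adults[taxon] / (area_total * len(config.years)),
        }
    ds.validate()
    return ds, truth


def _simulate_visual(
    ds: Dataset,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    wbs: list[WaterbodyRecord],
    taxon: str,
    tt: TaxonTruth,
    year: int,
    males: np.ndarray,
) -> None:
    surveyed_idx = [i for i, w in enumerate(wbs) if w.surveyed]
    if not surveyed_idx:
        return
    n_cover = math.ceil(cfg.visual_coverage * len(surveyed_idx))
    chosen = rng.choice(surveyed_idx, size=n_cover, replace=False)
    for i in sorted(int(j) for j in chosen):
        w = wbs[i]
        present_males = rng.binomial(males[i], tt.mp)
        seen = int(rng.binomial(present_males, cfg.visual_detection))
        ds.visual_records.append(
            VisualRecord(
                waterbody_id=w.waterbody_id,
                taxon=taxon,
                year=year,
                adults_seen=seen,
                sex_known=True,
                egg_masses=0,
                visibility_class=VisibilityClass.CLEAR_ACTIVE if seen else None,
            )
        )


def truth_parameters(config: SimulationConfig) -> dict[str, TaxonParameters]:
    """Estimator parameters matched exactly to the generative truth."""
    return {
        taxon: TaxonParameters(
            taxon=taxon,
            ma=tt.ma,
            mp=tt.mp,
            ms=tt.ms,
            ms_large=tt.ms_large,
            hearing_distance_m=tt.hearing_distance_m,
        )
        for taxon, tt in config.taxa.items()
    }


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    params_by_taxon: dict[str, TaxonParameters] | None = None,
) -> pd.DataFrame:
    """Bias/RMSE of the adult-density estimate against the generative truth.

    Replicate ``r`` runs the full simulate→estimate pipeline at seed
    ``config.seed + r``; relative errors compare the campaign-total
    estimated adults (Σ density × plot area) to the realized total.
    Reports per-taxon mean relative bias and RMSE, plus the mean covered
    fraction when visual records were simulated.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    errors: dict[str, list[float]] = {t: [] for t in config.taxa}
    covered: dict[str, list[float]] = {t: [] for t in config.taxa}
    for r in range(n_replicates):
        cfg = config.model_copy(update={"seed": config.seed + r})
        ds, truth = simulate_dataset(cfg)
        params = params_by_taxon or truth_parameters(cfg)
        table = estimate_density_table(ds, params, taxa=list(cfg.taxa))
        for taxon in cfg.taxa:
            true_total = truth["taxa"][taxon]["total_adults"] / len(cfg.years)
            sub = table[table["taxon"] == taxon]
            est_total = float((sub["mafd"] * sub["plot_area_km2"]).sum())
            if true_total > 0:
                errors[taxon].append((est_total - true_total) / true_total)
        if cfg.visual_coverage > 0:
            from .visual_correction import correction_table, summarize_corrections

            corr = summarize_corrections(correction_table(ds, params, taxa=list(cfg.taxa)))
            for _, row in corr.iterrows():
                if row["fraction_covered_mean"] is not None:
                    covered[row["taxon"]].append(row["fraction_covered_mean"])
    rows = []
    for taxon in config.taxa:
        errs = np.array(errors[taxon])
        rows.append(
            {
                "taxon": taxon,
                "n_replicates": int(len(errs)),
                "mean_relative_bias": float(errs.mean()) if len(errs) else None,
                "rmse": float(np.sqrt((errs**2).mean())) if len(errs) else None,
                "mean_fraction_covered": (
                    float(np.mean(covered[taxon])) if covered[taxon] else None
                ),
            }
        )
    return pd.DataFrame(rows)
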