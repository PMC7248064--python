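from __future__ import annotations

import datetime as dt

import pytest

from frogdensity.core_data import (
    CallCount,
    Dataset,
    SurveyEvent,
    TaxonParameters,
    VisibilityClass,
    VisualRecord,
    WaterbodyCategory,
    WaterbodyRecord,
)

TAXON = "Taxon test"


def make_survey(survey_id: str, plot_id: str, year: int, month: int, day: int) -> SurveyEvent:
    return SurveyEvent(
        survey_id=survey_id,
        plot_id=plot_id,
        year=year,
        calendar_date=dt.date(year, month, day),
        mid_time_hours=18.0,
        sunset_time_hours=21.0,
        earliest_season_date=dt.date(year, 4, 1),
    )


def small_wb(wb_id: str, plot_id: str, surveyed: bool = True) -> WaterbodyRecord:
    return WaterbodyRecord(
        waterbody_id=wb_id,
        plot_id=plot_id,
        category=WaterbodyCategory.SMALL,
        area_ha=0.2,
        surveyed=surveyed,
    )


@pytest.fixture
def toy_params() -> TaxonParameters:
    return TaxonParameters(
        taxon=TAXON, ma=0.5, mp=0.8, ms=0.5, hearing_distance_m=100.0,
    )


@pytest.fixture
def metrics_dataset() -> Dataset:
    """Two survey years on one plot, engineered for hand-checkable metrics.

    2016 per-site bests: A1=3, A2=5, A3=0 (total 8, the best year);
    2017 per-site bests: A1=2, A2=0, A4=4 (total 6).
    Visual evidence 2016 at A3 (adults) and A4 (egg masses).
    """
    ds = Dataset()
    for wb_id in ("A1", "A2", "A3", "A4"):
        ds.waterbodies[wb_id] = small_wb(wb_id, "A")
    ds.waterbodies["A5"] = small_wb("A5", "A", surveyed=False)
    for sid, (y, m, d) in {
        "s1": (2016, 4, 10), "s2": (2016, 4, 20),
        "s3": (2017, 4, 12), "s4": (2017, 4, 25),
    }.items():
        ds.surveys[sid] = make_survey(sid, "A", y, m, d)
    counts = [
        ("s1", "A1", 0), ("s1", "A2", 5), ("s1", "A3", 0),
        ("s2", "A1", 3), ("s2", "A2", 2), ("s2", "A3", 0),
        ("s3", "A1", 2), ("s3", "A2", 0), ("s3", "A4", 4),
        ("s4", "A1", 1), ("s4", "A2", 0),
    ]
    for sid, wb, n in counts:
        ds.call_counts.append(CallCount(survey_id=sid, waterbody_id=wb, taxon=TAXON, count=n))
    ds.visual_records += [
        VisualRecord(
            waterbody_id="A3", taxon=TAXON, year=2016, adults_seen=2,
            visibility_class=VisibilityClass.OBSTRUCTED,
        ),
        VisualRecord(waterbody_id="A4", taxon=TAXON, year=2016, egg_masses=3),
    ]
    ds.validate()
    return ds


@pytest.fixture
def density_dataset() -> Dataset:
    """One plot (25 km²) whose stratum tallies are known exactly.

    small: C=12, Pt=60, Ps=20; medium: C=5, Pt=4000 m, Ps=1000 m;
    large: none; ditch: C=3, Pt=12000 m, Ps=3000 m.
    """
    ds = Dataset()
    for i in range(60):
        ds.waterbodies[f"S{i:02d}"] = small_wb(f"S{i:02d}", "D", surveyed=i < 20)
    for i in range(2):
        ds.waterbodies[f"M{i}"] = WaterbodyRecord(
            waterbody_id=f"M{i}", plot_id="D", category=WaterbodyCategory.MEDIUM,
            area_ha=3.0, perimeter_m=2000.0, surveyed=i == 0,
            sampled_length_m=1000.0 if i == 0 else None,
        )
    for i in range(4):
        ds.waterbodies[f"L{i}"] = WaterbodyRecord(
            waterbody_id=f"L{i}", plot_id="D", category=WaterbodyCategory.DITCH,
            length_m=3000.0, surveyed=i == 0,
            sampled_length_m=3000.0 if i == 0 else None,
        )
    ds.surveys["d1"] = make_survey("d1", "D", 2016, 5, 1)
    for wb, n in [("S00", 8), ("S01", 4), ("M0", 5), ("L0", 3)]:
        ds.call_counts.append(CallCount(survey_id="d1", waterbody_id=wb, taxon=TAXON, count=n))
    ds.validate()
    return ds


@pytest.fixture
def nde_dataset() -> Dataset:
    """Fully sampled single-stratum plot for the visual-correction example.

    Audial bests: V1=4, V2=6, V3=0 (sum 10).  A visual record of 60 adults
    at V1 under clear/active conditions implies 80 present males.
    """
    ds = Dataset()
    for wb_id in ("V1", "V2", "V3"):
        ds.waterbodies[wb_id] = small_wb(wb_id, "N")
    ds.surveys["n1"] = make_survey("n1", "N", 2016, 5, 1)
    for wb, n in [("V1", 4), ("V2", 6), ("V3", 0)]:
        ds.call_counts.append(CallCount(survey_id="n1", waterbody_id=wb, taxon=TAXON, count=n))
    ds.visual_records += [
        VisualRecord(
            waterbody_id="V1", taxon=TAXON, year=2016, adults_seen=60,
            visibility_class=VisibilityClass.CLEAR_ACTIVE,
        ),
        VisualRecord(waterbody_id="V2", taxon=TAXON, year=2016),
        VisualRecord(waterbody_id="V3", taxon=TAXON, year=2016),
    ]
    ds.validate()
    return ds
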