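"""Domain types, file I/O and the date/time transforms shared by every stage.

The pipeline operates on five record types read from plain-text CSV files:
a waterbody/ditch inventory, a table of survey visits, calling-male counts,
optional visual observations, and per-taxon biological parameters.  All
validation (schema, referential integrity, value ranges) happens at load
time so downstream estimators can assume a consistent dataset.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "WaterbodyCategory",
    "VisibilityClass",
    "WaterbodyRecord",
    "SurveyEvent",
    "CallCount",
    "VisualRecord",
    "TaxonParameters",
    "Dataset",
    "DatasetError",
    "classify_waterbody",
    "relative_date",
    "relative_daytime",
    "read_dataset",
    "write_dataset",
    "load_taxon_parameters",
    "DEFAULT_TAXON_PARAMETERS",
    "DEFAULT_PLOT_AREA_KM2",
    "SMALL_MAX_HA",
    "MEDIUM_MAX_HA",
]

#: Default survey-plot area in km² (5 × 5 km squares).
DEFAULT_PLOT_AREA_KM2 = 25.0

#: Surface-area class boundaries (hectares) for lentic waterbodies.
SMALL_MAX_HA = 0.5
MEDIUM_MAX_HA = 10.0


class DatasetError(ValueError):
    """Raised when input files violate the documented schemas or integrity rules."""


class WaterbodyCategory(str, enum.Enum):
    """Habitat stratum of a survey site.

    Lentic waterbodies are classified purely by surface area; ditches
    (drainage channels, linear habitat) are a separate input class and are
    never derived from an area.
    """

    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"
    DITCH = "ditch"

    @property
    def is_linear(self) -> bool:
        """True for strata measured in metres of habitat (shoreline or channel)."""
        return self in (WaterbodyCategory.MEDIUM, WaterbodyCategory.LARGE, WaterbodyCategory.DITCH)


class VisibilityClass(str, enum.Enum):
    """Observation conditions attached to a visual adult count."""

    CLEAR_ACTIVE = "clear_active"
    CLEAR_INACTIVE = "clear_inactive"
    OBSTRUCTED = "obstructed"
    CASUAL = "casual"


def classify_waterbody(area_ha: float) -> WaterbodyCategory:
    """Classify a lentic waterbody by surface area.

    Boundaries: [0, 0.5) ha → small, [0.5, 10.0] ha → medium,
    (10.0, ∞) ha → large.  The 0.5 and 10.0 ha boundaries are assigned to
    the medium class.

    Parameters
    ----------
    area_ha
        Surface area in hectares; must be strictly positive.

    Raises
    ------
    ValueError
        If ``area_ha`` is not a positive finite number.
    """
    if not (isinstance(area_ha, (int, float)) and math.isfinite(area_ha) and area_ha > 0):
        raise ValueError(f"waterbody surface area must be a positive number, got {area_ha!r}")
    if area_ha < SMALL_MAX_HA:
        return WaterbodyCategory.SMALL
    if area_ha <= MEDIUM_MAX_HA:
        return WaterbodyCategory.MEDIUM
    return WaterbodyCategory.LARGE


def relative_date(calendar_date: dt.date, earliest_season_date: dt.date) -> float:
    """Days elapsed since the season onset (earliest calling record of any taxon).

    Returns 0.0 at the onset date and may be negative for surveys that
    pre-date the onset (the onset is defined post hoc from the data).
    Both dates must fall in the same calendar year.
    """
    if calendar_date.year != earliest_season_date.year:
        raise ValueError(
            f"cross-year relative date: {calendar_date} vs onset {earliest_season_date}"
        )
    return float((calendar_date - earliest_season_date).days)


def relative_daytime(mid_time: float, noon_time: float, sunset_time: float) -> float:
    """Map a time of day onto the unitless noon→sunset axis.

    0 corresponds to astronomic noon, 1 to sunset on the given date; the
    linear map extends beyond [0, 1] for pre-noon or post-sunset surveys.
    All inputs are fractional hours.
    """
    if not sunset_time > noon_time:
        raise ValueError(f"sunset ({sunset_time}) must be after noon ({noon_time})")
    return (mid_time - noon_time) / (sunset_time - noon_time)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterbodyRecord:
    """One lentic waterbody or one ditch segment on a plot."""

    waterbody_id: str
    plot_id: str
    category: WaterbodyCategory
    area_ha: float | None = None
    perimeter_m: float | None = None
    length_m: float | None = None
    surveyed: bool = False
    sampled_length_m: float | None = None

    def __post_init__(self) -> None:
        cat = self.category
        if cat is WaterbodyCategory.DITCH:
            if self.length_m is None or not self.length_m > 0:
                raise DatasetError(
                    f"ditch {self.waterbody_id!r}: length_m must be positive, got {self.length_m}"
                )
        else:
            if self.area_ha is None or not self.area_ha > 0:
                raise DatasetError(
                    f"waterbody {self.waterbody_id!r}: area_ha must be positive for lentic records"
                )
            if classify_waterbody(self.area_ha) is not cat:
                raise DatasetError(
                    f"waterbody {self.waterbody_id!r}: area {self.area_ha} ha does not match "
                    f"declared category {cat.value!r}"
                )
            if cat in (WaterbodyCategory.MEDIUM, WaterbodyCategory.LARGE):
                if self.perimeter_m is None or not self.perimeter_m > 0:
                    raise DatasetError(
                        f"waterbody {self.waterbody_id!r}: perimeter_m required for "
                        f"{cat.value} waterbodies"
                    )
        if self.sampled_length_m is not None:
            total = self.habitat_length_m
            if total is None:
                raise DatasetError(
                    f"waterbody {self.waterbody_id!r}: sampled_length_m set on a record "
                    "without linear habitat"
                )
            if not 0 <= self.sampled_length_m <= total:
                raise DatasetError(
                    f"waterbody {self.waterbody_id!r}: sampled_length_m "
                    f"({self.sampled_length_m}) exceeds habitat length ({total})"
                )

    @property
    def habitat_length_m(self) -> float | None:
        """Linear habitat extent: perimeter for medium/large, length for ditches."""
        if self.category is WaterbodyCategory.DITCH:
            return self.length_m
        if self.category in (WaterbodyCategory.MEDIUM, WaterbodyCategory.LARGE):
            return self.perimeter_m
        return None


@dataclass(frozen=True)
class SurveyEvent:
    """One visit to a plot: identifies the year, date and time context."""

    survey_id: str
    plot_id: str
    year: int
    calendar_date: dt.date
    mid_time_hours: float
    sunset_time_hours: float
    earliest_season_date: dt.date
    noon_time_hours: float = 12.0
    air_temperature_c: float | None = None
    wind_beaufort: int | None = None
    sky: str | None = None

    def __post_init__(self) -> None:
        if self.calendar_date.year != self.year:
            raise DatasetError(
                f"survey {self.survey_id!r}: calendar_date {self.calendar_date} outside year "
                f"{self.year}"
            )
        if self.earliest_season_date.year != self.year:
            raise DatasetError(
                f"survey {self.survey_id!r}: earliest_season_date must be in year {self.year}"
            )
        if not self.sunset_time_hours > self.noon_time_hours:
            raise DatasetError(f"survey {self.survey_id!r}: sunset must be after astronomic noon")

    @property
    def relative_date(self) -> float:
        return relative_date(self.calendar_date, self.earliest_season_date)

    @property
    def relative_daytime(self) -> float:
        return relative_daytime(self.mid_time_hours, self.noon_time_hours, self.sunset_time_hours)


@dataclass(frozen=True)
class CallCount:
    """Calling males of one taxon counted at one site during one survey.

    ``count`` is a non-negative real: integer for directly counted males,
    possibly fractional when the observer recorded a chorus as the average
    between a minimum and a maximum estimate (then ``chorus_averaged`` is
    set).  Absence is recorded as an explicit zero.
    """

    survey_id: str
    waterbody_id: str
    taxon: str
    count: float
    chorus_averaged: bool = False
    calling_index: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.count) and self.count >= 0):
            raise DatasetError(
                f"count for {self.taxon!r} at {self.waterbody_id!r} must be >= 0, "
                f"got {self.count}"
            )
        if not self.chorus_averaged and self.count != int(self.count):
            raise DatasetError(
                f"non-integer count {self.count} at {self.waterbody_id!r} without "
                "chorus_averaged flag"
            )


@dataclass(frozen=True)
class VisualRecord:
    """Visual evidence of one taxon at one waterbody within one breeding season."""

    waterbody_id: str
    taxon: str
    year: int
    adults_seen: int = 0
    sex_known: bool = True
    egg_masses: int = 0
    visibility_class: VisibilityClass | None = None
    tadpoles_seen: bool = False
    metamorphs_seen: bool = False

    def __post_init__(self) -> None:
        if self.adults_seen < 0 or self.egg_masses < 0:
            raise DatasetError(f"visual record at {self.waterbody_id!r}: negative counts")
        if self.adults_seen > 0 and self.visibility_class is None:
            raise DatasetError(
                f"visual record at {self.waterbody_id!r}: visibility_class required when "
                "adults were seen"
            )

    @property
    def any_evidence(self) -> bool:
        """True if the record documents presence of the taxon in any form."""
        return (
            self.adults_seen > 0
            or self.egg_masses > 0
            or self.tadpoles_seen
            or self.metamorphs_seen
        )


@dataclass(frozen=True)
class TaxonParameters:
    """Biological parameters converting calling-male counts to adult density.

    ``ma`` — proportion of males present in a waterbody that vocalise at
    peak activity; ``mp`` — proportion of the adult male population present
    in waterbodies at the breeding peak; ``ms`` — proportion of males in
    the adult population (sex ratio).  For the water-frog complex ``ms``
    holds the small-waterbody/ditch value and ``ms_large`` the
    large-waterbody value; medium waterbodies use their midpoint.
    """

    taxon: str
    ma: float
    mp: float
    ms: float
    sd_ma: float = 0.0
    sd_mp: float = 0.0
    sd_ms: float = 0.0
    ms_large: float | None = None
    sd_ms_large: float = 0.0
    hearing_distance_m: float = 100.0
    range_area_km2: float = 60_000.0
    plot_presence_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ma", "mp", "ms"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{self.taxon}: {name} must be in (0, 1], got {v}")
        if self.ms_large is not None and not 0 < self.ms_large <= 1:
            raise ValueError(f"{self.taxon}: ms_large must be in (0, 1]")
        for name in ("sd_ma", "sd_mp", "sd_ms", "sd_ms_large"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.taxon}: {name} must be >= 0")
        if not self.hearing_distance_m > 0:
            raise ValueError(f"{self.taxon}: hearing_distance_m must be positive")
        if not 0 <= self.plot_presence_fraction <= 1:
            raise ValueError(f"{self.taxon}: plot_presence_fraction must be in [0, 1]")

    def ms_for_category(self, category: WaterbodyCategory) -> float:
        """Sex ratio applicable to a habitat stratum.

        Scalar-``ms`` taxa return ``ms`` everywhere.  When ``ms_large`` is
        set (water-frog complex), small waterbodies and ditches use ``ms``,
        large waterbodies ``ms_large``, and medium the average of the two.
        """
        if self.ms_large is None:
            return self.ms
        if category is WaterbodyCategory.LARGE:
            return self.ms_large
        if category is WaterbodyCategory.MEDIUM:
            return (self.ms + self.ms_large) / 2.0
        return self.ms


# Shipped defaults: peak-activity calling proportion (ma), presence at peak
# (mp), population sex ratio (ms) with their SDs (0 where a single published
# estimate exists), minimum hearing distances, range areas and plot-presence
# fractions used for range-wide extrapolation.  All overridable via config.
DEFAULT_TAXON_PARAMETERS: dict[str, TaxonParameters] = {
    p.taxon: p
    for p in [
        TaxonParameters(
            taxon="Bombina bombina", ma=0.61, mp=1.00, ms=0.56, sd_mp=0.0, sd_ms=0.07,
            hearing_distance_m=100.0, range_area_km2=470.0, plot_presence_fraction=1.0,
        ),
        TaxonParameters(
            taxon="Pelobates fuscus", ma=0.29, mp=0.65, ms=0.55, sd_mp=0.04, sd_ms=0.04,
            hearing_distance_m=50.0, range_area_km2=60_000.0, plot_presence_fraction=0.29,
        ),
        TaxonParameters(
            taxon="Bufo bufo", ma=0.18, mp=0.78, ms=0.66, sd_mp=0.08, sd_ms=0.09,
            hearing_distance_m=150.0, range_area_km2=60_000.0, plot_presence_fraction=0.97,
        ),
        TaxonParameters(
            taxon="Hyla arborea", ma=0.58, mp=0.72, ms=0.55, sd_ms=0.04,
            hearing_distance_m=500.0, range_area_km2=4_000.0, plot_presence_fraction=1.0,
        ),
        TaxonParameters(
            taxon="Rana arvalis", ma=0.30, mp=0.95, ms=0.48, sd_mp=0.05, sd_ms=0.06,
            hearing_distance_m=100.0, range_area_km2=60_000.0, plot_presence_fraction=0.80,
        ),
        TaxonParameters(
            # presence fraction includes plots with only visual observations
            taxon="Rana temporaria", ma=0.30, mp=0.95, ms=0.48, sd_mp=0.05, sd_ms=0.06,
            hearing_distance_m=50.0, range_area_km2=60_000.0, plot_presence_fraction=0.84,
        ),
        TaxonParameters(
            taxon="Pelophylax spp.", ma=0.63, mp=1.00, ms=0.47, sd_ms=0.14,
            ms_large=0.36, sd_ms_large=0.08,
            hearing_distance_m=500.0, range_area_km2=60_000.0, plot_presence_fraction=0.98,
        ),
    ]
}


def load_taxon_parameters(path: str | Path | None = None) -> dict[str, TaxonParameters]:
    """Load taxon parameters from a YAML/JSON config, merged over the defaults.

    The config maps taxon name → field overrides; unknown taxa are added,
    known taxa are updated field-wise.  ``None`` returns a copy of the
    defaults.
    """
    params = dict(DEFAULT_TAXON_PARAMETERS)
    if path is None:
        return params
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise DatasetError(f"taxon parameter config {path} must be a mapping")
    for taxon, overrides in raw.items():
        if taxon in params:
            params[taxon] = replace(params[taxon], **dict(overrides))
        else:
            params[taxon] = TaxonParameters(taxon=taxon, **dict(overrides))
    return params


# ---------------------------------------------------------------------------
# Dataset container and I/O
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A validated survey dataset: the four record tables plus plot areas."""

    waterbodies: dict[str, WaterbodyRecord] = field(default_factory=dict)
    surveys: dict[str, SurveyEvent] = field(default_factory=dict)
    call_counts: list[CallCount] = field(default_factory=list)
    visual_records: list[VisualRecord] = field(default_factory=list)
    plot_areas: dict[str, float] = field(default_factory=dict)

    def plot_area_km2(self, plot_id: str) -> float:
        return self.plot_areas.get(plot_id, DEFAULT_PLOT_AREA_KM2)

    @property
    def plot_ids(self) -> list[str]:
        return sorted({w.plot_id for w in self.waterbodies.values()})

    @property
    def taxa(self) -> list[str]:
        return sorted({c.taxon for c in self.call_counts} | {v.taxon for v in self.visual_records})

    def plot_waterbodies(self, plot_id: str) -> list[WaterbodyRecord]:
        return [w for w in self.waterbodies.values() if w.plot_id == plot_id]

    def plot_surveys(self, plot_id: str, year: int | None = None) -> list[SurveyEvent]:
        out = [s for s in self.surveys.values() if s.plot_id == plot_id]
        if year is not None:
            out = [s for s in out if s.year == year]
        return sorted(out, key=lambda s: (s.calendar_date, s.survey_id))

    def plot_years(self, plot_id: str) -> list[int]:
        return sorted({s.year for s in self.surveys.values() if s.plot_id == plot_id})

    def validate(self) -> None:
        """Enforce referential integrity; raise DatasetError listing offenders."""
        problems: list[str] = []
        for c in self.call_counts:
            wb = self.waterbodies.get(c.waterbody_id)
            sv = self.surveys.get(c.survey_id)
            if wb is None:
                problems.append(f"count references unknown waterbody {c.waterbody_id!r}")
                continue
            if sv is None:
                problems.append(f"count references unknown survey {c.survey_id!r}")
                continue
            if not wb.surveyed:
                problems.append(
                    f"count at unsurveyed waterbody {c.waterbody_id!r} (survey {c.survey_id!r})"
                )
            if wb.plot_id != sv.plot_id:
                problems.append(
                    f"count links waterbody {c.waterbody_id!r} (plot {wb.plot_id!r}) to survey "
                    f"{c.survey_id!r} on plot {sv.plot_id!r}"
                )
        for v in self.visual_records:
            if v.waterbody_id not in self.waterbodies:
                problems.append(f"visual record references unknown waterbody {v.waterbody_id!r}")
        if problems:
            head = problems[:20]
            more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
            raise DatasetError("dataset integrity errors: " + "; ".join(head) + more)


_WATERBODY_COLS = [
    "waterbody_id", "plot_id", "category", "area_ha", "perimeter_m", "length_m",
    "surveyed", "sampled_length_m",
]
_SURVEY_COLS = [
    "survey_id", "plot_id", "year", "calendar_date", "mid_time_hours", "sunset_time_hours",
    "earliest_season_date", "noon_time_hours", "air_temperature_c", "wind_beaufort", "sky",
]
_COUNT_COLS = ["survey_id", "waterbody_id", "taxon", "count", "chorus_averaged", "calling_index"]
_VISUAL_COLS = [
    "waterbody_id", "taxon", "year", "adults_seen", "sex_known", "egg_masses",
    "visibility_class", "tadpoles_seen", "metamorphs_seen",
]


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def _opt_int(v) -> int | None:
    return None if pd.isna(v) else int(v)


def _bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetError(f"{name}: missing required columns {missing}")


def read_dataset(directory: str | Path) -> Dataset:
    """Read and validate a dataset from a directory of CSV files.

    Required: ``waterbodies.csv``, ``surveys.csv``, ``call_counts.csv``.
    Optional: ``visual_records.csv``, ``plots.csv`` (per-plot areas,
    defaulting to 25 km²).  Files are UTF-8, comma-delimited, with a
    mandatory header row.
    """
    directory = Path(directory)
    ds = Dataset()

    wb_path = directory / "waterbodies.csv"
    sv_path = directory / "surveys.csv"
    cc_path = directory / "call_counts.csv"
    for p in (wb_path, sv_path, cc_path):
        if not p.exists():
            raise DatasetError(f"required input file missing: {p}")

    wdf = pd.read_csv(wb_path, float_precision="round_trip")
    _require_columns(wdf, ["waterbody_id", "plot_id", "category", "surveyed"], "waterbodies.csv")
    for i, row in wdf.iterrows():
        rec = WaterbodyRecord(
            waterbody_id=str(row["waterbody_id"]),
            plot_id=str(row["plot_id"]),
            category=WaterbodyCategory(row["category"]),
            area_ha=_opt_float(row.get("area_ha")),
            perimeter_m=_opt_float(row.get("perimeter_m")),
            length_m=_opt_float(row.get("length_m")),
            surveyed=_bool(row["surveyed"]),
            sampled_length_m=_opt_float(row.get("sampled_length_m")),
        )
        if rec.waterbody_id in ds.waterbodies:
            raise DatasetError(f"waterbodies.csv row {i}: duplicate id {rec.waterbody_id!r}")
        ds.waterbodies[rec.waterbody_id] = rec

    sdf = pd.read_csv(sv_path, float_precision="round_trip")
    _require_columns(
        sdf,
        ["survey_id", "plot_id", "year", "calendar_date", "mid_time_hours",
         "sunset_time_hours", "earliest_season_date"],
        "surveys.csv",
    )
    for i, row in sdf.iterrows():
        ev = SurveyEvent(
            survey_id=str(row["survey_id"]),
            plot_id=str(row["plot_id"]),
            year=int(row["year"]),
            calendar_date=dt.date.fromisoformat(str(row["calendar_date"])),
            mid_time_hours=float(row["mid_time_hours"]),
            sunset_time_hours=float(row["sunset_time_hours"]),
            earliest_season_date=dt.date.fromisoformat(str(row["earliest_season_date"])),
            noon_time_hours=float(row.get("noon_time_hours", 12.0))
            if not pd.isna(row.get("noon_time_hours", 12.0)) else 12.0,
            air_temperature_c=_opt_float(row.get("air_temperature_c")),
            wind_beaufort=_opt_int(row.get("wind_beaufort")),
            sky=None if pd.isna(row.get("sky")) else str(row.get("sky")),
        )
        if ev.survey_id in ds.surveys:
            raise DatasetError(f"surveys.csv row {i}: duplicate id {ev.survey_id!r}")
        ds.surveys[ev.survey_id] = ev

    cdf = pd.read_csv(cc_path, float_precision="round_trip")
    _require_columns(cdf, ["survey_id", "waterbody_id", "taxon", "count"], "call_counts.csv")
    for _, row in cdf.iterrows():
        ds.call_counts.append(
            CallCount(
                survey_id=str(row["survey_id"]),
                waterbody_id=str(row["waterbody_id"]),
                taxon=str(row["taxon"]),
                count=float(row["count"]),
                chorus_averaged=_bool(row.get("chorus_averaged", False)),
                calling_index=_opt_int(row.get("calling_index")),
            )
        )

    vr_path = directory / "visual_records.csv"
    if vr_path.exists():
        vdf = pd.read_csv(vr_path, float_precision="round_trip")
        _require_columns(vdf, ["waterbody_id", "taxon", "year"], "visual_records.csv")
        for _, row in vdf.iterrows():
            vc = row.get("visibility_class")
            ds.visual_records.append(
                VisualRecord(
                    waterbody_id=str(row["waterbody_id"]),
                    taxon=str(row["taxon"]),
                    year=int(row["year"]),
                    adults_seen=int(row.get("adults_seen", 0) or 0),
                    sex_known=_bool(row.get("sex_known", True)),
                    egg_masses=int(row.get("egg_masses", 0) or 0),
                    visibility_class=None if pd.isna(vc) else VisibilityClass(vc),
                    tadpoles_seen=_bool(row.get("tadpoles_seen", False)),
                    metamorphs_seen=_bool(row.get("metamorphs_seen", False)),
                )
            )

    pl_path = directory / "plots.csv"
    if pl_path.exists():
        pdf = pd.read_csv(pl_path, float_precision="round_trip")
        _require_columns(pdf, ["plot_id", "area_km2"], "plots.csv")
        ds.plot_areas = {str(r["plot_id"]): float(r["area_km2"]) for _, r in pdf.iterrows()}

    ds.validate()
    return ds


def _fmt(v) -> object:
    if v is None:
        return ""
    if isinstance(v, enum.Enum):
        return v.value
    if isinstance(v, bool):
        return v
    if isinstance(v, dt.date):
        return v.isoformat()
    return v


def write_dataset(ds: Dataset, directory: str | Path) -> None:
    """Write a dataset back to the CSV schema read by :func:`read_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(records, cols, name):
        rows = []
        for r in records:
            rows.append({f.name: _fmt(getattr(r, f.name)) for f in fields(r)})
        pd.DataFrame(rows, columns=cols).to_csv(directory / name, index=False)

    dump(ds.waterbodies.values(), _WATERBODY_COLS, "waterbodies.csv")
    dump(ds.surveys.values(), _SURVEY_COLS, "surveys.csv")
    dump(ds.call_counts, _COUNT_COLS, "call_counts.csv")
    if ds.visual_records:
        dump(ds.visual_records, _VISUAL_COLS, "visual_records.csv")
    if ds.plot_areas:
        pd.DataFrame(
            [{"plot_id": k, "area_km2": v} for k, v in sorted(ds.plot_areas.items())]
        ).to_csv(directory / "plots.csv", index=False)
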