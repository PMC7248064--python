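from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, strategies as st

from frogdensity.core_data import (
    CallCount,
    Dataset,
    DatasetError,
    DEFAULT_TAXON_PARAMETERS,
    SurveyEvent,
    TaxonParameters,
    WaterbodyCategory,
    WaterbodyRecord,
    classify_waterbody,
    read_dataset,
    relative_date,
    relative_daytime,
    write_dataset,
)
from frogdensity.synthetic_data import SimulationConfig, TaxonTruth, simulate_dataset

from conftest import make_survey, small_wb


class TestClassifyWaterbody:
    @pytest.mark.parametrize(
        "area, expected",
        [
            (0.3, WaterbodyCategory.SMALL),
            (0.5, WaterbodyCategory.MEDIUM),  # boundary assigned to medium
            (10.0, WaterbodyCategory.MEDIUM),
            (15.0, WaterbodyCategory.LARGE),
            (0.499, WaterbodyCategory.SMALL),
            (10.001, WaterbodyCategory.LARGE),
        ],
    )
    def test_thresholds(self, area, expected):
        assert classify_waterbody(area) is expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_area(self, bad):
        with pytest.raises(ValueError):
            classify_waterbody(bad)

    @given(
        st.floats(min_value=1e-6, max_value=1e4),
        st.floats(min_value=1e-6, max_value=1e4),
    )
    def test_order_preserving(self, a, b):
        order = [WaterbodyCategory.SMALL, WaterbodyCategory.MEDIUM, WaterbodyCategory.LARGE]
        if a > b:
            a, b = b, a
        assert order.index(classify_waterbody(a)) <= order.index(classify_waterbody(b))


class TestRelativeTransforms:
    def test_onset_identity(self):
        d = dt.date(2016, 4, 1)
        assert relative_date(d, d) == 0.0

    def test_ten_days(self):
        assert relative_date(dt.date(2016, 4, 11), dt.date(2016, 4, 1)) == 10.0

    def test_fifty_day_activity_range(self):
        # onset 7 April, survey 27 May spans a 50-day activity range
        assert relative_date(dt.date(2016, 5, 27), dt.date(2016, 4, 7)) == 50.0

    def test_pre_onset_negative(self):
        assert relative_date(dt.date(2016, 3, 30), dt.date(2016, 4, 1)) == -2.0

    def test_cross_year_error(self):
        with pytest.raises(ValueError):
            relative_date(dt.date(2017, 4, 1), dt.date(2016, 4, 1))

    @given(
        st.integers(min_value=60, max_value=300),
        st.integers(min_value=60, max_value=300),
        st.integers(min_value=-30, max_value=30),
    )
    def test_affine_shift(self, doy_a, doy_b, k):
        base = dt.date(2016, 1, 1)
        a = base + dt.timedelta(days=doy_a)
        b = base + dt.timedelta(days=doy_b)
        shift = dt.timedelta(days=k)
        assert relative_date(a + shift, b + shift) == relative_date(a, b)

    def test_daytime_noon_and_sunset(self):
        assert relative_daytime(13.0, 13.0, 21.0) == 0.0
        assert relative_daytime(21.0, 13.0, 21.0) == 1.0

    def test_daytime_midpoint(self):
        assert relative_daytime(17.0, 13.0, 21.0) == pytest.approx(0.5)

    def test_daytime_outside_unit_interval(self):
        assert relative_daytime(22.0, 13.0, 21.0) > 1.0
        assert relative_daytime(11.0, 13.0, 21.0) < 0.0

    def test_sunset_before_noon_error(self):
        with pytest.raises(ValueError):
            relative_daytime(15.0, 13.0, 12.0)


class TestRecordValidation:
    def test_lentic_requires_area(self):
        with pytest.raises(DatasetError):
            WaterbodyRecord("w", "p", WaterbodyCategory.SMALL, area_ha=None)

    def test_medium_requires_perimeter(self):
        with pytest.raises(DatasetError):
            WaterbodyRecord("w", "p", WaterbodyCategory.MEDIUM, area_ha=2.0)

    def test_category_must_match_area(self):
        with pytest.raises(DatasetError):
            WaterbodyRecord("w", "p", WaterbodyCategory.SMALL, area_ha=5.0)

    def test_sampled_length_capped(self):
        with pytest.raises(DatasetError):
            WaterbodyRecord(
                "w", "p", WaterbodyCategory.DITCH, length_m=100.0, sampled_length_m=200.0
            )

    def test_non_integer_count_requires_flag(self):
        with pytest.raises(DatasetError):
            CallCount("s", "w", "t", count=2.5)
        c = CallCount("s", "w", "t", count=2.5, chorus_averaged=True)
        assert c.count == 2.5

    def test_negative_count_rejected(self):
        with pytest.raises(DatasetError):
            CallCount("s", "w", "t", count=-1)

    def test_taxon_parameters_ranges(self):
        with pytest.raises(ValueError):
            TaxonParameters(taxon="t", ma=0.0, mp=0.5, ms=0.5)
        with pytest.raises(ValueError):
            TaxonParameters(taxon="t", ma=0.5, mp=1.5, ms=0.5)

    def test_ms_for_category_mapping(self):
        p = TaxonParameters(taxon="wf", ma=0.63, mp=1.0, ms=0.47, ms_large=0.36)
        assert p.ms_for_category(WaterbodyCategory.SMALL) == 0.47
        assert p.ms_for_category(WaterbodyCategory.DITCH) == 0.47
        assert p.ms_for_category(WaterbodyCategory.LARGE) == 0.36
        assert p.ms_for_category(WaterbodyCategory.MEDIUM) == pytest.approx(0.415)


class TestDatasetIntegrity:
    def test_orphan_waterbody_rejected(self):
        ds = Dataset()
        ds.waterbodies["w1"] = small_wb("w1", "p")
        ds.surveys["s1"] = make_survey("s1", "p", 2016, 4, 10)
        ds.call_counts.append(CallCount("s1", "GHOST", "t", 1))
        with pytest.raises(DatasetError, match="GHOST"):
            ds.validate()

    def test_count_at_unsurveyed_site_rejected(self):
        ds = Dataset()
        ds.waterbodies["w1"] = small_wb("w1", "p", surveyed=False)
        ds.surveys["s1"] = make_survey("s1", "p", 2016, 4, 10)
        ds.call_counts.append(CallCount("s1", "w1", "t", 1))
        with pytest.raises(DatasetError, match="unsurveyed"):
            ds.validate()

    def test_orphan_survey_rejected(self):
        ds = Dataset()
        ds.waterbodies["w1"] = small_wb("w1", "p")
        ds.call_counts.append(CallCount("NOPE", "w1", "t", 1))
        with pytest.raises(DatasetError, match="NOPE"):
            ds.validate()


class TestRoundTrip:
    def test_synthetic_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            n_plots=2,
            seed=7,
            visual_coverage=0.8,
            taxa={"T": TaxonTruth(density=15, ma=0.5, mp=0.9, ms=0.5)},
        )
        ds, _ = simulate_dataset(cfg)
        write_dataset(ds, tmp_path)
        back = read_dataset(tmp_path)
        assert set(back.waterbodies) == set(ds.waterbodies)
        for k, wb in ds.waterbodies.items():
            assert back.waterbodies[k] == wb
        assert set(back.surveys) == set(ds.surveys)
        for k, sv in ds.surveys.items():
            assert back.surveys[k] == sv
        assert back.call_counts == ds.call_counts
        assert back.visual_records == ds.visual_records
        assert back.plot_areas == ds.plot_areas

    def test_missing_file_error(self, tmp_path):
        with pytest.raises(DatasetError, match="waterbodies.csv"):
            read_dataset(tmp_path)


class TestDefaults:
    def test_all_seven_taxa_present(self):
        assert len(DEFAULT_TAXON_PARAMETERS) == 7

    def test_hearing_distances(self):
        hd = {t: p.hearing_distance_m for t, p in DEFAULT_TAXON_PARAMETERS.items()}
        assert hd["Pelophylax spp."] == 500.0
        assert hd["Hyla arborea"] == 500.0
        assert hd["Bufo bufo"] == 150.0
        assert hd["Rana arvalis"] == 100.0
        assert hd["Bombina bombina"] == 100.0
        assert hd["Rana temporaria"] == 50.0
        assert hd["Pelobates fuscus"] == 50.0

    def test_water_frog_sex_ratio_pair(self):
        p = DEFAULT_TAXON_PARAMETERS["Pelophylax spp."]
        assert p.ms == 0.47 and p.ms_large == 0.36
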