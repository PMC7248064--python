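from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from frogdensity.core_data import (
    CallCount,
    Dataset,
    DatasetError,
    TaxonParameters,
    WaterbodyCategory,
    WaterbodyRecord,
)
from frogdensity.density import (
    CategoryTally,
    adjust_operational_sex_ratio,
    category_contributions,
    compute_dc,
    compute_mafd,
    estimate_density,
    sampled_length,
    tally_categories,
)
from frogdensity.synthetic_data import SimulationConfig, TaxonTruth, simulate_dataset, truth_parameters

from conftest import TAXON
from oracles import naive_dc, naive_mafd

CAT = WaterbodyCategory


def tallies_from(spec: dict[CAT, tuple[float, float, float]]) -> dict[CAT, CategoryTally]:
    out = {}
    for cat in CAT:
        c, pt, ps = spec.get(cat, (0.0, 0.0, 0.0))
        out[cat] = CategoryTally(category=cat, c=c, pt=pt, ps=ps)
    return out


class TestSampledLength:
    def test_ditch_default_rule(self):
        wb = WaterbodyRecord("d", "p", CAT.DITCH, length_m=5000.0, surveyed=True)
        assert sampled_length(wb, hearing_distance_m=150.0) == 300.0

    def test_fully_covered_capped_at_total(self):
        wb = WaterbodyRecord(
            "m", "p", CAT.MEDIUM, area_ha=1.0, perimeter_m=400.0, surveyed=True
        )
        assert sampled_length(wb, hearing_distance_m=500.0) == 400.0

    def test_explicit_override(self):
        wb = WaterbodyRecord(
            "m", "p", CAT.MEDIUM, area_ha=1.0, perimeter_m=400.0,
            surveyed=True, sampled_length_m=250.0,
        )
        assert sampled_length(wb, hearing_distance_m=500.0) == 250.0

    def test_small_waterbody_rejected(self):
        wb = WaterbodyRecord("s", "p", CAT.SMALL, area_ha=0.1)
        with pytest.raises(ValueError):
            sampled_length(wb, 100.0)


class TestTallyCategories:
    def test_hand_tally(self, density_dataset, toy_params):
        t = tally_categories(density_dataset, "D", TAXON, 2016, toy_params)
        assert (t[CAT.SMALL].c, t[CAT.SMALL].pt, t[CAT.SMALL].ps) == (12, 60, 20)
        assert (t[CAT.MEDIUM].c, t[CAT.MEDIUM].pt, t[CAT.MEDIUM].ps) == (5, 4000, 1000)
        assert (t[CAT.LARGE].c, t[CAT.LARGE].pt, t[CAT.LARGE].ps) == (0, 0, 0)
        assert (t[CAT.DITCH].c, t[CAT.DITCH].pt, t[CAT.DITCH].ps) == (3, 12000, 3000)

    def test_counts_without_surveyed_habitat_rejected(self):
        with pytest.raises(DatasetError):
            CategoryTally(category=CAT.SMALL, c=3, pt=10, ps=0)

    def test_pt_never_below_ps(self):
        with pytest.raises(ValueError):
            CategoryTally(category=CAT.SMALL, c=0, pt=5, ps=6)


class TestComputeDc:
    def test_fully_surveyed_identity(self):
        t = tallies_from({CAT.SMALL: (50, 20, 20)})
        assert compute_dc(t, 25.0) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        t = tallies_from({
            CAT.SMALL: (12, 60, 20),
            CAT.MEDIUM: (5, 4000, 1000),
            CAT.DITCH: (3, 12000, 3000),
        })
        assert compute_dc(t, 25.0) == pytest.approx(2.72)

    def test_zero_counts(self):
        t = tallies_from({CAT.SMALL: (0, 60, 20)})
        assert compute_dc(t, 25.0) == 0.0

    def test_unsampled_stratum_warns_and_contributes_zero(self):
        t = tallies_from({CAT.SMALL: (10, 20, 20), CAT.MEDIUM: (0, 500, 0)})
        with pytest.warns(UserWarning, match="medium"):
            assert compute_dc(t, 25.0) == pytest.approx(10 / 25)

    def test_dataset_level_matches_hand_value(self, density_dataset, toy_params):
        est = estimate_density(density_dataset, "D", TAXON, toy_params)
        assert est.dc == pytest.approx(2.72)


class TestComputeMafd:
    def test_worked_example_scalar(self):
        params = TaxonParameters(taxon="bb", ma=0.61, mp=1.00, ms=0.56)
        assert compute_mafd(4.1, params) == pytest.approx(12.0, abs=0.05)

    def test_identity_when_all_proportions_one(self):
        params = TaxonParameters(taxon="x", ma=1.0, mp=1.0, ms=1.0)
        assert compute_mafd(3.3, params) == pytest.approx(3.3)

    def test_water_frog_stratum_split(self):
        # per-stratum calling-male densities {small 2.0, medium 1.0,
        # large 0.5, ditch 0.5} on a 25 km² plot
        t = tallies_from({
            CAT.SMALL: (50, 10, 10),
            CAT.MEDIUM: (25, 10, 10),
            CAT.LARGE: (12.5, 10, 10),
            CAT.DITCH: (12.5, 10, 10),
        })
        params = TaxonParameters(taxon="wf", ma=0.63, mp=1.00, ms=0.47, ms_large=0.36)
        assert compute_mafd(t, params, 25.0) == pytest.approx(14.47, abs=0.005)

    def test_water_frog_requires_tallies(self):
        params = TaxonParameters(taxon="wf", ma=0.63, mp=1.00, ms=0.47, ms_large=0.36)
        with pytest.raises(ValueError):
            compute_mafd(2.0, params)

    def test_mafd_never_below_dc(self, density_dataset, toy_params):
        est = estimate_density(density_dataset, "D", TAXON, toy_params)
        assert est.mafd >= est.dc


class TestCategoryContributions:
    def test_scalar_shares(self, density_dataset, toy_params):
        est = estimate_density(density_dataset, "D", TAXON, toy_params)
        contrib = category_contributions(est)
        assert contrib[CAT.SMALL] == pytest.approx(36 / 68)
        assert sum(contrib.values()) == pytest.approx(1.0)

    def test_single_occupied_category(self):
        t = tallies_from({CAT.SMALL: (10, 20, 20)})
        params = TaxonParameters(taxon="x", ma=0.5, mp=0.5, ms=0.5)
        from frogdensity.density import DensityEstimate, _category_mafd

        cm = _category_mafd(t, params, 25.0)
        e = DensityEstimate("p", "x", 2016, compute_dc(t, 25.0), sum(cm.values()), 25.0,
                            category_mafd=cm)
        assert category_contributions(e)[CAT.SMALL] == pytest.approx(1.0)

    def test_water_frog_small_plus_ditch_share(self):
        t = tallies_from({
            CAT.SMALL: (50, 10, 10),
            CAT.MEDIUM: (25, 10, 10),
            CAT.LARGE: (12.5, 10, 10),
            CAT.DITCH: (12.5, 10, 10),
        })
        params = TaxonParameters(taxon="wf", ma=0.63, mp=1.00, ms=0.47, ms_large=0.36)
        from frogdensity.density import DensityEstimate, _category_mafd

        cm = _category_mafd(t, params, 25.0)
        e = DensityEstimate("p", "wf", 2016, compute_dc(t, 25.0), sum(cm.values()), 25.0,
                            category_mafd=cm)
        contrib = category_contributions(e)
        assert contrib[CAT.SMALL] + contrib[CAT.DITCH] == pytest.approx(0.583, abs=0.001)

    def test_zero_mafd_undefined(self):
        from frogdensity.density import DensityEstimate

        e = DensityEstimate("p", "x", 2016, 0.0, 0.0, 25.0)
        assert category_contributions(e) is None


class TestOperationalSexRatio:
    @pytest.mark.parametrize(
        "operational, expected",
        [(0.565, 0.48), (1.0, 0.85), (0.647, 0.55)],
    )
    def test_reduction(self, operational, expected):
        assert adjust_operational_sex_ratio(operational) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.2])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            adjust_operational_sex_ratio(bad)


@st.composite
def tally_sets(draw):
    spec = {}
    for cat in CAT:
        pt = draw(st.one_of(st.just(0.0), st.floats(min_value=1e-2, max_value=1e4)))
        frac = draw(st.one_of(st.just(0.0), st.floats(min_value=1e-3, max_value=1.0)))
        ps = frac * pt
        c = 0.0 if ps == 0 else draw(st.floats(min_value=0, max_value=500))
        spec[cat] = (c, pt, ps)
    return tallies_from(spec)


class TestAlgebraicProperties:
    @given(tally_sets(), st.floats(min_value=1.5, max_value=10))
    @settings(max_examples=100)
    def test_homogeneity_in_counts(self, tallies, factor):
        scaled = {
            cat: CategoryTally(category=cat, c=t.c * factor, pt=t.pt, ps=t.ps)
            for cat, t in tallies.items()
        }
        params = TaxonParameters(taxon="x", ma=0.5, mp=0.8, ms=0.6)
        assert compute_dc(scaled, 25.0) == pytest.approx(factor * compute_dc(tallies, 25.0))
        assert compute_mafd(scaled, params, 25.0) == pytest.approx(
            factor * compute_mafd(tallies, params, 25.0)
        )

    @given(tally_sets())
    @settings(max_examples=100)
    def test_mafd_at_least_dc(self, tallies):
        params = TaxonParameters(taxon="x", ma=0.9, mp=0.7, ms=0.5, ms_large=0.4)
        assert compute_mafd(tallies, params, 25.0) >= compute_dc(tallies, 25.0) - 1e-12

    def test_monotone_in_single_count(self, density_dataset, toy_params):
        base = estimate_density(density_dataset, "D", TAXON, toy_params)
        density_dataset.call_counts.append(
            CallCount(survey_id="d1", waterbody_id="S02", taxon=TAXON, count=5)
        )
        bumped = estimate_density(density_dataset, "D", TAXON, toy_params)
        assert bumped.dc > base.dc and bumped.mafd > base.mafd

    def test_extrapolation_identity_when_fully_surveyed(self):
        t = tallies_from({CAT.SMALL: (17, 30, 30), CAT.MEDIUM: (4, 800, 800)})
        assert compute_dc(t, 25.0) * 25.0 == pytest.approx(21.0)


class TestOracleEquivalence:
    def test_random_plots_match_naive_loop(self):
        cfg = SimulationConfig(
            n_plots=40,
            seed=11,
            mean_medium=3.0,
            mean_large=1.0,
            survey_rel_days=[10.0, 14.0],
            taxa={
                "scalar": TaxonTruth(density=25, ma=0.5, mp=0.9, ms=0.5,
                                     hearing_distance_m=120),
                "waterfrog": TaxonTruth(density=25, ma=0.63, mp=1.0, ms=0.47,
                                        ms_large=0.36, hearing_distance_m=500),
            },
        )
        ds, _ = simulate_dataset(cfg)
        params = truth_parameters(cfg)
        for plot in ds.plot_ids:
            for taxon in cfg.taxa:
                est = estimate_density(ds, plot, taxon, params[taxon])
                ref_dc = naive_dc(ds, plot, taxon, est.year, params[taxon])
                ref_mafd = naive_mafd(ds, plot, taxon, est.year, params[taxon])
                assert est.dc == pytest.approx(ref_dc, rel=1e-12, abs=1e-12)
                assert est.mafd == pytest.approx(ref_mafd, rel=1e-12, abs=1e-12)
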