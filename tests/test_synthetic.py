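"""Scenario generators: seasonality, declines, Tweedie noise, closures."""

import numpy as np
import pandas as pd
import pytest

from fishstab.dataio import to_panel
from fishstab.partition import cpe, sae, temporal_stats
from fishstab.synthetic import (EffortModel, ScenarioConfig, SpeciesParams,
                                SurveyDesign, decade_decline_factor,
                                gen_community, gen_harvest, gen_trawl_survey,
                                preset, rtweedie, simulate,
                                survey_biomass_indices)

_M = 2 * np.pi / 12


def two_species_config(delta=np.pi, amplitude=0.5, years=5, seed=0,
                       design=SurveyDesign(hauls_per_stratum=3), **kw):
    sp = {
        "a": SpeciesParams(baseline=1e5, amplitude=amplitude, phase=0.0,
                           catchability=0.1, price=1.0),
        "b": SpeciesParams(baseline=1e5, amplitude=amplitude, phase=delta,
                           catchability=0.1, price=1.0),
    }
    return ScenarioConfig(name="toy", region="XX", species=sp, years=years,
                          design=design, seed=seed, **kw)


class TestGenCommunity:
    def test_zero_amplitude_flat_within_year(self):
        cfg = two_species_config(amplitude=0.0)
        b = gen_community(cfg)
        for (_, sp), grp in b.groupby(["year", "species"]):
            assert grp["value"].nunique() == 1

    def test_opposite_phases_cancel_in_the_sum(self):
        cfg = two_species_config(delta=np.pi)
        b = gen_community(cfg)
        totals = b.groupby(["year", "month"])["value"].sum()
        assert totals.std() / totals.mean() < 1e-12

    def test_decline_targets_within_two_percent(self):
        for target in (0.92, 0.77, 0.51):
            g = decade_decline_factor(target)
            t = g ** np.arange(17)
            realized = 1 - t[9:].mean() / t[:9].mean()
            assert realized == pytest.approx(target, rel=0.02)

    def test_preset_declines_realized(self):
        cfg = preset("va_decline")
        b = gen_community(cfg)
        ann = b.groupby(["species", "year"])["value"].mean().unstack()
        for spec, target in (("Atlantic croaker", 0.92), ("spot", 0.77),
                             ("striped bass", 0.51)):
            early = ann.loc[spec, 2002:2010].mean()
            late = ann.loc[spec, 2011:2018].mean()
            assert 1 - late / early == pytest.approx(target, rel=0.02)

    def test_deterministic_given_config(self):
        cfg = two_species_config(seed=4)
        pd.testing.assert_frame_equal(gen_community(cfg), gen_community(cfg))


class TestTweedie:
    def test_moments(self):
        rng = np.random.default_rng(123)
        mu, p, phi = 5.0, 1.5, 2.0
        draws = rtweedie(rng, np.full(100_000, mu), p, phi)
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.var() == pytest.approx(phi * mu ** p, rel=0.02)

    def test_zero_mean_gives_zero(self):
        rng = np.random.default_rng(1)
        assert np.all(rtweedie(rng, np.zeros(100), 1.5, 2.0) == 0.0)

    def test_small_dispersion_concentrates(self):
        rng = np.random.default_rng(2)
        draws = rtweedie(rng, np.full(1000, 10.0), 1.5, 1e-4)
        assert draws.std() / draws.mean() < 0.05

    def test_exact_zeros_occur(self):
        rng = np.random.default_rng(3)
        draws = rtweedie(rng, np.full(1000, 0.5), 1.5, 2.0)
        assert (draws == 0).any() and (draws > 0).any()


class TestTrawlSurvey:
    def test_fixed_seed_bit_identical(self):
        cfg = two_species_config(seed=9)
        pd.testing.assert_frame_equal(gen_trawl_survey(cfg, seed=9),
                                      gen_trawl_survey(cfg, seed=9))

    def test_index_tracks_truth(self):
        cfg = two_species_config(
            amplitude=0.4, years=3,
            design=SurveyDesign(hauls_per_stratum=5, swept_km2=0.5))
        b = gen_community(cfg)
        idx = survey_biomass_indices(cfg, gen_trawl_survey(cfg, b))
        merged = idx.merge(b, on=["region", "year", "month", "species"],
                           suffixes=("_est", "_true"))
        r = np.corrcoef(merged["value_est"], merged["value_true"])[0, 1]
        assert r > 0.9

    def test_haul_count(self):
        cfg = two_species_config(years=2)
        hauls = gen_trawl_survey(cfg)
        # 2 species x 2 years x 5 survey months x 3 strata x 3 hauls
        assert len(hauls) == 2 * 2 * 5 * 3 * 3


class TestGenHarvest:
    def test_closure_mask_zero_harvest_and_trips(self):
        cfg = preset("md_closure", seed=1)
        fishery = gen_harvest(cfg)
        bass = fishery[(fishery["species"] == "striped bass")
                       & fishery["month"].isin([3, 4, 5])]
        assert (bass["value"] == 0).all()

    def test_single_open_species_gets_all_effort(self):
        cfg = two_species_config(
            closures={"b": frozenset(range(1, 13))})
        fishery = gen_harvest(cfg)
        b_rows = fishery[(fishery["species"] == "b")
                         & (fishery["quantity_kind"] == "harvest_kg")]
        a_rows = fishery[(fishery["species"] == "a")
                         & (fishery["quantity_kind"] == "harvest_kg")]
        assert (b_rows["value"] == 0).all()
        assert (a_rows["value"] > 0).all()

    def test_zero_elasticity_equal_shares(self):
        cfg = two_species_config(
            amplitude=0.0, effort=EffortModel(elasticity=0.0,
                                              harvest_noise_cv=0.0,
                                              trip_noise_cv=0.0))
        fishery = gen_harvest(cfg)
        h = fishery[fishery["quantity_kind"] == "harvest_kg"]
        by_sp = h.groupby("species")["value"].sum()
        assert by_sp["a"] == pytest.approx(by_sp["b"], rel=1e-9)

    def test_all_closed_month_is_valid_zero(self):
        cfg = two_species_config(closures={"a": frozenset({1}),
                                           "b": frozenset({1})})
        fishery = gen_harvest(cfg)
        jan = fishery[(fishery["month"] == 1)
                      & (fishery["quantity_kind"] == "harvest_kg")]
        assert (jan["value"] == 0).all()


class TestStructuralInvariants:
    def test_cpe_increases_with_phase_offset(self):
        # species compensation strengthens monotonically with phase offset
        deltas = [0.0, np.pi / 4, np.pi / 2, np.pi]
        means = []
        for d in deltas:
            vals = []
            for s in range(200):
                cfg = two_species_config(delta=d, years=2, seed=s)
                idx = survey_biomass_indices(
                    cfg, gen_trawl_survey(cfg, seed=s))
                for year in (2002, 2003):
                    p = to_panel(idx, "XX", year, "biomass_kg",
                                 (3, 5, 7, 9, 11))
                    vals.append(cpe(temporal_stats(p)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2] < means[3]

    def test_variance_skew_drives_sae(self):
        # dominant-variance species pulls SAE toward 1; even independent
        # species push it toward sqrt(n)
        rng = np.random.default_rng(0)
        n, T = 4, 60
        even = rng.normal(100.0, 5.0, size=(n, T))
        skewed = even.copy()
        skewed[0] = rng.normal(100.0, 200.0, size=T)
        assert sae(temporal_stats(np.abs(skewed))) < 1.3
        assert sae(temporal_stats(even)) > 1.9

    def test_pure_function_of_config_and_seed(self):
        cfg = preset("va_compensation", seed=5)
        a, b = simulate(cfg, 5), simulate(cfg, 5)
        pd.testing.assert_frame_equal(a.records, b.records)
        c = simulate(cfg, 6)
        assert not c.records["value"].equals(a.records["value"])
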