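"""Synthetic generators: determinism, construction contracts, ground truth."""

import numpy as np
import pandas as pd
import pytest

from fluxefp.lightresponse import fit_window
from fluxefp.qc import filter_daytime_measured, par_from_rg
from fluxefp.stats import distance_correlation
from fluxefp.synthetic import (
    SiteSimConfig,
    simulate_fapar_pixels,
    simulate_radiation,
    simulate_site_fluxes,
    simulate_trait_sites,
)
from fluxefp.traits import community_traits


class TestRadiation:
    def test_seeded_determinism(self):
        cfg = SiteSimConfig(seed=42)
        a = simulate_radiation(cfg)
        b = simulate_radiation(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_nonnegative_and_zero_at_night(self):
        rad = simulate_radiation(SiteSimConfig(seed=1))
        assert (rad["rg"] >= 0).all()
        hours = pd.to_datetime(rad["timestamp"]).dt.hour
        assert (rad.loc[(hours < 3) | (hours > 21), "rg"] == 0).all()

    def test_midsummer_noon_reaches_configured_maximum(self, noiseless_config):
        rad = simulate_radiation(noiseless_config)
        assert rad["rg"].max() == pytest.approx(noiseless_config.rg_max_summer, rel=1e-4)

    def test_daylight_fraction_matches_geometry(self, noiseless_config):
        # mean daylength is 12 h → half of all half-hours are daylit
        rad = simulate_radiation(noiseless_config)
        frac = float((rad["rg"] > 10.0).mean())
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_invalid_rg_max_rejected(self):
        with pytest.raises(ValueError):
            simulate_radiation(SiteSimConfig(rg_max_summer=0.0))


class TestSiteFluxes:
    def test_bit_identical_regeneration(self):
        cfg = SiteSimConfig(seed=9, noise_scale=0.1, gap_fraction=0.2)
        fa, ta = simulate_site_fluxes(cfg)
        fb, tb = simulate_site_fluxes(cfg)
        pd.testing.assert_frame_equal(fa, fb)
        np.testing.assert_array_equal(ta.amax_daily, tb.amax_daily)
        assert ta.gppsat_by_year == tb.gppsat_by_year

    def test_noiseless_window_fit_recovers_truth(self, noiseless_site):
        flux, truth = noiseless_site
        sub = filter_daytime_measured(flux)
        sub = sub.assign(par=par_from_rg(sub["rg"].to_numpy()))
        peak = truth.dates[int(np.argmax(truth.amax_daily))]
        p = fit_window(sub, peak, "PAR")
        i = truth.dates.get_loc(pd.Timestamp(peak))
        assert p.converged
        assert p.alpha == pytest.approx(truth.alpha_daily[i], rel=1e-3)
        assert p.amax == pytest.approx(truth.amax_daily[i], rel=1e-3)
        assert p.theta == pytest.approx(truth.theta, abs=1e-3)

    def test_gap_fraction_realized(self):
        cfg = SiteSimConfig(seed=3, gap_fraction=0.2)
        flux, _ = simulate_site_fluxes(cfg)
        assert (~flux["measured"]).mean() == pytest.approx(0.2, abs=0.01)

    def test_zero_gpp_at_night_without_noise(self, noiseless_site):
        flux, _ = noiseless_site
        assert (flux.loc[flux["rg"] == 0, "gpp"] == 0).all()

    def test_constant_years_without_year_effect(self):
        cfg = SiteSimConfig(seed=5, n_years=3, year_effect_sd=0.0)
        _, truth = simulate_site_fluxes(cfg)
        vals = list(truth.gppsat_by_year.values())
        assert vals == pytest.approx([vals[0]] * 3)

    def test_year_effect_varies_years(self):
        cfg = SiteSimConfig(seed=5, n_years=3, year_effect_sd=0.15)
        _, truth = simulate_site_fluxes(cfg)
        assert len(set(truth.gppsat_by_year.values())) == 3


class TestFaparPixels:
    def test_noiseless_neighbors_are_copies(self):
        cfg = SiteSimConfig(seed=2, n_years=2)
        tab, _ = simulate_fapar_pixels(cfg, n_neighbors=2, neighbor_noise=0.0,
                                       central_gap_fraction=0.0)
        central = tab[tab.pixel_id == "central"]["fapar"].to_numpy()
        for pid in ("nb00", "nb01"):
            np.testing.assert_array_equal(
                tab[tab.pixel_id == pid]["fapar"].to_numpy(), central
            )

    def test_independent_neighbor_weakly_associated(self):
        cfg = SiteSimConfig(seed=8, n_years=9)  # ~200 16-day steps
        tab, _ = simulate_fapar_pixels(cfg, n_neighbors=0, n_independent=1,
                                       central_gap_fraction=0.0)
        central = tab[tab.pixel_id == "central"]["fapar"].to_numpy()
        ind = tab[tab.pixel_id == "ind00"]["fapar"].to_numpy()
        assert distance_correlation(central, ind) < 0.5

    def test_values_in_unit_interval_and_lai_nonnegative(self):
        tab, lai = simulate_fapar_pixels(SiteSimConfig(seed=4), n_neighbors=3)
        vals = tab["fapar"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()
        assert (lai >= 0).all()

    def test_negative_neighbor_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_fapar_pixels(SiteSimConfig(), neighbor_noise=-0.1)


class TestTraitSites:
    def test_noiseless_linear_relation(self):
        # intercept 15.67, slope 7.25, N% = 2 → 30.17
        _, sites = simulate_trait_sites(
            n_sites=3, noise_sd=0.0, seed=0, npct_values=[2.0, 1.0, 3.0]
        )
        assert sites["gppsat_true"].iloc[0] == pytest.approx(30.17)

    def test_noiseless_regression_recovers_relation_exactly(self):
        from fluxefp.linking import ols

        species, sites = simulate_trait_sites(n_sites=12, noise_sd=0.0, seed=1)
        comm = community_traits(species)
        comm = comm[comm["source"] == "in_situ"].set_index("site")
        merged = sites.set_index("site").join(comm)
        res = ols(merged["gppsat_true"], merged[["n_pct"]])
        assert res.terms["intercept"][0] == pytest.approx(15.67, abs=1e-9)
        assert res.terms["n_pct"][0] == pytest.approx(7.25, abs=1e-9)
        assert res.r2 == pytest.approx(1.0)

    def test_abundances_sum_to_one(self):
        species, _ = simulate_trait_sites(n_sites=10, seed=6)
        insitu = species[species["source"] == "in_situ"]
        sums = insitu.groupby("site")["abundance"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_cwm_npct_pinned_to_target(self):
        species, sites = simulate_trait_sites(n_sites=6, noise_sd=0.0, seed=2)
        comm = community_traits(species)
        comm = comm[comm["source"] == "in_situ"].set_index("site")["n_pct"]
        for _, row in sites.iterrows():
            assert comm[row["site"]] == pytest.approx(row["npct_true"], abs=1e-9)

    def test_slope_recovery_within_sampling_error(self):
        """At moderate noise the linking regression is unbiased for the slope."""
        from fluxefp.linking import ols

        hits = 0
        for seed in range(60):
            species, sites = simulate_trait_sites(n_sites=20, noise_sd=4.5, seed=seed)
            comm = community_traits(species)
            comm = comm[comm["source"] == "in_situ"].set_index("site")
            merged = sites.set_index("site").join(comm)
            res = ols(merged["gppsat_true"], merged[["n_pct"]])
            slope, se = res.terms["n_pct"]
            if abs(slope - 7.25) <= 2.0 * se:
                hits += 1
        assert hits >= 51  # ~95% nominal coverage of ±2 SE

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            simulate_trait_sites(n_sites=2)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_trait_sites(noise_sd=-1.0)
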