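"""Generator tests: injected structure is present and seed-reproducible."""
import numpy as np
import pytest

from greenozone import (SyntheticConfig, generate_landcover,
                        generate_meteorology,
                        generate_population_and_incidence,
                        generate_scenario_pair, hot_day_count, urban_mask)
from greenozone.grid import block_sum

from _oracles import ar1_daily_anomalies


def _fine_mask(cfg):
    f = cfg.refine_factor
    return np.kron(urban_mask(cfg), np.ones((f, f), dtype=bool))


class TestLandcover:
    @pytest.mark.parametrize("frac,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_green_fraction_extremes(self, small_cfg, frac, expected):
        cfg = small_cfg.replace(urban_green_fraction=frac)
        lc = generate_landcover(cfg)
        mask = _fine_mask(cfg)
        assert (lc.fine_classes[mask] > 0).mean() == expected

    def test_green_fraction_target(self):
        # 100×100 urban fine cells: 10 km domain, 100 m cells, 3 km radius
        for seed in (1, 2, 3):
            cfg = SyntheticConfig(seed=seed, domain_size_km=10.0,
                                  fine_res_m=100.0, coarse_res_km=1.0,
                                  n_days=5, spinup_days=1, urban_radius_km=3.0,
                                  urban_green_fraction=0.25)
            lc = generate_landcover(cfg)
            mask = _fine_mask(cfg)
            got = (lc.fine_classes[mask] > 0).mean()
            assert abs(got - 0.25) <= 0.05

    def test_vegetation_clustered_not_salt_and_pepper(self, small_cfg):
        # clustered patches: vegetated cells neighbour vegetated cells far
        # more often than the areal fraction would give under independence
        lc = generate_landcover(small_cfg)
        veg = lc.fine_classes > 0
        mask = _fine_mask(small_cfg)
        both = veg[:, :-1] & veg[:, 1:]
        pair_mask = mask[:, :-1] & mask[:, 1:]
        p_pair = both[pair_mask].mean()
        p_marginal = veg[mask].mean()
        assert p_pair > 1.5 * p_marginal ** 2

    def test_coarse_chi_bounds(self, small_cfg):
        lc = generate_landcover(small_cfg)
        assert lc.coarse_chi.min() >= 0
        assert lc.coarse_chi.sum(axis=0).max() <= 1.0 + 1e-9
        assert np.all(lc.coarse_chi[:, lc.urban_mask] == 0)


class TestMeteorology:
    def test_zero_amplitude_gives_constant_field(self, small_cfg):
        cfg = small_cfg.replace(t_diurnal_amp_c=0.0, t_day_sd_c=0.0,
                                uhi_amp_c=0.0)
        met = generate_meteorology(cfg)
        assert np.ptp(met.t2m_c) == 0.0
        assert met.t2m_c.flat[0] == cfg.t_mean_c

    def test_par_zero_at_night(self, small_cfg):
        met = generate_meteorology(small_cfg)
        hours = np.arange(met.par.shape[0]) % 24
        night = (hours <= 6) | (hours >= 18)
        assert np.all(met.par[night] == 0.0)
        assert np.all(met.par >= 0.0)
        assert met.par[hours == 12].min() > 0.0

    def test_hot_day_count_matches_recipe_oracle(self):
        cfg = SyntheticConfig(seed=7, domain_size_km=10.0, fine_res_m=100.0,
                              n_days=88, spinup_days=4, urban_radius_km=3.0)
        met = generate_meteorology(cfg)
        # independently re-simulate the documented AR(1) recipe on the
        # meteorology stream (second spawned child of the seed)
        stream = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(4)[1])
        a = ar1_daily_anomalies(stream, cfg.n_days_total, cfg.t_day_sd_c,
                                cfg.t_day_rho)
        d = cfg.coarse_grid.distance_from(*cfg.center)
        uhi_mean = (cfg.uhi_amp_c * np.exp(
            -d ** 2 / (2 * (cfg.urban_radius_km / 2) ** 2))).mean()
        expected = int(np.sum(cfg.t_mean_c + a + uhi_mean
                              > cfg.hot_day_threshold_c))
        assert hot_day_count(cfg, met) == expected
        assert expected > 0  # defaults do produce hot days


class TestScenarioPair:
    def test_zero_injection_gives_identical_scenarios(self, small_cfg):
        cfg = small_cfg.replace(delta_o3_urban_ppb=0.0)
        met = generate_meteorology(cfg)
        pair = generate_scenario_pair(cfg, met)
        np.testing.assert_array_equal(pair.base, pair.ug)

    def test_noise_free_zero_wind_hits_target_exactly(self, small_cfg):
        from greenozone import delta_mda8
        cfg = small_cfg.replace(wind_kmh=(0.0, 0.0), base_noise_sd_ppb=0.0,
                                delta_noise_sigma=0.0, day_noise_sigma=0.0)
        met = generate_meteorology(cfg)
        pair = generate_scenario_pair(cfg, met)
        surf = delta_mda8(pair)
        got = np.nanmean(surf.delta_seasonal[urban_mask(cfg)])
        assert got == pytest.approx(3.6, abs=1e-6)

    def test_recovery_with_default_noise(self):
        from greenozone import delta_mda8
        cfg = SyntheticConfig(seed=3, domain_size_km=30.0, fine_res_m=100.0,
                              n_days=20, spinup_days=4, urban_radius_km=9.0)
        met = generate_meteorology(cfg)
        pair = generate_scenario_pair(cfg, met)
        surf = delta_mda8(pair)
        got = np.nanmean(surf.delta_seasonal[urban_mask(cfg)])
        assert got == pytest.approx(3.6, rel=0.05)

    def test_enhancement_concentrated_downwind(self, small_cfg):
        cfg = small_cfg.replace(wind_kmh=(3.0, 0.0), base_noise_sd_ppb=0.0,
                                delta_noise_sigma=0.0, day_noise_sigma=0.0)
        met = generate_meteorology(cfg)
        pair = generate_scenario_pair(cfg, met)
        delta = (pair.ug - pair.base).mean(axis=0)
        mask = urban_mask(cfg)
        assert delta[mask].mean() > delta[~mask].mean()
        nx = cfg.coarse_grid.nx
        east = delta[:, 3 * nx // 4:].mean()   # downwind of the centre
        west = delta[:, :nx // 4].mean()
        assert east > west
        assert delta.min() >= 0.0

    def test_grid_mismatch_rejected(self, small_cfg):
        met = generate_meteorology(small_cfg)
        other = small_cfg.replace(domain_size_km=10.0)
        with pytest.raises(ValueError):
            generate_scenario_pair(other, met)


class TestPopulation:
    def test_sum_normalized(self, small_cfg):
        cfg = small_cfg.replace(pop_total=1e6)
        pop, _ = generate_population_and_incidence(cfg)
        assert pop.sum() == pytest.approx(1e6, rel=1e-6)
        assert pop.min() >= 0

    def test_uniform_option(self, small_cfg):
        pop, _ = generate_population_and_incidence(
            small_cfg.replace(pop_uniform=True))
        assert np.ptp(pop) == pytest.approx(0.0, abs=1e-9)

    def test_majority_of_population_is_urban(self, small_cfg):
        pop, _ = generate_population_and_incidence(small_cfg)
        assert pop[urban_mask(small_cfg)].sum() / pop.sum() >= 0.5

    def test_incidence_table_schema(self, small_cfg):
        _, inc = generate_population_and_incidence(small_cfg)
        assert set(inc.columns) == {"age_group", "cause", "annual_rate"}
        assert (inc["annual_rate"] >= 0).all()

    def test_regridding_preserves_population_sum(self, small_cfg, rng):
        pop, _ = generate_population_and_incidence(small_cfg)
        fine = np.kron(pop / 4.0, np.ones((2, 2)))
        np.testing.assert_allclose(block_sum(fine, 2), pop, rtol=1e-12)


def test_fixed_seed_bit_identical(small_cfg):
    lc1, lc2 = (generate_landcover(small_cfg) for _ in range(2))
    np.testing.assert_array_equal(lc1.fine_classes, lc2.fine_classes)
    np.testing.assert_array_equal(lc1.coarse_chi, lc2.coarse_chi)
    met1, met2 = (generate_meteorology(small_cfg) for _ in range(2))
    np.testing.assert_array_equal(met1.t2m_c, met2.t2m_c)
    p1 = generate_scenario_pair(small_cfg, met1)
    p2 = generate_scenario_pair(small_cfg, met2)
    np.testing.assert_array_equal(p1.ug, p2.ug)
    pop1, _ = generate_population_and_incidence(small_cfg)
    pop2, _ = generate_population_and_incidence(small_cfg)
    np.testing.assert_array_equal(pop1, pop2)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(urban_green_fraction=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(fine_res_m=300.0, coarse_res_km=1.0)  # not a divisor
    with pytest.raises(ValueError):
        SyntheticConfig(n_days=0)
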