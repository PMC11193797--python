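"""Synthetic-data generator: geography, membership, assets, model outcomes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from wealthnet.alaam_engine import exact_distribution, gibbs_sample
from wealthnet.alaam_stats import AlaamModel, Effect, EffectSpec
from wealthnet.network_build import YEAR_MAX, YEAR_MIN, affiliate, build_ties
from wealthnet.synthetic_data import (
    ConfigError,
    GeneratorConfig,
    gen_assets,
    gen_geography,
    gen_membership,
    gen_outcomes_from_model,
    generate_population,
    write_population,
)
from conftest import random_multilevel_net


class TestConfig:
    def test_probability_bounds(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_households=10, secondary_membership_rate=1.2)

    def test_more_regions_than_households(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_households=5, n_regions=10)

    def test_nonfinite_loadings(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(
                n_households=10, n_regions=2, asset_items=2,
                item_loadings=np.array([1.0, np.inf]),
            )

    def test_loading_length_mismatch(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(
                n_households=10, n_regions=2, asset_items=3, item_loadings=np.ones(2)
            )


class TestGeography:
    def test_symmetric_centroids_split_evenly(self):
        cfg = GeneratorConfig(n_households=4, n_regions=2)
        centroids = np.array([[0.25, 0.5], [0.75, 0.5]])
        coords = np.array([[0.2, 0.5], [0.3, 0.5], [0.7, 0.5], [0.8, 0.5]])
        geo = gen_geography(cfg, centroids=centroids, coords=coords)
        counts = pd.Series(geo.affiliation).value_counts()
        assert counts.tolist() == [2, 2]

    def test_default_config_no_empty_regions(self):
        cfg = GeneratorConfig(seed=42)
        geo = gen_geography(cfg)
        assert len(set(geo.affiliation.values())) == 23

    def test_determinism(self):
        cfg = GeneratorConfig(n_households=200, n_regions=5, seed=9)
        a = gen_geography(cfg)
        b = gen_geography(cfg)
        assert a.affiliation == b.affiliation
        np.testing.assert_array_equal(a.coords, b.coords)


class TestMembership:
    def test_zero_secondary_rate_gives_edgeless_network(self):
        cfg = GeneratorConfig(
            n_households=100, n_regions=4, seed=1, secondary_membership_rate=0.0
        )
        geo = gen_geography(cfg)
        eps = gen_membership(cfg, geo)
        assert build_ties(eps).n_ties == 0

    def test_every_household_has_an_episode(self):
        cfg = GeneratorConfig(n_households=150, n_regions=4, seed=2)
        geo = gen_geography(cfg)
        eps = gen_membership(cfg, geo)
        assert eps["household_id"].nunique() == 150

    def test_years_within_window(self):
        cfg = GeneratorConfig(n_households=100, n_regions=4, seed=3)
        eps = gen_membership(cfg, gen_geography(cfg))
        assert eps["start_year"].between(YEAR_MIN, YEAR_MAX).all()
        assert eps["end_year"].between(YEAR_MIN, YEAR_MAX).all()
        assert (eps["start_year"] <= eps["end_year"]).all()

    def test_strong_distance_decay_keeps_ties_local(self):
        cfg = GeneratorConfig(
            n_households=400,
            n_regions=4,
            seed=4,
            distance_decay=400.0,
            triadic_closure_prob=0.0,
            extra_membership_prob=0.0,
        )
        geo = gen_geography(cfg)
        net = affiliate(build_ties(gen_membership(cfg, geo)), geo.affiliation)
        same = sum(1 for i in net.ties.values() if i.same_region)
        assert same / net.n_ties > 0.95


class TestAssets:
    def _net(self, n=80, seed=5):
        cfg = GeneratorConfig(n_households=n, n_regions=4, seed=seed)
        geo = gen_geography(cfg)
        return cfg, affiliate(build_ties(gen_membership(cfg, geo)), geo.affiliation)

    def test_full_persistence_identical_waves(self):
        cfg, net = self._net()
        cfg.wave_transition.stay_prob = 1.0
        cfg.wave_transition.contagion_strength = 0.0
        w1, w2, latent = gen_assets(cfg, net)
        pd.testing.assert_frame_equal(w1, w2)
        np.testing.assert_allclose(latent["z1"], latent["z2"])

    def test_noise_free_items_monotone_in_latent(self):
        cfg, net = self._net()
        cfg.item_noise = 0.0
        cfg.item_loadings = np.ones(cfg.asset_items)
        w1, _, latent = gen_assets(cfg, net)
        order = latent["z1"].argsort()
        sums = w1.sum(axis=1).to_numpy()[order]
        assert (np.diff(sums) >= 0).all()

    def test_attrition_drops_wave2_households(self):
        cfg, net = self._net()
        cfg.attrition = 0.25
        w1, w2, _ = gen_assets(cfg, net)
        assert len(w2) < len(w1)
        assert w2.index.isin(w1.index).all()


class TestOutcomeSimulation:
    def test_zero_theta_mean_half(self, toy_net):
        spec = EffectSpec([Effect("density_household"), Effect("density_region")])
        means = []
        for s in range(40):
            st = gen_outcomes_from_model(toy_net, spec, n_burn=30, seed=s)
            means.append(st.y.mean())
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_density_only_matches_logistic(self, toy_net):
        th = -0.9
        spec = EffectSpec(
            [Effect("density_household", theta=th), Effect("density_region")]
        )
        means = [
            gen_outcomes_from_model(toy_net, spec, n_burn=30, seed=s).y.mean()
            for s in range(60)
        ]
        assert abs(np.mean(means) - 1 / (1 + np.exp(-th))) < 0.04

    def test_toy_net_frequencies_match_enumeration(self):
        """Chi-square of simulated outcome-vector frequencies vs exact law."""
        net = random_multilevel_net(n_h=6, n_r=2, p=0.4, seed=8)
        spec = EffectSpec(
            [
                Effect("density_household", theta=-0.4),
                Effect("density_region", theta=0.2),
                Effect("contagion_same_region", theta=0.7),
            ]
        )
        model = AlaamModel(net, spec)
        probs = exact_distribution(model)
        draws = gibbs_sample(model, n_burn=100, n_draws=20000, thin=1, seed=9)
        counts = np.zeros(len(probs))
        for d in draws:
            counts[int(sum(int(b) << j for j, b in enumerate(list(d.y) + list(d.Y))))] += 1
        keep = probs * counts.sum() >= 5  # chi-square validity
        stat = chisquare(counts[keep], probs[keep] / probs[keep].sum() * counts[keep].sum())
        assert stat.pvalue > 0.01


class TestPopulation:
    def test_full_determinism_under_fixed_seed(self):
        cfg = GeneratorConfig(n_households=120, n_regions=5, seed=17)
        a = generate_population(cfg)
        b = generate_population(GeneratorConfig(n_households=120, n_regions=5, seed=17))
        pd.testing.assert_frame_equal(a.episodes, b.episodes)
        pd.testing.assert_frame_equal(a.asset_wave1, b.asset_wave1)
        pd.testing.assert_frame_equal(a.asset_wave2, b.asset_wave2)
        pd.testing.assert_frame_equal(a.household_attributes, b.household_attributes)
        assert a.affiliation == b.affiliation

    def test_write_population_round_trip(self, small_pop, tmp_path):
        write_population(small_pop, tmp_path)
        eps = pd.read_csv(tmp_path / "episodes.csv")
        assert len(eps) == len(small_pop.episodes)
        aff = pd.read_csv(tmp_path / "affiliations.csv")
        assert dict(zip(aff["household_id"], aff["region_id"])) == small_pop.affiliation
        assert (tmp_path / "truth.json").exists()

    def test_nonresident_marginal_rate(self, small_pop):
        prim = small_pop.episodes.groupby("individual_id")["resident_flag"].first()
        assert abs((~prim.astype(bool)).mean() - 0.28) < 0.06
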