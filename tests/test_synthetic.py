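"""Ground-truth generator: landscape, taxon pool, sampling, climate, census."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from forestshift.grid import Grid
from forestshift.synthetic import (
    ScenarioConfig,
    generate_climate_and_census,
    generate_ground_truth,
    generate_historical_surveys,
    generate_landscape,
    generate_modern_plots,
    generate_taxon_pool,
    mention_probabilities,
    simulate_scenario,
    true_frequency_tables,
)


def _cfg(**kw):
    base = dict(
        n_cells_x=4, n_cells_y=4, n_clusters=2, n_taxa=6,
        obs_per_cell=10, plots_per_cell=3, n_years=30, seed=7,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestConfig:
    def test_rejects_too_many_clusters(self):
        with pytest.raises(ValueError, match="n_clusters"):
            _cfg(n_cells_x=2, n_cells_y=2, n_clusters=5)

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_taxa": 0},
            {"point_fraction": 1.5},
            {"beta_disturbance": float("inf")},
            {"noise_sd": -0.1},
        ],
    )
    def test_rejects_invalid_fields(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)


class TestLandscape:
    def test_single_cluster_covers_all_cells(self):
        grid, labels = generate_landscape(_cfg(n_cells_x=10, n_cells_y=10, n_clusters=1))
        assert len(labels) == 100 and set(labels) == {0}

    def test_clusters_are_connected_sets(self):
        cfg = _cfg(n_cells_x=10, n_cells_y=10, n_clusters=4, seed=13)
        grid, labels = generate_landscape(cfg)
        adj = grid.adjacency()
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            sub = adj[members][:, members]
            n_comp, _ = connected_components(sub, directed=False)
            assert n_comp == 1

    def test_row_adjacent_centroids_5km_apart(self):
        grid, _ = generate_landscape(_cfg())
        cents = grid.centroids()
        assert cents.loc[1, "x"] - cents.loc[0, "x"] == pytest.approx(5.0)
        assert cents.loc[grid.n_x, "y"] - cents.loc[0, "y"] == pytest.approx(5.0)


class TestTaxonPool:
    def test_tolerance_scores_on_1_to_5_scale(self):
        pool = generate_taxon_pool(_cfg())
        assert pool.tolerance.min().min() >= 1.0
        assert pool.tolerance.max().max() <= 5.0

    def test_identical_seed_identical_pool(self):
        p1 = generate_taxon_pool(_cfg(seed=3))
        p2 = generate_taxon_pool(_cfg(seed=3))
        pd.testing.assert_frame_equal(p1.trait_table, p2.trait_table)
        pd.testing.assert_frame_equal(p1.tolerance, p2.tolerance)

    def test_at_least_two_multispecies_genus_groups(self):
        pool = generate_taxon_pool(_cfg())
        sizes = pd.Series(pool.genus_map).value_counts()
        assert (sizes > 1).sum() >= 2

    def test_southern_ranges_are_warmer(self):
        # the raster cools northward; a species whose band sits further
        # south (smaller row indices) must have the larger TTI
        pool = generate_taxon_pool(_cfg(n_taxa=8))
        mean_row = {
            sp: np.where(mask.any(axis=1))[0].mean()
            for sp, mask in pool.range_masks.items()
        }
        tti = {
            sp: np.median(pool.temperature_raster[pool.range_masks[sp]])
            for sp in pool.species
        }
        sps = sorted(pool.species, key=lambda s: mean_row[s])
        ttis = [tti[s] for s in sps]
        assert all(a >= b for a, b in zip(ttis, ttis[1:]))


def _pl_topk_oracle(abund, max_len=5):
    """Enumeration oracle: P(taxon in list) under the Plackett-Luce top-k
    model with list length 2 + Binomial(3, 0.5), for small taxon pools."""
    from scipy.stats import binom

    pos = np.flatnonzero(abund > 0)
    a = abund[pos]
    n = pos.size
    k_probs = {}
    for j in range(4):
        k = min(2 + j, n)
        k_probs[k] = k_probs.get(k, 0.0) + binom.pmf(j, 3, 0.5)
    inclusion = np.zeros(abund.size)
    for perm in itertools.permutations(range(n)):
        p = 1.0
        remaining = a.sum()
        for i in perm:
            p *= a[i] / remaining
            remaining -= a[i]
        for k, pk in k_probs.items():
            for i in perm[:k]:
                inclusion[pos[i]] += p * pk
    return inclusion


class TestHistoricalSurveys:
    def test_point_fraction_one_yields_no_lines(self):
        cfg = _cfg(point_fraction=1.0)
        sc = simulate_scenario(cfg)
        assert (sc.observations["kind"] == "point").all()

    def test_point_spacing_within_100_200m(self):
        cfg = _cfg(point_fraction=1.0, obs_per_cell=30)
        sc = simulate_scenario(cfg)
        one_line = sc.observations[sc.observations.line_id == "c0_t0"]
        gaps = np.diff(one_line["x"].to_numpy()) * 1000
        assert ((gaps >= 100 - 1e-9) & (gaps <= 200 + 1e-9)).all()

    def test_zero_abundance_taxon_never_listed(self):
        cfg = _cfg()
        grid, labels = generate_landscape(cfg)
        pool = generate_taxon_pool(cfg)
        truth = generate_ground_truth(cfg, grid, labels, pool)
        truth.hist_abund[:, 2] = 0.0
        truth.hist_abund /= truth.hist_abund.sum(axis=1, keepdims=True)
        obs = generate_historical_surveys(cfg, grid, truth)
        banned = truth.taxa[2]
        assert not any(banned in lst for lst in obs["taxa"])

    def test_sample_mention_frequency_matches_enumeration_oracle(self):
        cfg = _cfg(
            n_cells_x=1, n_cells_y=1, n_clusters=1, n_taxa=4,
            obs_per_cell=4000, seed=23,
        )
        grid, labels = generate_landscape(cfg)
        pool = generate_taxon_pool(cfg)
        truth = generate_ground_truth(cfg, grid, labels, pool)
        oracle = _pl_topk_oracle(truth.hist_abund[0])
        obs = generate_historical_surveys(cfg, grid, truth)
        counts = np.zeros(len(truth.taxa))
        for lst in obs["taxa"]:
            for t in lst:
                counts[truth.taxa.index(t)] += 1
        empirical = counts / len(obs)
        # 3 sigma binomial error at n = 4000
        tol = 3 * np.sqrt(oracle * (1 - oracle) / len(obs)) + 1e-3
        assert np.all(np.abs(empirical - oracle) < tol)
        # the deterministic Monte-Carlo probabilities agree with the oracle
        mc = mention_probabilities(truth.hist_abund[0], n_mc=40_000)
        assert np.allclose(mc, oracle, atol=0.02)


class TestModernPlots:
    def test_null_scenario_modern_equals_historical(self):
        cfg = _cfg(
            beta_disturbance=0.0, beta_temperature=0.0, beta_moisture=0.0,
            noise_sd=0.0,
        )
        sc = simulate_scenario(cfg)
        assert np.allclose(sc.truth.mod_abund, sc.truth.hist_abund, atol=1e-12)

    def test_basal_areas_nonnegative_finite(self, small_scenario):
        ba = small_scenario.plots["basal_area"]
        assert np.isfinite(ba).all() and (ba >= 0).all()

    def test_species_level_output_exercises_grouping(self, small_scenario):
        pool = small_scenario.pool
        multi = [s for s, t in pool.genus_map.items() if s != t]
        assert set(small_scenario.plots["species"]) & set(multi)

    def test_disturbance_beta_shifts_composition_along_planted_axis(self):
        cfg = _cfg(
            n_cells_x=8, n_cells_y=8, n_clusters=1, beta_disturbance=1.0,
            noise_sd=0.0, seed=17,
        )
        grid, labels = generate_landscape(cfg)
        pool = generate_taxon_pool(cfg)
        truth = generate_ground_truth(cfg, grid, labels, pool)
        std = pool.standardized_indices().loc[truth.taxa, "tdi"].to_numpy()
        planted_delta = (truth.mod_abund - truth.hist_abund) @ std
        rho, _ = spearmanr(truth.pop_change, planted_delta)
        assert rho > 0.9


class TestClimateAndCensus:
    def test_precipitation_nonnegative(self, small_scenario):
        assert (small_scenario.climate["prcp"] >= 0).all()

    def test_960_months_per_cell_in_study_configuration(self):
        cfg = _cfg(n_cells_x=2, n_cells_y=1, n_clusters=1, n_years=80)
        sc = simulate_scenario(cfg)
        assert (sc.climate.groupby("cell").size() == 960).all()

    def test_growing_population_gives_positive_delta(self, small_scenario):
        from forestshift.drivers import delta_population

        out = delta_population(small_scenario.census)
        assert (out["delta_population"] >= 0).all()
        assert (out["delta_population"] > 0).mean() > 0.5

    def test_census_has_four_years_per_cell(self, small_scenario):
        years = small_scenario.census.groupby("cell")["year"].agg(sorted)
        assert all(y == [1831, 1871, 1951, 2001] for y in years)


class TestReproducibilityAndTruthTables:
    def test_bit_reproducible_under_fixed_seed(self):
        s1 = simulate_scenario(_cfg(seed=31))
        s2 = simulate_scenario(_cfg(seed=31))
        pd.testing.assert_frame_equal(s1.observations, s2.observations)
        pd.testing.assert_frame_equal(s1.plots, s2.plots)
        pd.testing.assert_frame_equal(s1.climate, s2.climate)
        pd.testing.assert_frame_equal(s1.census, s2.census)

    def test_truth_tables_identical_under_null(self):
        cfg = _cfg(
            beta_disturbance=0.0, beta_temperature=0.0, beta_moisture=0.0,
            noise_sd=0.0,
        )
        sc = simulate_scenario(cfg)
        hist, mod = true_frequency_tables(sc.truth, n_mc=500)
        assert np.array_equal(
            hist["frequency"].to_numpy(), mod["frequency"].to_numpy()
        )

    def test_truth_frequencies_are_probabilities(self, small_scenario):
        hist, mod = true_frequency_tables(small_scenario.truth, n_mc=500)
        for tab in (hist, mod):
            assert tab["frequency"].between(0, 1).all()
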