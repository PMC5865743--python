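"""Synthetic-data generator: determinism, degenerate limits, survival-model
calibration."""

import numpy as np
import pytest
from scipy import stats

from mirsubpath.coxph import STATUS_OK, cox_univariate_batch
from mirsubpath.graphs import SubpathwayGraph
from mirsubpath.simulate import (
    ScenarioConfig,
    choose_planted,
    generate_cohort,
    generate_interactions,
    generate_pathways,
    simulate_expression,
    simulate_survival,
    solve_censoring_rate,
)

from conftest import cox_grid_oracle


class TestConfigValidation:
    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="edge_prob"):
            ScenarioConfig(edge_prob=1.5)

    def test_small_pathways_rejected(self):
        with pytest.raises(ValueError, match="genes_per_pathway"):
            ScenarioConfig(genes_per_pathway=2)

    def test_positive_hazard_required(self):
        with pytest.raises(ValueError, match="baseline_hazard"):
            ScenarioConfig(baseline_hazard=0.0)


class TestGeneratePathways:
    def test_complete_graph_limit(self):
        cfg = ScenarioConfig(n_pathways=1, genes_per_pathway=3, edge_prob=1.0)
        (g,) = generate_pathways(cfg)
        assert len(g.nodes) == 3 and len(g.edges) == 3  # a triangle

    def test_zero_edge_prob_gives_tree_via_bridging(self):
        cfg = ScenarioConfig(n_pathways=2, genes_per_pathway=8, edge_prob=0.0)
        for g in generate_pathways(cfg):
            G = g.to_networkx()
            import networkx as nx

            assert nx.is_connected(G)
            assert G.number_of_edges() == G.number_of_nodes() - 1

    def test_all_pathways_connected_and_gene_ids_unique(self):
        cfg = ScenarioConfig(n_pathways=6, genes_per_pathway=10, edge_prob=0.15, seed=2)
        import networkx as nx

        pws = generate_pathways(cfg)
        all_genes = [g for p in pws for g in p.nodes]
        assert len(all_genes) == len(set(all_genes))
        assert all(nx.is_connected(p.to_networkx()) for p in pws)

    def test_deterministic_under_seed(self):
        cfg = ScenarioConfig(seed=11)
        assert generate_pathways(cfg) == generate_pathways(cfg)


class TestGenerateInteractions:
    def test_saturated_case(self):
        cfg = ScenarioConfig(n_pathways=2, genes_per_pathway=3, n_mirnas=4, interaction_prob=1.0)
        tbl = generate_interactions(generate_pathways(cfg), cfg)
        assert len(tbl) == 4 * 6

    def test_zero_prob_empty(self):
        cfg = ScenarioConfig(interaction_prob=0.0)
        assert len(generate_interactions(generate_pathways(cfg), cfg)) == 0

    def test_row_count_matches_independent_resimulation(self):
        cfg = ScenarioConfig(n_pathways=1, genes_per_pathway=5, n_mirnas=2,
                             interaction_prob=0.5, seed=21)
        tbl = generate_interactions(generate_pathways(cfg), cfg)
        # brute-force re-simulation with the generator's own substream
        rng = np.random.default_rng([21, 2])
        hits = rng.random((2, 5)) < 0.5
        assert len(tbl) == int(hits.sum())

    def test_deterministic(self):
        cfg = ScenarioConfig(seed=4)
        pws = generate_pathways(cfg)
        assert generate_interactions(pws, cfg).df.equals(generate_interactions(pws, cfg).df)


def toy_subpathways():
    cfg = ScenarioConfig(n_pathways=4, genes_per_pathway=6, n_mirnas=10,
                         interaction_prob=0.3, n_samples=50, seed=8)
    sub = SubpathwayGraph(
        "sp001_1", "sp001", frozenset({"g0000", "g0001", "g0002"}), frozenset(),
        frozenset({"miR-001"}), frozenset({("miR-001", "g0000")}),
    )
    return cfg, [sub]


class TestGenerateCohort:
    def test_unknown_planted_id_rejected(self):
        cfg, subs = toy_subpathways()
        with pytest.raises(ValueError, match="not found"):
            generate_cohort(subs, {"nope_9"}, cfg)

    def test_expression_nonnegative_complete_and_deterministic(self):
        cfg, subs = toy_subpathways()
        m1, g1, c1 = generate_cohort(subs, {"sp001_1"}, cfg)
        m2, g2, c2 = generate_cohort(subs, {"sp001_1"}, cfg)
        for df in (m1, g1):
            assert (df.to_numpy() >= 0).all() and not np.isnan(df.to_numpy()).any()
        assert m1.equals(m2) and g1.equals(g2) and c1.equals(c2)
        assert g1.shape == (24, 50) and m1.shape == (10, 50)

    def test_no_censoring_means_all_events(self):
        cfg, subs = toy_subpathways()
        cfg = ScenarioConfig(**{**cfg.__dict__, "censor_rate": 0.0})
        _, _, clin = generate_cohort(subs, {"sp001_1"}, cfg)
        assert (clin["event"] == 1).all()

    def test_censor_fraction_near_target(self):
        cfg, subs = toy_subpathways()
        cfg = ScenarioConfig(**{**cfg.__dict__, "n_samples": 2000, "censor_rate": 0.4,
                                "effect_size_beta": 0.0})
        _, _, clin = generate_cohort(subs, set(), cfg)
        frac = 1.0 - clin["event"].mean()
        assert frac == pytest.approx(0.4, abs=0.04)

    def test_unreachable_censor_rate_is_an_error(self):
        hazards = np.full(10, 2.0)  # most events before a 1-month floor
        with pytest.raises(ValueError, match="unreachable"):
            solve_censoring_rate(hazards, 0.9, min_followup=1.0)


class TestSurvivalModelCalibration:
    def test_null_pvalues_uniform(self):
        """β = 0: Cox screening p-values across independent features are
        uniform (KS at α = 0.01, n_samples = 200)."""
        cfg = ScenarioConfig(n_samples=200, effect_size_beta=0.0, seed=17)
        rng = np.random.default_rng(17)
        expr = simulate_expression([f"f{i}" for i in range(400)], 200, rng)
        z = np.log2(expr.to_numpy() + 1)
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        clin = simulate_survival(z, np.zeros(400), cfg, rng)
        res = cox_univariate_batch(
            z, clin["time_months"].to_numpy(), clin["event"].to_numpy()
        )
        pvals = [r.p_value for r in res if r.status == STATUS_OK]
        assert len(pvals) > 380
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_effect_recovered_against_grid_oracle(self):
        """β = 1 planted feature at n = 300: the fitted coefficient matches a
        direct grid search on the same data, and sits near the truth."""
        cfg = ScenarioConfig(n_samples=300, effect_size_beta=1.0, seed=23)
        rng = np.random.default_rng(23)
        expr = simulate_expression(["hit", "null"], 300, rng)
        z = np.log2(expr.to_numpy() + 1)
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        clin = simulate_survival(z, np.array([1.0, 0.0]), cfg, rng)
        t, e = clin["time_months"].to_numpy(), clin["event"].to_numpy()
        res = cox_univariate_batch(z, t, e)[0]
        oracle = cox_grid_oracle(z[0], t, e, lo=-3, hi=3, n_grid=60001)
        assert res.coefficient == pytest.approx(oracle, abs=1e-3)
        assert res.coefficient == pytest.approx(1.0, abs=0.25)


def test_choose_planted_uses_distinct_parent_pathways():
    cfg = ScenarioConfig(seed=5)
    from mirsubpath.subpathways import build_subpathways

    pws = generate_pathways(cfg)
    tbl = generate_interactions(pws, cfg)
    subs = build_subpathways(pws, tbl)
    planted = choose_planted(subs, cfg)
    assert len(planted) == cfg.planted_subpathway_count
    parents = {s.parent_pathway for s in subs if s.subpathway_id in planted}
    assert len(parents) == cfg.planted_subpathway_count
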