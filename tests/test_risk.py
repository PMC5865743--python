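"""Risk-score models, median dichotomization, KM curves and the log-rank test."""

import json

import numpy as np
import pandas as pd
import pytest

from mirsubpath.graphs import SubpathwayGraph
from mirsubpath.risk import (
    CombinedRiskModel,
    RiskComponent,
    RiskScoreModel,
    combined_fit,
    compare_risk_groups,
    dichotomize,
    fit_risk_model,
    km_curve,
    logrank_test,
    read_models_json,
    score_samples,
    write_models_json,
)

from conftest import km_oracle


def expr_frame(columns_by_sample: dict, features: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns_by_sample, index=features)


@pytest.fixture()
def cohort():
    rng = np.random.default_rng(9)
    samples = [f"s{i}" for i in range(30)]
    gene_expr = pd.DataFrame(
        rng.lognormal(2, 1, size=(4, 30)), index=["ga", "gb", "gc", "gd"], columns=samples
    )
    mirna_expr = pd.DataFrame(
        rng.lognormal(1, 1, size=(2, 30)), index=["m1", "m2"], columns=samples
    )
    # hazard increases with ga expression
    risk = np.log2(gene_expr.loc["ga"].to_numpy() + 1)
    t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * (risk - risk.mean()) / risk.std())))
    clin = pd.DataFrame({"sample_id": samples, "time_months": t, "event": 1})
    sub = SubpathwayGraph(
        "p_1", "p", frozenset({"ga", "gb", "gc"}), frozenset(),
        frozenset({"m1"}), frozenset({("m1", "ga")}),
    )
    return sub, mirna_expr, gene_expr, clin


class TestFitRiskModel:
    def test_components_cover_all_measured_members(self, cohort):
        sub, mirna_expr, gene_expr, clin = cohort
        model = fit_risk_model(sub, mirna_expr, gene_expr, clin)
        assert {c.feature_id for c in model.components} == {"ga", "gb", "gc", "m1"}

    def test_score_is_hand_computed_linear_combination(self, cohort):
        sub, mirna_expr, gene_expr, clin = cohort
        model = fit_risk_model(sub, mirna_expr, gene_expr, clin)
        scores = score_samples(model, mirna_expr, gene_expr)
        sid = "s3"
        want = sum(
            c.weight
            * (np.log2((gene_expr if c.kind == "gene" else mirna_expr).loc[c.feature_id, sid] + 1) - c.mean)
            / c.sd
            for c in model.components
        )
        assert scores[sid] == pytest.approx(want, abs=1e-12)

    def test_training_median_reproduced_by_rescoring(self, cohort):
        sub, mirna_expr, gene_expr, clin = cohort
        model = fit_risk_model(sub, mirna_expr, gene_expr, clin)
        scores = score_samples(model, mirna_expr, gene_expr)
        assert np.median(list(scores.values())) == pytest.approx(model.training_median)

    def test_all_degenerate_components_error(self, cohort):
        sub, mirna_expr, gene_expr, clin = cohort
        flat_g = gene_expr.copy()
        flat_g.loc[:, :] = 1.0
        flat_m = mirna_expr.copy()
        flat_m.loc[:, :] = 1.0
        with pytest.raises(ValueError, match="no usable components"):
            fit_risk_model(sub, flat_m, flat_g, clin)

    def test_no_measured_members_error(self, cohort):
        sub, mirna_expr, gene_expr, clin = cohort
        orphan = SubpathwayGraph("q_1", "q", frozenset({"zz"}), frozenset())
        with pytest.raises(ValueError, match="no measured members"):
            fit_risk_model(orphan, mirna_expr, gene_expr, clin)


class TestScoreSamples:
    def _model(self, weights):
        comps = tuple(
            RiskComponent(f"g{i}", "gene", w, mean=0.0, sd=1.0, status="ok")
            for i, w in enumerate(weights)
        )
        return RiskScoreModel("p_1", comps, training_median=0.0)

    def test_zero_weights_zero_scores(self):
        samples = ["a", "b"]
        ge = expr_frame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, ["g0", "g1"])
        me = pd.DataFrame(index=pd.Index([], dtype=str), columns=samples, dtype=float)
        scores = score_samples(self._model([0.0, 0.0]), me, ge)
        assert scores == {"a": 0.0, "b": 0.0}

    def test_linearity_in_one_covariate(self):
        model = self._model([0.5, 2.0])
        samples = ["a"]
        me = pd.DataFrame(index=pd.Index([], dtype=str), columns=samples, dtype=float)
        ge1 = pd.DataFrame({"a": [3.0, 1.0]}, index=["g0", "g1"])
        ge2 = ge1.copy()
        ge2.loc["g1", "a"] = 3.0  # transformed covariate moves by log2(4)-log2(2)
        delta = np.log2(4.0) - np.log2(2.0)
        s1 = score_samples(model, me, ge1)["a"]
        s2 = score_samples(model, me, ge2)["a"]
        assert s2 - s1 == pytest.approx(2.0 * delta, abs=1e-12)

    def test_missing_feature_is_an_error(self):
        model = self._model([1.0])
        me = pd.DataFrame(index=pd.Index([], dtype=str), columns=["a"], dtype=float)
        ge = pd.DataFrame({"a": [1.0]}, index=["other"])
        with pytest.raises(KeyError, match="g0"):
            score_samples(model, me, ge)


class TestDichotomize:
    def test_median_cutoff(self):
        groups = dichotomize({"a": 1, "b": 2, "c": 3, "d": 4}, cutoff=2.5)
        assert groups == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_ties_at_cutoff_go_low(self):
        assert set(dichotomize({"a": 2.0, "b": 2.0}, 2.0).values()) == {"low"}

    def test_single_sample_above(self):
        groups = dichotomize({"a": 1, "b": 5}, 4)
        assert groups["b"] == "high" and groups["a"] == "low"


class TestCombined:
    def test_needs_two_models(self, cohort):
        sub, mirna_expr, gene_expr, clin = cohort
        model = fit_risk_model(sub, mirna_expr, gene_expr, clin)
        with pytest.raises(ValueError, match=">= 2"):
            combined_fit([model], mirna_expr, gene_expr, clin)

    def test_identical_submodels_get_identical_weights(self, cohort):
        sub, mirna_expr, gene_expr, clin = cohort
        model = fit_risk_model(sub, mirna_expr, gene_expr, clin)
        comb = combined_fit([model, model], mirna_expr, gene_expr, clin)
        assert comb.sub_weights[0] == pytest.approx(comb.sub_weights[1])

    def test_combined_score_is_hand_computed(self, cohort):
        from mirsubpath.risk import score_combined

        sub, mirna_expr, gene_expr, clin = cohort
        sub2 = SubpathwayGraph("p_2", "p", frozenset({"gd", "gb", "gc"}), frozenset())
        m1 = fit_risk_model(sub, mirna_expr, gene_expr, clin)
        m2 = fit_risk_model(sub2, mirna_expr, gene_expr, clin)
        comb = combined_fit([m1, m2], mirna_expr, gene_expr, clin)
        s = score_combined(comb, mirna_expr, gene_expr)
        sid = "s7"
        want = (
            comb.sub_weights[0] * score_samples(m1, mirna_expr, gene_expr)[sid]
            + comb.sub_weights[1] * score_samples(m2, mirna_expr, gene_expr)[sid]
        )
        assert s[sid] == pytest.approx(want, abs=1e-12)


def clin_of(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time_months": times, "event": events})


class TestKMCurve:
    def test_no_events_flat_at_one(self):
        clin = clin_of([2.0, 5.0, 9.0], [0, 0, 0])
        curve = km_curve(clin["sample_id"], clin)
        assert curve.at(0) == 1.0 and curve.at(100) == 1.0

    def test_three_sample_hand_example(self):
        # event at 1, censor at 2, event at 3: S(1)=2/3, S(3)=0
        clin = clin_of([1.0, 2.0, 3.0], [1, 0, 1])
        curve = km_curve(clin["sample_id"], clin)
        assert curve.at(1.0) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(2 / 3)
        assert curve.at(3.0) == pytest.approx(0.0)

    def test_all_events_distinct_times_closed_form(self):
        n = 6
        clin = clin_of(list(range(1, n + 1)), [1] * n)
        curve = km_curve(clin["sample_id"], clin)
        for k in range(1, n + 1):
            assert curve.at(float(k)) == pytest.approx((n - k) / n)

    def test_matches_hand_product_limit_with_censoring(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 25).round(1) + 0.1
        e = rng.integers(0, 2, 25)
        clin = clin_of(t, e)
        curve = km_curve(clin["sample_id"], clin)
        for tt, ss in km_oracle(t, e):
            assert curve.at(tt) == pytest.approx(ss, abs=1e-12)

    def test_monotone_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(13)
        clin = clin_of(rng.exponential(5, 40), rng.integers(0, 2, 40))
        curve = km_curve(clin["sample_id"], clin)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()

    def test_empty_group_rejected(self):
        clin = clin_of([1.0], [1])
        with pytest.raises(ValueError, match="empty"):
            km_curve([], clin)


class TestLogrank:
    def test_identical_event_patterns_give_zero_chi2(self):
        clin = clin_of([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        groups = {f"s{i}": ("high" if i < 3 else "low") for i in range(6)}
        chi2, p = logrank_test(groups, clin)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_four_sample_hand_computation(self):
        """Group A events at {1,2}, group B at {2,3}, all uncensored:
        Σ(O−E) = 5/6 and ΣV = 17/36, so chi2 = (5/6)²/(17/36) ≈ 1.4706."""
        clin = clin_of([1.0, 2.0, 2.0, 3.0], [1, 1, 1, 1], ["a1", "a2", "b1", "b2"])
        groups = {"a1": "high", "a2": "high", "b1": "low", "b2": "low"}
        chi2, p = logrank_test(groups, clin)
        assert chi2 == pytest.approx((5 / 6) ** 2 / (17 / 36), rel=1e-6)
        assert p == pytest.approx(0.225, abs=0.005)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(14)
        clin = clin_of(rng.exponential(5, 30), rng.integers(0, 2, 30))
        groups = {f"s{i}": ("high" if i % 2 else "low") for i in range(30)}
        swapped = {k: ("low" if v == "high" else "high") for k, v in groups.items()}
        assert logrank_test(groups, clin)[0] == pytest.approx(
            logrank_test(swapped, clin)[0], rel=1e-12
        )

    def test_single_group_rejected(self):
        clin = clin_of([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test({"s0": "high", "s1": "high"}, clin)


def test_compare_risk_groups_and_model_roundtrip(cohort, tmp_path):
    sub, mirna_expr, gene_expr, clin = cohort
    model = fit_risk_model(sub, mirna_expr, gene_expr, clin)
    scores = score_samples(model, mirna_expr, gene_expr)
    cmp_ = compare_risk_groups(scores, model.training_median, clin)
    assert set(cmp_.curves) == {"high", "low"}
    assert 0 <= cmp_.logrank_p <= 1

    sub2 = SubpathwayGraph("p_2", "p", frozenset({"gd", "gb"}), frozenset())
    m2 = fit_risk_model(sub2, mirna_expr, gene_expr, clin)
    comb = combined_fit([model, m2], mirna_expr, gene_expr, clin)
    write_models_json([model, m2], tmp_path / "models.json", combined=comb)
    models, comb2 = read_models_json(tmp_path / "models.json")
    assert models == [model, m2] and comb2 == comb
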