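"""Oversampling, LR fitting, evaluation metrics, DCA and linear SHAP."""

import numpy as np
import pandas as pd
import pytest

from gisthabitat.model_eval import (
    decision_curve,
    evaluate,
    fit_lr,
    net_benefit,
    oversample,
    shap_linear,
)


def _fit_simple(rng, n=80, beta=(2.0, -1.5), imbalance=0.5):
    p = len(beta)
    x = rng.normal(size=(n, p))
    logit = x @ np.array(beta) + np.log(imbalance / (1 - imbalance))
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    table = pd.DataFrame(x, columns=[f"f{i}" for i in range(p)])
    return table, y


class TestOversample:
    def test_195_44_becomes_195_195(self):
        y = np.array([0] * 195 + [1] * 44)
        idx = oversample(np.arange(239), y, seed=0)
        assert (y[idx] == 0).sum() == 195
        assert (y[idx] == 1).sum() == 195

    def test_balanced_input_unchanged(self):
        y = np.repeat([0, 1], 20)
        idx = oversample(np.arange(40), y, seed=0)
        np.testing.assert_array_equal(np.sort(idx), np.arange(40))

    def test_resampled_indices_come_from_minority(self):
        y = np.array([0] * 50 + [1] * 10)
        idx = oversample(np.arange(60), y, seed=1)
        extra = idx[60:]
        assert set(extra) <= set(range(50, 60))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            oversample(np.arange(5), np.zeros(5, dtype=int), seed=0)


class TestFitLR:
    def test_separable_data_training_auc_one(self):
        y = np.repeat([0, 1], 25)
        table = pd.DataFrame({"f0": np.concatenate([np.zeros(25), np.ones(25)])})
        model = fit_lr(table, y)
        rep = evaluate(model, table, y, n_boot=50, seed=0)
        assert rep.auc == 1.0

    def test_constant_feature_gets_zero_coefficient(self, rng):
        table, y = _fit_simple(rng)
        table["zero"] = 0.0
        model = fit_lr(table, y)
        assert abs(model.coef[list(table.columns).index("zero")]) < 1e-6

    def test_coefficient_signs_recover_planted_effects(self):
        correct = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table, y = _fit_simple(rng, n=150, beta=(1.5, -1.5))
            model = fit_lr(table, y)
            correct += model.coef[0] > 0 and model.coef[1] < 0
        assert correct >= 18


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat([0, 1], 10)
        rep = evaluate(y.astype(float), labels=y, n_boot=50, seed=0, threshold=0.5)
        assert rep.auc == 1.0
        assert rep.metrics["ACC"] == 1.0

    def test_anticorrelated_predictions(self):
        y = np.repeat([0, 1], 10)
        rep = evaluate(1.0 - y, labels=y, n_boot=50, seed=0, threshold=0.5)
        assert rep.auc < 0.5

    def test_rate_identities(self, rng):
        table, y = _fit_simple(rng)
        model = fit_lr(table, y)
        rep = evaluate(model, table, y, n_boot=50, seed=0)
        m = rep.metrics
        assert m["SEN"] == m["TPR"]
        assert m["FPR"] == pytest.approx(1.0 - m["SPE"])
        assert all(0 <= m[k] <= 1 for k in m)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_pairwise_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.round(rng.random(n), 1)  # coarse grid to force ties
        rep = evaluate(scores, labels=y, n_boot=10, seed=0, threshold=0.5)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_set_rejected(self, rng):
        table, _ = _fit_simple(rng, n=20)
        model = fit_lr(table, np.repeat([0, 1], 10))
        with pytest.raises(ValueError, match="single class"):
            evaluate(model, table, np.zeros(20, dtype=int), n_boot=10)

    def test_ci_brackets_point_estimate(self, rng):
        table, y = _fit_simple(rng, n=120)
        model = fit_lr(table, y)
        rep = evaluate(model, table, y, n_boot=200, seed=0)
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]


class TestDecisionCurve:
    def test_hand_computed_two_by_two(self):
        # TP=8, FP=2, n=20 at p_t=0.2: 8/20 - (2/20)(0.2/0.8) = 0.375
        assert net_benefit(8, 2, 20, 0.2) == pytest.approx(0.375)

    def test_treat_all_approaches_prevalence_at_small_pt(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        dca = decision_curve(np.linspace(0, 1, 10), labels=y, pt_grid=[1e-6])
        assert dca.net_benefit_all[0] == pytest.approx(0.2, abs=1e-5)

    def test_treat_all_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        scores = rng.random(50)
        pt = np.linspace(0.05, 0.95, 19)
        dca = decision_curve(scores, labels=y, pt_grid=pt)
        prev = y.mean()
        np.testing.assert_allclose(
            dca.net_benefit_all, prev - (1 - prev) * pt / (1 - pt), atol=1e-12
        )
        np.testing.assert_array_equal(dca.net_benefit_none, 0.0)

    def test_perfect_model_net_benefit_equals_prevalence(self):
        y = np.repeat([0, 1], 10)
        scores = y * 0.9 + 0.05  # positives 0.95, negatives 0.05
        dca = decision_curve(scores, labels=y, pt_grid=np.linspace(0.1, 0.9, 9))
        np.testing.assert_allclose(dca.net_benefit_model, y.mean(), atol=1e-12)

    def test_model_nb_never_exceeds_prevalence(self, rng):
        table, y = _fit_simple(rng)
        model = fit_lr(table, y)
        dca = decision_curve(model, table, y)
        assert (dca.net_benefit_model <= y.mean() + 1e-12).all()


class TestShapLinear:
    def test_zero_coefficient_zero_attribution(self, rng):
        table, y = _fit_simple(rng)
        table["zero"] = 0.0
        model = fit_lr(table, y)
        rep = shap_linear(model, table)
        j = rep.feature_names.index("zero")
        np.testing.assert_allclose(rep.values[:, j], 0.0, atol=1e-9)

    def test_additivity_to_logit(self, rng):
        table, y = _fit_simple(rng, n=60)
        model = fit_lr(table, y)
        rep = shap_linear(model, table)
        logits = model.decision_function(table)
        np.testing.assert_allclose(
            rep.values.sum(axis=1) + rep.baseline, logits, atol=1e-8
        )

    def test_schema_mismatch_rejected(self, rng):
        table, y = _fit_simple(rng)
        model = fit_lr(table, y)
        with pytest.raises(ValueError, match="schema"):
            shap_linear(model, table.rename(columns={"f0": "other"}))

    def test_dominant_feature_ranks_first(self, rng):
        table, y = _fit_simple(rng, n=200, beta=(3.0, 0.1))
        model = fit_lr(table, y)
        rep = shap_linear(model, table)
        assert rep.ranking[0] == "f0"
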