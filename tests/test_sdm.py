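import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from corridorscape import (build_ensemble, cross_validate, ensemble_predict,
                           evaluate_auc, evaluate_tss, fit_gbm, fit_glm,
                           fit_maxent, variable_importance)
from corridorscape.sdm import (EvalRecord, SDMFit, _maxent_nll,
                               ensemble_weights)
from conftest import toy_table


def make_table(x, labels, col="woodland"):
    return pd.DataFrame({col: np.asarray(x, dtype=float),
                         "label": labels, "study_area": "toy"})


class TestGLM:
    def test_balanced_intercept_only_predicts_half(self):
        table = pd.DataFrame({"label": ["presence"] * 50
                              + ["pseudo_absence"] * 50,
                              "study_area": "toy"})
        fit = fit_glm(table)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.predict(np.zeros((1, 0)))[0] == pytest.approx(0.5)

    def test_separable_data_bounded_and_correct_side(self):
        x = np.concatenate([np.linspace(0.6, 1.0, 20),
                            np.linspace(0.0, 0.4, 20)])
        labels = ["presence"] * 20 + ["pseudo_absence"] * 20
        fit = fit_glm(make_table(x, labels))
        assert np.isfinite(fit.params["coef"]).all()
        pred = fit.predict(make_table(x, labels))
        assert (pred[:20] > 0.5).all() and (pred[20:] < 0.5).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_glm(make_table([0.1, 0.9], ["presence", "presence"]))

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_glm(make_table([0.5, 0.5, 0.5, 0.5],
                               ["presence", "pseudo_absence"] * 2))

    def test_coefficient_recovery_small(self):
        """Quick sanity: 2000 Bernoulli draws from a known logistic model
        put the estimates within 3 SE of truth."""
        rng = np.random.default_rng(42)
        x = rng.random(2000)
        beta0, beta1 = -1.0, 2.5
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        labels = np.where(rng.random(2000) < p, "presence", "pseudo_absence")
        fit = fit_glm(make_table(x, labels))
        est = np.array([fit.params["intercept"], fit.params["coef"][0]])
        se = fit.params["se"]
        assert np.all(np.abs(est - [beta0, beta1]) < 3 * se)


class TestGBM:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_gbm(make_table([0.1, 0.9], ["presence", "presence"]))

    def test_single_stump_separates_thresholded_data(self):
        x = np.concatenate([np.linspace(0.6, 1.0, 10),
                            np.linspace(0.0, 0.4, 10)])
        labels = ["presence"] * 10 + ["pseudo_absence"] * 10
        t = make_table(x, labels)
        fit = fit_gbm(t, n_stages=1, learning_rate=1.0, max_depth=1)
        pred = fit.predict(t)
        assert ((pred > 0.5) == (np.arange(20) < 10)).all()

    def test_training_deviance_non_increasing(self):
        t = toy_table(seed=3)
        fit = fit_gbm(t, n_stages=50)
        dev = fit.params["train_deviance"]
        assert np.all(np.diff(dev) <= 1e-9)

    def test_gbm_beats_glm_on_step_function(self):
        """A sharp nonlinear (step) response favours trees over the linear
        logit on held-out AUC in most replicates."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.random(400)
            p = np.where((x > 0.3) & (x < 0.5), 0.95, 0.05)
            labels = np.where(rng.random(400) < p, "presence",
                              "pseudo_absence")
            if len(set(labels)) < 2:
                continue
            t = make_table(x, labels)
            recs = cross_validate(
                {"glm": fit_glm,
                 "gbm": lambda tt: fit_gbm(tt, n_stages=100)},
                t, n_reps=1, seed=seed)
            auc = {r.kind: r.auc for r in recs}
            wins += auc["gbm"] > auc["glm"]
        assert wins / n_seeds >= 0.80


class TestMaxent:
    def test_no_signal_shrinks_weights(self):
        # presences drawn from the same cells as the background
        rng = np.random.default_rng(0)
        xb = rng.random(200)
        x = np.concatenate([xb, xb])
        labels = np.array(["presence"] * 200 + ["pseudo_absence"] * 200)
        fit = fit_maxent(make_table(x, labels), l1_penalty=0.05)
        assert np.max(np.abs(fit.params["w"])) < 0.05

    def test_positive_signal_positive_weight(self):
        x = np.concatenate([np.ones(50), np.linspace(0, 1, 100)])
        labels = ["presence"] * 50 + ["pseudo_absence"] * 100
        fit = fit_maxent(make_table(x, labels), features="l",
                         l1_penalty=0.001)
        assert fit.params["w"][0] > 0

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_maxent(make_table([0.5, 0.5, 0.5, 0.5],
                                  ["presence", "pseudo_absence"] * 2))

    def test_unpenalized_fit_matches_moments_and_oracle(self):
        """Penalty 0: the fitted Gibbs expectation of the feature over the
        4-cell background equals the empirical presence mean; the weight
        agrees with direct numeric optimization of the likelihood."""
        xb = np.array([0.0, 0.25, 0.5, 1.0])     # 4-cell landscape feature
        xp = np.array([0.5, 1.0, 0.5])           # presences
        labels = ["presence"] * 3 + ["pseudo_absence"] * 4
        t = make_table(np.concatenate([xp, xb]), labels)
        fit = fit_maxent(t, features="l", l1_penalty=0.0)
        w = fit.params["w"]
        zb = (xb - fit.params["mean"]) / fit.params["scale"]
        zp = (xp - fit.params["mean"]) / fit.params["scale"]
        gibbs = np.exp(zb * w[0])
        gibbs /= gibbs.sum()
        assert (gibbs * zb).sum() == pytest.approx(zp.mean(), abs=1e-6)
        # independent oracle: scipy minimize of the same likelihood
        res = minimize(lambda v: _maxent_nll(v, zp[:, None], zb[:, None])[0],
                       np.zeros(1), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        assert w[0] == pytest.approx(res.x[0], abs=1e-4)

    def test_predictions_in_unit_interval(self):
        t = toy_table(seed=5)
        fit = fit_maxent(t, seed=1)
        p = fit.predict(t)
        assert np.all((p >= 0) & (p <= 1))


class TestAUC:
    def test_perfect_ranking(self):
        assert evaluate_auc([0.9, 0.8, 0.2, 0.1],
                            ["presence", "presence", "pseudo_absence",
                             "pseudo_absence"]) == 1.0

    def test_all_ties(self):
        assert evaluate_auc([0.5] * 6, ["presence"] * 3
                            + ["pseudo_absence"] * 3) == 0.5

    def test_worked_example(self):
        scores = [0.9, 0.4, 0.8, 0.2]
        labels = ["presence", "presence", "pseudo_absence", "pseudo_absence"]
        assert evaluate_auc(scores, labels) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            evaluate_auc([0.1, 0.2], ["presence", "presence"])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = int(rng.integers(1, 30)), int(rng.integers(1, 30))
        # coarse grid forces ties
        scores = rng.integers(0, 10, size=n1 + n0) / 10.0
        y = np.array([1] * n1 + [0] * n0)
        u = mannwhitneyu(scores[:n1], scores[n1:],
                         alternative="two-sided").statistic
        assert evaluate_auc(scores, y) == pytest.approx(u / (n1 * n0),
                                                        abs=1e-12)


class TestTSS:
    def test_perfect_separation(self):
        assert evaluate_tss([0.9, 0.8, 0.2, 0.1],
                            [1, 1, 0, 0]) == 1.0

    def test_all_ties_no_skill(self):
        assert evaluate_tss([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.0

    def test_worked_example(self):
        assert evaluate_tss([0.9, 0.4, 0.8, 0.2],
                            [1, 1, 0, 0]) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.random(n)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0], y[-1] = 0, 1
        base = evaluate_tss(scores, y)
        assert evaluate_tss(np.exp(3 * scores), y) == pytest.approx(base)
        assert evaluate_tss(scores ** 3, y) == pytest.approx(base)


class TestCrossValidate:
    def test_three_records_per_kind(self):
        t = toy_table(n1=40, n0=40)
        recs = cross_validate({"glm": fit_glm}, t, n_reps=3, seed=0)
        assert len(recs) == 3
        assert sorted(r.replicate for r in recs) == [0, 1, 2]

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            cross_validate({"glm": fit_glm}, toy_table(), train_fraction=1.0)

    def test_same_seed_same_splits(self):
        t = toy_table(n1=40, n0=40)
        a = cross_validate({"glm": fit_glm}, t, seed=5)
        b = cross_validate({"glm": fit_glm}, t, seed=5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.test_ids, rb.test_ids)
            assert ra.auc == rb.auc

    def test_splits_shared_across_kinds(self):
        t = toy_table(n1=40, n0=40)
        recs = cross_validate({"glm": fit_glm,
                               "gbm": lambda tt: fit_gbm(tt, n_stages=10)},
                              t, seed=2)
        by_kind = {}
        for r in recs:
            by_kind.setdefault(r.kind, []).append(r.test_ids)
        for a, b in zip(by_kind["glm"], by_kind["gbm"]):
            np.testing.assert_array_equal(a, b)


class StubFit:
    """Constant-prediction member for ensemble arithmetic checks."""

    columns = ["woodland"]

    def __init__(self, kind, value):
        self.kind = kind
        self.value = value

    def predict(self, table):
        return np.full(len(table), self.value)


def rec(kind, auc):
    return EvalRecord(kind=kind, replicate=0, auc=auc, tss=0.0,
                      test_ids=np.arange(2))


class TestEnsemble:
    def test_equal_weights_average(self):
        members = [StubFit("glm", 0.2), StubFit("gbm", 0.8)]
        recs = [rec("glm", 0.7), rec("gbm", 0.7)]
        x = pd.DataFrame({"woodland": [0.5]})
        assert ensemble_predict(members, recs, x)[0] == pytest.approx(0.5)

    def test_single_member_identity(self):
        members = [StubFit("glm", 0.37)]
        x = pd.DataFrame({"woodland": [0.1]})
        out = ensemble_predict(members, [rec("glm", 0.9)], x)[0]
        assert out == pytest.approx(0.37)

    def test_closed_form_weighting(self):
        members = [StubFit("glm", 1.0), StubFit("gbm", 0.0)]
        recs = [rec("glm", 0.8), rec("gbm", 0.6)]
        x = pd.DataFrame({"woodland": [0.0]})
        assert ensemble_predict(members, recs, x)[0] == \
            pytest.approx(0.8 / 1.4, abs=1e-12)

    def test_output_bounded_by_members(self):
        rng = np.random.default_rng(0)
        members = [StubFit(k, v) for k, v in
                   zip(("glm", "gbm", "maxent"), rng.random(3))]
        recs = [rec(k, a) for k, a in zip(("glm", "gbm", "maxent"),
                                          (0.6, 0.7, 0.9))]
        x = pd.DataFrame({"woodland": [0.5]})
        preds = [m.predict(x)[0] for m in members]
        out = ensemble_predict(members, recs, x)[0]
        assert min(preds) - 1e-12 <= out <= max(preds) + 1e-12

    def test_glm_only_ensemble_weight_is_one(self):
        ens = build_ensemble(toy_table(n1=40, n0=40), kinds=("glm",), seed=0)
        np.testing.assert_allclose(ens.weights, [1.0])


class TestVariableImportance:
    def test_zero_coefficient_variable_has_zero_importance(self):
        fit = SDMFit(kind="glm", columns=["woodland", "arable"],
                     params={"intercept": 0.0, "coef": np.array([2.0, 0.0])})
        t = toy_table(seed=1)
        imp = variable_importance(fit, t, n_permutations=3, seed=0)
        imp = imp.set_index("variable")["importance"]
        assert imp["arable"] == 0.0
        assert 0.0 <= imp["woodland"] <= 1.0
        assert imp["woodland"] > imp["arable"]

    def test_matches_hand_formula_single_permutation(self):
        fit = SDMFit(kind="glm", columns=["woodland"],
                     params={"intercept": -0.5, "coef": np.array([2.0])})
        t = toy_table(seed=2)[["woodland", "label", "study_area"]]
        imp = variable_importance(fit, t, n_permutations=1, seed=7)
        base = fit.predict(t)
        rng = np.random.default_rng(7)
        shuffled = t.copy()
        shuffled["woodland"] = rng.permutation(
            shuffled["woodland"].to_numpy())
        r = np.corrcoef(base, fit.predict(shuffled))[0, 1]
        assert imp["importance"].iloc[0] == pytest.approx(1 - abs(r),
                                                          abs=1e-12)
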