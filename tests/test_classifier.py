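import json

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from bicyclefinder import classifier as clf
from bicyclefinder import structure_features as sf
from bicyclefinder import synthetic_data as sd


def direct_mle(X, y):
    """Independent maximizer of the binomial log-likelihood (oracle for IRLS)."""
    Xc = np.column_stack([np.ones(len(X)), X])

    def nll(b):
        eta = Xc @ b
        return float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta))

    def grad(b):
        return Xc.T @ (1.0 / (1.0 + np.exp(-(Xc @ b))) - y)

    res = minimize(nll, np.zeros(Xc.shape[1]), jac=grad, method="BFGS", options={"gtol": 1e-12})
    return res.x


def scan_cutoff_oracle(probs, labels, grid=clf.DEFAULT_GRID):
    """Exhaustive scan over the grid with the documented tie-break."""
    best, best_t = None, None
    for t in grid:
        pred = probs >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        if tp + fp == 0:
            continue
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        if recall == 0:
            continue
        key = (abs(precision / recall - 1), -(precision + recall), t)
        if best is None or key < best:
            best, best_t = key, t
    return best_t


class TestFitLogistic:
    def test_intercept_only_balanced_data_gives_zero(self):
        df = pd.DataFrame({"label": ["family"] * 25 + ["non_family"] * 25})
        model = clf.fit_logistic(df, predictors=[])
        assert abs(model.intercept) < 1e-8

    def test_agrees_with_direct_likelihood_maximizer(self):
        beta = {"x1": 0.8, "x2": -0.5, "x3": 0.3}
        df = sd.simulate_features_from_model(0.2, beta, n=500, seed=2)
        model = clf.fit_logistic(df, predictors=list(beta))
        X = df[list(beta)].to_numpy()
        y = (df["label"] == "family").to_numpy(float)
        oracle = direct_mle(X, y)
        fitted = np.array([model.intercept] + [model.coefficients[k] for k in beta])
        assert np.abs(fitted - oracle).max() < 1e-6
        assert not model.training_meta["separation"]

    def test_perfect_separation_flags_and_stays_finite(self):
        df = pd.DataFrame(
            {
                "n_phase2": [10.0] * 20 + [0.0] * 20,
                "label": ["family"] * 20 + ["non_family"] * 20,
            }
        )
        model = clf.fit_logistic(df, predictors=["n_phase2"])
        assert model.training_meta["separation"]
        assert np.isfinite(model.intercept)
        assert np.isfinite(model.coefficients["n_phase2"])

    def test_ridge_refit_recorded_on_separation(self):
        df = pd.DataFrame(
            {
                "n_phase2": [10.0] * 20 + [0.0] * 20,
                "label": ["family"] * 20 + ["non_family"] * 20,
            }
        )
        model = clf.fit_logistic(df, predictors=["n_phase2"], ridge_alpha=1e-3)
        assert model.training_meta["ridge_alpha"] == 1e-3

    def test_single_class_and_nonfinite_inputs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "label": ["family", "family"]})
        with pytest.raises(ValueError, match="both classes"):
            clf.fit_logistic(df, predictors=["x"])
        df2 = pd.DataFrame({"x": [1.0, np.nan], "label": ["family", "non_family"]})
        with pytest.raises(ValueError, match="non-finite"):
            clf.fit_logistic(df2, predictors=["x"])


class TestPredictProb:
    def test_printed_coefficients_at_zero_features(self):
        # all-zero feature vector: p = logistic(intercept)
        coefs = {
            "cds_total_len": -0.0206,
            "gene_span_len": -0.0000642,
            "first_exon_len": -0.00632,
            "last_exon_len": 0.0103,
            "internal_exon_mean_len": -0.0655,
            "n_phase0": -3.32,
            "n_phase1": -1.12,
            "n_phase2": 1.21,
        }
        model = clf.ClassifierModel(coefficients=coefs, intercept=6.26)
        df = pd.DataFrame({k: [0.0] for k in coefs})
        p = clf.predict_prob(model, df)
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-6.26)), abs=1e-12)
        assert p[0] == pytest.approx(0.9981, abs=1e-4)

    def test_zero_model_gives_half(self):
        model = clf.ClassifierModel(coefficients={"x": 0.0}, intercept=0.0)
        p = clf.predict_prob(model, pd.DataFrame({"x": [3.0, -7.0]}))
        assert np.allclose(p, 0.5)

    def test_probability_monotone_in_intercept(self):
        df = pd.DataFrame({"x": [1.0]})
        probs = [
            clf.predict_prob(clf.ClassifierModel({"x": 0.5}, intercept=b), df)[0]
            for b in (0.0, 2.0, 5.0, 20.0)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 0.999999

    def test_missing_predictor_column_is_hard_error(self):
        model = clf.ClassifierModel(coefficients={"x": 1.0, "y": 1.0}, intercept=0.0)
        with pytest.raises(ValueError, match="lacks predictor"):
            clf.predict_prob(model, pd.DataFrame({"x": [1.0]}))


class TestPrecisionRecallCurve:
    def test_enumerated_small_cases(self):
        curve = clf.precision_recall_curve([0.9, 0.9, 0.1], [1, 1, 0])
        i = list(curve.thresholds).index(0.5)
        assert curve.precision[i] == 1.0 and curve.recall[i] == 1.0
        curve = clf.precision_recall_curve([0.9, 0.6, 0.1], [1, 0, 0])
        i = list(curve.thresholds).index(0.5)
        assert curve.precision[i] == 0.5 and curve.recall[i] == 1.0

    def test_threshold_zero_has_full_recall(self):
        rng = np.random.default_rng(0)
        curve = clf.precision_recall_curve(rng.random(50), rng.integers(0, 2, 50))
        assert curve.recall[0] == 1.0

    def test_recall_monotone_and_counts_conserved(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            curve = clf.precision_recall_curve(rng.random(n), labels)
            assert np.all(np.diff(curve.recall) <= 1e-12)
            assert np.all(curve.tp + curve.fp + curve.fn + curve.tn == n)

    def test_no_positives_is_hard_error(self):
        with pytest.raises(ValueError, match="positive"):
            clf.precision_recall_curve([0.5, 0.5], [0, 0])


class TestSelectCutoff:
    def test_exact_equality_point_is_selected(self):
        # constructed curve whose precision equals recall exactly at 0.72
        grid = np.asarray(clf.DEFAULT_GRID)
        precision = np.linspace(0.5, 1.0, 50)
        recall = np.linspace(1.0, 0.5, 50)
        i = list(grid).index(0.72)
        precision[i] = recall[i] = 0.9925
        curve = clf.PRCurve(grid, precision, recall, *(np.ones(50, int),) * 4)
        assert clf.select_cutoff(curve) == 0.72

    def test_matches_exhaustive_scan_on_random_sets(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(10, 300))
            probs = rng.random(n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            curve = clf.precision_recall_curve(probs, labels)
            assert clf.select_cutoff(curve) == scan_cutoff_oracle(probs, labels)

    def test_undefined_everywhere_is_hard_error(self):
        grid = np.asarray(clf.DEFAULT_GRID)
        nanv = np.full(50, np.nan)
        curve = clf.PRCurve(grid, nanv, np.zeros(50), *(np.zeros(50, int),) * 4)
        with pytest.raises(ValueError, match="no threshold"):
            clf.select_cutoff(curve)


@pytest.fixture(scope="module")
def table():
    return sd.simulate_features_from_model(0.0, {"a": 2.0, "b": -1.0}, n=300, seed=4)


@pytest.fixture(scope="module")
def fitted():
    beta = {"a": 1.2, "b": -0.8, "zero": 0.0, "d": 0.5}
    df = sd.simulate_features_from_model(0.3, beta, n=2000, seed=5)
    model = clf.train_classifier(df, predictors=list(beta))
    return df, model


class TestCrossValidate:
    def test_deterministic_under_seed(self, table):
        r1 = clf.cross_validate(table, reps=5, seed=9, predictors=["a", "b"])
        r2 = clf.cross_validate(table, reps=5, seed=9, predictors=["a", "b"])
        assert np.array_equal(r1.cutoffs, r2.cutoffs)

    def test_summary_lies_on_grid_with_spread(self, table):
        res = clf.cross_validate(table, reps=30, seed=1, predictors=["a", "b"])
        assert 0 <= res.mean <= 0.98
        assert res.sd >= 0
        assert len(res.cutoffs) + res.n_skipped == 30

    def test_zero_reps_flags_error(self, table):
        res = clf.cross_validate(table, reps=0, seed=0)
        assert res.error is not None
        assert res.cutoffs.size == 0


class TestAblation:
    def test_full_row_reproduces_training_performance(self, fitted):
        df, model = fitted
        rep = clf.ablate_predictors(df, model)
        full = rep[rep.config == "full"].iloc[0]
        assert full.precision == pytest.approx(model.training_meta["training_precision"])
        assert full.recall == pytest.approx(model.training_meta["training_recall"])

    def test_dropping_zero_weight_predictor_is_within_noise(self, fitted):
        df, model = fitted
        rep = clf.ablate_predictors(df, model)
        full = rep[rep.config == "full"].iloc[0]
        drop = rep[rep.config == "drop:zero"].iloc[0]
        assert abs(full.precision - drop.precision) < 0.02
        assert abs(full.recall - drop.recall) < 0.02

    def test_single_noise_predictor_performs_at_chance(self, fitted):
        # a pure-noise predictor yields near-constant probabilities: whatever
        # it calls positive is a chance-level sample, so precision collapses
        # to the base rate while the full model discriminates
        df, model = fitted
        rep = clf.ablate_predictors(df, model)
        single = rep[rep.config == "single:zero"].iloc[0]
        full = rep[rep.config == "full"].iloc[0]
        base_rate = (df.label == "family").mean()
        assert abs(single.precision - base_rate) < 0.05
        assert single.precision < full.precision - 0.1

    def test_report_has_all_configurations(self, fitted):
        df, model = fitted
        rep = clf.ablate_predictors(df, model)
        assert len(rep) == 1 + 2 * len(model.coefficients)

    def test_untrained_model_rejected(self, fitted):
        df, model = fitted
        bare = clf.ClassifierModel(model.coefficients, model.intercept, cutoff=None)
        with pytest.raises(ValueError, match="no cutoff"):
            clf.ablate_predictors(df, bare)


class TestClassifyCandidates:
    def test_empty_table(self):
        model = clf.ClassifierModel({"x": 1.0}, 0.0, cutoff=0.5)
        out = clf.classify_candidates(model, pd.DataFrame({"x": []}))
        assert len(out) == 0
        assert "candidate" in out.columns

    def test_counts_partition_and_determinism(self):
        beta = {"a": 2.0}
        df = sd.simulate_features_from_model(0.0, beta, n=200, seed=6)
        model = clf.train_classifier(df, predictors=["a"])
        out1 = clf.classify_candidates(model, df)
        out2 = clf.classify_candidates(model, df)
        assert out1.equals(out2)
        assert out1.candidate.sum() + (~out1.candidate).sum() == len(df)

    def test_synthetic_genome_candidates_are_mostly_true_family(self, small_genome):
        table = small_genome.truth
        model = clf.train_classifier(table)
        out = clf.classify_candidates(model, table)
        called = out[out.candidate]
        assert len(called) > 0
        assert (called.label == "family").mean() >= 0.95


def test_model_json_round_trip(tmp_path):
    model = clf.ClassifierModel({"a": 1.5, "b": -2.0}, intercept=0.25, cutoff=0.72, training_meta={"n_positive": 3})
    path = tmp_path / "model.json"
    model.to_json(path)
    back = clf.ClassifierModel.from_json(path)
    assert back.coefficients == model.coefficients
    assert back.intercept == model.intercept
    assert back.cutoff == model.cutoff
    payload = json.loads(path.read_text())
    assert set(payload) == {"intercept", "coefficients", "cutoff", "training_meta"}
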