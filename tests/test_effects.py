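"""Partialling-out estimator: splits, cross-fitting, closed-form theta,
cluster-robust sandwich variance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lagdml import (EdgeCandidate, EffectConfig, EligibilityError, LagSpec,
                    SimConfig, build_dml_frame, build_lagged_features,
                    cluster_robust_se, crossfit_residualize,
                    estimate_edge_effect, estimate_theta,
                    make_estimation_split, select_at_risk_rows,
                    select_stable_edges, simulate_panel)
from lagdml.effects import DmlFrame, confidence_interval


def brute_force_cluster_se(d_res, eps, groups):
    """Independent sandwich oracle: explicit sum over clusters, no
    vectorized shortcuts."""
    ss = sum(d * d for d in d_res)
    meat = 0.0
    for g in set(groups):
        s = sum(d * e for d, e, gg in zip(d_res, eps, groups) if gg == g)
        meat += s * s
    G = len(set(groups))
    return float(np.sqrt((G / (G - 1)) * meat / (ss * ss)))


def make_candidate(pred, outcome, stab, coef=0.1, n=100):
    return EdgeCandidate(pred, outcome, stability=stab, mean_coef=coef,
                         selection_count=int(round(stab * n)), n_bootstrap=n)


class TestSelectStableEdges:
    def test_threshold_inclusive(self):
        cands = [make_candidate("a", "use", 0.9),
                 make_candidate("b", "use", 0.6),
                 make_candidate("c", "use", 0.59)]
        kept = select_stable_edges(cands, EffectConfig(stability_threshold=0.6))
        assert [e.predictor for e in kept] == ["a", "b"]

    def test_cap_per_outcome(self):
        cands = [make_candidate("a", "use", 0.9),
                 make_candidate("b", "use", 0.8)]
        kept = select_stable_edges(cands, EffectConfig(max_edges_per_outcome=1))
        assert [e.predictor for e in kept] == ["a"]

    def test_all_below_threshold(self):
        cands = [make_candidate("a", "use", 0.3)]
        assert select_stable_edges(cands, EffectConfig()) == []


class TestEstimationSplit:
    @staticmethod
    def panel(n_subjects=10, rows_per=3):
        return pd.DataFrame({
            "subject_id": np.repeat([f"S{i}" for i in range(n_subjects)], rows_per),
            "step": np.tile(np.arange(rows_per), n_subjects)})

    def test_zero_fraction_keeps_everyone(self):
        est, test = make_estimation_split(self.panel(), EffectConfig(holdout_fraction=0.0))
        assert len(test) == 0 and len(est) == 30

    def test_subject_level_split(self):
        est, test = make_estimation_split(self.panel(), EffectConfig(holdout_fraction=0.2))
        est_s, test_s = set(est.subject_id), set(test.subject_id)
        assert len(est_s) == 8 and len(test_s) == 2
        assert not est_s & test_s

    def test_deterministic(self):
        cfg = EffectConfig(holdout_fraction=0.3, seed=5)
        a = make_estimation_split(self.panel(), cfg)
        b = make_estimation_split(self.panel(), cfg)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_too_few_left(self):
        with pytest.raises(ValueError):
            make_estimation_split(self.panel(2), EffectConfig(holdout_fraction=0.6))


class TestEstimateTheta:
    def test_two_point_example(self):
        theta, eps, _ = estimate_theta(np.array([2.0, -2.0]), np.array([1.0, -1.0]))
        assert theta == 2.0

    def test_exact_fit_zero_residuals(self, rng):
        d = rng.normal(size=50)
        theta, eps, _ = estimate_theta(0.5 * d, d)
        assert theta == pytest.approx(0.5, abs=1e-12)
        assert np.max(np.abs(eps)) < 1e-12

    @given(
        d=arrays(np.float64, 20, elements=st.floats(-5, 5)),
        y=arrays(np.float64, 20, elements=st.floats(-5, 5)),
        intercept=st.booleans(),
    )
    def test_matches_lstsq_oracle(self, d, y, intercept):
        X = np.column_stack([np.ones(20), d]) if intercept else d[:, None]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return
        expected = np.linalg.lstsq(X, y, rcond=None)[0][-1]
        theta, _, _ = estimate_theta(y, d, include_intercept=intercept)
        assert theta == pytest.approx(expected, abs=1e-10)

    def test_degenerate_treatment(self):
        with pytest.raises(ZeroDivisionError):
            estimate_theta(np.ones(5), np.zeros(5))


class TestClusterRobustSE:
    def test_zero_residuals_zero_se(self, rng):
        d = rng.normal(size=30)
        groups = np.repeat(np.arange(10), 3)
        assert cluster_robust_se(d, np.zeros(30), groups) == 0.0

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_robust_se(rng.normal(size=5), rng.normal(size=5),
                              np.zeros(5))

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("intercept", [False, True])
    def test_matches_brute_force(self, seed, intercept):
        rng = np.random.default_rng(seed)
        n_groups = int(rng.integers(3, 8))
        sizes = rng.integers(1, 5, n_groups)
        groups = np.repeat(np.arange(n_groups), sizes)
        n = groups.size
        d = rng.normal(size=n)
        eps = rng.normal(size=n)
        se = cluster_robust_se(d, eps, groups, include_intercept=intercept)
        if not intercept:
            assert se == pytest.approx(brute_force_cluster_se(d, eps, groups),
                                       abs=1e-10)
        else:
            # matrix-sandwich oracle
            X = np.column_stack([np.ones(n), d])
            bread = np.linalg.inv(X.T @ X)
            meat = np.zeros((2, 2))
            for g in range(n_groups):
                s = X[groups == g].T @ eps[groups == g]
                meat += np.outer(s, s)
            V = (n_groups / (n_groups - 1)) * bread @ meat @ bread
            assert se == pytest.approx(np.sqrt(V[1, 1]), abs=1e-10)

    def test_reduces_to_hc_with_singleton_clusters(self, rng):
        n = 500
        d, eps = rng.normal(size=n), rng.normal(size=n)
        se = cluster_robust_se(d, eps, np.arange(n))
        ss = d @ d
        hc_var = float((d * eps) @ (d * eps)) / (ss * ss)
        assert se == pytest.approx(np.sqrt(hc_var * n / (n - 1)), abs=1e-12)

    def test_cluster_duplication_closed_form(self, rng):
        d, eps = rng.normal(size=40), rng.normal(size=40)
        groups = np.repeat(np.arange(10), 4)
        se1 = cluster_robust_se(d, eps, groups)
        d2, eps2 = np.tile(d, 2), np.tile(eps, 2)
        groups2 = np.concatenate([groups, groups + 10])
        se2 = cluster_robust_se(d2, eps2, groups2)
        G = 10
        # doubling every cluster: meat x2, bread /2, correction changes
        expected = se1 * np.sqrt((2 * G / (2 * G - 1)) * ((G - 1) / G) / 2)
        assert se2 == pytest.approx(expected, abs=1e-12)


def toy_frame(rng, n_subjects=30, rows_per=4, p=3):
    n = n_subjects * rows_per
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{j}_L1" for j in range(p)])
    return DmlFrame(
        Y=rng.normal(size=n), D=rng.normal(size=n), X=X,
        groups=np.repeat([f"S{i}" for i in range(n_subjects)], rows_per),
        treatment="t_L1", outcome="use")


class TestCrossfit:
    def test_frame_invariants(self, rng):
        with pytest.raises(ValueError, match="length"):
            DmlFrame(Y=np.zeros(3), D=np.zeros(2), X=pd.DataFrame({"a": [1.0, 2.0]}),
                     groups=np.zeros(2), treatment="t", outcome="use")
        with pytest.raises(ValueError, match="treatment"):
            DmlFrame(Y=np.zeros(2), D=np.zeros(2), X=pd.DataFrame({"t": [1.0, 2.0]}),
                     groups=np.zeros(2), treatment="t", outcome="use")

    def test_orthogonality_linear_learner(self, rng):
        frame = toy_frame(rng, n_subjects=200)
        cfg = EffectConfig(nuisance_learner="linear", n_folds=5)
        y_res, d_res, _ = crossfit_residualize(frame, cfg)
        n = len(d_res)
        assert abs(d_res.mean()) < 3 / np.sqrt(n)
        for j in range(frame.X.shape[1]):
            r = np.corrcoef(d_res, frame.X.iloc[:, j])[0, 1]
            assert abs(r) < 3 / np.sqrt(n)

    def test_binary_outcome_residuals_bounded(self, rng):
        frame = toy_frame(rng, n_subjects=50)
        frame.Y = np.zeros(len(frame.Y))
        cfg = EffectConfig(nuisance_learner="random_forest", rf_n_estimators=10,
                           n_folds=3)
        y_res, _, _ = crossfit_residualize(frame, cfg)
        assert np.max(np.abs(y_res)) <= 1.0

    def test_two_subjects_leave_one_out(self):
        """With two subjects and two folds, each subject's predictions come
        from a model fit solely on the other subject."""
        X = pd.DataFrame({"a_L1": [1.0, 1.0, 1.0, 1.0]})
        frame = DmlFrame(Y=np.array([1.0, 1.0, 0.0, 0.0]),
                         D=np.array([2.0, 2.0, -2.0, -2.0]), X=X,
                         groups=np.array(["A", "A", "B", "B"]),
                         treatment="t_L1", outcome="use")
        cfg = EffectConfig(nuisance_learner="linear", n_folds=2)
        y_res, d_res, folds = crossfit_residualize(frame, cfg)
        # constant X: the other-subject model predicts that subject's mean
        np.testing.assert_allclose(y_res, [1.0, 1.0, -1.0, -1.0])
        np.testing.assert_allclose(d_res, [4.0, 4.0, -4.0, -4.0])
        assert len(set(folds[:2])) == 1 and folds[0] != folds[2]

    def test_fold_partition_by_subject(self, rng):
        frame = toy_frame(rng, n_subjects=20)
        cfg = EffectConfig(nuisance_learner="linear", n_folds=4)
        _, _, folds = crossfit_residualize(frame, cfg)
        per_subject = pd.DataFrame({"s": frame.groups, "f": folds}).groupby("s")["f"].nunique()
        assert (per_subject == 1).all()

    def test_too_few_subjects(self, rng):
        frame = toy_frame(rng, n_subjects=3)
        with pytest.raises(ValueError, match="subjects"):
            crossfit_residualize(frame, EffectConfig(n_folds=5))


def lagged_sim_panel(seed=0, **kw):
    base = dict(n_subjects=300, n_steps=4, n_predictors=6, n_causal=1,
                hazard_intercepts={"use": -2.0}, causal_coefs={"x001": 0.6},
                confounder_strength=0.0, confounded_predictors=[],
                missing_rate=0.02, seed=seed)
    base.update(kw)
    panel, truth = simulate_panel(SimConfig(**base))
    return build_lagged_features(panel, LagSpec(max_lag=2)), truth


class TestEstimateEdgeEffect:
    CFG = EffectConfig(nuisance_learner="linear", n_folds=4,
                       holdout_fraction=0.0, max_lag=2, seed=1)

    def test_end_to_end_estimate(self):
        panel, _ = lagged_sim_panel()
        est = estimate_edge_effect(panel, ("x001_L1", "use"), self.CFG,
                                   min_rows=100)
        assert est.ci_low <= est.theta <= est.ci_high
        assert est.n_subjects <= est.n_rows
        assert est.n_folds_used == 4
        assert est.theta > 0  # positive causal coefficient

    def test_treatment_excluded_from_covariates(self):
        panel, _ = lagged_sim_panel()
        rows = select_at_risk_rows(panel, "use")
        frame = build_dml_frame(rows, "x001_L1", "use", self.CFG)
        assert "x001_L1" not in frame.X.columns
        assert "x001_L2" in frame.X.columns  # other lags stay by default

    def test_all_treatment_lags_excluded_when_configured(self):
        import dataclasses
        cfg = dataclasses.replace(self.CFG, exclude_all_treatment_lags=True)
        panel, _ = lagged_sim_panel()
        rows = select_at_risk_rows(panel, "use")
        frame = build_dml_frame(rows, "x001_L1", "use", cfg)
        assert not any(c.startswith("x001_L") for c in frame.X.columns)

    def test_eligibility_failure_raises(self):
        panel, _ = lagged_sim_panel(n_subjects=30)
        with pytest.raises(EligibilityError, match="too_few_rows"):
            estimate_edge_effect(panel, ("x001_L1", "use"), self.CFG)

    def test_unknown_treatment(self):
        panel, _ = lagged_sim_panel()
        with pytest.raises(KeyError):
            estimate_edge_effect(panel, ("nope_L1", "use"), self.CFG,
                                 min_rows=100)


def test_confidence_interval_arithmetic():
    lo, hi = confidence_interval(0.01, 0.004, 0.95)
    assert lo == pytest.approx(0.00216, abs=1e-5)
    assert hi == pytest.approx(0.01784, abs=1e-5)
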