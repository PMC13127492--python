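"""Stage 2 — adjusted effect estimation by DML-style partialling-out.

For each stable edge the treatment D is the standardized lagged predictor
and the covariates X are all other lagged variables up to the same lag
order.  Nuisance regressions m(X) = E[Y|X] and g(X) = E[D|X] are cross-fit
over subject-partitioned folds, residuals

    Y~ = Y - m(X),    D~ = D - g(X)

are formed, and the adjusted effect theta is the slope of the residualized
outcome on the residualized treatment, with a cluster-robust sandwich
standard error aggregating score contributions within subjects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .config import EffectConfig
from .discovery import EdgeCandidate
from .panel import (check_eligibility, lagged_feature_columns, preprocess,
                    select_at_risk_rows)

__all__ = [
    "DmlFrame",
    "EffectEstimate",
    "EligibilityError",
    "select_stable_edges",
    "make_estimation_split",
    "build_dml_frame",
    "crossfit_residualize",
    "estimate_theta",
    "cluster_robust_se",
    "confidence_interval",
    "estimate_edge_effect",
    "naive_lagged_slope",
]

_LAG_RE = re.compile(r"_L\d+$")


class EligibilityError(RuntimeError):
    """Raised when an edge's outcome fails the eligibility screen."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"outcome {report.outcome!r} ineligible: "
                         f"{', '.join(report.failure_reasons)}")


@dataclass
class DmlFrame:
    """Aligned arrays for one edge: outcome, treatment, covariates, clusters."""

    Y: np.ndarray
    D: np.ndarray
    X: pd.DataFrame
    groups: np.ndarray
    treatment: str
    outcome: str

    def __post_init__(self) -> None:
        n = len(self.Y)
        if not (len(self.D) == len(self.X) == len(self.groups) == n):
            raise ValueError("Y, D, X, groups must have equal length")
        if self.treatment in self.X.columns:
            raise ValueError("treatment column must be absent from X")


@dataclass
class EffectEstimate:
    """DML output for one edge (theta is per 1 SD of the treatment, on the
    probability scale)."""

    predictor: str
    outcome: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    n_rows: int
    n_subjects: int
    n_folds_used: int
    stability: float = float("nan")

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("theta must lie inside its confidence interval")
        if self.n_subjects > self.n_rows:
            raise ValueError("n_subjects cannot exceed n_rows")


def select_stable_edges(candidates: list[EdgeCandidate],
                        config: EffectConfig) -> list[EdgeCandidate]:
    """Edges with stability >= threshold (inclusive), at most
    ``max_edges_per_outcome`` per outcome in rank order."""
    kept: dict[str, list[EdgeCandidate]] = {}
    for e in candidates:
        if e.stability >= config.stability_threshold:
            kept.setdefault(e.outcome, []).append(e)
    out = []
    for outcome in kept:
        ranked = sorted(kept[outcome],
                        key=lambda e: (-e.stability, -abs(e.mean_coef), e.predictor))
        out.extend(ranked[:config.max_edges_per_outcome])
    return out


def make_estimation_split(panel: pd.DataFrame, config: EffectConfig,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split SUBJECTS into estimation and held-out test sides; every row of
    a subject lands on exactly one side.  Deterministic given the seed."""
    subjects = np.unique(panel["subject_id"].to_numpy())
    rng = np.random.default_rng((config.seed + 211) % (2**31))
    perm = rng.permutation(subjects)
    n_test = int(round(config.holdout_fraction * subjects.size))
    if subjects.size - n_test < 2:
        raise ValueError("holdout_fraction leaves fewer than 2 estimation subjects")
    test_set = set(perm[:n_test])
    mask = panel["subject_id"].map(lambda s: s in test_set).to_numpy()
    return panel[~mask], panel[mask]


def build_dml_frame(rows: pd.DataFrame, treatment: str, outcome: str,
                    config: EffectConfig) -> DmlFrame:
    """Assemble (Y, D, X, groups) from at-risk rows that already carry
    lagged columns.  All lagged variables up to ``config.max_lag`` are
    preprocessed together (median impute + z-score on these rows); the
    treatment column — and, if configured, every lag of the treatment's raw
    variable — is excluded from X.
    """
    columns = lagged_feature_columns(rows, config.max_lag)
    if treatment not in columns:
        raise KeyError(f"treatment {treatment!r} is not a lagged column "
                       f"within max_lag={config.max_lag}")
    ycol = f"y_{outcome}"
    if ycol not in rows.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    matrix, _pre = preprocess(rows, columns)
    if config.exclude_all_treatment_lags:
        raw = _LAG_RE.sub("", treatment)
        drop = [c for c in columns if _LAG_RE.sub("", c) == raw]
    else:
        drop = [treatment]
    return DmlFrame(
        Y=rows[ycol].to_numpy(dtype=float),
        D=matrix[treatment].to_numpy(),
        X=matrix.drop(columns=drop),
        groups=rows["subject_id"].to_numpy(),
        treatment=treatment,
        outcome=outcome,
    )


def _make_learner(config: EffectConfig, random_state: int):
    if config.nuisance_learner == "random_forest":
        return RandomForestRegressor(
            n_estimators=config.rf_n_estimators,
            max_depth=config.rf_max_depth,
            min_samples_leaf=config.rf_min_samples_leaf,
            max_features=config.rf_max_features,
            random_state=random_state,
            n_jobs=1,
        )
    return LinearRegression()


def crossfit_residualize(frame: DmlFrame, config: EffectConfig,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-fit m(X) and g(X) over subject-partitioned folds and return
    (Y_res, D_res, fold_assignment).

    Every row's nuisance predictions come from models that never saw any row
    of that row's subject; this is asserted on every run.
    """
    subjects = frame.groups
    uniq = np.unique(subjects)
    if uniq.size < config.n_folds:
        raise ValueError(f"need >= {config.n_folds} distinct subjects, "
                         f"got {uniq.size}")
    rng = np.random.default_rng((config.seed + 307) % (2**31))
    perm = rng.permutation(uniq)
    fold_of = {s: i % config.n_folds for i, s in enumerate(perm)}
    folds = np.array([fold_of[s] for s in subjects])

    Xmat = frame.X.to_numpy()
    y_res = np.empty(len(frame.Y))
    d_res = np.empty(len(frame.D))
    for k in range(config.n_folds):
        te = folds == k
        tr = ~te
        if te.sum() == 0 or tr.sum() == 0:
            raise ValueError(f"fold {k} has no rows")
        train_subjects = set(subjects[tr])
        assert not (set(subjects[te]) & train_subjects), \
            "cross-fitting hygiene violated: test subject seen in training"
        rs_m = (config.seed + 2 * k) % (2**31)
        rs_g = (config.seed + 2 * k + 1) % (2**31)
        m_hat = _make_learner(config, rs_m).fit(Xmat[tr], frame.Y[tr])
        g_hat = _make_learner(config, rs_g).fit(Xmat[tr], frame.D[tr])
        y_res[te] = frame.Y[te] - m_hat.predict(Xmat[te])
        d_res[te] = frame.D[te] - g_hat.predict(Xmat[te])
    return y_res, d_res, folds


def estimate_theta(y_res: np.ndarray, d_res: np.ndarray,
                   include_intercept: bool = False,
                   ) -> tuple[float, np.ndarray, float]:
    """Residual-on-residual regression: returns (theta, eps, intercept).

    Without an intercept theta = sum(D~ Y~) / sum(D~^2) in closed form; with
    one, the OLS slope.  eps are the fitted residuals Y~ - theta*D~ (-
    intercept).
    """
    y_res = np.asarray(y_res, dtype=float)
    d_res = np.asarray(d_res, dtype=float)
    if y_res.shape != d_res.shape or y_res.size < 2:
        raise ValueError("residual vectors must have equal length >= 2")
    ss = float(d_res @ d_res)
    if ss == 0.0:
        raise ZeroDivisionError(
            "treatment residual is identically zero (treatment fully "
            "explained by covariates)")
    if include_intercept:
        dc = d_res - d_res.mean()
        ssc = float(dc @ dc)
        if ssc == 0.0:
            raise ZeroDivisionError("centered treatment residual is zero")
        theta = float(dc @ (y_res - y_res.mean()) / ssc)
        intercept = float(y_res.mean() - theta * d_res.mean())
    else:
        theta = float(d_res @ y_res / ss)
        intercept = 0.0
    eps = y_res - theta * d_res - intercept
    return theta, eps, intercept


def cluster_robust_se(d_res: np.ndarray, eps: np.ndarray, groups: np.ndarray,
                      include_intercept: bool = False) -> float:
    """Cluster-robust sandwich standard error for theta.

    Scores are summed within clusters; the variance is
    bread * meat * bread with the small-sample factor G/(G-1).  With no
    intercept the bread is the scalar 1/sum(D~^2).
    """
    d_res = np.asarray(d_res, dtype=float)
    eps = np.asarray(eps, dtype=float)
    groups = np.asarray(groups)
    codes, _ = pd.factorize(groups)
    G = int(codes.max()) + 1
    if G < 2:
        raise ValueError("cluster-robust variance undefined with one cluster")
    factor = G / (G - 1)
    if not include_intercept:
        ss = float(d_res @ d_res)
        score_sums = np.bincount(codes, weights=d_res * eps, minlength=G)
        var = factor * float(score_sums @ score_sums) / (ss * ss)
        return float(np.sqrt(var))
    Xd = np.column_stack([np.ones_like(d_res), d_res])
    bread = np.linalg.inv(Xd.T @ Xd)
    s0 = np.bincount(codes, weights=eps, minlength=G)
    s1 = np.bincount(codes, weights=d_res * eps, minlength=G)
    S = np.column_stack([s0, s1])
    meat = S.T @ S
    V = factor * bread @ meat @ bread
    return float(np.sqrt(V[1, 1]))


def confidence_interval(theta: float, se: float, level: float = 0.95,
                        ) -> tuple[float, float]:
    """Normal-quantile confidence interval theta -/+ z * se."""
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    return theta - z * se, theta + z * se


def estimate_edge_effect(panel: pd.DataFrame, edge, config: EffectConfig,
                         min_rows: int = 500,
                         prevalence_bounds: tuple[float, float] = (0.005, 0.995),
                         ) -> EffectEstimate:
    """End-to-end effect estimate for one edge on a lag-augmented panel.

    ``edge`` is an :class:`EdgeCandidate` or a (treatment, outcome) pair.
    Selects at-risk rows, screens eligibility (raising
    :class:`EligibilityError` on failure), builds the DML frame, cross-fits,
    and returns theta with a cluster-robust normal-quantile CI.
    """
    if isinstance(edge, EdgeCandidate):
        treatment, outcome, stability = edge.predictor, edge.outcome, edge.stability
    else:
        treatment, outcome = edge
        stability = float("nan")
    rows = select_at_risk_rows(panel, outcome)
    report = check_eligibility(rows, outcome, min_rows, prevalence_bounds)
    if not report.passed:
        raise EligibilityError(report)
    frame = build_dml_frame(rows, treatment, outcome, config)
    y_res, d_res, folds = crossfit_residualize(frame, config)
    theta, eps, intercept = estimate_theta(y_res, d_res, config.include_intercept)
    se = cluster_robust_se(d_res, eps, frame.groups, config.include_intercept)
    lo, hi = confidence_interval(theta, se, config.ci_level)
    return EffectEstimate(
        predictor=treatment, outcome=outcome, theta=theta, se=se,
        ci_low=lo, ci_high=hi,
        n_rows=len(rows), n_subjects=int(pd.unique(frame.groups).size),
        n_folds_used=int(np.unique(folds).size), stability=stability)


def naive_lagged_slope(panel: pd.DataFrame, treatment: str, outcome: str,
                       ) -> float:
    """Unadjusted benchmark: OLS slope (with intercept) of the interval
    outcome on the standardized lagged treatment over at-risk rows.  Used to
    quantify how much confounding the partialling-out stage removes."""
    rows = select_at_risk_rows(panel, outcome)
    matrix, _ = preprocess(rows, [treatment])
    d = matrix[treatment].to_numpy()
    y = rows[f"y_{outcome}"].to_numpy(dtype=float)
    dc = d - d.mean()
    ss = float(dc @ dc)
    if ss == 0.0:
        raise ZeroDivisionError("treatment has no variance on at-risk rows")
    return float(dc @ (y - y.mean()) / ss)
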