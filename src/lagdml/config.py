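"""Validated configuration objects for every stage of the pipeline.

Each dataclass checks its own invariants in ``__post_init__`` so that a bad
knob fails loudly at construction time rather than deep inside a bootstrap
loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

__all__ = [
    "SimConfig",
    "LagSpec",
    "DiscoveryConfig",
    "EffectConfig",
    "DEFAULT_HAZARD_INTERCEPTS",
]

# Per-interval logit intercepts chosen so that cumulative initiation over a
# five-interval follow-up lands in the rare-event range typical of an
# early-adolescent cohort (roughly 3% to 40% of subjects ever initiating).
DEFAULT_HAZARD_INTERCEPTS: Mapping[str, float] = {
    "alcohol": -2.40,
    "nicotine": -4.50,
    "cannabis": -5.00,
    "any_substance": -2.20,
}


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SimConfig:
    """Generating mechanism of a synthetic longitudinal panel.

    Predictors are Gaussian, AR(1) in time with coefficient
    ``predictor_autocorr``, and block-equicorrelated cross-sectionally
    (blocks of ``block_size`` share correlation ``predictor_block_corr``).
    One latent standard-Gaussian confounder per subject, constant in time,
    loads with ``confounder_loading`` on the ``confounded_predictors`` and
    with ``confounder_strength`` additively on each outcome's hazard scale.

    ``causal_coefs`` maps predictor name -> log-odds (``hazard_model ==
    "logistic"``) or probability increment (``"linear"``) per 1 SD of the
    predictor's lag-1 value; the same causal edges apply to every outcome.
    ``lag2_coefs`` optionally adds lag-2 edges for max-lag stress tests.
    """

    n_subjects: int = 10_000
    n_steps: int = 5
    n_predictors: int = 200
    n_causal: int = 5
    hazard_intercepts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_INTERCEPTS)
    )
    causal_coefs: Mapping[str, float] | None = None
    lag2_coefs: Mapping[str, float] | None = None
    predictor_autocorr: float = 0.6
    predictor_block_corr: float = 0.3
    block_size: int = 10
    confounder_strength: float = 0.5
    confounder_loading: float = 1.0
    confounded_predictors: Sequence[str] | None = None
    missing_rate: float = 0.05
    hazard_model: str = "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_subjects > 0, "n_subjects must be positive")
        _check(self.n_steps > 0, "n_steps must be positive")
        _check(self.n_predictors > 0, "n_predictors must be positive")
        _check(0 <= self.n_causal <= self.n_predictors,
               "n_causal must be in [0, n_predictors]")
        _check(self.block_size > 0, "block_size must be positive")
        _check(0.0 <= self.predictor_autocorr < 1.0,
               "predictor_autocorr must be in [0, 1)")
        _check(0.0 <= self.predictor_block_corr < 1.0,
               "predictor_block_corr must be in [0, 1)")
        _check(self.confounder_strength >= 0.0,
               "confounder_strength must be >= 0")
        _check(0.0 <= self.missing_rate < 1.0, "missing_rate must be in [0, 1)")
        _check(self.hazard_model in ("logistic", "linear"),
               f"unknown hazard_model {self.hazard_model!r}")
        _check(len(self.hazard_intercepts) > 0,
               "at least one outcome intercept required")
        for outcome, alpha in self.hazard_intercepts.items():
            if self.hazard_model == "logistic":
                _check(alpha < 0.0,
                       f"intercept for {outcome!r} implies baseline hazard >= 0.5")
            else:
                _check(0.0 < alpha < 0.5,
                       f"linear-hazard intercept for {outcome!r} must be in (0, 0.5)")

    @property
    def predictor_names(self) -> list[str]:
        return [f"x{j + 1:03d}" for j in range(self.n_predictors)]

    @property
    def outcomes(self) -> list[str]:
        return list(self.hazard_intercepts)


@dataclass
class LagSpec:
    """How far back lagged copies of each predictor are constructed.

    Columns follow the ``_L<k>`` suffix convention: ``p_L1`` is the value
    one interval before the current row, ``p_L2`` two intervals before.
    """

    max_lag: int = 2
    suffix_pattern: str = "_L{k}"

    def __post_init__(self) -> None:
        _check(self.max_lag >= 1, "max_lag must be >= 1")
        _check("{k}" in self.suffix_pattern, "suffix_pattern must contain {k}")

    def suffix(self, k: int) -> str:
        return self.suffix_pattern.format(k=k)


@dataclass
class DiscoveryConfig:
    """Knobs for stage 1: sparse lagged prediction + bootstrap stability.

    ``penalty_strength`` is the per-sample elastic-net penalty; the "cv"
    sentinel selects it once on the full eligible data by subject-grouped
    cross-validated log-loss (1-SE rule) and then holds it fixed across all
    bootstrap replicates.
    """

    n_bootstrap: int = 100
    l1_ratio: float = 0.5
    penalty_strength: float | str = "cv"
    class_weighting: str = "balanced"
    min_rows: int = 500
    prevalence_bounds: tuple[float, float] = (0.005, 0.995)
    max_lag: int = 2
    use_deltas: bool = False
    seed: int = 0
    nonzero_tol: float = 1e-8
    redraw_cap: int = 10
    cv_grid: tuple[float, ...] = (0.001, 0.003, 0.01, 0.03, 0.1)
    cv_folds: int = 3
    solver_tol: float = 1e-3
    solver_max_iter: int = 500

    def __post_init__(self) -> None:
        _check(self.n_bootstrap >= 2, "n_bootstrap must be >= 2")
        _check(0.0 < self.l1_ratio <= 1.0, "l1_ratio must be in (0, 1]")
        if isinstance(self.penalty_strength, str):
            _check(self.penalty_strength == "cv",
                   "penalty_strength must be a positive number or 'cv'")
        else:
            _check(self.penalty_strength > 0, "penalty_strength must be > 0")
        _check(self.class_weighting in ("balanced", "none"),
               f"unknown class_weighting {self.class_weighting!r}")
        lo, hi = self.prevalence_bounds
        _check(0.0 <= lo < hi <= 1.0, "prevalence_bounds must be ordered in [0, 1]")
        _check(self.max_lag >= 1, "max_lag must be >= 1")
        _check(self.nonzero_tol >= 0.0, "nonzero_tol must be >= 0")
        _check(self.redraw_cap >= 1, "redraw_cap must be >= 1")
        _check(self.cv_folds >= 2, "cv_folds must be >= 2")
        _check(all(g > 0 for g in self.cv_grid), "cv_grid entries must be > 0")


@dataclass
class EffectConfig:
    """Knobs for stage 2: DML partialling-out on stable edges."""

    stability_threshold: float = 0.6
    max_edges_per_outcome: int = 25
    n_folds: int = 5
    nuisance_learner: str = "random_forest"
    rf_n_estimators: int = 500
    rf_max_depth: int | None = None
    rf_min_samples_leaf: int = 5
    rf_max_features: float | str = 1.0
    ci_level: float = 0.95
    include_intercept: bool = False
    seed: int = 0
    holdout_fraction: float = 0.2
    max_lag: int = 2
    exclude_all_treatment_lags: bool = False

    def __post_init__(self) -> None:
        _check(0.0 <= self.stability_threshold <= 1.0,
               "stability_threshold must be in [0, 1]")
        _check(self.max_edges_per_outcome >= 1,
               "max_edges_per_outcome must be >= 1")
        _check(self.n_folds >= 2, "n_folds must be >= 2")
        _check(self.nuisance_learner in ("random_forest", "linear"),
               f"unknown nuisance_learner {self.nuisance_learner!r}")
        _check(self.rf_n_estimators >= 1, "rf_n_estimators must be >= 1")
        _check(self.rf_min_samples_leaf >= 1, "rf_min_samples_leaf must be >= 1")
        _check(0.0 < self.ci_level < 1.0, "ci_level must be in (0, 1)")
        _check(0.0 <= self.holdout_fraction < 1.0,
               "holdout_fraction must be in [0, 1)")
        _check(self.max_lag >= 1, "max_lag must be >= 1")


def asdict_shallow(cfg) -> dict:
    """Dataclass -> plain dict with JSON-friendly values (for fingerprints)."""
    out = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, Mapping):
            v = dict(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out
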