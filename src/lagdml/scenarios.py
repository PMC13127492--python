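"""Named study scenarios and reference cohort counts.

These are the fixed conditions under which the package validates itself:
the published analytic-cohort initiation counts (for summary arithmetic)
and three synthetic-panel scenarios exercising confounding removal,
confidence-interval calibration, and edge recovery.  Scenario parameters
are part of the validation design and are not tuned per run; only the seed
varies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DiscoveryConfig, EffectConfig, LagSpec, SimConfig

__all__ = [
    "ABCD_COHORT_COUNTS",
    "cohort_panel_from_counts",
    "confounded_effect_scenario",
    "linear_coverage_scenario",
    "recovery_scenario",
]

# Initiation counts (ever-initiators / analytic N) in the ABCD Study
# release 5.1 analytic cohort of 11,868 children followed from age ~10.
ABCD_COHORT_COUNTS: dict[str, tuple[int, int]] = {
    "alcohol": (4330, 11868),
    "nicotine": (646, 11868),
    "cannabis": (406, 11868),
    "any_substance": (4706, 11868),
}


def cohort_panel_from_counts(counts: dict[str, tuple[int, int]] | None = None,
                             ) -> pd.DataFrame:
    """Build a minimal single-interval panel realizing given initiation
    counts, for exercising cohort summary arithmetic on published totals."""
    counts = ABCD_COHORT_COUNTS if counts is None else counts
    n_total = max(n for _, n in counts.values())
    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i + 1:06d}" for i in range(n_total)]),
        "step": np.zeros(n_total, dtype=int),
    }
    for outcome, (n_init, n_tot) in counts.items():
        if n_tot != n_total:
            raise ValueError("all outcomes must share the denominator")
        y = np.zeros(n_total, dtype=int)
        y[:n_init] = 1
        data[f"y_{outcome}"] = y
        data[f"m_{outcome}"] = np.ones(n_total, dtype=int)
    return pd.DataFrame(data)


def confounded_effect_scenario(seed: int):
    """Logistic-hazard panel with a strong latent confounder.

    2,000 subjects x 5 intervals, 10 predictors, two true lag-1 effects
    (+0.5 / -0.5 log-odds per SD); the confounder loads on the causal
    predictors and two proxies and on the hazard (strength 1.0).  The DML
    stage must out-perform the naive lag-1 slope here.  Forests are kept
    small so a replicate runs in seconds.
    """
    sim = SimConfig(
        n_subjects=2000, n_steps=5, n_predictors=10, n_causal=2,
        hazard_intercepts={"use": -2.4},
        causal_coefs={"x001": 0.5, "x006": -0.5},
        predictor_autocorr=0.6, predictor_block_corr=0.3, block_size=5,
        confounder_strength=1.0, confounder_loading=1.0,
        confounded_predictors=["x001", "x006", "x002", "x007"],
        missing_rate=0.02, seed=seed,
    )
    lag = LagSpec(max_lag=2)
    eff = EffectConfig(
        n_folds=5, nuisance_learner="random_forest",
        rf_n_estimators=40, rf_max_depth=7, rf_min_samples_leaf=10,
        rf_max_features=0.3, holdout_fraction=0.0, max_lag=2, seed=seed,
    )
    edge = ("x001_L1", "use")
    return sim, lag, eff, edge


def linear_coverage_scenario(seed: int):
    """Linear-hazard panel for confidence-interval calibration.

    The hazard is linear on the probability scale (intercept 0.10, effects
    +-0.02 per SD), so the probability-scale estimand is exactly the
    generating coefficient and linear nuisance models are correctly
    specified.  No latent confounder: this scenario isolates the sampling
    behaviour of the cross-fitted estimator and its cluster-robust CI.
    """
    sim = SimConfig(
        n_subjects=2000, n_steps=5, n_predictors=15, n_causal=3,
        hazard_model="linear",
        hazard_intercepts={"use": 0.10},
        causal_coefs={"x001": 0.02, "x006": -0.015, "x011": 0.02},
        predictor_autocorr=0.6, predictor_block_corr=0.3, block_size=5,
        confounder_strength=0.0, confounded_predictors=[],
        missing_rate=0.02, seed=seed,
    )
    lag = LagSpec(max_lag=1)
    eff = EffectConfig(n_folds=5, nuisance_learner="linear",
                       holdout_fraction=0.0, max_lag=1, seed=seed)
    edge = ("x001_L1", "use")
    return sim, lag, eff, edge


def recovery_scenario(seed: int):
    """Discovery calibration: 5 true lag-1 effects among 100 predictors.

    2,000 subjects x 5 intervals; signal magnitudes 0.5-0.8 log-odds per
    SD, one signal per correlation block, no latent confounder (so that
    every non-causal predictor is a genuine null rather than a predictive
    proxy).  Discovery runs at 50 bootstraps with lag-1 features.
    """
    sim = SimConfig(
        n_subjects=2000, n_steps=5, n_predictors=100, n_causal=5,
        hazard_intercepts={"use": -2.4},
        predictor_autocorr=0.6, predictor_block_corr=0.3, block_size=10,
        confounder_strength=0.0, confounded_predictors=[],
        missing_rate=0.02, seed=seed,
    )
    disc = DiscoveryConfig(n_bootstrap=50, max_lag=1, seed=seed,
                           solver_tol=1e-3, solver_max_iter=300)
    return sim, disc
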