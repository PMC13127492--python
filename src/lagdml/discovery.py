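"""Stage 1 — Granger-style edge discovery with bootstrap stability.

For one outcome, fits class-weighted elastic-net logistic regression of the
interval-level initiation indicator on all lagged predictors, repeats the
fit over subject-level bootstrap resamples, and scores each (lagged
predictor -> outcome) edge by the proportion of replicates in which it
received a non-zero coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss

from .config import DiscoveryConfig
from .panel import Preprocessor, lagged_feature_columns

__all__ = [
    "EdgeCandidate",
    "fit_sparse_model",
    "choose_penalty",
    "subject_bootstrap_indices",
    "bootstrap_stability",
    "rank_edges",
    "export_edges",
]


@dataclass
class EdgeCandidate:
    """A directed lagged-predictor -> outcome edge with its stability score."""

    predictor: str
    outcome: str
    stability: float
    mean_coef: float
    selection_count: int
    n_bootstrap: int

    def __post_init__(self) -> None:
        if self.selection_count != round(self.stability * self.n_bootstrap):
            raise ValueError("stability must equal selection_count / n_bootstrap")
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError("stability must be in [0, 1]")


def _regularization_C(penalty: float, n_rows: int) -> float:
    # sklearn minimizes C * sum(loss) + penalty(w); a per-sample penalty
    # `lambda` therefore maps to C = 1 / (lambda * n).
    return 1.0 / (penalty * n_rows)


def fit_sparse_model(X: np.ndarray | pd.DataFrame, y: np.ndarray,
                     config: DiscoveryConfig,
                     penalty_strength: float | None = None,
                     ) -> tuple[np.ndarray, float]:
    """Elastic-net logistic regression; returns (coefficients, intercept).

    Class weights are inversely proportional to class frequencies when
    ``class_weighting == "balanced"``.  Deterministic given data and config.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant; cannot fit")
    penalty = config.penalty_strength if penalty_strength is None else penalty_strength
    if isinstance(penalty, str):
        raise ValueError("penalty_strength 'cv' must be resolved to a number "
                         "before fit_sparse_model (see choose_penalty)")
    model = LogisticRegression(
        solver="saga",
        l1_ratio=config.l1_ratio,
        C=_regularization_C(penalty, X.shape[0]),
        class_weight="balanced" if config.class_weighting == "balanced" else None,
        tol=config.solver_tol,
        max_iter=config.solver_max_iter,
        random_state=config.seed % (2**31),
    )
    model.fit(X, y)
    return model.coef_[0].copy(), float(model.intercept_[0])


def _grouped_folds(subjects: np.ndarray, n_folds: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Fold label per row, partitioning SUBJECTS (seeded permutation)."""
    uniq = np.unique(subjects)
    if uniq.size < n_folds:
        raise ValueError(f"need >= {n_folds} distinct subjects, got {uniq.size}")
    perm = rng.permutation(uniq)
    fold_of = {s: i % n_folds for i, s in enumerate(perm)}
    return np.array([fold_of[s] for s in subjects])


def choose_penalty(X: np.ndarray | pd.DataFrame, y: np.ndarray,
                   subjects: np.ndarray, config: DiscoveryConfig) -> float:
    """Pick the penalty once by subject-grouped CV log-loss with the 1-SE
    rule: the strongest penalty whose mean loss is within one standard error
    of the best.  Holding this fixed across bootstrap replicates keeps
    stability scores free of tuning noise."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng((config.seed + 101) % (2**31))
    folds = _grouped_folds(np.asarray(subjects), config.cv_folds, rng)
    grid = sorted(config.cv_grid)  # ascending penalty strength
    means, ses = [], []
    for penalty in grid:
        losses = []
        for k in range(config.cv_folds):
            tr, te = folds != k, folds == k
            if np.unique(y[tr]).size < 2 or te.sum() == 0:
                continue
            coef, icept = fit_sparse_model(X[tr], y[tr], config, penalty)
            p = 1.0 / (1.0 + np.exp(-(X[te] @ coef + icept)))
            losses.append(log_loss(y[te], p, labels=[0, 1]))
        if not losses:
            raise ValueError("cross-validation folds degenerate; cannot tune penalty")
        losses = np.asarray(losses)
        means.append(losses.mean())
        ses.append(losses.std(ddof=1) / np.sqrt(losses.size) if losses.size > 1 else 0.0)
    means, ses = np.asarray(means), np.asarray(ses)
    best = int(np.argmin(means))
    cutoff = means[best] + ses[best]
    eligible = [i for i in range(len(grid)) if means[i] <= cutoff]
    return float(grid[max(eligible)])


def subject_bootstrap_indices(subjects: np.ndarray, rng: np.random.Generator,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """One subject-level bootstrap draw: returns (row indices, sampled
    subject labels).  A sampled subject contributes ALL of its rows; a
    subject drawn twice contributes its rows twice."""
    subjects = np.asarray(subjects)
    uniq, inverse = np.unique(subjects, return_inverse=True)
    rows_of = [np.flatnonzero(inverse == i) for i in range(uniq.size)]
    sampled = rng.integers(0, uniq.size, uniq.size)
    idx = np.concatenate([rows_of[s] for s in sampled])
    return idx, uniq[sampled]


def bootstrap_stability(rows: pd.DataFrame, outcome: str,
                        config: DiscoveryConfig) -> list[EdgeCandidate]:
    """Subject-level bootstrap stability selection for one outcome.

    Each replicate resamples subjects with replacement (a sampled subject
    contributes all of its rows, duplicated subjects duplicated rows),
    recomputes preprocessing statistics on the resampled rows, refits the
    sparse model at the fixed penalty, and records which predictors receive
    coefficients with ``|coef| > nonzero_tol``.  A replicate whose resampled
    outcome is constant is redrawn, up to ``redraw_cap`` attempts.
    """
    columns = lagged_feature_columns(rows, config.max_lag, config.use_deltas)
    if not columns:
        raise ValueError("no lagged predictor columns found; build lags first")
    ycol = f"y_{outcome}"
    if ycol not in rows.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    rows = rows.reset_index(drop=True)
    y_full = rows[ycol].to_numpy()
    subjects = rows["subject_id"].to_numpy()

    penalty = config.penalty_strength
    if isinstance(penalty, str):
        pre = Preprocessor().fit(rows, columns)
        penalty = choose_penalty(pre.transform(rows).to_numpy(), y_full,
                                 subjects, config)

    rng = np.random.default_rng(config.seed % (2**31))

    counts = np.zeros(len(columns))
    coef_sums = np.zeros(len(columns))
    for _b in range(config.n_bootstrap):
        for attempt in range(config.redraw_cap + 1):
            idx, _sampled = subject_bootstrap_indices(subjects, rng)
            y_b = y_full[idx]
            if np.unique(y_b).size >= 2:
                break
        else:
            raise RuntimeError(
                f"outcome {outcome!r}: bootstrap outcome constant after "
                f"{config.redraw_cap} redraws")
        boot = rows.iloc[idx]
        X_b, _ = _preprocess_matrix(boot, columns)
        coef, _ = fit_sparse_model(X_b, y_b, config, penalty)
        selected = np.abs(coef) > config.nonzero_tol
        counts += selected
        coef_sums += np.where(selected, coef, 0.0)

    out = []
    for j, name in enumerate(columns):
        if counts[j] > 0:
            c = int(counts[j])
            out.append(EdgeCandidate(
                predictor=name, outcome=outcome,
                stability=c / config.n_bootstrap,
                mean_coef=float(coef_sums[j] / c),
                selection_count=c, n_bootstrap=config.n_bootstrap))
    return out


def _preprocess_matrix(rows: pd.DataFrame, columns: list[str]):
    pre = Preprocessor().fit(rows, columns)
    return pre.transform(rows).to_numpy(), pre


def rank_edges(candidates: list[EdgeCandidate],
               top_k: int | None = None) -> pd.DataFrame:
    """Rank candidates: stability desc, then |mean_coef| desc, then
    predictor name asc."""
    if not candidates:
        return pd.DataFrame(columns=["predictor", "outcome", "stability",
                                     "mean_coef", "selection_count"])
    ordered = sorted(candidates,
                     key=lambda e: (-e.stability, -abs(e.mean_coef), e.predictor))
    if top_k is not None:
        ordered = ordered[:top_k]
    return pd.DataFrame([{
        "predictor": e.predictor, "outcome": e.outcome,
        "stability": e.stability, "mean_coef": e.mean_coef,
        "selection_count": e.selection_count,
    } for e in ordered])


def export_edges(candidates: list[EdgeCandidate], path: str | Path,
                 top_k: int | None = None) -> pd.DataFrame:
    """Write the ranked edge table as delimited text; returns the table."""
    table = rank_edges(candidates, top_k)
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","
    table.to_csv(path, sep=sep, index=False)
    return table
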