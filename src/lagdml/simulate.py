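"""Synthetic longitudinal panels with known lagged causal structure.

The generator emulates a large adolescent-cohort panel: ~10^4 subjects
observed over a handful of discrete follow-up intervals, hundreds of
correlated time-varying predictors, rare binary initiation outcomes with an
absorbing at-risk state, and a latent per-subject confounder that loads on
both a subset of predictors and the hazard.  Because the mechanism is known,
a Monte-Carlo oracle for the true adjusted effect of any (predictor, lag,
outcome) edge is available, which is what makes the discovery and
effect-estimation stages testable without access-controlled cohort data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "SimTruth",
    "simulate_panel",
    "true_effect_oracle",
    "write_panel",
    "read_panel",
    "write_truth",
    "read_truth",
]

Edge = tuple[str, int, str]  # (predictor, lag, outcome)

_PROB_CLIP = 1e-4


@dataclass
class SimTruth:
    """Ground truth of a simulated panel: the edges that actually exist."""

    config: SimConfig
    causal_edges: set[Edge]
    causal_coefs: dict[Edge, float]
    confounder_loadings: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if set(self.causal_coefs) != self.causal_edges:
            raise ValueError("causal_coefs keys must equal causal_edges")
        names = set(self.config.predictor_names)
        for pred, _lag, _out in self.causal_edges:
            if pred not in names:
                raise ValueError(f"causal edge predictor {pred!r} not in panel")


def _resolve_lag_coefs(config: SimConfig, lag: int) -> dict[str, float]:
    """Per-predictor coefficients at the given lag, with spread defaults.

    Default lag-1 signals are placed one per correlation block (indices 0,
    block_size, 2*block_size, ...) with magnitudes evenly spaced on
    [0.5, 0.8] and alternating sign, so that each signal has correlated
    null neighbours but signals are not collinear with each other.
    """
    names = config.predictor_names
    if lag == 1:
        if config.causal_coefs is not None:
            return dict(config.causal_coefs)
        if config.n_causal == 0:
            return {}
        idx = [(i * config.block_size) % config.n_predictors
               for i in range(config.n_causal)]
        if len(set(idx)) < config.n_causal:  # more signals than blocks
            idx = list(range(config.n_causal))
        mags = np.linspace(0.5, 0.8, config.n_causal)
        return {names[j]: float(m if i % 2 == 0 else -m)
                for i, (j, m) in enumerate(zip(idx, mags))}
    if lag == 2:
        return dict(config.lag2_coefs) if config.lag2_coefs else {}
    raise ValueError(f"unsupported lag {lag}")


def _resolve_confounded(config: SimConfig, lag1: dict[str, float]) -> dict[str, float]:
    """Predictor -> confounder loading; default: the causal predictors plus
    an equal number of non-causal proxies."""
    if config.confounded_predictors is not None:
        chosen = list(config.confounded_predictors)
    else:
        chosen = list(lag1)
        n_extra = len(lag1)
        for name in config.predictor_names:
            if n_extra == 0:
                break
            if name not in lag1:
                chosen.append(name)
                n_extra -= 1
    names = set(config.predictor_names)
    for name in chosen:
        if name not in names:
            raise ValueError(f"confounded predictor {name!r} not in panel")
    return {name: config.confounder_loading for name in chosen}


def _draw_latents(config: SimConfig, rng: np.random.Generator,
                  loadings: dict[str, float]):
    """Draw (U, Z) where U is the latent confounder and Z the standardized
    predictor array of shape (n_subjects, n_steps, n_predictors)."""
    n, T, p = config.n_subjects, config.n_steps, config.n_predictors
    phi = config.predictor_autocorr
    rho = config.predictor_block_corr
    block_of = np.arange(p) // config.block_size
    n_blocks = int(block_of.max()) + 1

    def innovations() -> np.ndarray:
        g = rng.standard_normal((n, n_blocks))
        z = rng.standard_normal((n, p))
        return np.sqrt(rho) * g[:, block_of] + np.sqrt(1.0 - rho) * z

    U = rng.standard_normal(n)
    W = np.empty((n, T, p))
    W[:, 0, :] = innovations()
    for t in range(1, T):
        W[:, t, :] = phi * W[:, t - 1, :] + np.sqrt(1.0 - phi * phi) * innovations()

    load = np.zeros(p)
    for j, name in enumerate(config.predictor_names):
        if name in loadings:
            load[j] = loadings[name]
    X = W + load[None, None, :] * U[:, None, None]
    sd = np.sqrt(1.0 + load * load)
    Z = X / sd[None, None, :]
    return U, X, Z


def _hazard_probs(config: SimConfig, U: np.ndarray, Z: np.ndarray,
                  outcome: str, beta1: np.ndarray, beta2: np.ndarray) -> np.ndarray:
    """Per-interval event probabilities, shape (n_subjects, n_steps).

    The hazard at step t >= 1 depends on the PREVIOUS interval's
    standardized predictors (true edges are lag-1; optional lag-2 terms use
    t-2).  At step 0 no history exists, so only the intercept and the
    confounder act.
    """
    n, T, _ = Z.shape
    alpha = config.hazard_intercepts[outcome]
    gamma = config.confounder_strength
    eta = np.empty((n, T))
    eta[:, 0] = alpha + gamma * U
    for t in range(1, T):
        lin = alpha + gamma * U + Z[:, t - 1, :] @ beta1
        if t >= 2 and beta2.any():
            lin = lin + Z[:, t - 2, :] @ beta2
        eta[:, t] = lin
    if config.hazard_model == "logistic":
        return 1.0 / (1.0 + np.exp(-eta))
    return np.clip(eta, _PROB_CLIP, 1.0 - _PROB_CLIP)


def _coef_vector(config: SimConfig, coefs: Mapping[str, float]) -> np.ndarray:
    beta = np.zeros(config.n_predictors)
    for j, name in enumerate(config.predictor_names):
        if name in coefs:
            beta[j] = coefs[name]
    return beta


def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a tidy panel (one row per subject x step) and its truth.

    Returns a DataFrame with columns ``subject_id``, ``step``, per-outcome
    ``y_<outcome>`` / ``m_<outcome>`` pairs, and predictor columns
    ``x001..``; missing predictor values are NaN (injected completely at
    random at ``missing_rate``).  Initiation is absorbing: after the first
    event for an outcome, ``m`` is 0 and ``y`` stays 0.
    """
    rng = np.random.default_rng(config.seed)
    lag1 = _resolve_lag_coefs(config, 1)
    lag2 = _resolve_lag_coefs(config, 2)
    loadings = _resolve_confounded(config, lag1)
    U, X, Z = _draw_latents(config, rng, loadings)
    beta1 = _coef_vector(config, lag1)
    beta2 = _coef_vector(config, lag2)

    n, T = config.n_subjects, config.n_steps
    data: dict[str, np.ndarray] = {
        "subject_id": np.repeat([f"S{i + 1:06d}" for i in range(n)], T),
        "step": np.tile(np.arange(T), n),
    }
    for outcome in config.outcomes:
        probs = _hazard_probs(config, U, Z, outcome, beta1, beta2)
        u = rng.random((n, T))
        event = u < probs
        # first event step per subject (T if never)
        first = np.where(event.any(axis=1), event.argmax(axis=1), T)
        steps = np.arange(T)[None, :]
        y = (steps == first[:, None]).astype(np.int64)
        m = (steps <= first[:, None]).astype(np.int64)
        n_at_risk = int(m.sum())
        rate = float(y.sum()) / n_at_risk if n_at_risk else 0.0
        if rate >= 0.5:
            raise ValueError(
                f"outcome {outcome!r}: empirical per-interval hazard "
                f"{rate:.3f} >= 0.5; config leaves the rare-event regime")
        data[f"y_{outcome}"] = y.reshape(-1)
        data[f"m_{outcome}"] = m.reshape(-1)

    Xflat = X.reshape(n * T, config.n_predictors)
    if config.missing_rate > 0:
        mask = rng.random(Xflat.shape) < config.missing_rate
        Xflat = np.where(mask, np.nan, Xflat)
    for j, name in enumerate(config.predictor_names):
        data[name] = Xflat[:, j]

    panel = pd.DataFrame(data)
    edges: set[Edge] = set()
    coefs: dict[Edge, float] = {}
    for outcome in config.outcomes:
        for name, c in lag1.items():
            edges.add((name, 1, outcome))
            coefs[(name, 1, outcome)] = float(c)
        for name, c in lag2.items():
            edges.add((name, 2, outcome))
            coefs[(name, 2, outcome)] = float(c)
    truth = SimTruth(config=config, causal_edges=edges, causal_coefs=coefs,
                     confounder_loadings=loadings, seed=config.seed)
    return panel, truth


def true_effect_oracle(truth: SimTruth, predictor: str, lag: int, outcome: str,
                       n_mc: int = 100_000, seed: int | None = None,
                       return_se: bool = False):
    """Monte-Carlo oracle for the adjusted effect of a lagged edge.

    Simulates fresh subjects from the generating law and averages, over
    at-risk rows with at least ``lag`` intervals of history, the change in
    per-interval initiation probability under a +1 SD intervention on the
    lagged predictor with confounders held at their generated values.  This
    is the probability-scale estimand the partialling-out stage targets.
    """
    config = truth.config
    if predictor not in config.predictor_names:
        raise ValueError(f"unknown predictor {predictor!r}")
    if outcome not in config.outcomes:
        raise ValueError(f"unknown outcome {outcome!r}")
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10_000")
    if lag not in (1, 2):
        raise ValueError("only lag-1 and lag-2 edges are defined")

    coef = truth.causal_coefs.get((predictor, lag, outcome), 0.0)
    if seed is None:
        seed = (truth.seed + 987_654_321) % (2**31)
    rng = np.random.default_rng(seed)
    lag1 = _resolve_lag_coefs(config, 1)
    lag2 = _resolve_lag_coefs(config, 2)
    loadings = _resolve_confounded(config, lag1)
    beta1 = _coef_vector(config, lag1)
    beta2 = _coef_vector(config, lag2)

    usable_per_subject = max(config.n_steps - lag, 1)
    diffs: list[np.ndarray] = []
    total = 0
    while total < n_mc:
        chunk = dataclasses.replace(
            config,
            n_subjects=min(50_000, int(np.ceil((n_mc - total) / usable_per_subject)) + 1),
            missing_rate=0.0,
            seed=int(rng.integers(2**31)),
        )
        U, _X, Z = _draw_latents(chunk, np.random.default_rng(chunk.seed), loadings)
        p0 = _hazard_probs(chunk, U, Z, outcome, beta1, beta2)
        # intervene: +1 SD on the predictor at the given lag shifts the
        # standardized value by 1, i.e. adds `coef` to the linear index of
        # every hazard that reads it.
        if config.hazard_model == "logistic":
            eta0 = np.log(p0 / (1.0 - p0))
            p1 = 1.0 / (1.0 + np.exp(-(eta0 + coef)))
        else:
            p1 = np.clip(p0 + coef, _PROB_CLIP, 1.0 - _PROB_CLIP)
        # at-risk mask: no event strictly before step t
        u = rng.random(p0.shape)
        event = u < p0
        T = chunk.n_steps
        first = np.where(event.any(axis=1), event.argmax(axis=1), T)
        steps = np.arange(T)[None, :]
        at_risk = steps <= first[:, None]
        eligible = at_risk & (steps >= lag)
        d = (p1 - p0)[eligible]
        diffs.append(d)
        total += d.size
        if d.size == 0:  # degenerate panel (n_steps <= lag): nothing to average
            break
    alld = np.concatenate(diffs)
    if alld.size == 0:
        raise ValueError(
            f"no eligible rows for lag-{lag} edge with n_steps={config.n_steps}")
    alld = alld[:n_mc] if alld.size > n_mc else alld
    value = float(alld.mean())
    if return_se:
        se = float(alld.std(ddof=1) / np.sqrt(alld.size)) if alld.size > 1 else 0.0
        return value, se
    return value


# ---------------------------------------------------------------------------
# plain-text I/O

def _sep_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in (".tsv", ".txt") else ","


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a panel as delimited text (comma for .csv, tab for .tsv/.txt);
    empty cell = missing."""
    panel.to_csv(path, sep=_sep_for(path), index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "subject_id" not in df.columns or "step" not in df.columns:
        raise ValueError(f"{path}: panel must have subject_id and step columns")
    return df


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Sidecar ground-truth file (JSON) for test harnesses."""
    payload = {
        "config": {k: (dict(v) if isinstance(v, Mapping) else
                       list(v) if isinstance(v, (tuple, set)) else v)
                   for k, v in dataclasses.asdict(truth.config).items()},
        "causal_edges": sorted(list(e) for e in truth.causal_edges),
        "causal_coefs": [[list(edge), coef] for edge, coef in
                         sorted(truth.causal_coefs.items())],
        "confounder_loadings": truth.confounder_loadings,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    if cfg.get("confounded_predictors") is not None:
        cfg["confounded_predictors"] = list(cfg["confounded_predictors"])
    config = SimConfig(**cfg)
    edges = {tuple(e) for e in payload["causal_edges"]}
    coefs = {tuple(edge): coef for edge, coef in payload["causal_coefs"]}
    return SimTruth(config=config, causal_edges=edges, causal_coefs=coefs,
                    confounder_loadings=payload["confounder_loadings"],
                    seed=payload["seed"])
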