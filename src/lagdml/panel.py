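"""Panel-to-analysis-ready transforms.

Lag/delta feature construction with leak-free temporal ordering, at-risk row
selection for absorbing initiation outcomes, eligibility screening,
median-impute + z-score preprocessing with replayable statistics, and cohort
summary arithmetic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import LagSpec

__all__ = [
    "EligibilityReport",
    "Preprocessor",
    "raw_predictor_columns",
    "lagged_feature_columns",
    "build_lagged_features",
    "build_delta_features",
    "select_at_risk_rows",
    "check_eligibility",
    "preprocess",
    "cohort_summary",
    "round_sig",
]

_LAG_RE = re.compile(r"_L(\d+)$")
_DELTA_RE = re.compile(r"_D1$")
_RESERVED = ("subject_id", "step")


def raw_predictor_columns(panel: pd.DataFrame) -> list[str]:
    """Columns that are raw time-varying predictors (not bookkeeping,
    outcome, at-risk, lagged or delta columns)."""
    out = []
    for c in panel.columns:
        if c in _RESERVED or c.startswith("y_") or c.startswith("m_"):
            continue
        if _LAG_RE.search(c) or _DELTA_RE.search(c):
            continue
        out.append(c)
    return out


def lagged_feature_columns(panel: pd.DataFrame, max_lag: int,
                           include_deltas: bool = False) -> list[str]:
    """Lagged (and optionally delta) columns with lag order <= max_lag.

    Raw, unlagged predictors are deliberately excluded: only features that
    temporally precede the interval may enter any downstream model.
    """
    out = []
    for c in panel.columns:
        m = _LAG_RE.search(c)
        if m and int(m.group(1)) <= max_lag:
            out.append(c)
        elif include_deltas and _DELTA_RE.search(c):
            out.append(c)
    return out


def _sorted_panel(panel: pd.DataFrame) -> pd.DataFrame:
    return panel.sort_values(["subject_id", "step"], kind="mergesort").reset_index(drop=True)


def build_lagged_features(panel: pd.DataFrame, spec: LagSpec) -> pd.DataFrame:
    """Add ``p_Lk`` columns (k = 1..max_lag) holding predictor ``p``'s value
    k intervals earlier for the same subject; missing when no such interval
    exists.  Lags never cross subject boundaries.  The returned panel is
    sorted by (subject_id, step), which makes the operation invariant to the
    input row order.
    """
    df = _sorted_panel(panel)
    raw = raw_predictor_columns(df)
    new_cols = {}
    grouped = df.groupby("subject_id", sort=False)
    for p in raw:
        for k in range(1, spec.max_lag + 1):
            name = p + spec.suffix(k)
            if name in df.columns:
                raise ValueError(f"lag column {name!r} already exists")
            new_cols[name] = grouped[p].shift(k)
    return pd.concat([df, pd.DataFrame(new_cols, index=df.index)], axis=1)


def build_delta_features(panel: pd.DataFrame, spec: LagSpec) -> pd.DataFrame:
    """Add ``p_D1 = p_L1 - p_L2``: the change in ``p`` over the interval
    preceding the row, itself fully in the past.  Missing when either lag is
    missing.  Requires max_lag >= 2.
    """
    if spec.max_lag < 2:
        raise ValueError("delta features require max_lag >= 2")
    df = panel.copy()
    new_cols = {}
    for p in raw_predictor_columns(df):
        l1, l2 = p + spec.suffix(1), p + spec.suffix(2)
        if l1 not in df.columns or l2 not in df.columns:
            raise ValueError(f"lagged columns for {p!r} missing; "
                             "run build_lagged_features first")
        name = p + "_D1"
        if name in df.columns:
            raise ValueError(f"delta column {name!r} already exists")
        new_cols[name] = df[l1] - df[l2]
    return pd.concat([df, pd.DataFrame(new_cols, index=df.index)], axis=1)


def select_at_risk_rows(panel: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Rows where the subject is still at risk for the outcome (m = 1) and
    at least one prior interval exists (step >= 1).  Idempotent."""
    mcol = f"m_{outcome}"
    if mcol not in panel.columns or f"y_{outcome}" not in panel.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    return panel[(panel[mcol] == 1) & (panel["step"] >= 1)]


@dataclass
class EligibilityReport:
    """Whether an outcome has enough usable rows and variation to model."""

    outcome: str
    n_rows: int
    prevalence: float
    passed: bool = field(init=False)
    failure_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.passed = not self.failure_reasons

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "n_rows": self.n_rows,
                "prevalence": self.prevalence, "passed": self.passed,
                "failure_reasons": list(self.failure_reasons)}


def check_eligibility(rows: pd.DataFrame, outcome: str, min_rows: int = 500,
                      prevalence_bounds: tuple[float, float] = (0.005, 0.995),
                      ) -> EligibilityReport:
    """Screen an at-risk row subset: enough rows, prevalence inside bounds,
    outcome not constant.  Reports every triggered reason."""
    y = rows[f"y_{outcome}"] if f"y_{outcome}" in rows.columns else None
    if y is None:
        raise KeyError(f"unknown outcome {outcome!r}")
    n = len(rows)
    prevalence = float(y.mean()) if n else 0.0
    reasons = []
    if n < min_rows:
        reasons.append("too_few_rows")
    if prevalence < prevalence_bounds[0]:
        reasons.append("prevalence_low")
    if prevalence > prevalence_bounds[1]:
        reasons.append("prevalence_high")
    if n == 0 or y.nunique() < 2:
        reasons.append("no_variation")
    return EligibilityReport(outcome=outcome, n_rows=n, prevalence=prevalence,
                             failure_reasons=reasons)


class Preprocessor:
    """Median-impute + z-score transform with stored, replayable statistics.

    Values are coerced to numeric (uncoercible -> missing) and non-finite
    values are treated as missing.  Each column's missing entries are
    replaced by the median of its observed values, falling back to 0 when
    nothing is observed; columns are then standardized.  Columns constant
    after imputation are mapped to all-zero.  Statistics are computed on the
    rows passed to :meth:`fit`, so the identical transform can be replayed
    on held-out rows.
    """

    def __init__(self) -> None:
        self.columns: list[str] | None = None
        self.medians_: dict[str, float] = {}
        self.means_: dict[str, float] = {}
        self.sds_: dict[str, float] = {}

    def fit(self, rows: pd.DataFrame, columns: Sequence[str]) -> "Preprocessor":
        if len(columns) == 0:
            raise ValueError("no columns requested")
        self.columns = list(columns)
        for c in self.columns:
            v = self._coerce(rows[c])
            med = np.nanmedian(v) if np.isfinite(v).any() else 0.0
            if not np.isfinite(med):
                med = 0.0
            filled = np.where(np.isnan(v), med, v)
            mean = float(filled.mean()) if filled.size else 0.0
            sd = float(filled.std(ddof=0)) if filled.size else 0.0
            self.medians_[c] = float(med)
            self.means_[c] = mean
            self.sds_[c] = sd
        return self

    @staticmethod
    def _coerce(series: pd.Series) -> np.ndarray:
        v = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        v[~np.isfinite(v)] = np.nan
        return v

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        if self.columns is None:
            raise RuntimeError("Preprocessor not fitted")
        out = {}
        for c in self.columns:
            v = self._coerce(rows[c])
            v = np.where(np.isnan(v), self.medians_[c], v)
            sd = self.sds_[c]
            out[c] = (v - self.means_[c]) / sd if sd > 1e-12 else np.zeros_like(v)
        return pd.DataFrame(out, index=rows.index)


def preprocess(rows: pd.DataFrame, columns: Sequence[str],
               ) -> tuple[pd.DataFrame, Preprocessor]:
    """Fit a :class:`Preprocessor` on ``rows`` and return the transformed
    feature matrix together with the fitted transformer."""
    pre = Preprocessor().fit(rows, columns)
    return pre.transform(rows), pre


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1))


def cohort_summary(panel: pd.DataFrame, outcomes: Iterable[str]) -> pd.DataFrame:
    """Per-outcome count of subjects ever initiating, total subjects, and
    percentage (3 significant figures, matching typical cohort reporting)."""
    n_total = panel["subject_id"].nunique()
    rows = []
    for outcome in outcomes:
        ycol = f"y_{outcome}"
        if ycol not in panel.columns:
            raise KeyError(f"unknown outcome {outcome!r}")
        initiators = panel.loc[panel[ycol] == 1, "subject_id"].nunique()
        pct = round_sig(100.0 * initiators / n_total, 3) if n_total else 0.0
        rows.append({"outcome": outcome, "n_initiators": int(initiators),
                     "n_total": int(n_total), "percent": pct})
    return pd.DataFrame(rows)
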