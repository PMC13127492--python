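"""End-to-end orchestration: simulate/load -> lag -> discover -> estimate.

The run configuration is a strict-schema YAML file; every artifact is a
delimited-text or JSON file written atomically, stamped with a fingerprint
of the configuration, so identical config + seed reproduces byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import (DiscoveryConfig, EffectConfig, LagSpec, SimConfig,
                     asdict_shallow)
from .discovery import bootstrap_stability, rank_edges
from .effects import (EligibilityError, estimate_edge_effect,
                      make_estimation_split, select_stable_edges)
from .panel import (build_delta_features, build_lagged_features,
                    check_eligibility, select_at_risk_rows)
from .simulate import read_panel, simulate_panel, write_panel, write_truth

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_summaries"]

log = logging.getLogger("lagdml")

_SECTIONS = {"simulate": SimConfig, "lag": LagSpec,
             "discovery": DiscoveryConfig, "effects": EffectConfig}
_TOP_KEYS = {"simulate", "lag", "discovery", "effects", "input_panel",
             "outcomes", "output_dir", "top_k", "use_deltas"}


@dataclass
class RunConfig:
    """Union of the stage configurations plus I/O paths."""

    lag: LagSpec = field(default_factory=LagSpec)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    simulate: SimConfig | None = None
    input_panel: str | None = None
    outcomes: list[str] | None = None
    output_dir: str = "lagdml_run"
    top_k: int = 20
    use_deltas: bool = False

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_panel is None:
            raise ValueError("either a simulation config or an input panel "
                             "path is required")
        if not (self.lag.max_lag == self.discovery.max_lag == self.effects.max_lag):
            raise ValueError("max_lag must agree across lag/discovery/effects")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for section, typ in _SECTIONS.items():
            if section in raw and raw[section] is not None:
                sub = dict(raw[section])
                valid = {f.name for f in dataclasses.fields(typ)}
                bad = set(sub) - valid
                if bad:
                    raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
                if "prevalence_bounds" in sub:
                    sub["prevalence_bounds"] = tuple(sub["prevalence_bounds"])
                if "cv_grid" in sub:
                    sub["cv_grid"] = tuple(sub["cv_grid"])
                kwargs[section] = typ(**sub)
        for key in ("input_panel", "outcomes", "output_dir", "top_k", "use_deltas"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def fingerprint(self) -> str:
        payload = {
            "version": __version__,
            "lag": asdict_shallow(self.lag),
            "discovery": asdict_shallow(self.discovery),
            "effects": asdict_shallow(self.effects),
            "simulate": asdict_shallow(self.simulate) if self.simulate else None,
            "input_panel": self.input_panel,
            "outcomes": self.outcomes,
            "use_deltas": self.use_deltas,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Summary of one pipeline run."""

    eligibility: dict[str, dict]
    n_candidates: dict[str, int]
    n_selected: dict[str, int]
    n_effects: int
    theta_range: tuple[float, float] | None
    skipped_edges: list[dict]
    fingerprint: str
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    _atomic_write_text(path, df.to_csv(index=False))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline, skipping ineligible outcomes with logged
    reasons.  Identical config + seed produces byte-identical tables."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    fingerprint = config.fingerprint()
    try:
        log.info("run fingerprint %s (lagdml %s)", fingerprint, __version__)
        if config.simulate is not None:
            panel, truth = simulate_panel(config.simulate)
            write_panel(panel, outdir / "panel.csv")
            write_truth(truth, outdir / "truth.json")
            log.info("simulated panel: %d subjects x %d steps, %d predictors",
                     config.simulate.n_subjects, config.simulate.n_steps,
                     config.simulate.n_predictors)
        else:
            panel = read_panel(config.input_panel)
            log.info("loaded panel %s (%d rows)", config.input_panel, len(panel))

        outcomes = config.outcomes or sorted(
            c[2:] for c in panel.columns if c.startswith("y_"))
        panel = build_lagged_features(panel, config.lag)
        if config.use_deltas:
            panel = build_delta_features(panel, config.lag)
        est_panel, test_panel = make_estimation_split(panel, config.effects)
        log.info("estimation/test subject split: %d / %d",
                 est_panel["subject_id"].nunique(),
                 test_panel["subject_id"].nunique())

        eligibility: dict[str, dict] = {}
        n_candidates: dict[str, int] = {}
        n_selected: dict[str, int] = {}
        all_candidates = []
        for outcome in outcomes:
            rows = select_at_risk_rows(est_panel, outcome)
            report = check_eligibility(rows, outcome,
                                       config.discovery.min_rows,
                                       config.discovery.prevalence_bounds)
            eligibility[outcome] = report.to_dict()
            if not report.passed:
                log.warning("outcome %s skipped: %s", outcome,
                            ", ".join(report.failure_reasons))
                continue
            cands = bootstrap_stability(rows, outcome, config.discovery)
            n_candidates[outcome] = len(cands)
            all_candidates.extend(cands)
            log.info("outcome %s: %d candidate edges", outcome, len(cands))

        edges_df = rank_edges(all_candidates)
        _atomic_write_csv(edges_df, outdir / "edges.csv")
        selected = select_stable_edges(all_candidates, config.effects)
        for outcome in n_candidates:
            n_selected[outcome] = sum(e.outcome == outcome for e in selected)
        if not selected:
            log.warning("no edges at or above stability threshold %.2f",
                        config.effects.stability_threshold)

        effects_rows, skipped = [], []
        for edge in selected:
            try:
                est = estimate_edge_effect(
                    est_panel, edge, config.effects,
                    config.discovery.min_rows,
                    config.discovery.prevalence_bounds)
            except EligibilityError as err:
                skipped.append({"predictor": edge.predictor,
                                "outcome": edge.outcome,
                                "reason": str(err)})
                log.warning("edge %s -> %s skipped: %s", edge.predictor,
                            edge.outcome, err)
                continue
            effects_rows.append(dataclasses.asdict(est))
        effects_df = pd.DataFrame(
            effects_rows, columns=["predictor", "outcome", "theta", "se",
                                   "ci_low", "ci_high", "n_rows", "n_subjects",
                                   "n_folds_used", "stability"])
        _atomic_write_csv(effects_df, outdir / "effects.csv")

        theta_range = None
        if len(effects_df):
            theta_range = (float(effects_df["theta"].min()),
                           float(effects_df["theta"].max()))
        report = RunReport(eligibility=eligibility, n_candidates=n_candidates,
                           n_selected=n_selected, n_effects=len(effects_df),
                           theta_range=theta_range, skipped_edges=skipped,
                           fingerprint=fingerprint)
        _atomic_write_text(outdir / "report.json",
                           json.dumps(report.to_dict(), indent=2))
        return report
    finally:
        log.removeHandler(fh)
        fh.close()


def render_summaries(edges: pd.DataFrame, effects: pd.DataFrame,
                     top_k: int = 10) -> str:
    """Human-readable per-outcome top-k stability and effect tables."""
    lines = []
    for outcome in sorted(set(edges.get("outcome", pd.Series(dtype=str)))):
        sub = edges[edges["outcome"] == outcome].head(top_k)
        lines.append(f"== top stable predictors: {outcome} ==")
        lines.append(sub.to_string(index=False) if len(sub) else "(none)")
        lines.append("")
    lines.append("== adjusted effects (per 1 SD of predictor) ==")
    if len(effects):
        lines.append(effects.head(top_k).to_string(index=False))
    else:
        lines.append(effects.to_string(index=False))
    return "\n".join(lines) + "\n"
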