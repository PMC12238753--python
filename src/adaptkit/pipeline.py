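"""Reproducible pipeline runs: simulate -> adapt -> fnirs -> stats -> report.

A run directory receives stage outputs, a QC report and a provenance
manifest (config hash, seed, package version); rerunning with the same
config and seed reproduces the numeric outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adaptation import PsoConfig
from .stats.analysis import (
    adaptation_outcome_table,
    analyze_fnirs_contrasts,
    analyze_outcome_lmm,
    analyze_savings,
    savings_table,
)
from .synthetic import CohortConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    n_pwms: int = 28
    n_hc: int = 20
    n_strides: int = 1000
    include_fnirs: bool = False
    fnirs_n_long: int = 48
    fnirs_n_short: int = 8
    include_deadaptation: bool = True
    pso_particles: int = 50
    pso_iters: int = 500
    outcomes: tuple = ("adaptation_magnitude", "early_change_adapt",
                       "after_effect")
    log_level: str = "INFO"

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_pwms=self.n_pwms, n_hc=self.n_hc,
                            n_strides=self.n_strides, seed=self.seed,
                            include_fnirs=self.include_fnirs,
                            fnirs_n_long=self.fnirs_n_long,
                            fnirs_n_short=self.fnirs_n_short,
                            include_deadaptation=self.include_deadaptation)

    def pso_config(self) -> PsoConfig:
        return PsoConfig(n_particles=self.pso_particles,
                         n_iters=self.pso_iters, seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    if isinstance(o, pd.Series):
        return o.to_dict()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_json_default,
                               sort_keys=True))


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> adapt -> (fnirs) -> stats -> report; returns run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump({"config": config.to_dict(), "config_hash": config.digest,
           "version": __version__}, out / "provenance.json")

    # stage: simulate
    cohort = generate_cohort(config.cohort_config())
    write_cohort(cohort, out / "simulate")

    # stage: adapt
    pso = config.pso_config()
    outcomes = adaptation_outcome_table(cohort.trials, pso)
    outcomes.to_csv(out / "outcomes.tsv", sep="\t", index=False,
                    float_format="%.10g")
    fit_cols = [c for c in outcomes.columns
                if c.startswith(("fit_", "deadapt_fit_"))]
    _dump(outcomes[["participant", "visit", "tens"] + fit_cols],
          out / "fits.json")
    savings = savings_table(outcomes)
    savings.to_csv(out / "savings.tsv", sep="\t", index=False,
                   float_format="%.10g")

    # stage: fnirs
    fnirs_report = None
    if config.include_fnirs:
        from .fnirs import process_recording

        rows = []
        beta_rows = []
        roi_beta_rows = []
        qc_all = {}
        for t in cohort.trials:
            if t.fnirs is None:
                continue
            res = process_recording(t.fnirs)
            qc_all[f"{t.participant_id}_v{t.visit}"] = res.qc
            label = {"participant": t.participant_id, "group": t.group,
                     "visit": t.visit, "tens": t.tens}
            for _, r in res.betas.iterrows():
                beta_rows.append({**label, **r.to_dict()})
            for _, r in res.roi_betas.iterrows():
                roi_beta_rows.append({**label, **r.to_dict()})
            for _, r in res.roi_contrasts.iterrows():
                rows.append({**label, "roi": r["roi"],
                             "contrast": r["contrast"]})
        pd.DataFrame(beta_rows).to_csv(out / "fnirs_betas.csv", index=False,
                                       float_format="%.10g")
        pd.DataFrame(roi_beta_rows).to_csv(out / "fnirs_roi_betas.csv",
                                           index=False, float_format="%.10g")
        contrast_table = pd.DataFrame(rows)
        contrast_table.to_csv(out / "fnirs_contrasts.csv", index=False,
                              float_format="%.10g")
        _dump(qc_all, out / "fnirs_qc.json")
        if not contrast_table.empty:
            fnirs_report = analyze_fnirs_contrasts(contrast_table)
            fnirs_report["tests"].to_csv(out / "fnirs_tests.csv", index=False,
                                         float_format="%.10g")

    # stage: stats
    report: dict = {"config_hash": config.digest, "outcome_models": {},
                    "savings": {}}
    for outcome in config.outcomes:
        if outcome not in outcomes.columns or outcomes[outcome].isna().all():
            continue
        res = analyze_outcome_lmm(outcomes, outcome)
        report["outcome_models"][outcome] = {
            "anova": res["anova"], "emm": res["emm"],
            "singular": res["fit"].singular,
            "diagnostics": res["fit"].diagnostics,
        }
    for outcome in ("savings_initial", "savings_early"):
        try:
            res = analyze_savings(savings, outcome)
        except ValueError as e:
            report["savings"][outcome] = {"error": str(e)}
            continue
        report["savings"][outcome] = {"anova": res["anova"], "emm": res["emm"]}
    if fnirs_report is not None:
        report["fnirs_tests"] = fnirs_report["tests"]
    _dump(report, out / "report.json")
    return out
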