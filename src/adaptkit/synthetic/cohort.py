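"""Full synthetic crossover cohort with known injected effects.

Participants (default 28 PwMS + 20 HC) are counterbalanced into TENS
ON-first / ON-second orders; each completes two visits of Baseline (tied) ->
Adaptation (split) -> Deadaptation (tied) stride series, optionally with a
block-design fNIRS recording per visit.  Every stochastic draw's generating
value is stored in the ground-truth record; regenerating with the same
config reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ..stride import StrideSeries
from .fnirs_sim import default_block_design, simulate_fnirs_recording
from .params import CohortConfig, ParticipantParams, PhaseParams, window_decay_factor
from ..adaptation.outcomes import WINDOWS

__all__ = ["SyntheticTrial", "CohortData", "generate_cohort", "write_cohort",
           "read_stride_table"]

PHASES = ("Baseline", "Adaptation", "Deadaptation")


@dataclass
class SyntheticTrial:
    """One participant-visit: stride series per phase (+ optional fNIRS)."""

    participant_id: str
    group: str
    visit: int
    tens: str
    series: dict  # phase -> StrideSeries
    fnirs: object | None = None
    truth: dict = field(default_factory=dict)


@dataclass
class CohortData:
    trials: list
    participants: list
    config: CohortConfig
    truth: pd.DataFrame

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [{"participant": t.participant_id, "group": t.group,
                 "visit": t.visit, "tens": t.tens,
                 "phases": ",".join(t.series),
                 "has_fnirs": t.fnirs is not None} for t in self.trials]
        return pd.DataFrame(rows)


def _assign_orders(n: int, rng: np.random.Generator) -> list[str]:
    """Counterbalanced ON-first/ON-second assignment (odd n: extra is random)."""
    half = n // 2
    orders = ["ON-first"] * half + ["ON-second"] * half
    if n % 2:
        orders.append(str(rng.choice(["ON-first", "ON-second"])))
    perm = rng.permutation(n)
    return [orders[i] for i in perm]


def _build_participants(cfg: CohortConfig, rng: np.random.Generator) -> list[ParticipantParams]:
    """Realize per-participant random effects and injected fixed effects."""
    e_early = window_decay_factor(-0.012, *WINDOWS["early"])
    n_late = cfg.n_strides
    e_late = window_decay_factor(-0.012, n_late - 29, n_late)
    mag_factor = e_early - e_late  # magnitude change per unit amplitude

    participants = []
    specs = ([("PwMS", cfg.n_pwms, cfg.mean_step_mm_pwms)]
             + [("HC", cfg.n_hc, cfg.mean_step_mm_hc)])
    pid = 0
    for group, count, step_mm in specs:
        orders = _assign_orders(count, rng)
        for i in range(count):
            pid += 1
            a_re = rng.normal(0.0, cfg.participant_a_sd)
            c_re = rng.normal(0.0, cfg.participant_c_sd)
            base_a = -0.15 + a_re
            if group == "PwMS":
                base_a += cfg.group_magnitude_gap / mag_factor  # less adaptation
            visit_offsets = {1: rng.normal(0.0, cfg.visit_a_sd),
                             2: rng.normal(0.0, cfg.visit_a_sd)}
            # Visit-2 early-change gain (both groups), injected on amplitude
            visit_offsets[2] += cfg.visit_early_change_shift / e_early
            order = orders[i]
            if group == "PwMS" and order == "ON-second":
                # TENS-ON-at-Visit-2 savings shift, injected on amplitude
                visit_offsets[2] += cfg.tens_savings_shift
            deadapt_a = 0.10 + rng.normal(0.0, cfg.participant_a_sd * 0.6)
            participants.append(ParticipantParams(
                participant_id=f"P{pid:03d}", group=group, tens_order=order,
                fast_limb="right" if i % 2 else "left",
                baseline_sla=0.02 + rng.normal(0.0, cfg.baseline_sla_sd),
                adaptation=PhaseParams(float(np.clip(base_a, -0.99, -1e-3)),
                                       -0.012, float(np.clip(0.01 + c_re, -0.99, 0.99))),
                deadaptation=PhaseParams(float(np.clip(deadapt_a, 1e-3, 0.99)),
                                         -0.012, 0.0),
                stride_noise_sd=cfg.stride_noise_sd,
                visit_a_offsets=visit_offsets,
                mean_step_mm=step_mm))
    return participants


def _visit_deadapt(p: ParticipantParams, visit: int, cfg: CohortConfig) -> PhaseParams:
    if visit != 2 or cfg.visit_after_effect_shift == 0:
        return p.deadaptation
    e_early = window_decay_factor(p.deadaptation.b, *WINDOWS["early"])
    a2 = p.deadaptation.a + cfg.visit_after_effect_shift / e_early
    return replace(p.deadaptation, a=float(np.clip(a2, 1e-3, 0.99)))


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Generate all trials of a counterbalanced crossover cohort."""
    from .sla import simulate_sla_series  # local import avoids cycle

    cfg = config or CohortConfig()
    root_ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root_ss.spawn(1)[0])
    participants = _build_participants(cfg, rng)

    trials = []
    truth_rows = []
    ss_iter = iter(root_ss.spawn(len(participants) * 2 + 1)[1:])
    for p in participants:
        for visit in (1, 2):
            trial_rng = np.random.default_rng(next(ss_iter))
            tens = p.tens_at(visit)
            series = {}
            series["Baseline"] = simulate_sla_series(
                0.0, -0.01, p.baseline_sla, cfg.n_baseline,
                noise_sd=p.stride_noise_sd, seed=trial_rng, phase="Baseline",
                mean_step_mm=p.mean_step_mm, participant=p.participant_id,
                visit=visit, tens=tens)
            ap = p.phase_params("Adaptation", visit)
            series["Adaptation"] = simulate_sla_series(
                ap.a, ap.b, ap.c, cfg.n_strides, noise_sd=p.stride_noise_sd,
                seed=trial_rng, phase="Adaptation", mean_step_mm=p.mean_step_mm,
                participant=p.participant_id, visit=visit, tens=tens)
            dp = None
            if cfg.include_deadaptation:
                dp = _visit_deadapt(p, visit, cfg)
                series["Deadaptation"] = simulate_sla_series(
                    dp.a, dp.b, dp.c, cfg.n_strides, noise_sd=p.stride_noise_sd,
                    seed=trial_rng, phase="Deadaptation",
                    mean_step_mm=p.mean_step_mm, participant=p.participant_id,
                    visit=visit, tens=tens)
            fnirs = None
            if cfg.include_fnirs:
                fnirs = _simulate_trial_fnirs(p, visit, tens, cfg, trial_rng)
            truth = {
                "participant": p.participant_id, "group": p.group,
                "visit": visit, "tens": tens, "tens_order": p.tens_order,
                "baseline_sla": p.baseline_sla,
                "adapt_a": ap.a, "adapt_b": ap.b, "adapt_c": ap.c,
                "deadapt_a": dp.a if dp else np.nan,
                "deadapt_b": dp.b if dp else np.nan,
                "deadapt_c": dp.c if dp else np.nan,
                "stride_noise_sd": p.stride_noise_sd,
            }
            if fnirs is not None:
                tp_betas = {k: v for k, v in fnirs.ground_truth["betas"].items()}
                truth["fnirs_early_adapt_beta"] = float(np.mean(
                    [b.get("EarlyAdapt", 0.0) for b in tp_betas.values()])) if tp_betas else 0.0
            truth_rows.append(truth)
            trials.append(SyntheticTrial(
                participant_id=p.participant_id, group=p.group, visit=visit,
                tens=tens, series=series, fnirs=fnirs, truth=truth))
    return CohortData(trials=trials, participants=participants, config=cfg,
                      truth=pd.DataFrame(truth_rows))


def _simulate_trial_fnirs(p: ParticipantParams, visit: int, tens: str,
                          cfg: CohortConfig, rng: np.random.Generator):
    from ..fnirs.recording import default_montage

    channels = default_montage(cfg.fnirs_n_long, cfg.fnirs_n_short)
    design = default_block_design()
    amp = cfg.fnirs_activation + (cfg.fnirs_tens_on_shift if tens == "ON" else 0.0)
    amp += rng.normal(0.0, 0.02)  # participant-visit activation variability
    beta_map = {}
    for name in channels.loc[~channels["is_short"], "channel"]:
        beta_map[name] = {"EarlyAdapt": amp + rng.normal(0.0, 0.01)}
    return simulate_fnirs_recording(
        design, beta_map, cfg.fnirs_noise, seed=rng, fs=cfg.fnirs_fs,
        channels=channels, participant=p.participant_id, visit=visit,
        tens=tens)


def write_cohort(cohort: CohortData, out_dir) -> dict:
    """Write stride tables (CSV), manifest (TSV), truth (CSV) and fNIRS files."""
    from ..fnirs.io import write_tabular

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stride_frames = [s.to_frame() for t in cohort.trials for s in t.series.values()]
    strides = pd.concat(stride_frames, ignore_index=True)
    cols = ["participant", "visit", "tens", "phase", "stride_index",
            "step_fast_mm", "step_slow_mm", "sla"]
    strides = strides[cols]
    paths = {"strides": out / "strides.csv", "manifest": out / "manifest.tsv",
             "truth": out / "truth.csv"}
    strides.to_csv(paths["strides"], index=False, float_format="%.10g")
    cohort.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], index=False, float_format="%.10g")
    fnirs_dir = out / "fnirs"
    for t in cohort.trials:
        if t.fnirs is not None:
            fnirs_dir.mkdir(exist_ok=True)
            stem = f"{t.participant_id}_v{t.visit}"
            write_tabular(t.fnirs, fnirs_dir / f"{stem}.csv")
    return paths


def read_stride_table(path) -> list[StrideSeries]:
    """Read a strides.csv back into StrideSeries (one per trial-phase)."""
    df = pd.read_csv(path)
    out = []
    for (pid, visit, tens, phase), grp in df.groupby(
            ["participant", "visit", "tens", "phase"], sort=False):
        grp = grp.sort_values("stride_index")
        out.append(StrideSeries(
            sla=grp["sla"].to_numpy(), phase=phase,
            step_fast=grp["step_fast_mm"].to_numpy(),
            step_slow=grp["step_slow_mm"].to_numpy(),
            participant=pid, visit=int(visit), tens=tens))
    return out
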