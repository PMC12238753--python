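"""Window means and adaptation outcomes derived from fitted exponentials.

Six timepoint windows per visit (Initial/Early/Late x Adapt/Deadapt):
Initial = strides 1-5, Early = strides 6-30, Late = last 30 strides.  Window
means are evaluated from the fitted model at integer strides, not from raw
data (a raw-data variant exists for sensitivity checks).

Outcome sign conventions (documented, both orientations derivable):

* early_change       -- mean fitted SLA over the Early window of a phase.
* adaptation_magnitude   = Late Adapt mean - Early Adapt mean (positive when
  SLA rises toward symmetry during adaptation).
* deadaptation_magnitude = Early Deadapt mean - Late Deadapt mean (positive
  decay of the after-effect).
* after_effect       = Early Deadapt mean of baseline-adjusted curves
  (baseline mean is zero after adjustment).
* savings            = Visit 2 minus Visit 1 at Initial and Early Adapt
  (positive = less asymmetric on revisit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..stride import StrideSeries
from .expfit import ExponentialFit

__all__ = [
    "WINDOWS", "window_bounds", "window_means",
    "AdaptationOutcomes", "compute_outcomes",
    "SavingsRecord", "compute_savings",
]

#: fixed windows on 1-based stride indices; "late" is resolved per series length
WINDOWS = {"initial": (1, 5), "early": (6, 30)}
LATE_WIDTH = 30


def window_bounds(name: str, n_strides: int) -> tuple[int, int]:
    """Inclusive 1-based (first, last) stride of a named window."""
    if name == "late":
        lo, hi = n_strides - LATE_WIDTH + 1, n_strides
    else:
        lo, hi = WINDOWS[name]
    if hi > n_strides or lo < 1:
        raise ValueError(
            f"window '{name}' ({lo}-{hi}) exceeds series length {n_strides}")
    return lo, hi


def window_means(fit: ExponentialFit, n_strides: int | None = None, *,
                 source: str = "model", series: StrideSeries | None = None) -> dict:
    """Mean SLA over the Initial/Early/Late windows of one phase.

    ``source='model'`` (default) evaluates the fitted exponential at the
    integer strides of each window; ``source='raw'`` averages the observed
    strides instead (requires ``series``).
    """
    if n_strides is None:
        n_strides = fit.n_strides
    out = {}
    for name in ("initial", "early", "late"):
        lo, hi = window_bounds(name, n_strides)
        if source == "model":
            out[name] = float(np.mean(fit.predict(np.arange(lo, hi + 1))))
        elif source == "raw":
            if series is None:
                raise ValueError("source='raw' requires the stride series")
            out[name] = float(np.mean(series.sla[lo - 1:hi]))
        else:
            raise ValueError(f"unknown source {source!r}")
    return out


@dataclass
class AdaptationOutcomes:
    """Six window means and derived outcomes for one participant-visit."""

    adapt: dict
    deadapt: dict | None = None
    participant: str | None = None
    visit: int | None = None
    tens: str | None = None
    group: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def early_change_adapt(self) -> float:
        return self.adapt["early"]

    @property
    def early_change_deadapt(self) -> float | None:
        return None if self.deadapt is None else self.deadapt["early"]

    @property
    def adaptation_magnitude(self) -> float:
        return self.adapt["late"] - self.adapt["early"]

    @property
    def deadaptation_magnitude(self) -> float | None:
        if self.deadapt is None:
            return None
        return self.deadapt["early"] - self.deadapt["late"]

    @property
    def after_effect(self) -> float | None:
        # curves are baseline-adjusted, so baseline mean is 0 by construction
        return None if self.deadapt is None else self.deadapt["early"]

    def as_dict(self) -> dict:
        d = {
            "participant": self.participant, "visit": self.visit,
            "tens": self.tens, "group": self.group,
            "initial_adapt": self.adapt["initial"],
            "early_adapt": self.adapt["early"],
            "late_adapt": self.adapt["late"],
            "early_change_adapt": self.early_change_adapt,
            "adaptation_magnitude": self.adaptation_magnitude,
        }
        if self.deadapt is not None:
            d.update({
                "initial_deadapt": self.deadapt["initial"],
                "early_deadapt": self.deadapt["early"],
                "late_deadapt": self.deadapt["late"],
                "early_change_deadapt": self.early_change_deadapt,
                "deadaptation_magnitude": self.deadaptation_magnitude,
                "after_effect": self.after_effect,
            })
        return d


def compute_outcomes(adapt_fit: ExponentialFit,
                     deadapt_fit: ExponentialFit | None = None,
                     **labels) -> AdaptationOutcomes:
    """Assemble window means and the four adaptation outcomes for one visit."""
    adapt = window_means(adapt_fit)
    deadapt = window_means(deadapt_fit) if deadapt_fit is not None else None
    return AdaptationOutcomes(adapt=adapt, deadapt=deadapt, **labels)


@dataclass
class SavingsRecord:
    """Visit-2 minus Visit-1 change at Initial and Early Adapt for one participant."""

    participant: str
    savings_initial: float
    savings_early: float
    tens_at_v2: str | None = None  # TENS condition received at Visit 2
    group: str | None = None


def compute_savings(outcomes_v1: AdaptationOutcomes,
                    outcomes_v2: AdaptationOutcomes) -> SavingsRecord:
    """Savings = Visit 2 minus Visit 1 window means (positive = improvement)."""
    if outcomes_v1.participant != outcomes_v2.participant:
        raise ValueError("savings links the two visits of one participant")
    return SavingsRecord(
        participant=outcomes_v1.participant or "",
        savings_initial=outcomes_v2.adapt["initial"] - outcomes_v1.adapt["initial"],
        savings_early=outcomes_v2.adapt["early"] - outcomes_v1.adapt["early"],
        tens_at_v2=outcomes_v2.tens,
        group=outcomes_v2.group or outcomes_v1.group,
    )
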