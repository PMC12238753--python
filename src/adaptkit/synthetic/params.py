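"""Generating parameters for the synthetic crossover cohort.

Effects are injected on generating parameters (curve amplitude ``a``, the
asymptote ``c`` and per-visit amplitude offsets), never on derived outcomes,
so downstream recovery is a genuine pipeline test.  Because window means are
evaluated from the fitted exponential, an amplitude shift ``delta`` moves the
Initial window mean by ``delta * mean(exp(b*n), n=1..5)`` (~0.97 * delta for
typical rates) and the Early window mean by ~0.85 * delta.

Defaults realize the printed effect structure: a group gap of 0.022 in
adaptation magnitude, visit effects on early change (+0.024) and
after-effect (-0.012), and a +0.05 TENS-ON-at-Visit-2 savings shift for PwMS
against a between-participant savings sd of ~0.037 (implying d ~ 1.35).
Stride noise magnitude and between-participant variances are not reported
for the source cohort; the defaults below are chosen to make those effect
sizes attainable and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhaseParams", "ParticipantParams", "FnirsNoiseConfig",
           "CohortConfig", "window_decay_factor"]


def window_decay_factor(b: float, lo: int, hi: int) -> float:
    """Mean of exp(b*n) over the integer stride window [lo, hi]."""
    n = np.arange(lo, hi + 1)
    return float(np.mean(np.exp(b * n)))


@dataclass(frozen=True)
class PhaseParams:
    """Exponential generating parameters for one phase: y = a*exp(b*n) + c."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.b >= 0:
            raise ValueError("decay rate b must be negative")
        if abs(self.a) >= 1 or abs(self.c) >= 1:
            raise ValueError("|a| and |c| must be < 1 (SLA units)")


@dataclass
class ParticipantParams:
    """Per-participant generating parameters (random effects realized)."""

    participant_id: str
    group: str                      # "PwMS" | "HC"
    tens_order: str                 # "ON-first" | "ON-second"
    fast_limb: str = "right"
    baseline_sla: float = 0.02
    adaptation: PhaseParams = field(default_factory=lambda: PhaseParams(-0.15, -0.012, 0.01))
    deadaptation: PhaseParams = field(default_factory=lambda: PhaseParams(0.10, -0.012, 0.0))
    stride_noise_sd: float = 0.02
    visit_a_offsets: dict = field(default_factory=dict)  # visit -> amplitude offset
    mean_step_mm: float = 563.0

    def __post_init__(self):
        if self.stride_noise_sd < 0:
            raise ValueError("stride_noise_sd must be >= 0")
        if self.group not in ("PwMS", "HC"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.tens_order not in ("ON-first", "ON-second"):
            raise ValueError(f"unknown tens_order {self.tens_order!r}")

    def tens_at(self, visit: int) -> str:
        first = "ON" if self.tens_order == "ON-first" else "OFF"
        second = "OFF" if first == "ON" else "ON"
        return first if visit == 1 else second

    def phase_params(self, phase: str, visit: int) -> PhaseParams:
        base = {"Adaptation": self.adaptation,
                "Deadaptation": self.deadaptation}[phase]
        if phase == "Adaptation":
            off = float(self.visit_a_offsets.get(visit, 0.0))
            return replace(base, a=float(np.clip(base.a + off, -0.999, 0.999)))
        return base


@dataclass(frozen=True)
class FnirsNoiseConfig:
    """Noise composition of the synthetic optical recordings.

    The cardiac component sits at 1.1 Hz, below the 3.05 Hz Nyquist of the
    6.1 Hz optical sampling, so it is resolvable (not aliased); the Mayer
    wave sits at ~0.1 Hz.
    """

    drift_amp: float = 0.05          # peak linear drift (concentration units)
    cardiac_freq: float = 1.1
    cardiac_amp: float = 0.02
    mayer_freq: float = 0.1
    mayer_amp: float = 0.02
    spike_rate_hz: float = 0.01      # expected spikes per second
    spike_amp: float = 0.5
    scalp_weight: float = 0.4        # long-channel weight of the scalp component
    scalp_amp: float = 0.1
    sensor_noise_sd: float = 0.01

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        for name in ("cardiac_freq", "mayer_freq"):
            if getattr(self, name) >= nyq:
                raise ValueError(f"{name} must be below the Nyquist ({nyq} Hz) "
                                 "to be resolvable")

    @classmethod
    def off(cls) -> "FnirsNoiseConfig":
        return cls(drift_amp=0.0, cardiac_amp=0.0, mayer_amp=0.0,
                   spike_rate_hz=0.0, spike_amp=0.0, scalp_weight=0.0,
                   scalp_amp=0.0, sensor_noise_sd=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout, injected effects and noise settings."""

    n_pwms: int = 28
    n_hc: int = 20
    n_strides: int = 1000            # adaptation/deadaptation strides per phase
    n_baseline: int = 100
    seed: int = 0

    # injected effects (SLA units, on generating parameters)
    group_magnitude_gap: float = 0.022    # PwMS adaptation magnitude deficit
    visit_early_change_shift: float = 0.024  # Visit-2 early-change gain (both groups)
    visit_after_effect_shift: float = -0.012  # Visit-2 after-effect change
    tens_savings_shift: float = 0.05      # PwMS TENS-ON-at-V2 amplitude shift

    # between-participant variability
    participant_a_sd: float = 0.03
    participant_c_sd: float = 0.008
    visit_a_sd: float = 0.0255            # per-visit amplitude sd; savings sd
                                          # ~ sqrt(2)*visit_a_sd + fit noise ~ 0.037
    baseline_sla_sd: float = 0.012
    stride_noise_sd: float = 0.02

    # fNIRS settings
    include_fnirs: bool = False
    fnirs_noise: FnirsNoiseConfig = field(default_factory=FnirsNoiseConfig)
    fnirs_fs: float = 6.1
    fnirs_activation: float = 0.10        # EarlyAdapt HbO amplitude, TENS OFF
    fnirs_tens_on_shift: float = -0.08    # activation change with TENS ON
    fnirs_n_long: int = 48
    fnirs_n_short: int = 8

    include_deadaptation: bool = True
    mean_step_mm_pwms: float = 563.0
    mean_step_mm_hc: float = 602.0

    def __post_init__(self):
        if self.n_pwms <= 0 or self.n_hc <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_strides < 60 or self.n_baseline <= 0:
            raise ValueError("need >= 60 strides per phase and a baseline phase")
        self.fnirs_noise.validate(self.fnirs_fs)

    def zeroed(self) -> "CohortConfig":
        """Copy with all injected effects set to zero (type-I simulations)."""
        return replace(self, group_magnitude_gap=0.0,
                       visit_early_change_shift=0.0,
                       visit_after_effect_shift=0.0, tens_savings_shift=0.0,
                       fnirs_tens_on_shift=0.0)
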