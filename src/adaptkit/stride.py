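"""Stride-level step length and step-length-asymmetry (SLA) series.

SLA for stride ``i`` is the normalized difference of fast- and slow-limb step
lengths::

    SLA(i) = (step_fast(i) - step_slow(i)) / (step_fast(i) + step_slow(i))

which is dimensionless, antisymmetric under limb swap and bounded in (-1, 1)
for positive step lengths.  Adaptation and deadaptation curves are
baseline-adjusted by subtracting the mean SLA of the last 30 tied-belt
baseline strides before any model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["StrideSeries", "compute_sla", "baseline_adjust", "BASELINE_WINDOW"]

#: number of trailing baseline strides whose mean defines the baseline offset
BASELINE_WINDOW = 30


def compute_sla(step_fast, step_slow):
    """Step length asymmetry from paired step lengths (mm).

    Parameters
    ----------
    step_fast, step_slow : float or array-like
        Step length of the fast and slow limb in mm.  Must have a strictly
        positive sum (stride length).

    Returns
    -------
    float or ndarray
        ``(step_fast - step_slow) / (step_fast + step_slow)``.
    """
    f = np.asarray(step_fast, dtype=float)
    s = np.asarray(step_slow, dtype=float)
    denom = f + s
    if np.any(denom <= 0):
        raise ValueError("step_fast + step_slow must be strictly positive")
    out = (f - s) / denom
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class StrideSeries:
    """Per-phase sequence of paired step lengths and SLA values.

    Stride indices are 1-based in user-facing fields (``n``), matching the
    convention that the exponential model is evaluated at n = 1, 2, ...
    """

    sla: np.ndarray
    phase: str = "Adaptation"
    step_fast: np.ndarray | None = None
    step_slow: np.ndarray | None = None
    participant: str | None = None
    visit: int | None = None
    tens: str | None = None
    baseline_offset: float | None = None  # recorded when baseline-adjusted
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sla = np.asarray(self.sla, dtype=float)
        if self.sla.ndim != 1:
            raise ValueError("sla must be one-dimensional")
        for name in ("step_fast", "step_slow"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.sla.shape:
                    raise ValueError(f"{name} must match sla length")
                if np.any(v <= 0):
                    raise ValueError(f"{name} must be strictly positive")
                setattr(self, name, v)

    @property
    def n(self) -> np.ndarray:
        """1-based stride indices."""
        return np.arange(1, self.sla.size + 1)

    def __len__(self) -> int:
        return self.sla.size

    @classmethod
    def from_step_lengths(cls, step_fast, step_slow, **kw) -> "StrideSeries":
        sla = compute_sla(step_fast, step_slow)
        return cls(sla=np.atleast_1d(sla), step_fast=np.atleast_1d(step_fast),
                   step_slow=np.atleast_1d(step_slow), **kw)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"stride_index": self.n, "sla": self.sla})
        if self.step_fast is not None:
            df.insert(1, "step_fast_mm", self.step_fast)
            df.insert(2, "step_slow_mm", self.step_slow)
        for col, val in (("participant", self.participant), ("visit", self.visit),
                         ("tens", self.tens), ("phase", self.phase)):
            if val is not None:
                df[col] = val
        return df


def baseline_adjust(series: StrideSeries, baseline: StrideSeries,
                    window: int = BASELINE_WINDOW) -> StrideSeries:
    """Subtract the mean of the last ``window`` baseline strides from a series.

    Returns a new :class:`StrideSeries` whose ``sla`` is shifted by the
    visit-specific baseline mean; the applied constant is stored in
    ``baseline_offset``.  If fewer than ``window`` baseline strides are
    available, all of them are used and a warning is emitted.
    """
    nb = len(baseline)
    if nb == 0:
        raise ValueError("baseline series is empty")
    if nb < window:
        warnings.warn(
            f"baseline has only {nb} strides (< {window}); using all of them",
            UserWarning, stacklevel=2)
        window = nb
    offset = float(np.mean(baseline.sla[-window:]))
    return replace(series, sla=series.sla - offset, baseline_offset=offset)
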