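"""Heel-strike detection and step lengths from force and marker traces.

Vertical ground reaction forces (per belt, default 1000 Hz) are low-pass
filtered with a zero-lag Butterworth filter, heel strikes are detected as
threshold crossings with a refractory period, and step length is the
anterior-posterior distance in mm between the two heel markers at each heel
strike (default 100 Hz markers, linearly interpolated to event times).
Because step length is a between-heel difference, any rigid-body AP
translation common to both heels cancels.

Coordinate convention: AP axis positive in the walking direction; sample
indices are 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "ForceTrace", "MarkerTrace", "GaitEvents",
    "lowpass_filter_zero_lag", "detect_heel_strikes", "compute_step_lengths",
]

DEFAULT_FORCE_FS = 1000.0
DEFAULT_MARKER_FS = 100.0
DEFAULT_THRESHOLD_N = 20.0
DEFAULT_REFRACTORY_S = 0.2
MARKER_LOWPASS_HZ = 6.0  # zero-lag Butterworth substitute for spline smoothing


@dataclass
class ForceTrace:
    """Per-belt vertical ground reaction force (N)."""

    fast: np.ndarray
    slow: np.ndarray
    fs: float = DEFAULT_FORCE_FS

    def __post_init__(self):
        self.fast = np.asarray(self.fast, dtype=float)
        self.slow = np.asarray(self.slow, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("fast", "slow"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} force contains non-finite values")


@dataclass
class MarkerTrace:
    """Heel-marker anterior-posterior position (mm) for one limb."""

    ap: np.ndarray
    fs: float = DEFAULT_MARKER_FS

    def __post_init__(self):
        self.ap = np.asarray(self.ap, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.ap)):
            raise ValueError("marker trace contains non-finite values")

    def at_time(self, t) -> np.ndarray:
        """AP position at time(s) t (s), linearly interpolated between samples."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        grid = np.arange(self.ap.size) / self.fs
        return np.interp(t, grid, self.ap)


@dataclass
class GaitEvents:
    """Heel-strike sample indices per limb (on the force time base)."""

    fast: np.ndarray
    slow: np.ndarray
    fs: float = DEFAULT_FORCE_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("fast", "slow"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if idx.size and np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} heel-strike indices must be strictly increasing")
            setattr(self, name, idx)

    @property
    def stride_count(self) -> int:
        return int(min(self.fast.size, self.slow.size))

    def times(self, limb: str) -> np.ndarray:
        return getattr(self, limb) / self.fs


def lowpass_filter_zero_lag(x, order: int = 4, cutoff: float = 300.0,
                            fs: float = DEFAULT_FORCE_FS) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The cutoff must lie below the Nyquist frequency; e.g. a 300 Hz cutoff is
    valid for 1000 Hz force data but not for 100 Hz marker data.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must satisfy 0 < cutoff < fs/2 = {fs / 2}")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, x)


def _detect_one(force: np.ndarray, fs: float, threshold: float,
                refractory: float) -> np.ndarray:
    above = force > threshold
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if rising.size == 0:
        return rising
    min_above = max(1, int(round(refractory * fs)))
    keep = []
    last = -np.inf
    for idx in rising:
        if idx - last < min_above:
            continue
        stop = min(idx + min_above, force.size)
        if np.all(above[idx:stop]):  # must stay loaded through the refractory
            keep.append(idx)
            last = idx
    return np.asarray(keep, dtype=int)


def detect_heel_strikes(vgrf: ForceTrace, threshold: float = DEFAULT_THRESHOLD_N,
                        refractory: float = DEFAULT_REFRACTORY_S) -> GaitEvents:
    """Heel strikes as upward force-threshold crossings with a refractory hold.

    A heel strike is the first sample where the filtered vertical force rises
    above ``threshold`` N and remains above it for at least ``refractory``
    seconds.  Emits a warning (and empty events) when no crossing is found.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fast = _detect_one(vgrf.fast, vgrf.fs, threshold, refractory)
    slow = _detect_one(vgrf.slow, vgrf.fs, threshold, refractory)
    if fast.size == 0 and slow.size == 0:
        warnings.warn("no heel strikes detected on either belt", UserWarning,
                      stacklevel=2)
    return GaitEvents(fast=fast, slow=slow, fs=vgrf.fs)


def compute_step_lengths(heel_fast: MarkerTrace, heel_slow: MarkerTrace,
                         events: GaitEvents) -> tuple[np.ndarray, np.ndarray, dict]:
    """Paired step lengths (mm) at each limb's heel strikes.

    At a fast-limb heel strike, ``step_fast = AP(heel_fast) - AP(heel_slow)``
    evaluated at the event time (and symmetrically for the slow limb).  Events
    falling outside the marker trace are skipped and counted in the returned
    info dict.
    """
    dur = (min(heel_fast.ap.size, heel_slow.ap.size) - 1) / heel_fast.fs
    skipped = {"fast": 0, "slow": 0}
    out = {}
    for limb, other_sign in (("fast", 1.0), ("slow", -1.0)):
        t = events.times(limb)
        ok = t <= dur
        skipped[limb] = int(np.sum(~ok))
        t = t[ok]
        diff = heel_fast.at_time(t) - heel_slow.at_time(t)
        out[limb] = other_sign * diff
    return out["fast"], out["slow"], {"skipped": skipped}
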