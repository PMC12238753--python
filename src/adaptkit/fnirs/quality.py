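"""Signal-quality metrics: scalp coupling index and robust spike detection.

SCI is the Pearson correlation of a channel's two wavelengths after
band-passing to the cardiac band; at the 6.1 Hz optical sampling rate the
Nyquist frequency is 3.05 Hz, so the nominal 0.5-2.0 Hz cardiac band is fully
resolvable (a ~1.1 Hz cardiac component is NOT aliased).  SCI is a QC flag
only -- no automatic channel rejection is performed.

Spikes are flagged with a trailing-window robust z-score detector
(lag-window mean/dispersion, threshold in dispersion units, flagged samples
down-weighted by the influence factor when entering the running statistics),
repeated for a fixed number of iterations.  Defaults: 10 iterations, 5-s lag,
threshold 3.5, influence 0.5; the 5-s lag converts to round(5 * fs) samples.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["compute_sci", "detect_spikes", "CARDIAC_BAND"]

CARDIAC_BAND = (0.5, 2.0)  # Hz; below Nyquist at fs = 6.1 Hz
MIN_SCI_DURATION_S = 60.0


def _cardiac_bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    lo, hi = CARDIAC_BAND
    hi = min(hi, 0.95 * fs / 2)  # guard for low sampling rates
    b, a = butter(3, [lo, hi], btype="band", fs=fs)
    return filtfilt(b, a, x, axis=0)


def compute_sci(x_wl1: np.ndarray, x_wl2: np.ndarray, fs: float) -> float:
    """Scalp coupling index: cardiac-band correlation of the two wavelengths.

    Returns NaN (undefined, to be QC-flagged) when less than 60 s of data is
    available or either band-passed signal has zero variance.
    """
    x1 = np.asarray(x_wl1, dtype=float)
    x2 = np.asarray(x_wl2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("wavelength series must be equal-length 1-D arrays")
    if x1.size / fs < MIN_SCI_DURATION_S:
        return float("nan")
    b1 = _cardiac_bandpass(x1, fs)
    b2 = _cardiac_bandpass(x2, fs)
    s1, s2 = b1.std(), b2.std()
    if s1 == 0 or s2 == 0:
        return float("nan")
    r = float(np.corrcoef(b1, b2)[0, 1])
    return r


def _spike_pass(x: np.ndarray, lag: int, threshold: float,
                influence: float) -> np.ndarray:
    """One pass of the trailing-window robust z-score detector."""
    n = x.size
    mask = np.zeros(n, dtype=bool)
    filt = x.copy()  # series with flagged samples down-weighted
    # rolling first/second moments over the trailing lag window of `filt`
    wsum = float(np.sum(filt[:lag]))
    wsq = float(np.sum(filt[:lag] ** 2))
    mean = wsum / lag
    var = max(wsq / lag - mean * mean, 0.0)
    sqrt = np.sqrt
    for t in range(lag, n):
        sd = sqrt(var)
        if sd > 0 and abs(x[t] - mean) > threshold * sd:
            mask[t] = True
            filt[t] = influence * x[t] + (1.0 - influence) * filt[t - 1]
        else:
            filt[t] = x[t]
        new, old = filt[t], filt[t - lag]
        wsum += new - old
        wsq += new * new - old * old
        mean = wsum / lag
        var = max(wsq / lag - mean * mean, 0.0)
    return mask


def detect_spikes(series: np.ndarray, fs: float, *, lag_s: float = 5.0,
                  threshold: float = 3.5, influence: float = 0.5,
                  iterations: int = 10) -> np.ndarray:
    """Boolean spike mask via the iterated robust z-score detector.

    Each iteration runs the trailing-window detector on the series with
    previously flagged samples replaced by their down-weighted values; masks
    accumulate across iterations.
    """
    x = np.asarray(series, dtype=float).copy()
    lag = int(round(lag_s * fs))
    if lag < 2:
        raise ValueError("lag window must span at least 2 samples")
    if lag >= x.size:
        raise ValueError(f"lag window ({lag} samples) must be shorter than the series")
    total = np.zeros(x.size, dtype=bool)
    work = x.copy()
    for _ in range(iterations):
        mask = _spike_pass(work, lag, threshold, influence)
        if not mask.any():
            break
        total |= mask
        # next iteration sees flagged samples replaced by a local bridge
        idx = np.flatnonzero(mask)
        good = np.flatnonzero(~total)
        if good.size >= 2:
            work[idx] = np.interp(idx, good, x[good])
    return total
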