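"""Temporal filtering and normalization for haemoglobin series.

High-pass: zero-phase Butterworth at 0.01 Hz.  Low-pass: Gaussian kernel
smoothing whose amplitude response is -3 dB at 0.4 Hz; for a Gaussian kernel
of standard deviation ``sigma`` (seconds) the response is
``H(f) = exp(-2 pi^2 sigma^2 f^2)``, so ``|H| = 1/sqrt(2)`` at ``f0`` gives
``sigma = sqrt(ln 2) / (2 pi f0)``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt

__all__ = ["gaussian_sigma_for_cutoff", "temporal_filter", "z_normalize"]

HIGHPASS_HZ = 0.01
LOWPASS_HZ = 0.4


def gaussian_sigma_for_cutoff(f0: float) -> float:
    """Kernel sd (s) whose Gaussian response is -3 dB (|H| = 2^-1/2) at f0 Hz."""
    return float(np.sqrt(np.log(2.0)) / (2.0 * np.pi * f0))


def temporal_filter(series: np.ndarray, fs: float, *,
                    highpass_hz: float = HIGHPASS_HZ,
                    lowpass_hz: float = LOWPASS_HZ) -> np.ndarray:
    """0.01 Hz zero-phase Butterworth high-pass then 0.4 Hz Gaussian smoothing.

    Works on 1-D series or ``(n_samples, n_channels)`` arrays (time on axis 0).
    Warns when the record is shorter than ~3 high-pass time constants.
    """
    x = np.asarray(series, dtype=float)
    if fs <= 0.8:
        raise ValueError("sampling rate too low for the 0.4 Hz smoothing stage")
    n = x.shape[0]
    if n / fs < 3.0 / highpass_hz:
        warnings.warn(
            f"record ({n / fs:.0f}s) shorter than 3 high-pass time constants "
            f"({3.0 / highpass_hz:.0f}s); high-pass transient may dominate",
            UserWarning, stacklevel=2)
    b, a = butter(2, highpass_hz, btype="high", fs=fs)
    hp = filtfilt(b, a, x, axis=0)
    sigma_samples = gaussian_sigma_for_cutoff(lowpass_hz) * fs
    return gaussian_filter1d(hp, sigma_samples, axis=0, mode="nearest")


def z_normalize(series: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (per channel for 2-D input).

    Refuses zero-variance channels (these should be QC-flagged upstream).
    """
    x = np.asarray(series, dtype=float)
    mu = x.mean(axis=0, keepdims=x.ndim > 1)
    sd = x.std(axis=0, keepdims=x.ndim > 1)
    if np.any(sd == 0):
        raise ValueError("zero-variance channel cannot be z-normalized")
    return (x - mu) / sd
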