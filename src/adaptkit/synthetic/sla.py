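"""Stride-level SLA series generator.

Inverts the single-exponential learning model as ground truth:
``SLA(n) = a*exp(b*n) + c + eps(n)`` with 1-based stride index and
independent Gaussian stride noise by default (an AR(1) option exists, off by
default, since stride-noise structure is not characterized for the source
cohort).  Paired step lengths consistent with each SLA value are emitted
around a configurable mean step length.
"""

from __future__ import annotations

import numpy as np

from ..stride import StrideSeries

__all__ = ["simulate_sla_series"]


def simulate_sla_series(a: float, b: float, c: float, n_strides: int,
                        noise_sd: float = 0.0, *,
                        seed: int | np.random.Generator = 0,
                        phase: str = "Adaptation",
                        mean_step_mm: float = 563.0,
                        ar1: float = 0.0,
                        **labels) -> StrideSeries:
    """Simulate one phase of stride-level SLA data.

    Parameters
    ----------
    a, b, c : float
        Generating exponential parameters (|a + c| < 1 keeps SLA in range;
        use ``a = 0`` for tied-belt phases).
    n_strides : int
        Number of strides; must be >= 60 so the Early and Late windows do
        not overlap.
    noise_sd : float
        Stride-to-stride noise sd (SLA units).
    seed : int or Generator
        Randomness source; identical seeds reproduce the series bit-for-bit.
    ar1 : float
        Optional lag-1 autocorrelation of the noise (default 0, independent).
    labels : passed through to :class:`StrideSeries` (participant, visit, ...).
    """
    if n_strides < 60:
        raise ValueError(
            f"n_strides must be >= 60 (got {n_strides}): the Early (6-30) and "
            "Late (last 30) windows would overlap")
    if abs(a + c) >= 1.0:
        raise ValueError(f"|a + c| = {abs(a + c):.3f} >= 1: SLA out of range at stride 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = np.arange(1, n_strides + 1)
    clean = a * np.exp(b * n) + c
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=n_strides)
        if ar1:
            out = np.empty_like(eps)
            out[0] = eps[0]
            scale = np.sqrt(1.0 - ar1 ** 2)
            for i in range(1, n_strides):
                out[i] = ar1 * out[i - 1] + scale * eps[i]
            eps = out
        sla = clean + eps
    else:
        sla = clean
    sla = np.clip(sla, -0.999, 0.999)  # |SLA| < 1 invariant, noise tail guard
    total = 2.0 * mean_step_mm
    step_fast = total * (1.0 + sla) / 2.0
    step_slow = total * (1.0 - sla) / 2.0
    return StrideSeries(sla=sla, phase=phase, step_fast=step_fast,
                        step_slow=step_slow, **labels)
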