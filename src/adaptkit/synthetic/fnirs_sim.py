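"""Synthetic block-design fNIRS recordings with known ground truth.

Each long channel is built in HbO-concentration space as::

    sum_blocks(beta * boxcar (*) HRF) + linear drift + cardiac sinusoid
    + Mayer-wave sinusoid + sparse motion spikes + w * scalp component
    + sensor noise

while short channels carry the scalp component (plus noise) and no
activation.  HbR is generated as a scaled inverse of HbO.  Concentrations
are pushed through the forward Beer-Lambert model to dual-wavelength
intensities, so the analysis pipeline exercises the full inversion chain.
Ground-truth betas, the scalp component and spike locations are stored on
the recording.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..fnirs.convert import haemo_to_od
from ..fnirs.glm import HrfParams, double_gamma_hrf
from ..fnirs.recording import FnirsRecording, default_montage, validate_events
from .params import FnirsNoiseConfig

__all__ = ["default_block_design", "simulate_fnirs_recording"]

HBR_RATIO = -0.33  # HbR tracks HbO inversely at reduced amplitude
BASE_INTENSITY = 1.0


def default_block_design(timepoints=("Baseline", "EarlyAdapt"), *,
                         rest_s: float = 60.0, block_s: float = 30.0,
                         inter_block_s: float = 30.0,
                         inter_timepoint_s: float = 30.0) -> pd.DataFrame:
    """Event table: 60-s rest then two 30-s blocks per timepoint."""
    rows = []
    t = rest_s
    for tp in timepoints:
        for block in (1, 2):
            rows.append({"timepoint": tp, "block": block, "onset": t,
                         "duration": block_s})
            t += block_s + (inter_block_s if block == 1 else inter_timepoint_s)
    return pd.DataFrame(rows)


def _scalp_component(n: int, fs: float, amp: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth band-limited scalp haemodynamic signal (sum of slow sinusoids)."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    for f in (0.03, 0.07, 0.13, 0.23):
        out += rng.normal(0, 1) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    sd = out.std()
    return amp * out / sd if sd else out


def simulate_fnirs_recording(design: pd.DataFrame, beta_map: dict,
                             noise_cfg: FnirsNoiseConfig | None = None, *,
                             seed: int | np.random.Generator = 0,
                             fs: float = 6.1,
                             channels: pd.DataFrame | None = None,
                             tail_s: float = 60.0,
                             hrf_params: HrfParams | None = None,
                             **labels) -> FnirsRecording:
    """Generate one dual-wavelength recording.

    Parameters
    ----------
    design : DataFrame
        Event table with ``timepoint``, ``block``, ``onset``, ``duration``
        columns; blocks must be non-overlapping and fit the record.
    beta_map : dict
        ``channel -> {timepoint -> HbO amplitude}`` (missing entries = 0).
    noise_cfg : FnirsNoiseConfig
        Noise composition; ``FnirsNoiseConfig.off()`` gives noiseless data.
    channels : DataFrame, optional
        Channel/montage table; defaults to the standard 48+8 montage.
    """
    noise = noise_cfg or FnirsNoiseConfig()
    noise.validate(fs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if channels is None:
        channels = default_montage()
    duration = float((design["onset"] + design["duration"]).max()) + tail_s
    n = int(round(duration * fs))
    validate_events(design, n / fs)
    t = np.arange(n) / fs
    hrf = double_gamma_hrf(fs, hrf_params)

    # per-timepoint regressors (unit boxcar convolved with HRF)
    regressors = {}
    for tp, grp in design.groupby("timepoint", sort=False):
        box = np.zeros(n)
        for _, row in grp.iterrows():
            i0 = int(round(row["onset"] * fs))
            i1 = min(n, i0 + int(round(row["duration"] * fs)))
            box[i0:i1] = 1.0
        regressors[tp] = np.convolve(box, hrf)[:n]

    scalp = _scalp_component(n, fs, noise.scalp_amp, rng)
    names = list(channels["channel"])
    is_short = channels["is_short"].to_numpy()
    hbo = np.zeros((n, len(names)))
    truth_betas = {}
    spike_idx = {}
    for j, name in enumerate(names):
        if is_short[j]:
            x = scalp.copy()
        else:
            x = noise.scalp_weight * scalp
            betas = beta_map.get(name, {})
            truth_betas[name] = dict(betas)
            for tp, amp in betas.items():
                x = x + amp * regressors[tp]
            x = x + noise.drift_amp * np.linspace(-1, 1, n)
            x = x + noise.cardiac_amp * np.sin(
                2 * np.pi * noise.cardiac_freq * t + rng.uniform(0, 2 * np.pi))
            x = x + noise.mayer_amp * np.sin(
                2 * np.pi * noise.mayer_freq * t + rng.uniform(0, 2 * np.pi))
            n_spikes = rng.poisson(noise.spike_rate_hz * duration)
            if n_spikes:
                idx = rng.integers(1, n - 1, size=n_spikes)
                x[idx] += rng.choice([-1, 1], size=n_spikes) * noise.spike_amp
                spike_idx[name] = np.sort(idx)
        if noise.sensor_noise_sd:
            x = x + rng.normal(0, noise.sensor_noise_sd, size=n)
        hbo[:, j] = x

    hbr = HBR_RATIO * hbo
    od = haemo_to_od(hbo, hbr)
    intensity = {wl: BASE_INTENSITY * 10.0 ** (-od[wl]) for wl in od}
    return FnirsRecording(
        intensity=intensity, channels=channels, events=design, fs=fs,
        ground_truth={"betas": truth_betas, "scalp": scalp,
                      "scalp_weight": noise.scalp_weight,
                      "spikes": spike_idx, "hbo": hbo},
        **labels)
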