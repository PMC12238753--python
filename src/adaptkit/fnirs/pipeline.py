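"""End-to-end fNIRS processing: raw intensity to HbO betas and contrasts.

Stage order (each stage can be toggled for diagnostics, defaults mirror the
standard chain): intensity -> optical density -> HbO/HbR (MBLL, no DPF) ->
spike detection -> TDDR motion repair -> short-channel regression (highest
correlated short channel, long channels only) -> 0.01 Hz high-pass + 0.4 Hz
Gaussian low-pass -> z-normalization -> double-gamma block GLM -> ROI means
and Baseline-vs-EarlyAdapt contrasts.  SCI is computed per channel as a QC
flag only; no automatic channel rejection is performed.  HbR is converted
and carried in the result but not analyzed further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .betas import channel_wide_beta, compute_contrasts, roi_betas
from .convert import intensity_to_od, od_to_haemo
from .filters import temporal_filter, z_normalize
from .glm import HrfParams, fit_glm_betas
from .quality import compute_sci, detect_spikes
from .recording import FnirsRecording
from .scr import short_channel_regress
from .tddr import correct_motion_tddr

__all__ = ["FnirsPipelineConfig", "FnirsResult", "process_recording"]


@dataclass(frozen=True)
class FnirsPipelineConfig:
    detect_spikes: bool = True
    tddr: bool = True
    short_channel_regression: bool = True
    temporal_filter: bool = True
    z_normalize: bool = True
    per_block_regressors: bool = True
    hrf: HrfParams = field(default_factory=HrfParams)
    contrast_minuend: str = "EarlyAdapt"
    contrast_subtrahend: str = "Baseline"


@dataclass
class FnirsResult:
    """Processed series, per-channel/ROI betas, contrasts and QC report."""

    hbo: pd.DataFrame            # cleaned (analyzed) HbO, columns = channels
    hbr: pd.DataFrame            # converted HbR (not analyzed further)
    betas: pd.DataFrame          # channel x timepoint HbO betas (long channels)
    roi_betas: pd.DataFrame
    channel_wide: pd.DataFrame
    contrasts: pd.DataFrame      # per-channel EarlyAdapt-Baseline contrast
    roi_contrasts: pd.DataFrame
    qc: dict
    z_scale: dict[str, float]    # per-channel sd removed by z-normalization
    meta: dict = field(default_factory=dict)


def process_recording(rec: FnirsRecording,
                      cfg: FnirsPipelineConfig | None = None) -> FnirsResult:
    """Run the full processing chain on one recording."""
    cfg = cfg or FnirsPipelineConfig()
    ch_names = list(rec.channels["channel"])
    is_short = rec.channels["is_short"].to_numpy()

    # conversion: intensity -> OD -> haemoglobin (per source-detector pair)
    od = {wl: intensity_to_od(rec.intensity[wl]) for wl in rec.intensity}
    hbo, hbr = od_to_haemo(od)

    qc: dict = {"sci": {}, "spike_counts": {}, "rejected_channels": [],
                "chosen_short": {}}
    wls = sorted(rec.intensity)
    for j, name in enumerate(ch_names):
        qc["sci"][name] = compute_sci(od[wls[0]][:, j], od[wls[1]][:, j], rec.fs)

    # per-channel cleaning on HbO (HbR follows the same spike/TDDR treatment)
    cleaned = hbo.copy()
    for j, name in enumerate(ch_names):
        x = cleaned[:, j]
        mask = None
        if cfg.detect_spikes:
            mask = detect_spikes(x, rec.fs)
            qc["spike_counts"][name] = int(mask.sum())
        if cfg.tddr:
            x = correct_motion_tddr(x, rec.fs, spike_mask=mask)
        cleaned[:, j] = x

    # short-channel regression for long channels
    short_cols = np.flatnonzero(is_short)
    if cfg.short_channel_regression and short_cols.size:
        shorts = cleaned[:, short_cols]
        for j in np.flatnonzero(~is_short):
            resid, chosen = short_channel_regress(cleaned[:, j], shorts)
            cleaned[:, j] = resid
            qc["chosen_short"][ch_names[j]] = (
                ch_names[short_cols[chosen]] if chosen >= 0 else None)

    if cfg.temporal_filter:
        cleaned = temporal_filter(cleaned, rec.fs)

    z_scale: dict[str, float] = {}
    if cfg.z_normalize:
        sds = cleaned.std(axis=0)
        zero = sds == 0
        for j in np.flatnonzero(zero):
            qc["rejected_channels"].append(ch_names[j])
            sds[j] = 1.0  # leave the dead channel unscaled but flagged
        cleaned = (cleaned - cleaned.mean(axis=0)) / sds
        z_scale = dict(zip(ch_names, (float(s) for s in sds)))

    # GLM per long channel
    rows = []
    for j in np.flatnonzero(~is_short):
        tp_betas = fit_glm_betas(cleaned[:, j], rec.events, rec.fs, cfg.hrf,
                                 per_block=cfg.per_block_regressors)
        for _, r in tp_betas.iterrows():
            rows.append({"channel": ch_names[j], "timepoint": r["timepoint"],
                         "beta": r["beta"]})
    betas = pd.DataFrame(rows)

    roi = roi_betas(betas, rec.roi_map())
    wide = channel_wide_beta(betas)
    contrasts = compute_contrasts(betas, minuend=cfg.contrast_minuend,
                                  subtrahend=cfg.contrast_subtrahend)
    roi_all = pd.concat([roi, wide], ignore_index=True)
    roi_contrasts = compute_contrasts(roi_all, minuend=cfg.contrast_minuend,
                                      subtrahend=cfg.contrast_subtrahend,
                                      unit_col="roi")

    times = rec.times
    return FnirsResult(
        hbo=pd.DataFrame(cleaned, index=times, columns=ch_names),
        hbr=pd.DataFrame(hbr, index=times, columns=ch_names),
        betas=betas, roi_betas=roi, channel_wide=wide,
        contrasts=contrasts, roi_contrasts=roi_contrasts,
        qc=qc, z_scale=z_scale,
        meta={"participant": rec.participant, "visit": rec.visit,
              "tens": rec.tens})
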