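"""fNIRS recording container and the standard motor-montage ROI map.

A recording holds dual-wavelength (760/850 nm) intensity series for a set of
source-detector channels at a nominal 6.1 Hz, an event table of 30-s task
blocks (block design: 60-s standing rest, then paired 30-s blocks per
timepoint), and a channel table flagging short-distance channels and mapping
long channels to Brodmann-labelled ROIs (PMd, PMv, M1, S1, SPL, IPL;
bilaterally symmetric, no channel in two ROIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FnirsRecording", "default_montage", "roi_map_from_channels",
           "validate_events", "ROI_LABELS", "WAVELENGTHS"]

WAVELENGTHS = (760, 850)
ROI_LABELS = ("PMd", "PMv", "M1", "S1", "SPL", "IPL")
DEFAULT_FS = 6.1


def default_montage(n_long: int = 48, n_short: int = 8,
                    channels_per_roi: int = 4) -> pd.DataFrame:
    """Channel table for the standard 48-long / 8-short motor cortex montage.

    The first ``len(ROI_LABELS) * channels_per_roi`` long channels are
    assigned to ROIs in bilaterally symmetric pairs (half ``-L``/half ``-R``
    hemisphere tags); remaining long channels carry no ROI.  Short channels
    are named ``S{i}-D{i}s``.
    """
    rows = []
    k = 0
    for roi in ROI_LABELS:
        for j in range(channels_per_roi):
            if k >= n_long:
                break
            k += 1
            rows.append({
                "channel": f"S{k}-D{k}",
                "source": f"S{k}", "detector": f"D{k}",
                "is_short": False, "roi": roi,
                "hemisphere": "L" if j < channels_per_roi / 2 else "R",
            })
    while k < n_long:
        k += 1
        rows.append({"channel": f"S{k}-D{k}", "source": f"S{k}",
                     "detector": f"D{k}", "is_short": False, "roi": None,
                     "hemisphere": "L" if k % 2 else "R"})
    for i in range(1, n_short + 1):
        rows.append({"channel": f"S{i}-D{i}s", "source": f"S{i}",
                     "detector": f"D{i}s", "is_short": True, "roi": None,
                     "hemisphere": "L" if i % 2 else "R"})
    return pd.DataFrame(rows)


def roi_map_from_channels(channels: pd.DataFrame) -> dict[str, list[str]]:
    """ROI label -> member long-channel names, validated for disjointness."""
    long_ch = channels[~channels["is_short"] & channels["roi"].notna()]
    seen: dict[str, str] = {}
    out: dict[str, list[str]] = {}
    for _, row in long_ch.iterrows():
        if row["channel"] in seen:
            raise ValueError(f"channel {row['channel']} assigned to two ROIs")
        seen[row["channel"]] = row["roi"]
        out.setdefault(row["roi"], []).append(row["channel"])
    return out


def validate_events(events: pd.DataFrame, duration_s: float) -> None:
    """Blocks must be non-overlapping and lie inside the recording."""
    ev = events.sort_values("onset").reset_index(drop=True)
    for _, row in ev.iterrows():
        if row["onset"] < 0 or row["onset"] + row["duration"] > duration_s:
            raise ValueError(
                f"block {row.get('timepoint', '?')} at {row['onset']}s exceeds "
                f"the {duration_s:.1f}s recording")
    ends = (ev["onset"] + ev["duration"]).to_numpy()
    if np.any(ev["onset"].to_numpy()[1:] < ends[:-1]):
        raise ValueError("event blocks overlap")


@dataclass
class FnirsRecording:
    """Dual-wavelength intensity time series plus channel and event tables.

    ``intensity`` maps wavelength (nm) to an array of shape
    ``(n_samples, n_channels)`` aligned with ``channels`` rows.
    """

    intensity: dict[int, np.ndarray]
    channels: pd.DataFrame
    events: pd.DataFrame
    fs: float = DEFAULT_FS
    participant: str | None = None
    visit: int | None = None
    tens: str | None = None
    ground_truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = set()
        for wl, arr in self.intensity.items():
            arr = np.asarray(arr, dtype=float)
            self.intensity[wl] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError("intensity arrays must share one shape")
        (shape,) = shapes
        if shape[1] != len(self.channels):
            raise ValueError("intensity columns must match the channel table")
        if not self.channels["is_short"].any():
            raise ValueError("montage must include at least one short channel")
        validate_events(self.events, self.duration_s)

    @property
    def n_samples(self) -> int:
        return next(iter(self.intensity.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def long_channels(self) -> pd.DataFrame:
        return self.channels[~self.channels["is_short"]]

    @property
    def short_channels(self) -> pd.DataFrame:
        return self.channels[self.channels["is_short"]]

    def roi_map(self) -> dict[str, list[str]]:
        return roi_map_from_channels(self.channels)
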