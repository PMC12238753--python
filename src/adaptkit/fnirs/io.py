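"""Recording I/O: tabular time series + JSON montage/events, optional SNIRF.

The text format is the portable default: one CSV of intensities with a
``time_s`` column and ``{channel}@{wavelength}`` columns, plus a JSON sidecar
holding the channel table, event table, sampling rate and labels.  A minimal
SNIRF (HDF5) writer/reader is provided when ``h5py`` is importable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import FnirsRecording

__all__ = ["write_tabular", "read_tabular", "write_snirf", "read_snirf"]


def write_tabular(rec: FnirsRecording, csv_path, json_path=None) -> None:
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    cols = {"time_s": rec.times}
    for wl, arr in sorted(rec.intensity.items()):
        for j, name in enumerate(rec.channels["channel"]):
            cols[f"{name}@{wl}"] = arr[:, j]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "fs": rec.fs,
        "participant": rec.participant,
        "visit": rec.visit,
        "tens": rec.tens,
        "channels": rec.channels.where(rec.channels.notna(), None)
                                 .to_dict(orient="records"),
        "events": rec.events.to_dict(orient="records"),
        "ground_truth": _jsonable(rec.ground_truth),
        "meta": _jsonable(rec.meta),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))


def read_tabular(csv_path, json_path=None) -> FnirsRecording:
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    side = json.loads(json_path.read_text())
    df = pd.read_csv(csv_path)
    channels = pd.DataFrame(side["channels"])
    wls = sorted({int(c.split("@")[1]) for c in df.columns if "@" in c})
    intensity = {
        wl: np.column_stack([df[f"{name}@{wl}"].to_numpy()
                             for name in channels["channel"]])
        for wl in wls
    }
    return FnirsRecording(
        intensity=intensity, channels=channels,
        events=pd.DataFrame(side["events"]), fs=side["fs"],
        participant=side.get("participant"), visit=side.get("visit"),
        tens=side.get("tens"), ground_truth=side.get("ground_truth") or {},
        meta=side.get("meta") or {})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_snirf(rec: FnirsRecording, path) -> None:
    """Minimal SNIRF v1.0 writer (raw CW intensity), requires h5py."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        arrs = [rec.intensity[wl] for wl in sorted(rec.intensity)]
        d1.create_dataset("dataTimeSeries", data=np.hstack(arrs))
        d1.create_dataset("time", data=rec.times)
        k = 0
        for wi, wl in enumerate(sorted(rec.intensity), start=1):
            for j in range(len(rec.channels)):
                k += 1
                ml = d1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=j + 1)
                ml.create_dataset("detectorIndex", data=j + 1)
                ml.create_dataset("wavelengthIndex", data=wi)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=sorted(rec.intensity))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("channels_json",
                            data=rec.channels.to_json(orient="records"))
        meta.create_dataset("events_json",
                            data=rec.events.to_json(orient="records"))
        meta.create_dataset("fs", data=rec.fs)


def read_snirf(path) -> FnirsRecording:
    """Read a recording written by :func:`write_snirf`."""
    import h5py

    from io import StringIO

    def _as_str(v):
        return v.decode() if isinstance(v, bytes) else str(v)

    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        data = d1["dataTimeSeries"][()]
        meta = f["nirs/metaDataTags"]
        channels = pd.read_json(StringIO(_as_str(meta["channels_json"][()])),
                                orient="records")
        events = pd.read_json(StringIO(_as_str(meta["events_json"][()])),
                              orient="records")
        fs = float(meta["fs"][()])
        wls = [int(w) for w in f["nirs/probe/wavelengths"][()]]
    n = len(channels)
    intensity = {wl: data[:, i * n:(i + 1) * n] for i, wl in enumerate(sorted(wls))}
    return FnirsRecording(intensity=intensity, channels=channels,
                          events=events, fs=fs)
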