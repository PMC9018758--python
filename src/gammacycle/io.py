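"""File formats: HDF5 containers and delimited-text mirrors.

Recordings, cycle tables and spike trains round-trip through an HDF5
container (full numeric precision) for real use, and through plain CSV
for small fixtures and diffs.  Extension selects the format: ``.h5`` /
``.hdf5`` for the binary container, anything else is treated as CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import CYCLE_COLUMNS, ContinuousRecording, HalfCycleTable, SpikeTrainSet

__all__ = [
    "write_recording", "read_recording",
    "write_cycles", "read_cycles",
    "write_spikes", "read_spikes",
]

_EVENT_COLS = ["trial", "time_s", "label"]


def _is_hdf5(path) -> bool:
    return Path(path).suffix.lower() in (".h5", ".hdf5")


def write_recording(path, rec: ContinuousRecording) -> None:
    """Write a recording (HDF5: datasets + attributes; CSV: long format)."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "w") as h:
            d = h.create_dataset("samples", data=rec.data)
            d.attrs["sampling_rate_hz"] = rec.sampling_rate
            d.attrs["units"] = rec.units
            if rec.events is not None and len(rec.events):
                ev = h.create_group("events")
                ev.create_dataset("trial", data=rec.events["trial"].to_numpy(int))
                ev.create_dataset("time_s", data=rec.events["time_s"].to_numpy(float))
                labels = rec.events.get("label", pd.Series([""] * len(rec.events)))
                ev.create_dataset("label", data=np.array(labels, dtype="S64"))
        return
    t, tr, ch = np.meshgrid(np.arange(rec.n_samples), np.arange(rec.n_trials),
                            np.arange(rec.n_channels), indexing="ij")
    df = pd.DataFrame({
        "sample": t.ravel(), "trial": tr.ravel(), "channel": ch.ravel(),
        "value": rec.data.ravel(),
    })
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rec.sampling_rate!r} units={rec.units}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_recording(path) -> ContinuousRecording:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as h:
            d = h["samples"]
            data = d[()]
            fs = float(d.attrs["sampling_rate_hz"])
            units = str(d.attrs.get("units", "a.u."))
            events = None
            if "events" in h:
                ev = h["events"]
                events = pd.DataFrame({
                    "trial": ev["trial"][()],
                    "time_s": ev["time_s"][()],
                    "label": [s.decode() for s in ev["label"][()]],
                })
        return ContinuousRecording(data=data, sampling_rate=fs,
                                   events=events, units=units)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(kv.split("=", 1) for kv in header[1:].split())
        df = pd.read_csv(fh, float_precision="round_trip")
    fs = float(meta["sampling_rate_hz"])
    n_s = int(df["sample"].max()) + 1
    n_t = int(df["trial"].max()) + 1
    n_c = int(df["channel"].max()) + 1
    data = np.full((n_s, n_t, n_c), np.nan)
    data[df["sample"], df["trial"], df["channel"]] = df["value"]
    return ContinuousRecording(data=data, sampling_rate=fs,
                               units=meta.get("units", "a.u."))


def write_cycles(path, table: HalfCycleTable) -> None:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "w") as h:
            g = h.create_group("cycles")
            g.attrs["sampling_rate_hz"] = table.sampling_rate
            for col in CYCLE_COLUMNS:
                v = table.df[col].to_numpy()
                if v.dtype == object:
                    v = np.array(v, dtype="S16")
                g.create_dataset(col, data=v)
        return
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={table.sampling_rate!r}\n")
        table.df.to_csv(fh, index=False, float_format="%.17g")


def read_cycles(path) -> HalfCycleTable:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as h:
            g = h["cycles"]
            cols = {}
            for col in CYCLE_COLUMNS:
                v = g[col][()]
                if v.dtype.kind == "S":
                    v = np.array([s.decode() for s in v])
                cols[col] = v
            fs = float(g.attrs["sampling_rate_hz"])
        return HalfCycleTable(df=pd.DataFrame(cols), sampling_rate=fs)
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=", 1) for kv in header[1:].split()) \
            if header.startswith("#") else {}
        df = pd.read_csv(fh, float_precision="round_trip")  # header-keyed: column order is irrelevant
    return HalfCycleTable(df=df[CYCLE_COLUMNS],
                          sampling_rate=float(meta.get("sampling_rate_hz", "nan")))


def write_spikes(path, spikes: SpikeTrainSet) -> None:
    spikes.df.to_csv(path, index=False, float_format="%.17g")


def read_spikes(path) -> SpikeTrainSet:
    df = pd.read_csv(path, float_precision="round_trip")
    # Reject unsorted spike times with the offending line number.
    for (_, _), grp in df.groupby(["unit_id", "trial"], sort=False):
        t = grp["time_s"].to_numpy()
        bad = np.flatnonzero(np.diff(t) < 0)
        if bad.size:
            line = int(grp.index[bad[0] + 1]) + 2  # +header +1-based
            raise ValueError(f"{path}: unsorted spike time at line {line}")
    return SpikeTrainSet(df=df)
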