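"""In-memory containers shared across the package.

The package revolves around three data objects:

``ContinuousRecording``
    A multi-trial, multi-channel sampled voltage signal (LFP-like) with its
    sampling rate and optional event markers (e.g. stimulus onsets).

``HalfCycleTable``
    The output of a cycle detector: one row per detected half-cycle (or full
    cycle) with its times, extremum voltages, amplitude, duration and
    polarity, grouped into oscillatory epochs.

``SpikeTrainSet``
    Per-unit spike event times with trial structure and optional waveform
    metadata.

All times are in seconds, sampling rates in Hz, trial/channel indices are
0-based, and time intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousRecording",
    "HalfCycleTable",
    "SpikeTrainSet",
    "CYCLE_COLUMNS",
]


def _as_3d(data: np.ndarray) -> np.ndarray:
    """Coerce a 1-D/2-D/3-D array to (samples, trials, channels)."""
    a = np.asarray(data, dtype=float)
    if a.ndim == 1:
        a = a[:, None, None]
    elif a.ndim == 2:
        a = a[:, :, None]
    elif a.ndim != 3:
        raise ValueError(f"data must be 1-, 2- or 3-D, got shape {a.shape}")
    return a


@dataclass
class ContinuousRecording:
    """Multi-trial sampled signal.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, n_trials, n_channels)``.  1-D or 2-D
        input is promoted by adding singleton trial/channel axes.
    sampling_rate
        Sampling rate in Hz.
    events
        Optional event table with columns ``trial``, ``time_s``, ``label``
        (e.g. stimulus onsets), times relative to trial start.
    units
        Physical units of the samples (bookkeeping only).
    """

    data: np.ndarray
    sampling_rate: float
    events: pd.DataFrame | None = None
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data)
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be a positive finite number")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to trial start."""
        return np.arange(self.n_samples) / self.sampling_rate

    def series(self, trial: int = 0, channel: int = 0) -> np.ndarray:
        """One (samples,) voltage trace."""
        return self.data[:, trial, channel]

    def squeeze1d(self) -> np.ndarray:
        """The single trace of a 1-trial, 1-channel recording."""
        if self.n_trials != 1 or self.n_channels != 1:
            raise ValueError("recording has more than one trial/channel")
        return self.data[:, 0, 0]

    def with_data(self, data: np.ndarray) -> "ContinuousRecording":
        """Copy of this recording with new samples (same rate/events)."""
        return ContinuousRecording(
            data=data,
            sampling_rate=self.sampling_rate,
            events=None if self.events is None else self.events.copy(),
            units=self.units,
        )


#: Column order of a serialized half-cycle table.
CYCLE_COLUMNS = [
    "trial",
    "channel",
    "epoch_id",
    "cycle_index",
    "polarity",
    "start_index",
    "end_index",
    "start_time",
    "end_time",
    "start_extremum_value",
    "end_extremum_value",
    "amplitude",
    "duration",
    "frequency",
]


@dataclass
class HalfCycleTable:
    """Detected half-cycles (one row each), grouped into epochs.

    ``polarity`` is ``"trough-peak"`` or ``"peak-trough"``.  ``epoch_id``
    labels maximal runs of contiguous surviving cycles; ``cycle_index``
    numbers half-cycles within their (trial, channel) in temporal order.
    ``frequency`` follows the half-cycle convention ``1 / (2 * duration)``,
    so a 10 ms half-cycle maps to 50 Hz.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CYCLE_COLUMNS))
    sampling_rate: float = float("nan")

    def __post_init__(self) -> None:
        missing = [c for c in CYCLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"half-cycle table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def empty(self) -> bool:
        return len(self.df) == 0

    def full_cycles(self) -> pd.DataFrame:
        """Peak-to-peak full cycles derived from consecutive half-cycles.

        A full cycle spans a peak→trough half-cycle followed by the next
        trough→peak half-cycle within the same epoch; its amplitude is the
        first peak minus the intervening trough, its duration the
        peak-to-peak interval, and its frequency ``1/duration``.
        """
        rows = []
        if self.empty:
            return pd.DataFrame(columns=CYCLE_COLUMNS)
        for (trial, channel, epoch), grp in self.df.groupby(
            ["trial", "channel", "epoch_id"], sort=True
        ):
            g = grp.sort_values("start_time").reset_index(drop=True)
            for i in range(len(g) - 1):
                a, b = g.iloc[i], g.iloc[i + 1]
                if a["polarity"] != "peak-trough" or b["polarity"] != "trough-peak":
                    continue
                if a["end_index"] != b["start_index"]:
                    continue
                duration = b["end_time"] - a["start_time"]
                rows.append(
                    {
                        "trial": trial,
                        "channel": channel,
                        "epoch_id": epoch,
                        "cycle_index": a["cycle_index"],
                        "polarity": "peak-peak",
                        "start_index": a["start_index"],
                        "end_index": b["end_index"],
                        "start_time": a["start_time"],
                        "end_time": b["end_time"],
                        "start_extremum_value": a["start_extremum_value"],
                        "end_extremum_value": b["end_extremum_value"],
                        "amplitude": abs(a["start_extremum_value"] - a["end_extremum_value"]),
                        "duration": duration,
                        "frequency": 1.0 / duration,
                    }
                )
        return pd.DataFrame(rows, columns=CYCLE_COLUMNS)

    def frequencies(self) -> np.ndarray:
        """Half-cycle frequencies in Hz."""
        return self.df["frequency"].to_numpy()

    def amplitudes(self) -> np.ndarray:
        return self.df["amplitude"].to_numpy()

    def durations(self) -> np.ndarray:
        return self.df["duration"].to_numpy()


@dataclass
class SpikeTrainSet:
    """Spike events for a set of units.

    ``df`` columns: ``unit_id``, ``trial``, ``time_s`` (sorted within
    (unit, trial)); optional ``waveform_peak_to_trough`` (ms) and
    ``unit_class``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"unit_id", "trial", "time_s"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"spike table missing columns: {sorted(missing)}")
        for (_, _), grp in self.df.groupby(["unit_id", "trial"], sort=False):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError("spike times must be sorted within each (unit, trial)")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def unit_ids(self) -> np.ndarray:
        return np.unique(self.df["unit_id"].to_numpy())

    def unit(self, unit_id) -> pd.DataFrame:
        return self.df[self.df["unit_id"] == unit_id]
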