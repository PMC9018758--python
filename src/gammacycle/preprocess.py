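"""Filtering, epoch segmentation and eye-movement event detection.

These are the steps applied before cycle detection and spectral analysis:
zero-phase Butterworth filtering, the 40 ms moving-average high-pass used
by the baseline peak/trough cycle detector, backward epoch cutting that
excludes data shortly after stimulus onset, and a velocity-threshold
microsaccade detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import ContinuousRecording

__all__ = [
    "FilterSpec",
    "EpochPlan",
    "apply_filter",
    "boxcar_highpass",
    "segment_epochs",
    "detect_microsaccades",
    "decimate_recording",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification.

    ``kind`` is one of ``low``, ``high``, ``band``, ``band-stop``;
    ``corners`` the corner frequency (Hz) or (low, high) pair; ``order``
    the design order; ``two_pass`` selects zero-phase forward-backward
    application (squares the magnitude response, cancels phase).
    """

    kind: str
    corners: tuple
    order: int = 3
    two_pass: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("low", "high", "band", "band-stop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        c = np.atleast_1d(np.asarray(self.corners, float))
        if self.kind in ("band", "band-stop"):
            if c.size != 2 or not c[0] < c[1]:
                raise ValueError("band filters need ordered (low, high) corners")
        elif c.size != 1:
            raise ValueError("low/high filters take a single corner")
        if np.any(c <= 0):
            raise ValueError("corners must be positive")

    def sos(self, sampling_rate: float) -> np.ndarray:
        c = np.atleast_1d(np.asarray(self.corners, float))
        nyq = sampling_rate / 2.0
        if np.any(c >= nyq):
            raise ValueError(f"corner {c.max()} Hz at or above Nyquist ({nyq} Hz)")
        btype = {"low": "lowpass", "high": "highpass",
                 "band": "bandpass", "band-stop": "bandstop"}[self.kind]
        wn = c / nyq
        return sps.butter(self.order, wn if wn.size > 1 else wn[0],
                          btype=btype, output="sos")


@dataclass(frozen=True)
class EpochPlan:
    """Backward epoch cutting within a trial period.

    ``period`` is the (start, end) of the usable period in seconds relative
    to trial start; ``epoch_length`` the fixed epoch length; epochs are cut
    backward from the period end, and any epoch that would include data
    within ``exclusion_after_event`` seconds of ``event_time`` is dropped.
    """

    period: tuple
    epoch_length: float
    exclusion_after_event: float = 0.5
    event_time: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.period[1] <= self.period[0]:
            raise ValueError("period must have positive length")


def apply_filter(rec: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    """Apply a Butterworth filter to every trace of a recording.

    With ``two_pass`` the filter runs forward and backward (``sosfiltfilt``
    with reflect padding of one transient length), giving zero phase
    distortion at the cost of doubling the effective magnitude order.
    """
    sos = spec.sos(rec.sampling_rate)
    out = np.empty_like(rec.data)
    for tr in range(rec.n_trials):
        for ch in range(rec.n_channels):
            x = rec.data[:, tr, ch]
            if spec.two_pass:
                out[:, tr, ch] = sps.sosfiltfilt(sos, x)
            else:
                out[:, tr, ch] = sps.sosfilt(sos, x)
    return rec.with_data(out)


def boxcar_highpass(rec: ContinuousRecording, window: float = 0.040) -> ContinuousRecording:
    """Subtract a centered moving average (default 40 ms) from the signal.

    Removing the boxcar-smoothed trace acts as a ~20 Hz high-pass for the
    default window.  Edges use a truncated window so the output keeps the
    input length.
    """
    from scipy.ndimage import uniform_filter1d

    win = int(round(window * rec.sampling_rate))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    if win > rec.n_samples:
        raise ValueError("window longer than the signal")
    smoothed = uniform_filter1d(rec.data, size=win, axis=0, mode="nearest")
    return rec.with_data(rec.data - smoothed)


def segment_epochs(rec: ContinuousRecording, plan: EpochPlan) -> list[np.ndarray]:
    """Cut fixed-length, non-overlapping epochs backward from the period end.

    Returns a list of ``(epoch_samples, n_trials, n_channels)`` arrays in
    temporal order.  Epochs never extend before ``event_time +
    exclusion_after_event`` nor outside the stated period.  A period too
    short for a single epoch yields an empty list.
    """
    fs = rec.sampling_rate
    start_lim = max(plan.period[0], plan.event_time + plan.exclusion_after_event)
    end = plan.period[1]
    n_ep = int(np.floor((end - start_lim) / plan.epoch_length + 1e-9))
    epochs = []
    ep_samp = int(round(plan.epoch_length * fs))
    for k in range(n_ep, 0, -1):
        t0 = end - k * plan.epoch_length
        i0 = int(round(t0 * fs))
        if i0 < 0 or i0 + ep_samp > rec.n_samples:
            continue
        epochs.append(rec.data[i0:i0 + ep_samp])
    return epochs


def detect_microsaccades(x: np.ndarray, y: np.ndarray, sampling_rate: float,
                         threshold_sd: float = 4.0,
                         min_duration: float = 0.030,
                         smooth_halfwidth: float = 0.015) -> pd.DataFrame:
    """Velocity-threshold microsaccade detection on one trial.

    Positions are smoothed by replacing each value with the mean over
    itself +/- ``smooth_halfwidth`` (default 15 ms); eye speed is the
    magnitude of the first temporal derivative of (x, y); the speed SD is
    computed for the trial, and contiguous runs with speed above
    ``threshold_sd`` SDs lasting at least ``min_duration`` are returned as
    events (columns ``onset_s``, ``offset_s``, ``peak_speed``).
    """
    from scipy.ndimage import uniform_filter1d

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    win = 2 * int(round(smooth_halfwidth * sampling_rate)) + 1
    if win > len(x):
        raise ValueError("trial shorter than the smoothing window")
    xs = uniform_filter1d(x, size=win, mode="nearest")
    ys = uniform_filter1d(y, size=win, mode="nearest")
    vx = np.diff(xs) * sampling_rate
    vy = np.diff(ys) * sampling_rate
    speed = np.hypot(vx, vy)
    sd = speed.std()
    if sd == 0:
        return pd.DataFrame(columns=["onset_s", "offset_s", "peak_speed"])
    above = speed > threshold_sd * sd
    events = []
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    for i in range(0, len(edges), 2):
        a, b = edges[i], edges[i + 1]
        dur = (b - a) / sampling_rate
        if dur >= min_duration:
            events.append({
                "onset_s": a / sampling_rate,
                "offset_s": b / sampling_rate,
                "peak_speed": float(speed[a:b].max()),
            })
    return pd.DataFrame(events, columns=["onset_s", "offset_s", "peak_speed"])


def decimate_recording(rec: ContinuousRecording, factor: int) -> ContinuousRecording:
    """Anti-aliased decimation by an integer factor (zero-phase FIR)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return rec.with_data(rec.data.copy())
    out = sps.decimate(rec.data, factor, axis=0, ftype="fir", zero_phase=True)
    return ContinuousRecording(data=out, sampling_rate=rec.sampling_rate / factor,
                               events=None if rec.events is None else rec.events.copy(),
                               units=rec.units)
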