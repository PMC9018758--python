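"""Spectral estimation and AR modelling.

Fourier power spectra (Hann or rectangular taper), baseline normalization,
sliding time-frequency power, the analytic AR(2) spectrum

    S(f) = sigma_z^2 / (1 + phi1^2 + phi2^2
                        - 2 phi1 (1 - phi2) cos(2 pi f)
                        - 2 phi2 cos(4 pi f)),

with f in cycles/sample, least-squares fitting of AR(2) parameters to an
empirical spectrum with eigenvalue extraction, high-order AR surrogate
fitting, and the phase-plane density of the analytic signal.

The AR(2) spectrum has a single interior maximum for complex eigenvalues;
its sharpness grows as the eigenvalue magnitude approaches 1, which is the
spectral signature of a noise-driven damped harmonic oscillator close to
criticality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as opt
from scipy import signal as sps

from .containers import ContinuousRecording
from .synth import AR2Params

__all__ = [
    "Spectrum",
    "AR2Model",
    "power_spectrum",
    "baseline_normalize",
    "tfr",
    "ar2_spectrum",
    "ar2_spectral_density",
    "ar2_peak_frequency",
    "fit_ar2",
    "fit_arp",
    "phase_plane_density",
]


@dataclass
class Spectrum:
    """One-sided power spectrum.

    ``power`` is a spectral density (signal units^2 / Hz) for raw spectra,
    or dimensionless after baseline normalization.  Integrating the density
    over frequency recovers the signal variance (Parseval).
    """

    frequencies: np.ndarray
    power: np.ndarray
    taper: str = "hann"
    epoch_length: float = float("nan")
    relative: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.power = np.asarray(self.power, float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def band(self, lo: float, hi: float) -> "Spectrum":
        sel = (self.frequencies >= lo) & (self.frequencies <= hi)
        return Spectrum(self.frequencies[sel], self.power[sel],
                        taper=self.taper, epoch_length=self.epoch_length,
                        relative=self.relative)

    @property
    def peak_frequency(self) -> float:
        return float(self.frequencies[int(np.argmax(self.power))])


@dataclass
class AR2Model:
    """A fitted (or specified) AR(2) oscillator model."""

    params: AR2Params
    fit_error: float = float("nan")
    fit_band: tuple | None = None

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.params.eigenvalues

    @property
    def eigenvalue_magnitude(self) -> float:
        return self.params.eigenvalue_magnitude

    @property
    def is_oscillatory(self) -> bool:
        return self.params.is_oscillatory

    @property
    def peak_frequency(self) -> float:
        """Frequency (Hz) of the spectral maximum of S(f)."""
        return ar2_peak_frequency(self.params)

    def to_record(self) -> dict:
        lam = np.sort_complex(self.eigenvalues)[-1]
        return {
            "phi1": self.params.phi1,
            "phi2": self.params.phi2,
            "sigma_z": self.params.sigma_z,
            "eig_re": float(lam.real),
            "eig_im": float(abs(lam.imag)),
            "eig_mag": self.eigenvalue_magnitude,
            "peak_hz": self.peak_frequency if self.is_oscillatory else float("nan"),
            "fit_err": self.fit_error,
        }


# ---------------------------------------------------------------------------
# Empirical spectra
# ---------------------------------------------------------------------------

def _epoch_array(data, epoch_length: float | None, sampling_rate: float | None):
    """Normalize input to (epoch array list, fs)."""
    if isinstance(data, ContinuousRecording):
        fs = data.sampling_rate
        if epoch_length is None:
            epochs = [data.data[:, tr, ch] for tr in range(data.n_trials)
                      for ch in range(data.n_channels)]
        else:
            n = int(round(epoch_length * fs))
            if n > data.n_samples:
                raise ValueError("epoch longer than the recording")
            n_ep = data.n_samples // n
            epochs = [data.data[k * n:(k + 1) * n, tr, ch]
                      for tr in range(data.n_trials)
                      for ch in range(data.n_channels)
                      for k in range(n_ep)]
        return epochs, fs
    if sampling_rate is None:
        raise ValueError("sampling_rate required for plain-array input")
    arr = [np.asarray(e, float) for e in data]
    return arr, sampling_rate


def power_spectrum(data, taper: str = "hann", epoch_length: float | None = None,
                   sampling_rate: float | None = None) -> Spectrum:
    """Averaged tapered periodogram over epochs and trials.

    ``data`` is a :class:`ContinuousRecording` (optionally re-cut into
    non-overlapping epochs of ``epoch_length`` seconds) or a sequence of
    equal-length 1-D epochs with an explicit ``sampling_rate``.  The output
    is a one-sided spectral density normalized so that its integral over
    frequency equals the signal variance.  The rectangular taper minimizes
    spectral smearing around sharp peaks and is the right choice when the
    spectrum feeds the AR(2) fit.
    """
    epochs, fs = _epoch_array(data, epoch_length, sampling_rate)
    if not epochs:
        raise ValueError("no epochs to average")
    n = len(epochs[0])
    if any(len(e) != n for e in epochs):
        raise ValueError("epochs must share a common length")
    if taper == "hann":
        w = sps.windows.hann(n, sym=False)
    elif taper in ("rect", "rectangular", "boxcar"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    u = np.mean(w ** 2)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    acc = np.zeros(len(freqs))
    for e in epochs:
        spec = np.fft.rfft(w * e)
        p = np.abs(spec) ** 2 / (fs * n * u)
        p[1:] *= 2.0
        if n % 2 == 0:
            p[-1] /= 2.0
        acc += p
    acc /= len(epochs)
    return Spectrum(frequencies=freqs, power=acc, taper=taper,
                    epoch_length=n / fs)


def baseline_normalize(stim: Spectrum, base: Spectrum) -> Spectrum:
    """Relative power change, (stim - base) / base per frequency bin."""
    if not np.array_equal(stim.frequencies, base.frequencies):
        raise ValueError("spectra must share a frequency grid")
    if np.any(base.power <= 0):
        raise ValueError("baseline power must be strictly positive everywhere")
    return Spectrum(frequencies=stim.frequencies.copy(),
                    power=(stim.power - base.power) / base.power,
                    taper=stim.taper, epoch_length=stim.epoch_length,
                    relative=True)


def tfr(x: np.ndarray, sampling_rate: float, frequencies: np.ndarray,
        window_cycles: float = 2.5, step: float = 0.001
        ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window power per frequency (window = +/-``window_cycles``).

    For each frequency f the window spans ``2 * window_cycles / f`` seconds
    (Hann tapered) and slides in steps of ``step`` seconds; power at f is
    the squared magnitude of the tapered Fourier coefficient at f.  Returns
    ``(window-center times, power array of shape (n_freqs, n_times))``.
    """
    x = np.asarray(x, float)
    frequencies = np.asarray(frequencies, float)
    nstep = max(int(round(step * sampling_rate)), 1)
    n_max = int(round(2 * window_cycles / frequencies.min() * sampling_rate))
    if n_max > len(x):
        raise ValueError("lowest frequency's window does not fit in the trial")
    centers = np.arange(n_max // 2, len(x) - (n_max - n_max // 2) + 1, nstep)
    out = np.full((len(frequencies), len(centers)), np.nan)
    t = np.arange(len(x)) / sampling_rate
    for i, f in enumerate(frequencies):
        nwin = int(round(2 * window_cycles / f * sampling_rate))
        w = sps.windows.hann(nwin, sym=False)
        w /= np.linalg.norm(w)
        carrier = np.exp(-2j * np.pi * f * np.arange(nwin) / sampling_rate)
        kern = w * carrier
        for j, c in enumerate(centers):
            lo = c - nwin // 2
            hi = lo + nwin
            if lo < 0 or hi > len(x):
                continue
            out[i, j] = np.abs(np.dot(kern, x[lo:hi])) ** 2
    return t[centers], out


# ---------------------------------------------------------------------------
# AR(2) analytic spectrum and fitting
# ---------------------------------------------------------------------------

def _ar2_denominator(phi1: float, phi2: float, f_norm: np.ndarray) -> np.ndarray:
    return (1.0 + phi1 ** 2 + phi2 ** 2
            - 2.0 * phi1 * (1.0 - phi2) * np.cos(2.0 * np.pi * f_norm)
            - 2.0 * phi2 * np.cos(4.0 * np.pi * f_norm))


def ar2_spectrum(params: AR2Params, frequencies: np.ndarray) -> Spectrum:
    """Analytic AR(2) power spectrum S(f) on a grid of frequencies in Hz.

    The formula's frequency argument is normalized (cycles/sample); Hz
    input is divided by the sampling rate internally.  For white noise
    (phi1 = phi2 = 0) the spectrum is flat at sigma_z^2.
    """
    f = np.asarray(frequencies, float)
    if np.any(f >= params.sampling_rate / 2.0 + 1e-9):
        raise ValueError("frequencies must lie below Nyquist")
    denom = _ar2_denominator(params.phi1, params.phi2, f / params.sampling_rate)
    if np.any(denom <= 0):
        raise ValueError("non-positive spectral denominator: parameters non-stationary")
    return Spectrum(frequencies=f, power=params.sigma_z ** 2 / denom,
                    taper="analytic")


def ar2_spectral_density(params: AR2Params, frequencies: np.ndarray) -> Spectrum:
    """One-sided AR(2) spectral density, 2/fs * S(f), comparable to
    :func:`power_spectrum` output (integral over [0, Nyquist] = variance)."""
    s = ar2_spectrum(params, frequencies)
    return Spectrum(frequencies=s.frequencies,
                    power=s.power * 2.0 / params.sampling_rate,
                    taper="analytic")


def ar2_peak_frequency(params: AR2Params) -> float:
    """Frequency (Hz) maximizing S(f); closed form for complex eigenvalues.

    dS/df vanishes where cos(2 pi f/fs) = -phi1 (1 - phi2) / (4 phi2).
    Falls back to 0 or Nyquist when the stationary point leaves [-1, 1].
    """
    p1, p2, fs = params.phi1, params.phi2, params.sampling_rate
    if p2 == 0:
        return 0.0 if p1 >= 0 else fs / 2.0
    c = -p1 * (1.0 - p2) / (4.0 * p2)
    if not -1.0 < c < 1.0:
        grid = np.linspace(0.0, fs / 2.0 * 0.999, 4096)
        d = _ar2_denominator(p1, p2, grid / fs)
        return float(grid[int(np.argmin(d))])
    return float(np.arccos(c) / (2.0 * np.pi) * fs)


def fit_ar2(spectrum: Spectrum, fit_band: tuple[float, float],
            sampling_rate: float, init: AR2Params | None = None,
            max_iter: int = 4000) -> AR2Model:
    """Fit AR(2) parameters to an empirical spectrum by squared error.

    Minimizes ``sum_band (density(f; phi1, phi2, sigma_z) - P(f))^2`` with
    a derivative-free simplex, multi-started over a coarse grid of
    eigenvalue magnitude and peak frequency (plus ``init`` when supplied).
    The innovation scale is profiled out analytically at each step: for a
    fixed spectral shape the optimal sigma_z^2 is a linear least-squares
    scale factor.  Raises if the best fit is non-stationary.
    """
    lo, hi = fit_band
    sel = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    if sel.sum() < 4:
        raise ValueError("fit band covers fewer than 4 frequency bins")
    f = spectrum.frequencies[sel]
    p_emp = spectrum.power[sel]
    fs = sampling_rate
    f_norm = f / fs

    def sse(theta) -> tuple[float, float]:
        phi1, phi2 = theta
        # keep the search inside the stationarity triangle so degenerate
        # (e.g. flat) spectra collapse to |lambda| -> 0 instead of running
        # off to explosive parameters
        if abs(phi2) >= 1.0 or abs(phi1) >= 1.0 - phi2:
            return np.inf, 0.0
        denom = _ar2_denominator(phi1, phi2, f_norm)
        if np.any(denom <= 1e-12):
            return np.inf, 0.0
        shape = (2.0 / fs) / denom
        scale = float(np.dot(shape, p_emp) / np.dot(shape, shape))
        if scale <= 0:
            return np.inf, 0.0
        resid = scale * shape - p_emp
        return float(np.dot(resid, resid)), scale

    starts = []
    if init is not None:
        starts.append((init.phi1, init.phi2))
    for m in (0.9, 0.95, 0.97, 0.99):
        for fpk in np.linspace(lo, hi, 5):
            th = 2.0 * np.pi * fpk / fs
            starts.append((2.0 * m * np.cos(th), -m * m))
    best = None
    for x0 in starts:
        res = opt.minimize(lambda th: sse(th)[0], x0=np.asarray(x0),
                           method="Nelder-Mead",
                           options={"maxiter": max_iter, "xatol": 1e-10,
                                    "fatol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("AR(2) spectral fit did not converge")
    phi1, phi2 = best.x
    err, scale = sse(best.x)
    params = AR2Params(phi1=float(phi1), phi2=float(phi2),
                       sigma_z=float(np.sqrt(scale)), sampling_rate=fs)
    if not params.is_stationary:
        raise RuntimeError(
            f"fitted AR(2) is non-stationary (|lambda| = {params.eigenvalue_magnitude:.4f})"
        )
    return AR2Model(params=params, fit_error=err, fit_band=(lo, hi))


def fit_arp(data, order: int, sampling_rate: float | None = None
            ) -> tuple[np.ndarray, float]:
    """Least-squares AR(p) fit, simultaneously to all trials.

    Stacks the lagged regression ``x[t] = sum_k phi_k x[t-k] + eps`` over
    every trial/channel and solves the joint normal equations.  Returns the
    coefficient vector (generator-ready for :func:`gammacycle.synth.simulate_ar`)
    and the innovation SD.  Raises on non-stationary solutions.
    """
    if isinstance(data, ContinuousRecording):
        traces = [data.series(tr, ch) for tr in range(data.n_trials)
                  for ch in range(data.n_channels)]
    else:
        traces = [np.asarray(t, float) for t in np.atleast_2d(data)]
    rows_X, rows_y = [], []
    for x in traces:
        if len(x) <= order + 1:
            raise ValueError("trace shorter than the AR order")
        X = np.column_stack([x[order - k - 1: len(x) - k - 1] for k in range(order)])
        rows_X.append(X)
        rows_y.append(x[order:])
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)
    phi, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ phi
    sigma = float(np.std(resid, ddof=order))
    roots = np.roots(np.r_[1.0, -phi])
    if np.max(np.abs(roots)) >= 1.0:
        raise RuntimeError("fitted AR(p) coefficients are non-stationary")
    return phi, sigma


def phase_plane_density(x: np.ndarray, grid: int = 61, zmax: float = 3.0,
                        highpass: tuple[float, float] | None = None,
                        sampling_rate: float | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint density of the z-scored real and imaginary analytic components.

    For a noise-driven damped oscillator the density has a single central
    focus (radially decreasing); a pure sinusoid gives an annulus.  Returns
    (x edges, y edges, density) with density normalized to unit sum.
    """
    x = np.asarray(x, float)
    if np.std(x) == 0:
        raise ValueError("constant signal has no phase plane")
    if highpass is not None:
        if sampling_rate is None:
            raise ValueError("sampling_rate required with highpass")
        sos = sps.butter(3, np.asarray(highpass) / (sampling_rate / 2.0),
                         btype="highpass" if np.size(highpass) == 1 else "bandpass",
                         output="sos")
        x = sps.sosfiltfilt(sos, x)
    z = sps.hilbert(x)
    re = (z.real - z.real.mean()) / z.real.std()
    im = (z.imag - z.imag.mean()) / z.imag.std()
    edges = np.linspace(-zmax, zmax, grid + 1)
    h, _, _ = np.histogram2d(re, im, bins=[edges, edges])
    h /= h.sum()
    return edges, edges, h
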