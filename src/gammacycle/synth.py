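"""Synthetic signal generation.

Everything the analysis pipeline consumes can be generated here: colored
(1/f^n) background noise, AR(2) and higher-order autoregressive
realizations, linear stochastic E-I circuit trajectories, additive
oscillation+noise mixtures, inhomogeneous Poisson spike trains modulated by
an excitatory population variable, and fixational eye traces with injected
microsaccades.

The AR(2) process is the package's central generative model: with complex
companion-matrix eigenvalues it is a damped harmonic oscillator forced by
white noise, and its eigenvalue magnitude (0 < |lambda| < 1) sets the
oscillation strength.  ``ar2_from_eigen`` maps (magnitude, peak frequency,
sampling rate) to the coefficients phi1 = 2 m cos(2 pi f / fs),
phi2 = -m^2.

Every operation takes an explicit seed (or a ``numpy.random.Generator``)
and is bit-reproducible; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, SpikeTrainSet

__all__ = [
    "ColoredNoiseSpec",
    "AR2Params",
    "EIWeights",
    "SpikeSimSpec",
    "generate_colored_noise",
    "ar2_from_eigen",
    "simulate_ar",
    "simulate_ei_circuit",
    "simulate_modulated_spikes",
    "add_noise_mixture",
    "generate_eye_trace",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColoredNoiseSpec:
    """1/f^n noise: amplitude coefficients scaled by 1/f^n, so power ~ 1/f^(2n)."""

    exponent: float
    n_samples: int
    n_traces: int = 1
    sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent):
            raise ValueError("exponent must be finite")
        if not 0.0 <= self.exponent <= 4.0:
            raise ValueError("exponent must lie in [0, 4]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")


@dataclass(frozen=True)
class AR2Params:
    """AR(2) coefficients x[t] = phi1 x[t-1] + phi2 x[t-2] + eps[t]."""

    phi1: float
    phi2: float
    sigma_z: float = 1.0
    sampling_rate: float = 1000.0

    @property
    def eigenvalues(self) -> np.ndarray:
        """Roots of lambda^2 - phi1 lambda - phi2 (companion eigenvalues)."""
        return np.roots([1.0, -self.phi1, -self.phi2])

    @property
    def is_stationary(self) -> bool:
        return bool(np.all(np.abs(self.eigenvalues) < 1.0))

    @property
    def is_oscillatory(self) -> bool:
        """Complex-conjugate eigenvalues, i.e. phi1^2 + 4 phi2 < 0."""
        return self.phi1 ** 2 + 4.0 * self.phi2 < 0.0

    @property
    def eigenvalue_magnitude(self) -> float:
        return float(np.max(np.abs(self.eigenvalues)))

    @property
    def peak_frequency(self) -> float:
        """Eigenvalue angle expressed in Hz (for complex eigenvalues)."""
        lam = self.eigenvalues
        ang = float(np.max(np.abs(np.angle(lam))))
        return ang / (2.0 * np.pi) * self.sampling_rate


@dataclass(frozen=True)
class EIWeights:
    """2x2 interaction matrix of the linear stochastic E-I circuit.

    The circuit iterates (with epsilon either shared between the two
    populations or drawn independently)::

        E[t] = v_ee E[t-1] + v_ei I[t-1] + eps_E[t]
        I[t] = v_ie E[t-1] + v_ii I[t-1] + eps_I[t]

    A complex-eigenvalue (oscillatory) regime requires v_ei * v_ie < 0:
    the two populations must have opposite interaction weights.
    """

    v_ee: float
    v_ei: float
    v_ie: float
    v_ii: float
    noise_sd: float = 1.0
    noise_shared: bool = True

    @property
    def matrix(self) -> np.ndarray:
        """Weight matrix V acting on the state (E, I)."""
        return np.array([[self.v_ee, self.v_ei], [self.v_ie, self.v_ii]])

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.matrix)

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(self.eigenvalues)))


@dataclass(frozen=True)
class SpikeSimSpec:
    """Inhomogeneous Poisson spiking driven by the E variable.

    Rate is ``link(base_rate + gain * E[t])`` with ``link`` either
    ``"rectified"`` (clip at zero, the default) or ``"exp"``
    (``base_rate * exp(gain * E[t])``).
    """

    base_rate: float
    gain: float = 0.0
    link: str = "rectified"
    n_units: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")
        if self.link not in ("rectified", "exp"):
            raise ValueError("link must be 'rectified' or 'exp'")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


# ---------------------------------------------------------------------------
# Colored noise
# ---------------------------------------------------------------------------

def generate_colored_noise(spec: ColoredNoiseSpec) -> ContinuousRecording:
    """Generate 1/f^n noise by frequency-domain shaping of white noise.

    White Gaussian traces are Fourier transformed, the complex coefficients
    of the positive frequencies are multiplied by 1/f^n, the spectrum is
    made Hermitian by concatenating the conjugated, reversed coefficients,
    and the result is inverse transformed.  The DC coefficient is set to
    zero (zero-mean output); for even lengths the Nyquist coefficient is
    made real.  Amplitude scaling by 1/f^n implies a power-spectral slope
    of -2n on a log-log plot.
    """
    rng = _rng(spec.seed)
    n = spec.n_samples
    white = rng.standard_normal((n, spec.n_traces))
    coef = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / freqs[1:] ** spec.exponent
    coef *= scale[:, None]
    if n % 2 == 0:
        # Nyquist bin of a real signal must be real.
        coef[-1] = coef[-1].real
    out = np.fft.irfft(coef, n=n, axis=0)
    return ContinuousRecording(data=out, sampling_rate=spec.sampling_rate)


# ---------------------------------------------------------------------------
# AR processes
# ---------------------------------------------------------------------------

def ar2_from_eigen(magnitude: float, peak_freq: float, sampling_rate: float,
                   sigma_z: float = 1.0) -> AR2Params:
    """AR(2) coefficients for given eigenvalue magnitude and peak frequency.

    The complex-conjugate eigenvalue pair ``m * exp(+/- i 2 pi f / fs)``
    corresponds to ``phi1 = 2 m cos(2 pi f / fs)`` and ``phi2 = -m^2``.
    """
    if not 0.0 < magnitude < 1.0:
        raise ValueError("magnitude must lie in (0, 1) for a stationary process")
    if not 0.0 < peak_freq < sampling_rate / 2.0:
        raise ValueError("peak_freq must lie strictly below the Nyquist frequency")
    theta = 2.0 * np.pi * peak_freq / sampling_rate
    return AR2Params(
        phi1=2.0 * magnitude * np.cos(theta),
        phi2=-magnitude ** 2,
        sigma_z=sigma_z,
        sampling_rate=sampling_rate,
    )


def _ar_coefficients(params) -> tuple[np.ndarray, float, float]:
    """Extract (phi vector, sigma_z, sampling_rate) from AR2Params or a vector."""
    if isinstance(params, AR2Params):
        return np.array([params.phi1, params.phi2]), params.sigma_z, params.sampling_rate
    phi = np.asarray(params, dtype=float)
    return phi, 1.0, 1000.0


def _check_stationary(phi: np.ndarray) -> np.ndarray:
    roots = np.roots(np.r_[1.0, -phi]) if len(phi) else np.array([])
    if len(roots) and np.max(np.abs(roots)) >= 1.0:
        raise ValueError(
            f"AR coefficients are non-stationary (max |root| = {np.max(np.abs(roots)):.4f})"
        )
    return roots


def default_burn_in(phi: np.ndarray) -> int:
    """Burn-in of 20 envelope decay times, 20 / (1 - max |root|) samples."""
    roots = np.roots(np.r_[1.0, -np.asarray(phi, float)]) if len(phi) else []
    m = np.max(np.abs(roots)) if len(roots) else 0.0
    return int(np.ceil(20.0 / max(1.0 - m, 1e-6)))


def simulate_ar(params, n_samples: int, seed=0, burn_in: int | None = None,
                n_trials: int = 1, sigma_z: float | None = None,
                sampling_rate: float | None = None,
                return_innovations: bool = False):
    """Simulate a stationary AR(p) process with Gaussian innovations.

    ``params`` is either an :class:`AR2Params` or a coefficient vector
    ``(phi_1, ..., phi_p)``.  Iterates
    ``x[t] = sum_k phi_k x[t-k] + eps[t]`` with ``eps ~ N(0, sigma_z^2)``,
    discarding ``burn_in`` initial samples (default: 20 envelope decay
    times).  Seeded runs are bit-reproducible.
    """
    phi, sz, fs = _ar_coefficients(params)
    if sigma_z is not None:
        sz = sigma_z
    if sampling_rate is not None:
        fs = sampling_rate
    _check_stationary(phi)
    if burn_in is None:
        burn_in = default_burn_in(phi)
    rng = _rng(seed)
    p = len(phi)
    total = n_samples + burn_in
    out = np.empty((n_samples, n_trials))
    kept_eps = np.empty((n_samples, n_trials)) if return_innovations else None
    from scipy.signal import lfilter

    for tr in range(n_trials):
        eps = rng.standard_normal(total) * sz
        # AR(p) recursion as an all-pole IIR filter: 1 / (1 - sum phi_k z^-k)
        x = lfilter([1.0], np.r_[1.0, -phi], eps)
        out[:, tr] = x[burn_in:]
        if return_innovations:
            kept_eps[:, tr] = eps[burn_in:]
    rec = ContinuousRecording(data=out, sampling_rate=fs)
    if return_innovations:
        return rec, kept_eps
    return rec


def ar_variance(params: AR2Params) -> float:
    """Analytic stationary variance of an AR(2) process."""
    p1, p2, s = params.phi1, params.phi2, params.sigma_z
    return s ** 2 * (1 - p2) / ((1 + p2) * ((1 - p2) ** 2 - p1 ** 2))


# ---------------------------------------------------------------------------
# E-I circuit
# ---------------------------------------------------------------------------

def simulate_ei_circuit(weights: EIWeights, n_samples: int, seed=0,
                        burn_in: int | None = None,
                        sampling_rate: float = 1000.0,
                        innovations: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the two-population linear stochastic difference system.

    Returns ``(E, I)`` series of length ``n_samples``.  With
    ``weights.noise_shared`` the same innovation enters both equations (the
    form induced by rewriting an AR(2), where the single innovation drives
    both state components); otherwise E and I receive independent noise.
    ``innovations`` may supply a precomputed noise array of shape
    ``(n_samples + burn_in, 2)`` for co-simulation against an AR(2).
    """
    V = weights.matrix
    if weights.spectral_radius >= 1.0:
        raise ValueError(
            f"spectral radius {weights.spectral_radius:.4f} >= 1: circuit is unstable"
        )
    if burn_in is None:
        burn_in = int(np.ceil(20.0 / max(1.0 - weights.spectral_radius, 1e-6)))
    total = n_samples + burn_in
    if innovations is None:
        rng = _rng(seed)
        if weights.noise_shared:
            e = rng.standard_normal(total) * weights.noise_sd
            innovations = np.column_stack([e, e])
        else:
            innovations = rng.standard_normal((total, 2)) * weights.noise_sd
    else:
        innovations = np.asarray(innovations, float)
        if innovations.shape != (total, 2):
            raise ValueError(f"innovations must have shape ({total}, 2)")
    state = np.zeros(2)
    traj = np.empty((total, 2))
    for t in range(total):
        state = V @ state + innovations[t]
        traj[t] = state
    kept = traj[burn_in:]
    return kept[:, 0], kept[:, 1]


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def simulate_modulated_spikes(e_signal: np.ndarray, spec: SpikeSimSpec,
                              sampling_rate: float, trial: int = 0
                              ) -> SpikeTrainSet:
    """Inhomogeneous Poisson spikes with rate driven by the E variable.

    The rate function is evaluated per sample, ``lambda(t) = link(base_rate
    + gain * E[t])`` (or ``base_rate * exp(gain * E[t])``), and spikes are
    drawn by thinning a homogeneous Poisson process at the rate maximum.
    """
    e = np.asarray(e_signal, dtype=float)
    if spec.link == "rectified":
        lam = np.clip(spec.base_rate + spec.gain * e, 0.0, None)
    else:
        lam = spec.base_rate * np.exp(spec.gain * e)
    if not np.all(np.isfinite(lam)):
        raise ValueError("rate function produced non-finite values")
    rng = _rng(spec.seed)
    duration = len(e) / sampling_rate
    lam_max = float(lam.max(initial=0.0))
    rows = []
    for unit in range(spec.n_units):
        if lam_max <= 0.0:
            continue
        n_cand = rng.poisson(lam_max * duration)
        t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        idx = np.minimum((t_cand * sampling_rate).astype(int), len(e) - 1)
        keep = rng.uniform(0.0, lam_max, size=n_cand) < lam[idx]
        for t in t_cand[keep]:
            rows.append({"unit_id": unit, "trial": trial, "time_s": t})
    df = pd.DataFrame(rows, columns=["unit_id", "trial", "time_s"])
    return SpikeTrainSet(df=df)


# ---------------------------------------------------------------------------
# Mixtures and eye traces
# ---------------------------------------------------------------------------

def add_noise_mixture(oscillation: ContinuousRecording,
                      noise: ContinuousRecording,
                      noise_level: float) -> ContinuousRecording:
    """Additive mixture with SD(noise)/SD(oscillation) = ``noise_level``."""
    if oscillation.data.shape != noise.data.shape:
        raise ValueError("oscillation and noise must have identical shapes")
    if oscillation.sampling_rate != noise.sampling_rate:
        raise ValueError("oscillation and noise must share a sampling rate")
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    if noise_level == 0:
        return oscillation.with_data(oscillation.data.copy())
    sd_osc = float(np.std(oscillation.data))
    sd_noise = float(np.std(noise.data))
    if sd_noise == 0:
        raise ValueError("noise has zero variance; cannot scale")
    scaled = noise.data * (noise_level * sd_osc / sd_noise)
    return oscillation.with_data(oscillation.data + scaled)


def generate_eye_trace(n_samples: int, sampling_rate: float,
                       microsaccade_times: np.ndarray,
                       amplitudes: np.ndarray,
                       durations: np.ndarray,
                       noise_sd: float = 0.01,
                       seed=0) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Fixational jitter plus ramped displacements at specified times.

    Returns horizontal and vertical position traces (degrees) and a ground
    truth table (``onset_s``, ``offset_s``, ``amplitude_deg``) for scoring
    a microsaccade detector.  Jitter is smoothed white noise (a crude model
    of slow drift + tremor); each injected event is a smooth sigmoidal ramp
    of the stated amplitude over the stated duration, displacing x and y by
    amplitude/sqrt(2) each.  Events must not overlap.
    """
    times = np.asarray(microsaccade_times, float)
    amps = np.broadcast_to(np.asarray(amplitudes, float), times.shape)
    durs = np.broadcast_to(np.asarray(durations, float), times.shape)
    order = np.argsort(times)
    times, amps, durs = times[order], amps[order], durs[order]
    for i in range(len(times) - 1):
        if times[i] + durs[i] > times[i + 1]:
            raise ValueError("injected microsaccade events overlap")
    rng = _rng(seed)
    t = np.arange(n_samples) / sampling_rate
    # Heavily smoothed white noise emulates drift-like fixational jitter.
    from scipy.ndimage import uniform_filter1d

    win = max(int(0.050 * sampling_rate), 1)
    x = uniform_filter1d(rng.standard_normal(n_samples), win) * noise_sd * np.sqrt(win)
    y = uniform_filter1d(rng.standard_normal(n_samples), win) * noise_sd * np.sqrt(win)
    truth_rows = []
    for t0, a, d in zip(times, amps, durs):
        ramp = 0.5 * (1.0 + np.tanh((t - (t0 + d / 2.0)) / (d / 6.0)))
        comp = a / np.sqrt(2.0)
        x = x + comp * ramp
        y = y + comp * ramp
        truth_rows.append({"onset_s": t0, "offset_s": t0 + d, "amplitude_deg": a})
    truth = pd.DataFrame(truth_rows, columns=["onset_s", "offset_s", "amplitude_deg"])
    return x, y, truth
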