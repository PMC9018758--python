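"""AR(2) <-> linear E-I circuit correspondence.

An AR(2) process x[t] = phi1 x[t-1] + phi2 x[t-2] + eps[t] is a
first-order system on the state (x[t], x[t-1]) with companion matrix
C = [[phi1, phi2], [1, 0]].  Any invertible change of basis T produces an
equivalent two-variable system y[t] = V y[t-1] + T (eps, 0) with
V = T C T^{-1}; for a real T with complex companion eigenvalues the
off-diagonal weights of V always have opposite signs (v_ei * v_ie < 0),
which is the linear analogue of an excitatory-inhibitory loop.  Choosing
T from a pair of lag-1 filters E[t] = x[t] - c_E x[t-1],
I[t] = x[t] - c_I x[t-1] makes both transformed variables receive the
*same* innovation (T maps (eps, 0) to (eps, eps)), the signal is an exact
linear combination x = w_E E + w_I I with w_E + w_I = 1 and
w_E c_E + w_I c_I = 0, and for the documented filter family the E
component phase-leads the I component at the spectral peak, as in PING
models of gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth import AR2Params, EIWeights

__all__ = [
    "EIDecomposition",
    "EICircuit",
    "ar2_to_ei",
    "cosimulate",
    "decompose_signal",
    "phase_lead",
    "filter_phase_lead",
    "DEFAULT_C_E",
    "DEFAULT_C_I",
]

#: Canonical lag-1 filter coefficients of the default decomposition.
DEFAULT_C_E = 1.1
DEFAULT_C_I = 0.86


@dataclass
class EIDecomposition:
    """Lag-1 filter decomposition of a scalar signal into E and I."""

    c_E: float
    c_I: float
    w_E: float
    w_I: float
    E: np.ndarray | None = None
    I: np.ndarray | None = None
    phase_lead_ms: float = float("nan")


@dataclass
class EICircuit:
    """E-I weight matrix equivalent to a source AR(2) model."""

    weights: EIWeights
    source_params: AR2Params
    transformation: np.ndarray

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.weights.eigenvalues

    def companion_roundtrip(self) -> np.ndarray:
        """Recover the companion matrix T^{-1} V T (similarity inverse)."""
        T = self.transformation
        return np.linalg.solve(T, self.weights.matrix @ T)


def _solve_weights(c_E: float, c_I: float) -> tuple[float, float]:
    """Solve {w_E + w_I = 1, w_E c_E + w_I c_I = 0} for the reconstruction."""
    if c_E == c_I:
        raise ValueError("c_E must differ from c_I (decomposition singular)")
    A = np.array([[1.0, 1.0], [c_E, c_I]])
    w = np.linalg.solve(A, np.array([1.0, 0.0]))
    return float(w[0]), float(w[1])


def transformation_from_filters(c_E: float, c_I: float) -> np.ndarray:
    """Change of basis (x[t], x[t-1]) -> (E[t], I[t]) for lag-1 filters."""
    if c_E == c_I:
        raise ValueError("c_E must differ from c_I")
    return np.array([[1.0, -c_E], [1.0, -c_I]])


def ar2_to_ei(params: AR2Params, c_E: float = DEFAULT_C_E,
              c_I: float = DEFAULT_C_I,
              transformation: np.ndarray | None = None) -> EICircuit:
    """Rewrite an AR(2) as an equivalent linear E-I circuit.

    ``transformation`` may supply any invertible 2x2 change of basis; the
    default is the one induced by the canonical lag-1 filters
    (c_E, c_I) = (1.1, 0.86).  Eigenvalues are preserved by similarity,
    and for complex eigenvalues the resulting off-diagonal interaction
    weights satisfy v_ei * v_ie < 0.
    """
    if not params.is_oscillatory:
        raise ValueError("AR(2) has real eigenvalues; no oscillatory circuit")
    if transformation is None:
        T = transformation_from_filters(c_E, c_I)
    else:
        T = np.asarray(transformation, float)
        if T.shape != (2, 2) or abs(np.linalg.det(T)) < 1e-12:
            raise ValueError("transformation must be an invertible 2x2 matrix")
    C = np.array([[params.phi1, params.phi2], [1.0, 0.0]])
    V = T @ C @ np.linalg.inv(T)
    noise_vec = T @ np.array([1.0, 0.0])
    shared = bool(np.allclose(noise_vec, noise_vec[0]))
    weights = EIWeights(v_ee=float(V[0, 0]), v_ei=float(V[0, 1]),
                        v_ie=float(V[1, 0]), v_ii=float(V[1, 1]),
                        noise_sd=params.sigma_z, noise_shared=shared)
    return EICircuit(weights=weights, source_params=params, transformation=T)


def cosimulate(circuit: EICircuit, innovations: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drive the circuit with an explicit AR(2) innovation stream.

    ``innovations`` is the 1-D eps series of the source AR(2).  Returns
    (E, I, x) where x is reconstructed from the circuit state via the
    inverse transformation; it coincides to machine precision with the
    AR(2) recursion driven by the same stream.
    """
    eps = np.asarray(innovations, float)
    T = circuit.transformation
    V = circuit.weights.matrix
    drive = np.outer(eps, T @ np.array([1.0, 0.0]))
    y = np.zeros(2)
    E = np.empty(len(eps))
    I = np.empty(len(eps))
    x = np.empty(len(eps))
    Tinv = np.linalg.inv(T)
    for t in range(len(eps)):
        y = V @ y + drive[t]
        E[t], I[t] = y
        x[t] = (Tinv @ y)[0]
    return E, I, x


def decompose_signal(x: np.ndarray, c_E: float = DEFAULT_C_E,
                     c_I: float = DEFAULT_C_I) -> EIDecomposition:
    """Split a scalar signal into E and I components by lag-1 filtering.

    E[t] = x[t] - c_E x[t-1], I[t] = x[t] - c_I x[t-1] (defined for
    t >= 1); the reconstruction weights solve the 2x2 system
    {w_E + w_I = 1, w_E c_E + w_I c_I = 0}, making
    x[t] = w_E E[t] + w_I I[t] an exact identity.
    """
    x = np.asarray(x, float)
    w_E, w_I = _solve_weights(c_E, c_I)
    E = x[1:] - c_E * x[:-1]
    I = x[1:] - c_I * x[:-1]
    return EIDecomposition(c_E=c_E, c_I=c_I, w_E=w_E, w_I=w_I, E=E, I=I)


def _wrap_phase(p: float) -> float:
    return float((p + np.pi) % (2.0 * np.pi) - np.pi)


def phase_lead(E: np.ndarray, I: np.ndarray, peak_freq: float,
               sampling_rate: float, min_coherence: float = 0.1,
               nperseg: int | None = None) -> float:
    """Phase of E relative to I at ``peak_freq``, in milliseconds.

    Estimated from the cross-spectral density of the two series; positive
    values mean E leads.  Raises when the magnitude-squared coherence at
    the peak is below ``min_coherence`` (the phase would be meaningless).
    """
    E = np.asarray(E, float)
    I = np.asarray(I, float)
    if E.shape != I.shape:
        raise ValueError("E and I must come from the same realization")
    if nperseg is None:
        nperseg = min(len(E), max(256, int(round(sampling_rate))))
    f, pxy = sps.csd(E, I, fs=sampling_rate, nperseg=nperseg)
    _, cxy = sps.coherence(E, I, fs=sampling_rate, nperseg=nperseg)
    k = int(np.argmin(np.abs(f - peak_freq)))
    if cxy[k] < min_coherence:
        raise ValueError(
            f"coherence {cxy[k]:.3f} at {f[k]:.1f} Hz below {min_coherence}"
        )
    # scipy's csd(E, I) estimates conj(E_f) * I_f, so a positive E-over-I
    # lead appears as a negative cross-spectral angle.
    dphi = _wrap_phase(-float(np.angle(pxy[k])))
    return dphi / (2.0 * np.pi * peak_freq) * 1000.0


def filter_phase_lead(c_E: float, c_I: float, peak_freq: float,
                      sampling_rate: float) -> float:
    """Analytic phase lead (ms) of the E over the I lag-1 filter output.

    Both components are the same signal passed through 1 - c z^{-1}; their
    phase difference at angular frequency w0 = 2 pi f / fs is
    arg(1 - c_E e^{-i w0}) - arg(1 - c_I e^{-i w0}).
    """
    w0 = 2.0 * np.pi * peak_freq / sampling_rate
    h_e = 1.0 - c_E * np.exp(-1j * w0)
    h_i = 1.0 - c_I * np.exp(-1j * w0)
    dphi = _wrap_phase(float(np.angle(h_e) - np.angle(h_i)))
    return dphi / (2.0 * np.pi * peak_freq) * 1000.0
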