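"""Rewrite the oscillator as a linear excitatory-inhibitory circuit.

Any AR(2) with complex eigenvalues is similarity-equivalent to a
two-population linear stochastic system.  Choosing the change of basis
E[t] = x[t] - 1.1 x[t-1], I[t] = x[t] - 0.86 x[t-1] yields a circuit in
which (i) the cross-population weights always have opposite signs (the
linear analogue of an E-I loop), (ii) the signal is an exact weighted sum
of E and I, with opposite weights, and (iii) E phase-leads I by a few
milliseconds at the spectral peak, as in PING-type gamma.
"""

import numpy as np

import gammacycle as gc

FS = 2035.0
params = gc.ar2_from_eigen(0.97, 50.0, FS)

circuit = gc.ar2_to_ei(params)
V = circuit.weights.matrix
print("E-I weight matrix V:")
print(np.array_str(V, precision=4))
print(f"cross weights: v_EI = {circuit.weights.v_ei:+.4f}, "
      f"v_IE = {circuit.weights.v_ie:+.4f} (product < 0: "
      f"{circuit.weights.v_ei * circuit.weights.v_ie < 0})")

x = gc.simulate_ar(params, 400_000, seed=6).squeeze1d()
dec = gc.decompose_signal(x)
print(f"reconstruction weights: w_E = {dec.w_E:+.3f}, w_I = {dec.w_I:+.3f} "
      f"(sum = {dec.w_E + dec.w_I:.1f})")
resid = np.max(np.abs(x[1:] - (dec.w_E * dec.E + dec.w_I * dec.I)))
print(f"max reconstruction residual: {resid:.2e}")

lead = gc.phase_lead(dec.E, dec.I, peak_freq=50.0, sampling_rate=FS)
lead_th = gc.filter_phase_lead(1.1, 0.86, 50.0, FS)
print(f"E leads I by {lead:.2f} ms at 50 Hz "
      f"(analytic filter phase: {lead_th:.2f} ms)")

# The millisecond-scale E-over-I lead and the opposite-sign weights drop
# out of the algebra alone: no biophysics is needed to produce the
# signature timing of an E-I gamma loop.
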