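"""Cycle statistics across oscillation strengths.

Sweeps the AR(2) eigenvalue magnitude from 0.90 (heavily damped) to
0.999 (near-critical) and tabulates three cycle statistics.  As the
oscillator approaches criticality, the amplitude-duration correlation
shrinks toward zero, the amplitude autocorrelation across neighbouring
half-cycles grows toward one, and the full-cycle duration
autocorrelation decays toward zero - the dynamical fingerprint that
distinguishes a noise-driven resonator from excitation-balance models.
"""

import gammacycle as gc

sweep = gc.eigenvalue_sweep(seed=0)
print(sweep.to_string(index=False,
                      float_format=lambda v: f"{v: .3f}"))

slope, intercept = gc.eigen_sweep_regression(sweep["magnitude"],
                                             sweep["amp_dur_rho"])
print(f"\nOLS slope of amplitude-duration correlation on |lambda|: "
      f"{slope:+.2f} (negative: stronger rhythms decorrelate)")
slope2, _ = gc.eigen_sweep_regression(sweep["magnitude"], sweep["amp_ac1"])
print(f"OLS slope of amplitude lag-1 autocorrelation on |lambda|: "
      f"{slope2:+.2f} (positive: stronger rhythms have longer memory)")
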