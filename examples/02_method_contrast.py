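"""Why cycle detection needs noise robustness.

On pure 1/f^n colored noise - a signal with no rhythm at all - the
classic band-pass + peak/trough method reports thousands of "gamma
cycles" whose amplitudes and durations correlate strongly (random-walk
excursions that run longer also run higher).  The phase-based method
rejects those deflections as phase slips and finds almost nothing, which
is the correct answer on rhythm-free noise.
"""

import gammacycle as gc

for exponent, label in ((0.0, "white"), (1.0, "1/f^2 power"),
                        (2.0, "1/f^4 power")):
    spec = gc.ColoredNoiseSpec(exponent=exponent, n_samples=30_000,
                               n_traces=4, sampling_rate=1000.0, seed=31)
    noise = gc.generate_colored_noise(spec)

    baseline = gc.detect_cycles_atallah(noise, gamma_peak=50.0)
    rho = gc.cycle_lagged_correlation(baseline, lag=0).rho
    phase = gc.detect_cycles_phase(noise)

    print(f"{label:12s} noise: baseline method {len(baseline):5d} cycles, "
          f"amplitude-duration rho = {rho:+.3f}; "
          f"phase-based method {len(phase):4d} cycles")

# The baseline correlations are strongly positive and grow with the
# spectral exponent even though the input contains no oscillation; the
# phase-based cycle counts collapse instead - no cycles, no spurious
# correlation.
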