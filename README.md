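# gammacycle

Cycle-by-cycle analysis of gamma-band (30–80 Hz) neural oscillations.

Gamma rhythms in cortical field potentials fluctuate from cycle to cycle in
both amplitude and duration. Whether those fluctuations reflect nonlinear
excitation–inhibition dynamics or simply noise filtered through a resonant
circuit is a question one can only answer with cycle statistics that are
themselves robust to noise — naive band-pass + peak/trough extraction
manufactures strong amplitude–duration correlations out of rhythm-free
1/f noise. `gammacycle` provides, for electrophysiologists and modellers:

- a **noise-robust, phase-based gamma-cycle detector**: half-cycles are
  anchored to zero crossings of the Hilbert (analytic-signal) phase of the
  broadband signal, and any crossing embedded in a *phase slip* (an interval
  of negative instantaneous frequency) is discarded together with its
  neighbours, so only genuinely rhythmic epochs contribute;
- the **noise-driven damped harmonic oscillator** model of the field
  potential: an AR(2) process x[t] = φ₁x[t−1] + φ₂x[t−2] + ε[t] with complex
  eigenvalues λ = m·e^(±iω₀), whose spectrum
  S(f) = σ_z² / (1 + φ₁² + φ₂² − 2φ₁(1−φ₂)cos 2πf − 2φ₂ cos 4πf)
  is fitted to empirical power spectra to read off the oscillation strength
  |λ| and peak frequency;
- the exact **linear E-I circuit equivalence** of that oscillator (similarity
  transform of the companion matrix), including the opposite-sign interaction
  weights and the millisecond E-over-I phase lead of PING-type gamma;
- the surrounding **statistics pipeline**: time-resolved lagged Spearman
  correlations with across-trial permutation inference, exact sign-flip
  tests, regression-residual de-trending, cycle-based amplitude spectra
  (CBAS), three cycle-frequency variability estimators (Gaussian fit,
  Bessel-corrected pairs, 2/3-debias triplets), and spike–cycle metrics
  (per-cycle counts/rates, PPC1 phase locking, phase-bin firing profiles);
- a **synthetic-data layer** that generates every input the pipeline needs:
  1/f^n colored noise, AR(p) realizations, E-I circuit trajectories,
  oscillation+noise mixtures, E-modulated Poisson spike trains, and eye
  traces with injected microsaccades.

## Worked example

`examples/01_detect_cycles.py` simulates the reference oscillator
(|λ| = 0.987, ~50 Hz peak, 2035 Hz sampling) and runs the detector:

```
AR(2) coefficients: phi1=1.9505, phi2=-0.9742
detected 20108 half-cycles in 1500 oscillatory epochs (9329 full cycles)
mean half-cycle frequency: 53.08 Hz
cycle-frequency SD (gaussian_fit): 11.46 Hz
cycle-frequency SD (pairs_bessel): 10.23 Hz
cycle-frequency SD (triplets_debias): 9.95 Hz
amplitude-duration Spearman correlation (lag 0): +0.267 over 20108 cycle pairs
```

The three variability estimators agree that even this strong, stationary
oscillator wanders by ~10–12 Hz from cycle to cycle, and the weakly positive
lag-0 amplitude–duration correlation arises from nothing but white noise
passing through linear dynamics. The other examples cover the
detector-contrast experiment on colored noise (`02`), spectral fitting
(`03`), the E-I circuit equivalence (`04`), spike–cycle locking (`05`), the
oscillation-strength sweep (`06`), and the config-driven pipeline (`07`);
each prints a short interpretation of its numbers.

## Layout

```
src/gammacycle/
  containers.py   recordings, half-cycle tables, spike trains
  synth.py        colored noise, AR(p), E-I circuits, spikes, eye traces
  preprocess.py   Butterworth/boxcar filtering, epoching, microsaccades
  cycles.py       phase-based, band-passed and baseline cycle detectors
  spectral.py     spectra, TFR, AR(2) analytics and fitting, phase plane
  cyclestats.py   lagged correlations, inference, CBAS, variability
  spikestats.py   per-cycle spike metrics, PPC1, phase-bin profiles
  eicircuit.py    AR(2) <-> E-I circuit, decomposition, phase lead
  io.py           HDF5 containers and CSV mirrors
  pipeline.py     config-driven runs and the eigenvalue sweep
```
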