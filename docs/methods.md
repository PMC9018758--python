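# Methods

## The signal model

The package treats a gamma-band field potential as a noise-driven damped
harmonic oscillator: a second-order autoregressive process

    x[t] = φ₁ x[t−1] + φ₂ x[t−2] + ε[t],    ε ~ N(0, σ_z²),

with complex companion-matrix eigenvalues λ = m·e^(±iθ), m ∈ (0, 1).
The magnitude m sets the damping (m → 1 is an undamped oscillator, small m
a heavily damped resonance) and the angle θ the oscillation frequency
(θ = 2πf₀/fs). `ar2_from_eigen` maps (m, f₀, fs) to φ₁ = 2m cos θ,
φ₂ = −m². The analytic one-sided spectrum is

    S(f) = σ_z² / (1 + φ₁² + φ₂² − 2φ₁(1−φ₂)cos 2πν − 2φ₂ cos 4πν),

with ν the normalized frequency f/fs (the cosine arguments are
dimensionless; Hz input is converted internally). Its maximum sits at
cos 2πν₀ = −φ₁(1−φ₂)/4φ₂, and the peak narrows monotonically as m → 1.

Three model assumptions matter downstream: the dynamics are *linear*
(all cycle-to-cycle variability comes from the innovation noise), they
are *stationary* (no slow drifts), and the innovations are Gaussian
(chosen for tractability; the distribution is not otherwise constrained
by the model).

## Cycle detection

The phase-based detector works on the broadband signal — deliberately so,
because narrow-band filtering smears amplitude across neighbouring time
points and turns transient deflections into apparent rhythms:

1. The instantaneous phase is the angle of the analytic signal
   (FFT Hilbert transform).
2. All sign changes of the wrapped phase are located: passages through 0
   (negative-to-positive, near signal peaks) and through ±π (the wrap,
   positive-to-negative, near troughs).
3. For each crossing k, the discrete angular velocity (first difference of
   the unwrapped phase) must be strictly positive on the whole span from
   crossing k−1 to k+1. A violation is a *phase slip* — the instantaneous
   frequency went negative, so "cycle" is not interpretable there — and the
   crossing plus its two neighbours are discarded. Backward crossings fail
   automatically.
4. Each surviving peak-type (trough-type) crossing is anchored to the
   nearest local maximum (minimum) of the raw signal, searched in the
   half-open window bounded by the adjacent crossings; ties break toward
   the earlier sample.
5. Alternating extrema are cut into half-cycles — amplitude = |peak −
   trough|, duration = extremum-to-extremum interval, frequency =
   1/(2·duration) so a 10 ms half-cycle is 50 Hz — and full (peak-to-peak)
   cycles. Maximal contiguous runs form epochs; epochs spanning fewer than
   two full cycles are dropped.

Pure noise legitimately yields a (near-)empty table; that is the method's
point, not a failure mode. Two companions are provided: a band-passed
variant that adds the amplitude criterion (A − μ_ref)/σ_ref > 1.63 (a
one-sided ~5% test against an oscillation-free reference segment), and the
classic baseline method (40 ms boxcar high-pass, 5–100 Hz Butterworth,
multitaper power episodes, raw local extrema), kept for the method-contrast
experiments.

Discretization choices the continuous description leaves open, fixed here:
angular velocity is the first difference of the unwrapped phase; the
slip-discard radius is one crossing on each side (the flagged crossing and
its two neighbours — a wider ±2 radius annihilates detection entirely on
weakly damped oscillators at m = 0.90, which contradicts the method's
usable range); extremum anchoring falls back to the window arg-extremum
when no interior local extremum exists; boundary crossings of a run, which
cannot be velocity-checked on both sides, only bound search windows.

## Statistics

**Correlation scheme.** Spearman throughout (Pearson behind a flag). For
multi-trial data, correlations are computed *across trials separately at
each post-onset time point* — each time point inherits the amplitude and
duration of the half-cycle containing it — then averaged over time points;
this removes stimulus-locked co-trends in amplitude and duration. Time
points with fewer than two valid trials are skipped, not zero-filled. For
trial-less simulations the correlation is pooled directly across cycles,
with lags taken within epochs.

**Permutation inference.** Durations are shuffled across trials
independently at each time point, the statistic is recomputed (default
1000 shuffles), a Gaussian is moment-matched to the surrogates, and the
empirical value is called significant beyond ±3 surrogate SDs (a
nonparametric two-sided test at p ≈ 0.003). One caveat the implementation
makes explicit: the rule is calibrated when time points are effectively
independent (roughly, one point per cycle). On a dense millisecond grid
adjacent time points share cycles, the empirical statistic averages far
fewer independent values than the surrogate does, and the rule becomes
anti-conservative; calibration tests therefore use one grid point per
cycle. The sign-flip test for across-dataset means enumerates all 2^k
sign assignments exactly (k ≤ 20) and takes the empirical mean from the
same enumeration so ties are exact.

**De-trending.** Residual correlations regress each half-cycle's amplitude
(and duration) on its two neighbours by OLS and correlate the residuals,
removing slow co-fluctuations while preserving the instantaneous coupling.

**CBAS.** Half-cycle frequencies are binned at 1 Hz around the Fourier
gamma peak (±20 Hz), with mean amplitude and incidence count per bin and
linear interpolation over empty interior bins. At a single sampling rate
the attainable frequencies form a comb (fs/2k for integer durations k),
so single-dataset count curves carry comb artifacts; curves are meant to
be normalized and averaged across datasets with different sampling rates,
which fills the combs in.

**Cycle-frequency variability.** Three estimators of the cycle-frequency
SD: (i) `gaussian_fit` — the SD of a Gaussian fitted to the distribution,
by maximum likelihood by default (sample mean/SD; an LSQ fit to the binned
histogram is available, but on the comb-structured, heavy-tailed
distributions the detector produces it tracks only the central peak and
reads ~4 Hz low); (ii) `pairs_bessel` — adjacent-pair variances with
Bessel's correction, mean((fᵢ−fᵢ₊₁)²/2), square-rooted; (iii)
`triplets_debias` — the mean squared deviation of each middle cycle from
its neighbours' mean, multiplied by exactly 2/3 (for i.i.d. values
E[(f₂−(f₁+f₃)/2)²] = 3σ²/2), square-rooted. The pair and triplet forms are
insensitive to slow drift in the mean frequency, which is their purpose;
adjacency is restricted to within-epoch runs.

**Spike metrics.** Spikes belong to the cycle whose half-open [start, end)
interval contains them; phase is linear, 2π·(t−start)/T. PPC1 averages
cos(θᵢ−θⱼ) over spike pairs from *different trials only* (computed from
per-trial resultant vectors), which removes spike-count and within-trial
history biases; pooled bins need ≥ 50 spikes. Per-unit counts and rates
are normalized by the unit's own mean across cycles, preserving the
within-unit frequency dependence that the correlations test. Phase-bin
profiles split cycles at the per-unit median duration.

## The E-I circuit equivalence

On the state (x[t], x[t−1]) the AR(2) is first-order with companion matrix
C = [[φ₁, φ₂], [1, 0]]. Any invertible T gives an equivalent system
y[t] = V y[t−1] + T(ε, 0)ᵀ with V = T C T⁻¹; eigenvalues are preserved,
and a real 2×2 matrix has complex eigenvalues iff its off-diagonal product
is negative — so every oscillatory circuit in this family has
opposite-sign interaction weights, the linear analogue of an E-I loop.
The canonical basis uses the lag-1 filters E[t] = x[t] − 1.1·x[t−1],
I[t] = x[t] − 0.86·x[t−1] (both components then receive the *same*
innovation, since T maps (ε, 0) to (ε, ε); independent noise is available
as an option). The reconstruction weights solve {w_E + w_I = 1,
w_E c_E + w_I c_I = 0} exactly — for (1.1, 0.86) they are
(−3.583, +4.583) — and the phase lead of E over I at the spectral peak is
measured on the cross-spectrum (Welch), checked against the analytic
filter-phase difference arg(1 − c_E e^(−iω₀)) − arg(1 − c_I e^(−iω₀)),
a few milliseconds for the canonical filters in the gamma range.

## Synthetic data: what it does and does not emulate

The generators produce the study conditions used throughout the tests:
1/f^n noise by frequency-domain shaping (white Gaussian draws, positive
frequency amplitudes scaled by 1/f^n — power slope −2n — DC zeroed,
Hermitian reconstruction), AR(p) realizations via the all-pole filter with
burn-in 20/(1 − m) samples, E-I trajectories, additive mixtures scaled to
a stated noise/oscillation SD ratio, inhomogeneous Poisson spikes with a
rectified-linear (or exponential) link by thinning, and fixational eye
traces with sigmoidal displacement injections. All randomness flows
through per-call `numpy.random.Generator` seeds; no global state.

They deliberately do not model: non-stationarity (stimulus-onset
transients, drifts in state), asymmetric cycle wave shapes, multiple
interacting frequency bands, conductance-based network dynamics, spike
sorting artifacts, or cell-type structure beyond a waveform-width label.
Consequently, passing tests show that the pipeline measures what it claims
on stationary linear signals with known ground truth; they do not show
that real recordings satisfy the model (on real data the duration
autocorrelations, for instance, can carry wave-shape asymmetries the
synthetic layer never produces).

Conditions chosen for the standard experiments, fixed once: sampling rate
2035 Hz and gamma peak ~50 Hz; the reference oscillation strength m =
0.987 and the strong-oscillation condition m = 0.99, each 10⁶ samples × 5
seeds for variability estimates; the sweep m ∈ {0.90, 0.91, …, 0.99,
0.999} with longer simulations at low m (4×10⁶ samples below 0.94, tapering
to 5×10⁵ near 1) because slip rejection discards most crossings of weak
oscillators; the detector-contrast mixtures use Brownian background noise
(1/f² power), trials of ~3 s, and noise/oscillation SD ratios 0–16; spike
simulations use 30 trials × 3 s, base rate 40 Hz and gain 60 per unit-SD of
E, deep enough that rectification clips firing at the non-preferred phase
of large cycles.

## Numerical notes and limitations

- Detected durations are integer sample counts; half-cycle frequencies
  live on the comb fs/2k. Mode and distribution statistics should be
  computed in the duration domain or across sampling rates (see CBAS).
- The AR(2) spectral fit profiles σ_z out analytically and multi-starts a
  Nelder-Mead simplex over a coarse (m, f₀) grid, constrained to the
  stationarity triangle |φ₂| < 1, |φ₁| < 1 − φ₂; flat (noise) spectra
  collapse to |λ| → 0 or real eigenvalues and are flagged non-oscillatory
  rather than erroring.
- The Hilbert transform is FFT-based; non-periodic boundary leakage
  produces phase ripple near trace edges, which the slip criterion and the
  two-full-cycle epoch rule absorb in practice.
- Two-pass Butterworth filtering uses reflect padding of one transient
  length; the 40 ms boxcar has even length at common rates and therefore a
  half-sample centering offset.
- The amplitude criterion of the band-passed detector uses the printed
  threshold 1.63 (the one-sided 5% normal quantile is 1.645); it is a
  configurable constant. The baseline detector's permissive episode
  threshold (power mean − SD) is implemented verbatim with a mean + SD
  switch.
- `signflip_mean_test` is exact but exponential in the number of datasets
  (capped at 20). `permutation_null` below ~100 shuffles gives an unstable
  surrogate Gaussian and warns.
- At m = 0.97 and below, cycle counting over-represents short cycles and
  the detected frequency mode sits a few Hz above the spectral peak; the
  mode-matches-peak property holds in the strong-oscillation regime
  (m ≈ 0.987 and up) typical of stimulus-driven gamma.
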