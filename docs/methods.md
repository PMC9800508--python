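# Methods

## The measurement being emulated

A multi-angle dynamic light scattering (MDLS) bench shines a 660 nm laser
through a dilute suspension of micron-scale spheres. Twelve photodiodes at
fixed scattering angles record the intensity of the scattered light at
1 kHz. Two physical effects encode particle size in those voltage traces:

1. **Brownian dynamics.** The scattered field at wavevector
   `q = 4π n sin(θ/2)/λ` decorrelates at rate `Γ = D q²`, where
   `D = k_B T / (3π η d)` is the Stokes–Einstein diffusion coefficient of a
   sphere of diameter `d`. Larger particles diffuse more slowly, so their
   intensity fluctuations are slower at every angle.
2. **Mie angular weighting.** The time-averaged intensity at angle `θ` is
   proportional to the unpolarized Mie pattern `(|S1(θ)|² + |S2(θ)|²)/2`,
   which for micron spheres at visible wavelengths is strongly
   forward-peaked and size-dependent.

The package classifies the particle size (1, 2 or 4 µm classes) from short
windows of the 12-channel recording, without ever fitting `Γ` explicitly at
classification time: the classifier works on generic time-domain
spectral-moment descriptors.

## The simulator (`mdls.simulate`)

No recordings of the physical instrument are available, so the package
generates its own with a phasor-sum model chosen as the minimal physics
that exercises every downstream stage:

* `n` point scatterers random-walk in a periodic box of side `L = 50 µm`
  with per-axis step `√(2 D Δt)`, `Δt = 1 ms`.
* Channel `c` sees the coherent sum
  `E_c(t) = Σ_j b(r_j) √w(θ_c) · exp(i q_c·r_j)` with `b` the amplitude
  profile of a Gaussian beam of waist 12 µm and `w(θ_c)` the max-normalized
  Mie weight. Particles wrapping across the box boundary re-enter with a
  fresh phase, mimicking exchange with the surrounding volume.
* The detector chain is `v = clip(g_c |E_c|², full_scale) + dark + noise`
  with dark level 0.05 V, Gaussian noise σ = 0.01 V and a 1.0 V full-scale
  (DAQ rail).

This reproduces the three statistical signatures the pipeline relies on:
intensity autocorrelations decaying at `2Γ_c` per channel, concentration
scaling of the scattered power, and slow beam-occupancy fluctuations that
appear as peaks in the traces.

Choices worth calling out:

* **Per-channel gain calibration.** The Mie pattern spans decades over
  15°–125°; a single amplifier gain would leave most channels at the noise
  floor. Gains are therefore set analytically (never from the simulated
  data) so each channel's *expected* scattering level is 0.3 V at the
  reference concentration 0.025 mg/ml — the software analogue of trimming
  each photodiode amplifier on a real bench. A consequence is that the mean
  level carries no class information; classification rests on the
  fluctuation dynamics, which is the harder and more interesting case.
* **Particle count.** `n = round(2000 × concentration in mg/ml)`, i.e. 50
  walkers at the 0.025 mg/ml operating point — a desk-scale count that
  preserves linear concentration scaling.
* **Full-scale clipping.** With gains calibrated at 0.025 mg/ml, higher
  concentrations push the signal into the 1 V rail and progressively flatten
  it. This is ordinary detector physics, and it is what gives the simulated
  peak-count-versus-concentration curve its interior maximum; the competing
  real-world mechanism (particle–particle interaction) is out of scope.
* **Angles.** The 12 detector angles default to 15°–125° in 10° steps
  (forward hemisphere, where the scattered power is). They are fully
  configurable; no claim is made that they match any particular instrument.
* **Surrogate mode.** An Ornstein–Uhlenbeck intensity process with the same
  per-channel decay rates `2Γ_c`, for unit tests that need the correlation
  structure but not the optics (runs ~50× faster).
* **Constants.** T = 298.15 K, η = 8.9·10⁻⁴ Pa·s (water at 25 °C),
  n_medium = 1.33, n_particle = 1.59 (polystyrene), λ = 660 nm, fs = 1 kHz.

The generator is deterministic given `(config, seed)`; dataset builders
derive per-recording seeds from a base seed.

What the simulator deliberately does **not** model: polydispersity,
non-spherical particles, multiple scattering, hydrodynamic interaction,
convective drift by default (a `drift_velocity_um_s` hook exists), detector
afterpulsing, and 1/f electronics noise. Tests passing on this generator
show that the *pipeline* is correct and that the *method* can separate
sizes whose only difference is diffusion dynamics; they do not certify
performance on real instrument data.

## Decay-rate estimation

`estimate_decay_rate` fits `A·exp(-2Γτ) + C` to the intensity
autocovariance, excluding lag 0 (which carries the white detector-noise
variance) and extending the window to ≈4 decay times so slow
beam-occupancy components are absorbed by `C`. Single channels scatter by
10–30% on minute-long records; `estimate_diffusion` therefore pools
channels by converting each fitted rate to `D_c = Γ_c/q_c²` and taking the
median over channels whose fitted rate lies in a resolvable band
(default 2–150 s⁻¹ at 1 kHz sampling — slower rates do not average enough
decay times in a minute, faster ones span too few samples). The pooled
estimate lands within a few percent of the Stokes–Einstein value for all
three classes.

## Preprocessing

* **Denoising**: second-order zero-phase (forward–backward) low-pass
  Butterworth. The cutoff is not dictated by the method; the default 100 Hz
  sits above the diffusion fluctuation band of these particles and well
  below the 500 Hz Nyquist. Zero-phase filtering was chosen so the
  difference-based descriptors see no phase distortion; its magnitude
  response is the squared one-pass response (−6 dB at the nominal cutoff).
* **SNR**: `10·log₁₀(Ps/Pn)` with `Ps`, `Pn` the mean squares of the signal
  and of a blank (dark/water) reference recording.
* **Windowing**: 250 ms windows, 150 ms step, aligned across channels,
  trailing partial windows dropped.
* **Peak counting**: local maxima above a prominence threshold (default 5×
  the dark-noise σ) separated by ≥10 ms.

## Moment descriptors (`mdls.features`)

Per window and channel, with `Δ` the forward difference:

    m0 = Σ x[j]²            (total power; Parseval links it to the spectrum)
    m2 = (1/N) Σ (Δx)²      (second spectral moment via time differences)
    m4 = (1/N) Σ (Δ²x)²     (fourth moment)

`m0` is kept as a plain sum while `m2`, `m4` carry 1/N, exactly as the
descriptor family is conventionally written; a `uniform_scaling` flag
divides `m0` by N too. Raw moments are compressed by `m ↦ m^λ/λ` with
λ = 0.1, then

    f1 = log m0,  f2 = log(m0 − m2),  f3 = log(m0 − m4)
    f4 = log(m0 / ((m0 − m2)(m0 − m4)))        (sparsity, product form)
    f5 = log(Σ|Δ²x| / Σ|Δ⁴x|)                  (waveform-length ratio, raw window)

Numerical safeguards: the compressed `m2` can exceed the compressed `m0`,
so every difference inside a log is wrapped as `|·| + ε` (ε = 10⁻¹²) and
each trigger is counted and logged; `0^λ` is defined as 0; `f1` carries the
same ε so a constant window degenerates consistently (`f2 = f3 = f1`,
`f4 = −f1`, `f5 = 0`). A `sparsity_sqrt` flag switches `f4` to the
square-root denominator variant found in the descriptor literature.
Normalization is applied before the subtractions in `f2`–`f4` (the order
the equations are stated in). Columns are channel-major:
`ch01_f1 … ch01_f5, ch02_f1, …` — 60 features for 12 channels, with the
`*_f1` entries forming the zero-order-moment block.

## Selection, classification, attribution

* **Sweep protocol**: candidate feature counts 5…60 step 5, stratified
  5-fold CV, reduction refitted inside each training fold (no leakage).
  Backward elimination removes one feature per refit, ranked by summed
  |coefficients| (linear models) or impurity importance (random forest);
  because single-step elimination yields nested subsets, one elimination
  pass per fold serves the whole grid. The model driving the ranking
  defaults to the downstream classifier. PCA components are computed on
  column-standardized features.
* **Classifiers**: linear SVM at the reference operating point
  (`kernel=linear, decision_function_shape=ovr, C=100, gamma=1e-4,
  probability=True`; `gamma` is inert for a linear kernel and is stored and
  logged only for fidelity), multinomial L2 logistic regression (C = 1),
  and a 100-tree random forest at conventional defaults.
  SVM/LR are standardized in-pipeline;
  sweeps use a probability-free SVM clone because calibration costs an
  internal CV and accuracy sweeps never use it.
* **Metrics**: the evaluation report tallies its own confusion matrix
  (rows = actual), derives per-class one-vs-rest TP/TN/FP/FN, and applies
  accuracy = (TP+TN)/n, precision = TP/(TP+FP), recall = TP/(TP+FN),
  F1 = 2TP/(2TP+FP+FN). Headline precision/recall/F1 are support-weighted
  (macro also reported); headline accuracy is trace/n and is reported side
  by side with the mean one-vs-rest accuracy, which differs in the
  multi-class case. Per-class recall (diagonal over row sum) is exposed
  directly, since per-class "accuracies" quoted for such experiments are
  usually exactly that.
* **Shapley values**: classic permutation Monte Carlo with backgrounds
  drawn from a seeded training subsample (default 100 rows) and 200
  permutations per explained sample. Per-permutation contributions
  telescope, so efficiency holds exactly against the mean output over the
  drawn backgrounds; per-feature Monte-Carlo standard errors are reported
  and used as tolerances in the axiomatic tests (symmetry, dummy, linear
  closed form, exhaustive enumeration at d ≤ 10). The explained output is
  the per-class probability by default, with any scalar output callable
  accepted.

## Study conditions and problem sizes

The reference protocols in `mdls.benchmarks` fix the desk-scale study:
decay-rate recovery on 3 × 60 s recordings per class; classification on
8 × 10 s recordings per class (528 windows per class of 250 ms at 150 ms
step), split 7:3, seeds 0–4; planted-feature recovery over 20 runs
(3 informative features at 3σ shifts among 57 noise features, n = 300,
eliminate to k = 5); the peak sweep over 0.0125–0.125 mg/ml with 3 × 20 s
recordings per concentration. These sizes are long enough that the fitted
physics stabilizes at the few-percent level and the classifier accuracies
at the ~1% level, while a full run stays in the minutes range on one core.

## Known limitations

* The phasor simulator is monodisperse and single-scattering; its class
  separability is likely optimistic relative to a real bench (no flow,
  vibration, laser drift, or impurity particles).
* Decay-rate fits assume a single-exponential intensity correlation; at
  the few effective particles in the beam the field is only approximately
  Gaussian, which the pooled median estimator tolerates but a per-channel
  fit does not always.
* The ε-guarded logarithms make the descriptors finite everywhere but
  non-smooth where `m0 ≈ m2` after compression; the guard rate is logged
  so a drift into that regime is visible.
* Shapley estimates are Monte Carlo: feature *rankings* near the tail of
  the mean-|φ| ordering are unstable at the default permutation budget.
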