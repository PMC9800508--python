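# mdls

Multi-angle dynamic light scattering (MDLS) simulation and micro-particle
size classification.

## What this is for

Rapid sizing of micron-scale particles (1–4 µm polystyrene spheres, and by
extension microbial-scale particles) from the fluctuating light they
scatter. An MDLS bench points a 660 nm laser through a dilute suspension
and records the scattered intensity on 12 photodiodes at different angles,
sampled at 1 kHz. Two pieces of physics tie those voltage traces to
particle size:

* **Stokes–Einstein diffusion** — a sphere of diameter `d` diffuses with
  `D = k_B T / (3π η d)`, so the scattered field at wavevector
  `q = 4π n sin(θ/2)/λ` decorrelates at rate `Γ = D q²`: bigger particles,
  slower flicker.
* **Mie scattering** — the angular intensity pattern
  `(|S1(θ)|² + |S2(θ)|²)/2` of a sphere is strongly forward-peaked and
  size-dependent.

Rather than inverting `Γ` directly, the pipeline treats sizing as
classification: each 250 ms window of the 12-channel recording is reduced
to five time-domain power-spectrum descriptors per channel (60 features),
built from the spectral moments

    m0 = Σ x²,   m2 = (1/N) Σ (Δx)²,   m4 = (1/N) Σ (Δ²x)²

compressed by `m ↦ m^λ/λ` (λ = 0.1) and combined into `f1 = log m0`,
`f2 = log(m0 − m2)`, `f3 = log(m0 − m4)`, a sparsity term
`f4 = log(m0/((m0−m2)(m0−m4)))` and a waveform-length ratio
`f5 = log(Σ|Δ²x|/Σ|Δ⁴x|)`. Feature counts are swept with PCA or recursive
feature elimination under stratified 5-fold cross-validation, classifiers
(logistic regression, random forest, linear SVM with C = 100) are trained
on a 7:3 split, evaluated through one-vs-rest confusion-matrix metrics,
and interpreted with permutation-sampling Shapley values.

Because no instrument recordings ship with the package, a physics-based
simulator stands in for the hardware: Brownian phasor sums weighted by the
Mie pattern of each particle class, a Gaussian beam profile, per-channel
amplifier gains, dark level, detector noise and a finite acquisition
range. `docs/methods.md` describes the model, its defaults, and what it
does and does not emulate.

## Worked example

```python
import numpy as np
from mdls import benchmarks

# 1) simulator physics: fit the intensity-autocorrelation decay of one
#    60 s recording per class and compare with Gamma = D q^2 at the
#    35-degree channel
recovery = benchmarks.gamma_recovery(base_seed=0, n_seeds=1, duration_s=60.0)
for _, r in recovery.iterrows():
    print(f"d={r.diameter_um:.0f} um:  Gamma_pred={r.gamma_pred_hz:6.2f} 1/s   "
          f"Gamma_fit={r.gamma_fit_hz:6.2f} 1/s   dev={100*r.rel_dev:+.1f}%")

# 2) the three-class study: 8 x 10 s recordings per class, 60 descriptors
#    per 250 ms window, 7:3 split, LR/RF/SVM on the held-out windows
reports = benchmarks.three_class_benchmark(seed=0)
for name, rep in reports.items():
    rec = ", ".join(f"{v:.3f}" for v in rep.per_class_recall)
    print(f"{name}: held-out accuracy {rep.accuracy:.4f}  per-class recall [{rec}]")
```

prints

```
d=1 um:  Gamma_pred= 28.46 1/s   Gamma_fit= 27.44 1/s   dev=-3.6%
d=2 um:  Gamma_pred= 14.23 1/s   Gamma_fit= 14.40 1/s   dev=+1.2%
d=4 um:  Gamma_pred=  7.11 1/s   Gamma_fit=  7.17 1/s   dev=+0.7%
lr: held-out accuracy 0.9937  per-class recall [0.994, 0.994, 0.994]
rf: held-out accuracy 0.9328  per-class recall [0.918, 0.931, 0.949]
svm: held-out accuracy 0.9937  per-class recall [0.994, 0.994, 0.994]
```

The decay-rate fits recover the Stokes–Einstein prediction within a few
percent for every class, and the classifiers separate the three sizes from
the window descriptors alone — on synthetic data whose per-channel mean
levels carry no class information, so the separation rests entirely on the
fluctuation dynamics.

A one-command version of the whole chain (simulate → denoise → window →
features → selection sweep → train → evaluate → explain) is available as

```
mdls pipeline --out runs/demo --seed 0
```

which writes `features.csv`, `cv_scores.csv`, `retained.json`,
`evaluation.json`, `shapley.csv`, a manifest and a run log into the output
directory. The other subcommands (`mdls simulate|peaks|features|select|
train|evaluate|explain`) expose the individual stages on CSV/JSON files.

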