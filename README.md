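# tfkinetics

Quantitative analysis of how long a transcription factor stays bound to
chromatin in living cells, and of what that residence time means for its
target genes — built around NF-κB p65 and its DNA-affinity and
transactivation-domain variants, but applicable to any factor imaged by
single-molecule tracking.

The package bundles four analyses that are usually scattered across imaging
and genomics toolchains, plus a seeded simulator so each estimator can be
validated by parameter recovery without any raw data:

1. **Residence times from slow stroboscopic movies.** Localizations are linked
   into tracks (optimal assignment, 725 nm search radius, 3-frame gap closing),
   chromatin-bound segments are extracted with a spatiotemporal filter
   (every step < 435 nm, duration ≥ 10 frames = 1 s), and the empirical
   survival probability S(t) = P(t_b ≥ t) (the 1-CDF of bound durations) is
   corrected for photobleaching by division with the survival curve of an
   immobile histone (H2B) control imaged identically:

       S_corrected(t) = S_target(t) / S_control(t).

   The corrected curve is fitted with mono- and bi-exponential decays
   A₁e^(−t/t₁) (+ A₂e^(−t/t₂)), and an F-test on the nested fits selects the
   model. The bi-exponential fit yields the fast and slow binding times
   t_b^fast, t_b^slow and their fractions.

2. **Bound fraction from fast movies.** Single-step displacements at
   Δt = 20 ms are fitted with an n-component 2D diffusion mixture

       p(r) = r Σᵢ fᵢ/(2DᵢΔt) · exp(−r²/(4DᵢΔt)),   Σᵢ fᵢ = 1.

   The weight of the slowest component, when its Dᵢ matches the immobile
   control (~0.04 µm²/s), is the bound fraction BF, and the pseudo-first-order
   association rate follows from BF = k_on\*/(k_on\* + k_off).

3. **FRAP.** Double-normalized recovery curves are fitted with
   FRAP(t) = I₁(1−e^(−t/τ₁)) + I₂(1−e^(−t/τ₂)); the global half-time is the
   numerically solved root of I₁(0.5−e^(−t/τ₁)) + I₂(0.5−e^(−t/τ₂)) = 0.

4. **Target-gene classification.** Differentially expressed genes are
   restricted to direct targets by strand-aware promoter-window/ChIP-peak
   intersection (2 kb upstream through the gene end); per-gene log₂ fold
   changes versus the non-transfected (NT) control are compared between a
   variant and the wild type through the per-gene difference of log₂FCs (the
   "logFC ratio"); its median over target genes calls gain (> 0) or loss of
   function. Row z-scoring, hierarchical clustering and qPCR NRQ
   transformation round out the stage.

Fitting stages follow a statsmodels-like Model/Results pattern
(`ExponentialSurvivalModel`, `DiffusionMixtureModel`, `FrapRecoveryModel`;
each `.fit()` returns a result dataclass with a `summary()`), with plain
functions (`estimate_binding_times`, `fit_diffusion_components`, …) as
one-line wrappers.

## Worked example

Simulate wild-type-like slow movies (95.7% of binding events with a 0.53 s
mean dwell, 4.3% with 4.13 s) together with an immobile control, then run the
full residence pipeline and the fast-movie bound-fraction analysis:

```python
import numpy as np
import tfkinetics as tk
from tfkinetics.pipeline import tracks_from_truth

target_cfg = tk.SmtSimConfig(n_molecules=20000, frac_bound=1.0, frac_slow=0.0,
    frac_free=0.0, t_fast=0.53, t_slow=4.13, frac_slow_bound=0.043, seed=7)
control_cfg = tk.SmtSimConfig(n_molecules=8000, frac_bound=1.0, frac_slow=0.0,
    frac_free=0.0, t_fast=np.inf, t_slow=np.inf, frac_slow_bound=0.0, seed=8)

locs, _ = tk.simulate_tracks(target_cfg)
ctrl, _ = tk.simulate_tracks(control_cfg)
summary = tk.estimate_binding_times(tracks_from_truth(locs), tracks_from_truth(ctrl))
print(summary.summary())

r = tk.simulate_displacements([0.21, 0.395, 0.395], [0.04, 0.5, 5.0], 0.02,
                              50000, seed=9)
fit = tk.fit_diffusion_components(tk.DisplacementSet(r, dt=0.02), 3)
print(fit.summary())
bf = tk.bound_fraction(fit)
print("k_on* = %.4f 1/s" % tk.compute_kon_star(bf, summary.k_off))
```

Output:

```
Residence-time analysis
  events: 3907
  model preferred by F-test: 2 component(s) (p = 8.7e-114)
  t_fast = 0.521 s (fraction 0.965)
  t_slow = 4.08 s (fraction 0.035)
Diffusion mixture fit (3 components)
  component 1: fraction 0.2136, D = 0.04116 um^2/s
  component 2: fraction 0.3965, D = 0.5106 um^2/s
  component 3: fraction 0.3899, D = 5.014 um^2/s
  objective (rss) 0.02687
k_on* = 0.0665 1/s
```

The F-test rejects the mono-exponential model; the recovered lifetimes
(0.52 s / 4.08 s) and slow fraction (3.5%) sit close to the simulated truth,
the slowest displacement component matches the immobile reference so its
weight (21.4%) is the bound fraction, and k_on\* combines it with
k_off = 1/t_b^slow.

A command-line interface mirrors the library
(`tfkinetics simulate-smt | link | residence | ssd | frap | classify | qpcr |
run-all`); `run-all` writes all reports plus a manifest with content digests
so identical seeds give byte-identical outputs.

## Layout

```
src/tfkinetics/
  simulate.py      trajectory / FRAP / count-matrix generators (seeded)
  linking.py       localization -> track assembly
  residence.py     bound events, survival curves, bleach correction, exp fits
  displacement.py  step-length mixtures, bound fraction, k_on*
  frap.py          normalization, double-exponential fit, global half-time
  txome.py         promoter/peak intersection, log2FC, classification, NRQ
  pipeline.py      RunConfig, run_smt, run_all (manifest, determinism)
  plotting.py      diagnostic plots for the fitted models
  cli.py           click-based command-line interface
docs/methods.md    model assumptions, parameter choices, limitations
```
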