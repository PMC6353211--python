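# Methods

This note records the models implemented in `tfkinetics`, the assumptions they
make, the defaults chosen where the procedure left a choice open, and what the
simulation-based tests do and do not demonstrate about real data.

## Trajectory simulator

The generator (`simulate.simulate_tracks`) produces 2D localizations of
nuclear molecules sampled stroboscopically (default cycle
Δt = t_int + t_gap = 5 + 95 ms = 100 ms; the fast-acquisition preset uses
t_gap = 15 ms, Δt = 20 ms). Its state model:

* Each molecule starts bound, slowly diffusing, or free with configurable
  fractions. A binding event's dwell is exponential with mean `t_fast`
  (default 0.53 s) or `t_slow` (default 4.13 s); the long-lived class is drawn
  once per event with probability `frac_slow_bound`. After unbinding the
  molecule diffuses freely; re-association inside a track is available through
  `rebind_rate` but defaults to 0 so that events are independent by
  construction.
* Bound molecules are not frozen: they jitter with `d_bound` = 0.04 µm²/s,
  matching the apparent diffusivity of the chromatin-bound histone control —
  "immobile" in these experiments means indistinguishable from chromatin
  motion, not literally static.
* Positions advance by Brownian steps with the state's diffusivity and
  reflecting boundaries in a square nucleus (default 10 µm). A molecule that
  unbinds between exposures receives a variance-split step
  (bound-diffusivity for the residual dwell, free for the remainder); without
  this the step following the true last bound frame would always look bound
  and every event would gain one frame.
* The 5 ms exposure is treated as instantaneous at the cycle start; motion
  blur is ignored because dwell times far exceed the integration time.
* Photophysics per exposure: permanent bleaching with `p_bleach` (default
  0.01, giving the control survival a ~10 s apparent lifetime — much slower
  than the binding kinetics, as the correction requires), else a reversible
  dark state with `p_blink` (default 0.05) capped at `max_blink` = 3
  consecutive frames, the gap length the tracking tolerates. Localization
  noise is Gaussian with `sigma_loc` = 0.03 µm per axis, a typical
  single-molecule localization precision; neither the noise level nor the
  bleaching probability is stated by the imaging protocol, so both are free
  parameters with these defaults.
* Movies default to 400 frames so that the usable correction window is
  bounded by the photobleaching floor (control survival 0.05, reached near
  30 s) rather than by the movie end; binding events longer than the movie
  are right-censored at the final frame.

All draws come from a single `numpy` generator stream per config, so a config
plus seed fully determines the output.

What the generator does **not** emulate: camera noise (EM gain, shot noise),
PSF rendering and detection, 3D defocus loss, spatially heterogeneous binding
site distributions, and dwell-time distributions beyond a two-exponential
mixture. Passing recovery tests therefore shows that the estimators invert
the assumed kinetic model at realistic sampling, noise and censoring — not
that real movies satisfy that model.

## Linking

Frame-to-frame assignment minimizes total squared displacement over candidate
pairs within 725 nm (5 pixels at 145 nm) using the Hungarian algorithm; this
is deterministic and order-independent, unlike greedy nearest-neighbour
matching, with ties broken by (frame, x, y) order. Unmatched track ends remain
eligible for 3 further frames (gap closing for blinking); gap-closed
candidates compete with the same radius regardless of gap length — the
conservative reading where the original tool's behaviour is unstated, since a
growing radius would inflate apparent dwell times. Tracks shorter than 2
detections are discarded. Kalman/motion-model linking and track
splitting/merging are out of scope.

## Residence-time analysis

* **Bound filter.** Maximal runs of consecutive detections with every
  displacement < 435 nm and length ≥ 10 frames (1 s). Closed blink gaps count
  toward the event length, consistent with gap closing having asserted
  continuity. Durations use the n_frames × Δt convention (10 frames ⇒ 1.0 s).
* **Survival curve.** S(t) = fraction of events with duration ≥ t on the
  unique-duration grid; S at the shortest duration is 1.
* **Photobleaching correction.** The target curve is divided by the
  immobile-control curve interpolated log-linearly onto the target grid,
  restricted to where the control is ≥ 0.05 (division blow-up control), then
  projected onto the non-increasing cone (isotonic least squares — sampling
  noise makes the raw ratio locally increasing, which a survival function
  cannot be) and renormalized to start at 1. The correction assumes target
  and control share the photobleaching rate and that bleaching is slower than
  unbinding.
* **Exponential fits.** Unweighted nonlinear least squares of ΣAᵢe^(−t/tᵢ) on
  the empirical grid, amplitudes free and normalized afterwards — mirroring
  the interactive-fitting convention this analysis historically used. Because
  amplitudes are free, fitting a curve whose grid starts at 1 s still
  extrapolates the component weights back to t = 0. Initialization is a
  deterministic multistart over log-spaced lifetime pairs spanning the
  observed window (best RSS wins); lifetime standard errors come from the
  Jacobian. A left-truncated maximum-likelihood fit is available via
  `method="mle"` (with lifetimes bounded below at the grid resolution to
  exclude the classic boundary likelihood spike), but the survival-grid least
  squares is the default and the reference.
* **Model selection.** F = ((RSS₁−RSS₂)/(p₂−p₁)) / (RSS₂/(n−p₂)) with
  p-value from F(p₂−p₁, n−p₂); the bi-exponential model is preferred at
  α = 0.05 (the threshold is a package choice; the procedure's source states
  the test but not α). Improvements below 1e−10 in RSS are treated as
  optimizer noise (relevant only for machine-precision fits such as a
  perfectly flat self-corrected curve). The F-test's nominal calibration
  holds for independent Gaussian residuals; on empirical survival grids the
  residuals are correlated and the test over-rejects, which is why the
  type-I-error check simulates decay curves with iid noise.
* **k_off.** Reported as 1/t_b^slow of the selected model (1/t_b of the mono
  fit if that is selected). Which dissociation rate enters the
  bound-fraction relation is not stated by the source analysis; the slow
  (stable-binding) rate is the package's documented choice.

Known biases, quantified by the recovery tests: frame quantization
(ceil(dwell/Δt)) inflates the fast amplitude relative to the slow one, so the
recovered long-lived fraction runs ~1 percentage point below the simulated
truth (e.g. ~3.3% recovered for 4.3% truth) while both lifetimes recover
within a few percent; blink-shortened event ends contribute a smaller bias in
the same direction. Three-or-more exponential components, Bayesian dwell
inference and within-gap rebinding corrections are out of scope.

## Displacement analysis

Single-step displacements (consecutive frames only; gap-spanning pairs
excluded) are histogrammed at 0.02 µm bins up to the 99.5th percentile and
density-normalized; the Rayleigh-mixture density is fitted by least squares
at the bin centres with the simplex constraint enforced by a softmax
reparameterization and a deterministic multistart over log-spaced
diffusivity tuples (a raw-likelihood alternative sits behind
`method="mle"`). Components are reported by ascending D. The bound fraction
is the slowest component's weight provided its D lies within 3-fold of the
immobile reference 0.04 µm²/s — a window wide enough for fit scatter but
excluding the next mobility class (≳0.5 µm²/s); otherwise BF = 0 with a
warning. k_on\* = k_off·BF/(1−BF). Localization-noise broadening of the
apparent D (σ²-per-axis adds ~σ_loc²/Δt ≈ 0.045 µm²/s at 20 ms if noise is
left on) is not deconvolved; recovery experiments therefore generate
displacement sets from the mixture directly. HMM state segmentation,
anomalous diffusion and defocus corrections are out of scope.

## FRAP

Raw ROI traces are double-normalized: (bleach − background)/(nucleus −
background), then scaled by the pre-bleach mean, with t = 0 at the first
post-bleach frame. The recovery model has no offset term, so any residual
post-bleach intensity must be removed during normalization — this is the
pre-processing contract. The double-exponential fit uses a log-spaced (τ₁,
τ₂) multistart with amplitudes seeded from the observed plateau; parameter
SEs come from the Jacobian (delta method for the log-parametrized lifetimes).
The global half-time solves I₁(0.5−e^(−t/τ₁)) + I₂(0.5−e^(−t/τ₂)) = 0 by
Brent's method on (0, 50·τ₂]; the left side rises strictly from −(I₁+I₂)/2
to +(I₁+I₂)/2, so the root is unique, and the residual at the root is below
1e−8 by construction of the 1e−9 relative tolerance. Reaction–diffusion FRAP
models and bleach-geometry corrections are out of scope.

## Transcriptome classification

Upstream differential-expression calling (alignment, TMM, moderated
statistics) is out of scope; the stage accepts any DE gene list, and the
count generator labels DE genes directly. Promoter windows are
strand-extended 2 kb upstream (forward: start−2000 to end; reverse: start to
end+2000), 0-based half-open, clipped at 0; a gene is retained on ≥ 1 bp
overlap with any peak. Fold changes use counts-per-million with pseudocount
0.5 and log-scale replicate averaging — a deterministic stand-in for TMM at
this scale; the count generator reports both the injected per-gene effect and
its realized CPM-scale value (they differ by a global compositional shift).
The "logFC ratio" is implemented as the per-gene difference of log₂ fold
changes (equivalently the log₂ of the fold-change ratio): this reproduces
negative medians for loss-of-function variants naturally and makes the
up/down rule equal to the sign of the difference; the alternative reading
(quotient of log FC values) was rejected as it is undefined at log2FC_wt = 0.
Clustering is agglomerative with Euclidean distance and average linkage
(complete linkage is a plausible alternative the source leaves unstated) with
scipy's deterministic leaf order. qPCR Ct values convert to NRQs assuming
2-fold amplification per cycle, normalized by the geometric mean over
multiple reference genes.

## Problem sizes

Recovery experiments use ≥ 10⁴ filtered binding events (7–11 × 10⁴ simulated
molecules per construct, 2 × 10⁴ control molecules) and 2–5 × 10⁴
displacement steps; the replicate-based calibration checks use 500 synthetic
decay curves (F-test type-I error) and 50–60 replicates (parameter-recovery
medians, FRAP SE coverage). These sizes put the statistical error of each
check comfortably below the tolerance it asserts.
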