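# Methods

This note documents the models, numerical choices and limitations behind
`mweeg`. It is written for a reader who wants to know exactly what the code
computes and why, and what passing its tests does and does not demonstrate.

## Single-trial ERP estimation

An idealized ERP deflection is modeled as a Mexican hat
ψ(u) = (1 − 16u²)e^(−8u²): unit peak, zero crossings at u = ±1/4, even,
negligible beyond |u| ≈ 1. The template family is parameterized by a time lag
t (peak position, ms) and a scale s (breadth, approximately one wavelength,
ms), and matched to an epoch f by the cross-covariance
W(s, t) = s^(−1/2) Σ_τ f(τ) ψ((τ − t)/s) Δτ with Δτ = 1000/fs ms and zero
contribution outside the epoch support.

Numerics. Because ψ is even, the lag scan at fixed scale is a convolution;
it is evaluated by FFT with a kernel covering every in-epoch offset, which
matches the literal Riemann sum to machine precision (the literal sum is kept
as `riemann_cross_covariance` and the two routes are compared on random
epochs in the tests). For an embedded template a·ψ((τ−t₀)/s₀) the extreme
sits at (t₀, s₀) with W = a·√s₀·(3√π/16), so detected amplitudes are linear
in embedded amplitudes.

Detection. The component estimate is the polarity-signed grid extreme of W
over {t in window} × all scales; ties break toward the earliest lag, then the
smallest scale. An extreme on the boundary of the search region, or with the
wrong sign, is flagged `degraded` but still reported — single-trial analyses
need a value for every trial. Windows: P1 50–150 ms (+, A10/B7), N1
100–200 ms (−, A10/B7), P3 250–600 ms (+, A19). The canonical N1 window
clips late N1 peaks (the averaged N1 centers near 200 ms); `with_n1_window`
widens it to 100–230 ms. Scale grids are logarithmic with 32 steps —
50–400 ms for P1/N1, 200–1400 ms for P3 — chosen to bracket each component's
plausible breadth; the grids are configurable per `ComponentSpec`.

Recovery regime. The recovery guarantee the test suite enforces — embedded
vs detected P3 amplitude correlation r ≥ 0.9 with median latency error
≤ 20 ms at noise of half the template amplitude — holds in the classical
matched-filter regime of spectrally flat noise. Under 1/f background noise
the amplitude correlation degrades below that bound, because low-frequency
noise power falls inside the P3 template band — a caveat that applies
equally to real recordings with strong slow activity.

The traditional averaging path (`traditional_erp`) computes per-state mean
waveforms plus per-trial window-mean amplitudes (P1 120–130 ms, N1
195–205 ms, P3 400–500 ms) so averaged and single-trial estimates can be
compared on identical data.

## Spectral markers

Band-pass filters are least-squares linear-phase FIRs (`scipy.signal.firls`)
with a plateau-shaped ideal: zero up to lo·(1 − 0.2), one over [lo, hi], zero
from hi·(1 + 0.2), i.e. transition bands of 20% of each edge. The kernel is
odd-length (type I, integer group delay). Its length starts at 3 cycles of
the band's low edge and grows one cycle at a time until the realized response
passes three gates evaluated on a 1000-point 0–Nyquist grid: sum of squared
errors vs the plateau ideal < 1, midband gain within [0.95, 1.05], DC gain
≤ 0.05. At 256 Hz this yields 193 taps for theta (4–8 Hz) and 151 for alpha
(8.5–12 Hz). The SSE is computed against the piecewise-linear plateau ideal
(the same shape the design optimizes); against a discontinuous 0/1 step the
transition samples alone would dominate the error for any realizable FIR.

Epochs are demeaned (exact DC invariance), mirror-padded by one kernel
length, convolved in 'same' mode (zero-phase for a symmetric kernel), cropped
back, and Hilbert-transformed. Power is the time-averaged |z(t)|²; pairwise
synchrony is ISPC = |mean exp(i(φ_x − φ_y))| ∈ [0, 1]. Both are summarized
over baseline (−400–0 ms) and after-stimulus-onset (0–600 ms), giving
2 bands × (4 sites + 6 pairs) × 2 periods = 40 values per trial. Filter edge
transients span roughly half a kernel length at each epoch edge; the analysis
periods are interior, and amplitude-accuracy checks exclude that margin.

## Trial labeling and inclusion

Probe responses map 1–2 → on-task, 3/5 → mind-wandering, 4/6 → excluded.
The six trials immediately preceding a probe (the probed trial is the sixth)
inherit its class, so labeled trials = 6 × kept probes; the minimum 7-trial
probe gap guarantees windows never overlap. Artifact-flagged trials are
dropped before anything is counted. A subject is retained only if every
task × state cell keeps ≥ 30 clean labeled trials.

## Classification

The 25 classifier markers are the 5 single-trial ERP amplitudes plus the
8 powers and 12 ISPCs from the after-stimulus-onset period (one value per
marker; the baseline period feeds only the ANOVA stage). Markers are
z-transformed per subject and task over the labeled trials (the default
`global` scope); a `train_fold_only` scope that standardizes with
training-fold statistics is provided for leakage-sensitive use and is what
the no-leakage tests exercise. Zero-variance columns are dropped with a
warning.

Class imbalance is handled by random oversampling — minority rows duplicated
with replacement until counts match — applied inside each training fold,
never to a test fold (duplicating before the split would leak test rows).
The model is an RBF-kernel SVM (`sklearn.svm.SVC`). Hyperparameters come
from an explicit grid search (default C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, odd
powers) maximizing stratified inner-CV accuracy (5 folds, oversampling inside
each inner split), with ties broken toward smaller C then smaller γ — the
hand-rolled search exists precisely to make that tie-break deterministic.
By default the search runs once per subject and the chosen point is used for
every LOOCV fold; a fully nested mode (fresh search per fold) is available
via `ModelSpec.grid_mode`. Models are fit per subject only — individual
differences in EEG patterns are the point of the per-subject design — and
across-task transfer fits once on all of one task and evaluates on all of
the other. Single-marker models pool the per-task-normalized tables from
both tasks and LOOCV each marker separately, plus the full model.

## Group statistics

MW is the positive class everywhere; metrics whose reference class is absent
propagate as missing, never zero. t tests are two-sided by default (flag
available) with Cohen's d = mean/sd; the degenerate all-zero-difference input
returns t = 0, p = 1 rather than erroring, so identical paired samples
compare cleanly. Spearman correlations use average ranks for ties. TOST
equivalence uses the (1 − 2α) confidence interval criterion (90% CI at
α = .05); exactly constant differences degenerate to a point interval. The
2×2 within-subject ANOVA is delegated to `pingouin.rm_anova` with
generalized η² (`ng2`) as the effect size; the test suite re-derives F and
η_g² from paired contrasts in closed form as an independent check.

## The synthetic generator

The generator's job is to emulate the probe-scheduled study design and its
reported state effects so the pipeline is testable end to end. Per task it
lays out 12 blocks (SART 135, VS 140 trials), schedules 54 probes with
uniformly drawn gaps in [7, 24] (constrained so the remaining probes always
fit), blocks the latent state so all six pre-probe trials share the probe's
state, and draws the probe response from the state's category pair, with a
16% "leak" to the excluded categories matching the observed share of
distraction/blank reports. Filler trials between windows carry independent
latent states. Go/no-go and target-present/absent structure is carried as
metadata only; it feeds nothing downstream.

Each rendered epoch sums:

* **ERP components** — Mexican-hat bumps, so the matched filter is exact
  under zero noise: P1 (+, 120 ms, scale 100 ms, A10/B7; 3.0 → 2.4 µV
  OT → MW), N1 (−, 200 ms, 120 ms, A10/B7; −3.0 → −2.4 µV), P3 (+, 450 ms,
  400 ms, A19; 5.0 → 4.0 µV), each with per-trial amplitude noise (sd 1.0 /
  1.0 / 1.5 µV, clipped to the component's sign) and Gaussian latency jitter
  (sd 15 / 15 / 20 ms).
* **Alpha** (10.25 Hz ± per-trial jitter, independent phase per channel,
  occipital-weighted): amplitude 1.5 µV on-task → 2.1 µV mind-wandering
  (cv 0.3) — the elevated-alpha effect.
* **Theta** (6 Hz, frontal/parietal-weighted, 2.2 µV in both states — no
  designed theta power effect). A19 and A10 share one oscillator; A10's
  phase offset Δ(t) follows the circular diffusion
  dΔ = −(κσ²/2)·sin(Δ)dt + σ dW with σ = 2 rad/√s, whose stationary law is
  exactly von Mises(0, κ). This gives a closed-form recovery target — pooled
  ISPC → I₁(κ)/I₀(κ) — while κ also controls within-trial phase stability,
  so per-trial ISPC is monotone in κ: κ = 0.3 on-task → 3.0 mind-wandering
  is the tighter-coupling-during-MW effect. (A trial-constant von Mises
  offset would satisfy the closed form but leave per-trial ISPC blind to κ,
  since any constant offset yields ISPC = 1.) For very large κ the
  Euler–Maruyama drift is capped at 0.4·fs with the noise rescaled to keep
  the stationary variance 1/κ.
* **1/f^β noise** (β = 1, sd 2 µV per channel; β = 0 gives flat noise), via
  spectral shaping of white noise.

Behavior is state-conditional: accuracy 0.96/0.94 (OT/MW), correct-trial RTs
normal with means 654/687 ms — the observed visual-search values. Trials are
artifact-flagged with probability 0.05.

Amplitudes and the κ contrast were fixed once so that each designed effect
is reliably detectable by the group statistics at the test suite's cohort
sizes while single-trial overlap remains substantial. With these defaults the
full 25-marker model reaches mean LOOCV accuracies near 0.8 on synthetic
cohorts (the acceptance script recomputes this) — above what is typically
reported for human mind-wandering EEG, as expected: the
generator contains only the modeled sources of variability (no drowsiness,
no residual artifacts, no label noise from uncertain self-reports, no
between-subject differences in marker topography). Passing tests therefore
demonstrate that the pipeline recovers what its generative model puts in,
at realistic effect directions and magnitudes — not that real EEG would
classify this well. The class-imbalance bias the cohort tests replicate
(sensitivity rising and specificity falling with a subject's mind-wandering
rate, despite oversampling) emerges from the classifier itself, not from the
generator, which makes its cohort-level replication a meaningful check.

## Problem sizes

Heavy checks are scaled to remain exact in kind but modest in size: the
bias-replication cohort uses 18 subjects × 36 probes on one task with a
3 × 3 hyperparameter grid; effect-direction recovery uses 10 cohorts of
6 subjects at the full 54-probe session; the acceptance script runs an
8-subject, two-task cohort at the full session size. These are the package's
default demonstration sizes; all are configurable upward.

## Known limitations

* The generator renders only the four analysis channels and starts from
  clean epochs; re-referencing, ocular-artifact removal and channel
  interpolation are upstream concerns it does not model.
* ISPC edge behavior depends on the epoch-wise filtering scheme
  (demean + mirror-pad); continuous-data filtering would differ near epoch
  boundaries.
* The von Mises diffusion's pooled-ISPC identity is exact in distribution
  but measured through the filter–Hilbert chain; very fast diffusion (large
  σ) pushes phase sidebands outside the theta band and biases the pooled
  estimate upward, which bounds how sharp a coupling contrast the generator
  should use.
* Single-marker model runs are computationally heavy (26 grid searches +
  LOOCVs per subject); they are exposed as an option (`run_single_markers`)
  rather than a default pipeline stage.
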