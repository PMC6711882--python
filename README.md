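# mweeg — task-general mind-wandering detection from EEG

`mweeg` implements an experience-sampling EEG analysis for detecting
mind-wandering — self-generated, task-unrelated thought — from single trials.
It is written for cognitive electrophysiologists who want a tested, reusable
version of the full chain: single-trial ERP estimation, band-limited power and
phase synchrony, probe-based trial labeling, and per-subject machine-learning
classification, together with a synthetic EEG generator that reproduces the
probe-scheduled study design so every stage can be exercised and validated
without any recorded data.

## The analysis

**Design.** Subjects perform a sustained attention to response task (SART,
go/no-go, 135 trials/block) and a visual search task (140 trials/block).
Thought probes (54 per task, 7–24 trials apart) ask for a 6-way report:
responses 1–2 → on-task (OT), 3 and 5 → mind-wandering (MW), 4 and 6
(external distraction / mind-blanking) are excluded. The six trials preceding
each probe inherit its class; subjects need ≥ 30 clean labeled trials per
task × state cell.

**Single-trial ERPs.** Instead of trial averaging, each epoch f(τ) is matched
against Mexican-hat templates ψ(u) = (1 − 16u²)e^(−8u²) over a grid of time
lags t and scales s:

    W(s, t) = s^(−1/2) ∫ f(τ) ψ((τ − t)/s) dτ

The polarity-appropriate extreme of W inside a component's search window
(P1: +, 50–150 ms at A10/B7; N1: −, 100–200 ms at A10/B7; P3: +, 250–600 ms
at A19) gives the component's single-trial amplitude, latency and breadth.

**Spectral markers.** Epochs at A10, A19, B7, C21 are band-pass filtered
(plateau-shaped least-squares FIR; alpha 8.5–12 Hz, theta 4–8 Hz, 20%
transitions, kernel ≥ 3 cycles of the band's low edge, design gated on its
realized frequency response) and Hilbert-transformed. Power is |z(t)|²;
phase synchrony between sites x, y is the intersite phase clustering

    ISPC = | n⁻¹ Σ_t exp(i(φ_x(t) − φ_y(t))) |

both averaged over the baseline (−400–0 ms) and after-stimulus-onset
(0–600 ms) periods.

**Classification.** 25 markers per trial (5 single-trial ERP amplitudes,
8 band powers, 12 pair ISPCs) are z-transformed; per subject, an RBF-kernel
SVM with grid-searched (C, γ) and random oversampling of the minority class
inside each training fold is validated by leave-one-out cross-validation,
by across-task transfer (train SART → test VS and vice versa), and
marker-by-marker on pooled two-task data. MW is the positive class:
sensitivity = MW trials detected, specificity = OT trials detected.

**Evaluation.** Paired/one-sample t tests with Cohen's d, Spearman rank
correlations of classifier bias against the subject's mind-wandering rate,
TOST equivalence tests, and 2×2 within-subject ANOVA (state × period) with
generalized η².

**Synthetic sessions.** `mweeg.synth` embeds Mexican-hat shaped P1/N1/P3
components (attenuated during MW), an alpha oscillation (elevated during MW),
a theta oscillation whose A19–A10 phase offset follows a circular diffusion
with a von Mises stationary law (concentration κ higher during MW), and 1/f
background noise — all per-trial randomized, fully seeded and
bit-reproducible.

## Worked example

`examples/04_classify_states.py` runs the full single-subject path —
simulate a SART session with a 35% mind-wandering rate, label the six
pre-probe trials of each kept probe, extract the 25 markers, and validate
per-subject classification:

```
$ python examples/04_classify_states.py
feature table: 245 labeled trials x 25 markers
LOOCV: accuracy 0.857, sensitivity 0.761, specificity 0.893  (C=1, gamma=0.04)
```

245 trials survive labeling (probes reporting distraction/blank are dropped,
as are artifact-flagged trials). Accuracy is the fraction of held-out trials
whose state the SVM recovers; the sensitivity/specificity split shows the
classifier is better at the majority (on-task) class even though training
folds are oversampled to balance — the same bias pattern the bias-replication
test quantifies cohort-wide. The other examples cover session simulation,
single-trial ERP recovery, spectral state effects, and a multi-subject
pipeline run with group statistics.

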