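# Methods

This note documents the models, algorithms and numerical choices behind
`ventpulse`: a pipeline that quantifies inspiratory effort during pressure
support ventilation (PSV) from esophageal pressure, labels weak efforts,
and trains a convolutional classifier to recognize them from the two
waveforms a ventilator already has — flow and airway pressure.

## Physiological background

During PSV every patient-triggered breath receives a fixed pressure boost
(PS) above PEEP, cycled off when inspiratory flow decays to a set fraction
of its peak. When assist is excessive, the patient's respiratory muscles
contribute little (weak effort), which promotes diaphragm disuse atrophy.
Effort is quantified by the pressure-time product (PTP) of the respiratory
muscle pressure Pmus: the time integral of Pmus over the mechanical
inspiration (PTP per breath, cmH2O·s), multiplied by the respiratory rate
to give PTP per minute. Breaths with PTP/min < 50 cmH2O·s/min are labeled
weak; this threshold is the conventional lower bound of the desirable
effort range.

## Pmus reconstruction (annotate)

Pmus is reconstructed from esophageal pressure (Pes) via the chest-wall
equation of motion (Campbell-type reconstruction):

    Pmus(t) = Ecw·V(t) + Rcw·Flow(t) + Pes_endexp − Pes(t)

- `V(t)` is the trapezoidal cumulative integral of flow, re-zeroed at each
  breath onset. The static formulation's "VT × Ecw" is applied as the
  instantaneous V(t)·Ecw, which equals VT·Ecw at end-inspiration.
- `Rcw = 1.5 cmH2O/(L/s)` (chest-wall resistance, population constant).
- `Pes_endexp` is the end-expiratory esophageal pressure of the patient.
- `Ecw` derives from predicted vital capacity,
  VC = (27.63 − 0.112·age)·height(cm) mL for males and
  (21.78 − 0.101·age)·height(cm) for females. The default takes chest-wall
  compliance as 4% of predicted VC per cmH2O, i.e. Ecw = 1/(0.04·VC_L)
  ≈ 7 cmH2O/L for a typical adult. A literal mode Ecw = 0.025·VC (with VC
  in mL) is retained behind `ecw_mode="literal"`; it yields values two
  orders of magnitude larger and is provided only for comparison with
  sources that print the formula in that form.

PTP per breath integrates the *signed* Pmus over [onset, inspiration end]
(no rectification of negative excursions; a positive-part variant would be
a one-line change and was deliberately not made the default). PTP per
minute uses the breath's own instantaneous rate 60/Ttot. Weakness is a
strict inequality: PTP/min < 50 is weak, exactly 50 is not.

## Breath segmentation (segment)

Onset: the start of the rapid Paw decline at triggering. Candidates come
from Haar-style multiscale detail coefficients of the (lightly smoothed)
Paw signal — boxcar right-minus-left mean differences at dyadic scales of
40/80/160 ms — thresholded at 2.5 robust (MAD-based) standard deviations;
the flow-crossing refinement below, not the threshold, provides the
false-positive control, so the threshold is set permissive enough to catch
the shallow dips of zero-support breaths.
Because a weak effort's trigger dip can be fractions of a cmH2O while the
pressure-support upstroke is never small, a rescue pass walks backward from
any large positive deflection lacking a preceding candidate. Each candidate
is then refined to the upward zero crossing of flow that initiates the dip;
a candidate with no upward flow crossing nearby is a cycling-off decline
and is discarded (when flow is flat and uninformative the refinement falls
back to a Paw slope walk-back). Detected onsets closer than a 0.4 s
refractory period are merged keeping the earlier one.

End of inspiration: the first positive-to-negative flow zero crossing after
the onset, with sub-sample linear interpolation rounded to the nearest
sample. Breaths without a crossing before the next onset are flagged
`no_cycle`; inspiratory times outside [0.2 s, 3 s] are flagged
`ti_out_of_range`; breaths overlapping a user-supplied exclusion mask
(esophageal spasm, cough) are flagged `artifact`. Invalid breaths are kept
in the table but never annotated or used for training.

## Patient–ventilator simulator (simulate)

Because ground-truth muscle pressure is unobservable in clinical
recordings, the package ships a simulator in which it is known exactly.

- **Mechanics**: single-compartment linear model,
  Paw + Pmus − PEEP − PEEPi = Ers·V + Rrs·V̇. Linearity keeps the
  Pes-inversion identity exact and testable. Volume is advanced with a
  semi-implicit trapezoid rule, solved in closed form each step, so the
  integrator's volume coincides with the trapezoidal cumulative integral
  of the recorded flow to floating-point round-off.
- **Effort**: a quadratic rise to `pmax` over `t_rise` (zero slope at the
  peak) and quadratic release over `t_release`; any smooth unimodal
  template satisfying the boundary conditions would do, and the choice is
  isolated in `pmus_profile`. Neural timing follows a lognormally jittered
  breath clock.
- **Ventilator FSM**: exhalation (Paw relaxes toward PEEP minus a
  demand-valve drop proportional to flow, 4 cmH2O/(L/s) — this produces the
  physiologic trigger dip the segmenter detects) → flow trigger at
  0.05 L/s → fixed trigger delay (80–100 ms per patient) → exponential
  pressurization toward PEEP+PS with a 50 ms time constant (producing the
  decelerating PSV flow morphology) → cycling off when flow falls to 25%
  of the breath's peak inspiratory flow.
- **Pes synthesis**: Pes = Pes_endexp + Ecw·V + Rcw·Flow − Pmus, the exact
  algebraic inverse of the reconstruction formula, using the same
  per-breath re-zeroed trapezoidal volume the annotator recomputes. On
  noise-free data the reconstructed Pmus therefore equals the true Pmus to
  machine precision — this identity is asserted in the tests at 1e-6 and
  holds at ~1e-13.
- **Noise**: i.i.d. Gaussian noise on the pressure channels only (flow is
  left clean; ventilator flow signals are internally filtered). Default
  0.3 cmH2O for cohort generation, 0 and 0.5 in the fidelity tests.

### Synthetic cohort

`generate_cohort` draws, per patient: sex (46% male), age ~ N(70, 10),
height by sex, respiratory-system compliance ~ N(46, 14) mL/cmH2O
(truncated), resistance ~ U(8, 15) cmH2O/(L/s), PEEP ~ N(7, 2) rounded,
Pes_endexp ~ N(5, 2), a per-patient trigger delay ~ U(80, 100) ms, and 2–5
pressure-support levels centered on 7 ± 4 cmH2O (clipped to 0–20). Ecw
comes from the same predicted-VC formula the annotator uses, so annotation
constants match the synthesis constants by construction.

Effort amplitude falls exponentially with the support level
(scale 18 cmH2O of PS), emulating down-regulation of respiratory drive
under increasing assist; 15% of patient-levels additionally have their
drive suppressed to 35%, representing over-assisted ventilation — this
mixture reproduces a clinically realistic effort distribution (PTP/min
median ≈ 125–140, IQR ≈ 75–200 cmH2O·s/min) with a weak-breath prevalence
near 14%. Respiratory rate ~ N(21, 5) per patient with a mild negative
dependence on support. These defaults were fixed once against the target
distribution and are not tuned per experiment.

What the simulator does **not** model: nonlinear or two-compartment
mechanics, expiratory muscle activity (Pga flat), intrinsic-PEEP dynamics
beyond a static term, cardiogenic oscillations (available as an option,
off by default), ineffective efforts and premature cycling beyond what the
trigger threshold naturally produces, and ventilator-brand idiosyncrasies.
Passing tests on synthetic cohorts therefore demonstrate internal
consistency of the pipeline and recoverability of known truth under the
stated physics — not clinical performance on real recordings.

## Classifier (classifier, nn)

Input: one segmented breath, two channels (flow, Paw) over
[onset, next onset), linearly resampled to 50 Hz and right-zero-padded to
300 samples (6 s covers a full breath for rates ≥ 10/min). Channels are
normalized by fixed population scales — flow/2 L/s, (Paw − PEEP)/20 cmH2O —
rather than per-breath statistics, because amplitude carries the class
signal. Esophageal pressure is structurally absent from the prediction
path.

Architecture: five 1D convolutional blocks, each two identical ReLU
convolutions followed by max pooling of size 2, with (filters, kernel) =
(64,3), (64,9), (128,9), (256,9), (32,7); the flattened output feeds two
dense ReLU layers of 128 units with dropout 0.5, then a single sigmoid
unit — 1,311,553 parameters at input length 300. The network, its
backward passes and the Adam optimizer are implemented directly in NumPy
(im2col convolutions as BLAS matmuls); every layer's gradient is verified
against central differences in the test suite.

Training: class-weighted binary cross-entropy (weights inversely
proportional to class frequency, mean 1) with label smoothing 0.1 — the
smoothing keeps output probabilities away from saturation, which both
regularizes and keeps the threshold search on the validation set well
conditioned. Adam at 5e-4 (library default 1e-3), batch 64, early stopping
on validation loss with best-weights restoration. All randomness (init,
shuffling, dropout) flows from one seed; training is bit-reproducible
single-threaded.

Decision threshold: sensitivity + specificity − 1 (Youden's J) evaluated
on the validation set over a 0.01-grid, choosing the *smallest* threshold
whose J is within one binomial standard error of the maximum. Among
statistically indistinguishable operating points this prefers sensitivity,
which is the correct asymmetry for a screening alarm whose costly error is
the missed weak effort; the raw argmax on a handful of validation patients
is substantially noisier. Prediction uses `prob >= threshold`.

## Evaluation (evaluate)

Splits are by patient (no patient contributes breaths to two splits),
default fractions 0.45/0.15/0.40 of patients; shuffles are retried
(bounded, seeded) until every split contains both classes, keeping the
shuffle whose breath-level prevalence best matches the cohort. Metrics
come from the standard confusion-matrix formulas with weak as the positive
class; ratios with zero denominator are reported as None, never silently
as 0. The respiratory-rate baseline predicts weak iff the breath's own
rate 60/Ttot falls below a threshold (17 or 12 breaths/min), the bedside
rule the classifier should beat on sensitivity. A histogram of PTP/min
among false positives (bins 50–75–100–125–150–∞) quantifies how close the
"wrong" alarms are to genuinely low effort.

## Numerical and scale choices

- Sampling rate 100 Hz for simulation and fixtures (resolves the 80–100 ms
  trigger delay with 8–10 samples); classifier input at 50 Hz.
- All integrals are trapezoidal; a 10x-oversampled integral of the analytic
  effort profile serves as the oracle in tests (agreement within 2%,
  typically 0.1%).
- Test and acceptance cohorts: 10 patients x 3 levels x 60 s for the
  annotation-fidelity checks, 40 patients x 2-5 levels x 126 s
  (~6,000–7,000 breaths, ~8–15% weak) for classifier training, with up to
  14 epochs — sizes chosen to exercise the full pipeline at desk scale.
- Degenerate inputs: zero effort produces apnea at PEEP and an empty truth
  table (not an error); single-class training labels and sub-32-sample
  inputs are rejected with explicit errors.

## Known limitations

- The Ecw default rests on a population regression of predicted VC; no
  esophageal-balloon calibration or occlusion-test validation is modeled.
- PTP is computed over the mechanical inspiration only; pre-trigger effort
  (isometric work before flow starts) is not included, and no PEEPi
  correction is applied.
- The classifier's reported performance is on synthetic patients drawn
  from the same generative family as its training data; transfer to real
  recordings is untested by construction.
- The RR baseline uses per-breath rate; a windowed-rate variant would give
  slightly different numbers.
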