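# Methods

`ecgvt` estimates the ventilatory threshold (VT) of an incremental cycle
ergometer test from single-lead ECG with a windowed deep-learning
classifier, and evaluates that estimate against the conventional
gas-exchange determination. Because no public dataset pairs exercise ECG
with breath-by-breath gas exchange at the required granularity, the
package ships a physiology simulator that generates complete test sessions
with a known threshold; every downstream stage is developed and validated
against that known truth.

## The CPX session model

A session follows the standard in-hospital protocol: 2 min seated rest,
2 min unloaded (0 W) warm-up, a ramp at 10–15 W/min to volitional
exhaustion, and 3 min of recovery. Work rate rises linearly during the
ramp, so the ramp lasts `peak_work_rate / ramp_rate` minutes.

**Gas exchange.** Oxygen uptake follows the classic linear on-kinetics
approximation, VO2(t) = VO2_rest + g·WR(t) with g = 10 mL/min/W scaled by
body mass (mL/kg/min units throughout). CO2 output is piecewise linear in
VO2: slope `vslope_below` (default 0.85) below the threshold and
`vslope_above` (1.25) above it, continuous at the breakpoint — the
V-slope picture of buffering-driven excess CO2. Minute ventilation tracks
VCO2 with gain ~30 (the VE–VCO2 slope) up to the respiratory compensation
point (RCP, placed 60% of the way from VT to peak), then steepens by a
further factor 1.4. The resting respiratory quotient is 0.95; this keeps
the VCO2-on-VO2 intercept positive so that VE/VO2 falls before VT and
rises after it, the geometry the ventilatory-equivalent detector needs.
Breath samples arrive every ~3 s with independent Gaussian noise per
channel (default SD 0.25 mL/kg/min); with the noise at zero the VCO2–VO2
breakpoint sits exactly at VO2(VT).

**The ECG-borne VT signature.** What a real exercise ECG carries about VT
is unknown; the simulator *declares* its signal, so that recovering it is
a well-posed test of the learning pipeline. Two RR-interval changes occur
at the threshold:

1. **HRV withdrawal** — a respiratory-sinus-like sinusoidal RR modulation
   (0.25 Hz) whose amplitude drops from `hrv_below` = 60 ms to
   `hrv_above` = 12 ms at VT, reflecting the loss of vagally mediated
   variability near the aerobic threshold;
2. **an HR trajectory knot** — mean HR climbs linearly from its resting
   value to a fixed fraction `hr_vt_frac` = 0.46 of heart-rate reserve at
   VT (75 → ~103 → 136 bpm at the cohort means), then with a different
   slope on to peak. The 0.46 comes from the cohort table's rest/VT/peak
   heart rates; per-subject fractions get SD 0.03.

Setting `hr_vt_frac = None` and `hrv_above = hrv_below`
(`zero_signal_params()`) removes both signatures while leaving the gas
breakpoint intact — the negative-control configuration in which the ECG
carries no threshold information.

In atrial-fibrillation mode the deterministic modulation is replaced by
independent multiplicative RR draws (CV 0.15), reproducing the rhythm for
which classical HRV analysis fails; AF subjects retain the HR-trajectory
cue. Default AF prevalence is 9.6%.

**ECG rendering.** Each beat is a sum of five Gaussians (P, Q, R, S, T)
placed relative to the R time; P and T offsets and the T width stretch
with the local RR. R amplitude is fixed per subject (0.8–1.4 mV). R-peak
times are recoverable from the rendered trace to within one sample, which
the round-trip test exploits. The native sampling rate is 1000 Hz; desk
runs use 250 Hz (the rendered content is band-limited well below either
Nyquist, so this only rescales compute).

**Cohort draws.** Age ~ N(58.9, 14.6), 73.1% male, weight ~ N(64.7,
13.8) kg, beta-blocker 68.1% — the cardiovascular in-patient population
the protocol targets. Rest / VT / peak VO2 are drawn as N(3.9, 0.8),
N(14.0, 4.5), N(21.8, 7.4) mL/kg/min, with peak at least 6 above rest and
VT truncated to 25–80% of the VO2 reserve: thresholds essentially never
sit adjacent to rest or peak physiologically, and the truncation also
guarantees the breakpoint detectors a few 30-s windows on each side.
HR rest/peak are N(75, 13) and N(136, 27) bpm. All draws are
per-subject child streams of one seed; cohorts are bit-reproducible.

## Gas-exchange VT determination

All detectors operate on non-overlapping 30-s window means (half-open
`[start, start+30)` windows tiled from exercise onset, trailing partial
window dropped), mirroring the averaging a metabolic cart applies.

* **Modified V-slope** fits the continuous segmented (hinge) model
  `VCO2 = a + m1·VO2 + d·(VO2 − c)+` by exhaustive grid search over the
  breakpoint `c` with Brent refinement. The window straddling the kink
  lies on neither limb after averaging; the fit is therefore repeated with
  the sample nearest `c` excluded and kept only if that halves the
  residual sum of squares — on noiseless data this collapses the RSS to
  zero and recovers the constructed breakpoint exactly, while on noisy
  data the all-points fit (which is statistically better) is retained.
  The added slope `d` must exceed a small relative margin, so exactly
  collinear data yield "no VT" rather than a floating-point artifact.
* **Ventilatory equivalent**: the earliest window after the VE/VO2 nadir
  with two consecutive VE/VO2 rises while VE/VCO2 stays within 2%
  (configurable) of its running minimum.
* **Excess CO2**: the same hinge machinery applied to
  VCO2²/VO2 − VCO2 against time.
* **Consensus**: the median of the successful detectors' times (midpoint
  for two); a session where all three fail is flagged and excluded, the
  count reported. The VO2 at any threshold time is read as the containing
  window's mean — no interpolation, matching the instrument's granularity.

Derived metrics: peak VO2 is the last complete 30-s window of exercise;
the VE–VCO2 slope is the OLS slope from exercise onset to the RCP (itself
a hinge fit of VE on VCO2), conventionally dimensionless when body mass
is supplied to convert units.

With the default breath noise the consensus lands within one averaging
window of the constructed truth (bias ≈ +5 s, SD ≈ 15 s), which is the
resolution floor the 30-s protocol imposes. A related identifiability
floor applies even without noise: the breakpoint is exactly recoverable
from window means only when at least two clean windows flank it, so a
threshold falling in the penultimate window of a very short test is
determined only to within that window — the detector then keeps the
all-points fit rather than an underdetermined excluded fit.

## Windowing, labels, covariates, split

The exercise-phase ECG (only) is cut into consecutive 30-s windows;
window *i* is labeled 0 if it ends at or before the (gas-determined) VT
and 1 if it contains or follows it, so labels are monotone within a
session and exactly one window contains the threshold. Each window
carries three covariates: age/100, sex (0/1), and exercise time — by
default the window's elapsed time from exercise onset in units of 600 s
(the alternative reading, the subject's total ramp duration, is a config
switch). Voltage is fed at native scale: amplitude and rhythm dynamics
are the signal, and per-window normalization would partly erase them.

Sessions are split 37.3% / 27.7% / 35.0% into derivation, validation and
test cohorts by largest-remainder rounding of a seeded permutation — by
session, never by window, so no subject leaks across cohorts. 260
sessions yield the reference counts 97/72/91; the desk-scale default of
200 yields 75/55/70.

## The classifier

A stack of (1D convolution → ReLU → 1D max pooling) blocks abstracts the
raw voltage sequence, an LSTM reads the reduced sequence and its final
hidden state summarizes the window, the covariates are concatenated to
that summary (pre-LSTM injection is available), and two dense layers end
in a single sigmoid. Training minimizes binary cross entropy with
RMSprop (ρ = 0.9, batch 64; the desk preset uses lr 2e-3 with decoupled
weight decay 1e-4 on the weight matrices) for a fixed number of epochs,
snapshotting validation loss each epoch and restoring the
best-validation weights — the final model is the epoch that generalized
best, not the last. The weight decay matters: without it the network
memorizes the ~75 derivation subjects' individual HR trajectories and
test-cohort agreement drops sharply.

The engine is a compact numpy implementation (shift-and-matmul
convolutions, BPTT through the LSTM's final state) with hand-written
backward passes verified against central finite differences to ~1e-6
relative error; float32 is used for training throughput, float64 for the
gradient checks. Everything is seeded and single-threaded-deterministic:
two runs of the same config are bitwise identical.

Layer sizes are deliberately configuration, with two presets. The
desk-scale preset (for 250-Hz windows, one CPU) is conv blocks
(8 filters, kernel 7, pool 10) → (16, 17, 5) → (24, 9, 4), LSTM 24,
dense 16, 35 epochs. The shape is chosen so the receptive fields bracket
the cardiac scales: after the first pool one step is 40 ms, so the second
conv's kernel of 17 spans ~680 ms — at least one full RR interval, which
is what lets filters measure beat spacing rather than merely detect
beats — and the third block spans several beats, exposing modulation of
the rhythm. (An earlier variant whose second kernel covered only 200 ms
could detect beats but not time them, and learned little beyond mean
heart rate.) The paper-scale preset scales the same shape to 1000-Hz
input and defaults to 60 epochs.

**Dummy-ECG ablation.** The control model trains the identical
architecture on windows whose voltage is identically zero, so it can use
only age, sex, and exercise time. With all-zero input every window's
convolution/LSTM path is identical; the implementation computes that path
once per batch and sums the upstream gradients — an exact algebraic
shortcut (tested against the generic path) that makes the ablation
training nearly free.

## From window probabilities to the DLT

The deep-learning threshold is the start time of the earliest window
whose probability reaches 0.5 — the first 30-s zone the model calls
at-or-after VT. An optional smoothing mode demands k consecutive
supra-threshold windows; the default k = 1 keeps the literal "initial
window" reading, and raising the cutoff can only move the DLT later.
Sessions in which no window fires are excluded from agreement statistics
with an explicit count rather than silently imputed. DLT-VO2 is the
containing gas window's mean, exactly as for VT-VO2, so a perfect
classifier yields identically zero differences.

## Agreement evaluation

Per cohort: Pearson r (t-test p, n−2 df) between VT-VO2 and DLT-VO2, and
Bland–Altman mean difference with ±1.96 SD limits of agreement plus a
one-sample t-test of zero bias. The full-vs-dummy comparison uses the
Fisher z test for two correlations,
z = (atanh r1 − atanh r2) / √(1/(n1−3) + 1/(n2−3)); the two correlations
share the test subjects and the VT-VO2 variable, which makes this
independent-samples form conservative under the positive dependence
present here, and Steiger's dependent-correlation variant is available
when the inter-method correlation is known. Subgroup analysis computes
per-stratum r on the test cohort (sex, AF rhythm, beta-blocker use in the
simulated cohort) with a Fisher-z interaction p for binary strata; strata
under n = 4 are skipped with a warning. All p-values are two-sided at
α = 0.05, with no multiplicity correction across subgroups.

## Problem sizes and what the synthetic results do (not) show

The package's own experiments run at desk scale: 200 sessions at 250 Hz
(~75/55/70 after splitting), desk preset — sized so a full experiment
(simulation, gas analysis, both trainings, evaluation) fits in a few
minutes on one CPU. Under the default strong-signal physiology the
trained classifier's test-cohort r is ~0.7–0.8 with |bias| well under
1 mL/kg/min, the dummy-ECG model is substantially worse, and the
correlation-difference test detects the gap; under the zero-signal
physiology the two models are statistically indistinguishable. The
negative-control replicates run smaller (60 sessions, 125 Hz, a 2-block
network, 15 epochs) since the quantity of interest there is a type-I
error rate, not accuracy — though both models must still be trained to
their covariate-only ceiling, or under-training itself manufactures
spurious correlation differences.

These results demonstrate that the pipeline recovers a threshold that is
genuinely encoded in the ECG, with the declared RR-dynamics signature and
cohort statistics matched to the clinical population. They do not
demonstrate that real exercise ECG encodes VT that way: real signals add
morphology drift, motion artifact, ectopy, and whatever the true VT
correlates are, none of which the simulator models. The synthetic
experiment validates the machinery — detectors, labeling, training,
threshold extraction, statistics — not the clinical claim.

## Numerical and design choices

* Half-open `[start, start+30)` intervals and 0-based window indexing
  everywhere; a boundary time belongs to the later window.
* Consensus rule: median of detector times (the combination rule is not
  standardized in the literature; the median is symmetric and robust to
  one divergent method).
* Minimum 6 averaged exercise windows to attempt detection; shorter
  sessions are flagged and excluded (their real-world counterparts are
  tests terminated early).
* The V-slope breakpoint must be a genuine slope increase
  (`d > 1e-8 + 0.01·max(|m1|, |m2|)`), so collinear input is "no VT".
* Degenerate inputs raise: empty averaging windows, all-zero VCO2,
  constant vectors in correlations, single-class training labels.
* RMSprop hyperparameters, class weighting (off by default), and the
  covariate merge point are exposed config; none are claimed optimal.
* Known limitations: no motion artifact or electrode-noise taxonomy, no
  12-lead synthesis, no blood pressure, no VO2 estimation without gas
  data (the DLT yields a time; VO2 at that time still needs the gas
  record), and the Fisher-z ablation test is conservative rather than
  exact for the shared-sample design.
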