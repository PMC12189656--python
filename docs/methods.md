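# Methods

`pvrkit` models the diagnostic workflow of forefoot pulse volume recording
(PVR) in diabetic foot disease: a pneumatic cuff held at 50 mmHg transduces
pulsatile limb-volume changes into a pressure oscillation; readers grade the
waveform visually, and quantitative software extracts upstroke time (UST,
ms), upstroke ratio (USR = UST / foot-to-foot wavelength) and maximum
systolic amplitude (MSA, mmHg — peak minus preceding foot). These features
are evaluated as index tests against angiographic disease severity staged by
GLASS (0–III) with the inframalleolar descriptor P0–P2. Because no raw
clinical recordings are publicly deposited, the package pairs the analysis
code with two synthetic-data generators — a waveform simulator with exact
ground truth, and a limb-level cohort simulator calibrated to the published
per-cell feature moments — so every stage is testable end to end.

## Waveform model (`wavesim`)

Each beat is a piecewise-smooth analytic curve on a foot-to-foot period:

* **Upstroke** — raised cosine from 0 to `amplitude` over `upstroke_time`;
  the systolic peak therefore falls exactly at UST and the foot at 0.
* **Descent** — a normalised exponential decay with a quadratic time warp,
  `g(s) = decay(s^2)`, which is C1 at the peak (zero initial slope, so the
  peak survives filtering without displacement) while keeping a nonzero
  terminal slope into the next foot.
* **Dicrotic notch** (optional) — monotone smoothstep segments
  peak → notch → dicrotic wave; the notch is an exact local minimum at
  `upstroke_time + notch_delay`, so ground-truth notch times are
  sample-accurate. `notch_depth` is the trough depth as a fraction of
  amplitude.
* **Flat interbeat interval** — `interbeat_flatness` in [0, 1] ends the
  descent early (up to 70 % of the descent span) and holds the baseline at
  the foot level, reproducing the "scooped or flat interval between peaks"
  of a healthy recording.

Recordings concatenate beats with 2 % SD per-beat period jitter (default;
makes segmentation nontrivial), then add white Gaussian noise and an
optional slow sinusoidal baseline drift (period ≥ 5 s). Samples are pressure
offsets around zero at 1 ms resolution; an optional quantizer snaps values
to the 2^18-level device grid. Identical configuration and seed give
bit-identical traces. Motion artifacts and arrhythmia are deliberately out
of scope.

Canonical class presets (amplitudes anchored to the calibration table): the
normal waveform (MSA 1.1 mmHg, UST 220 ms, notch, flat interval), the mildly
abnormal one (MSA 0.6, UST 250, notch and flat interval lost), the severely
abnormal one (MSA 0.25, UST 340 of an 800 ms period), and a non-pulsatile
flat trace. The severe preset's UST was set to 340 ms — approaching the
class-defining "equal upstroke and downslope" geometry (USR 0.425,
upstroke/downslope 0.74) — so that the preset lies past the prolonged-
upstroke rule boundary (USR ≥ 0.40) by a margin larger than the measurement
noise of the extractor; a preset at USR 0.375 would sit on the wrong side of
the class's own rule and no detector could separate the classes reliably.

The default recording length is 10 s (about 12 beats); source material does
not state a recording duration, and 10 s is a typical vascular-lab capture.

## Fiducial detection and features (`fiducials`)

All detection runs on zero-phase filtered copies (4th-order Butterworth,
`sosfiltfilt`): a 25 Hz "heavy" signal for landmarks and amplitudes, an
80 Hz "light" signal for timing refinement, an 8 Hz signal for the upstroke
slope, and a 12 Hz signal for apex fitting on flattened waveforms. The
rationale: heavy smoothing stabilises landmark search but rounds waveform
corners by up to ~10 ms; timing is therefore refined near each landmark on
a lightly smoothed copy with parametric local fits that are exact on clean
waveforms.

* **Pulsatility** — a trace is pulsatile iff the drift-free pulse band
  (0.4–25 Hz) has a robust peak-to-trough excursion (2.5–97.5 percentile
  spread) of at least 0.05 mmHg *and* a dominant autocorrelation peak at a
  lag of 300–2000 ms. The 0.05 mmHg floor operationalises "absence of
  visible pulsations", which is nowhere quantified; the measured decision
  boundary on synthetic amplitude sweeps is ≈ 0.05 mmHg.
* **Feet** — one steepest-upslope landmark per beat is taken from the 8 Hz
  slope signal (narrow band, because the onset slope of a flattened
  waveform is comparable to derivative noise), walked back to the slope
  zero-crossing, and refined by a corner-model least-squares fit on the
  light signal. Two model variants share the structure "tail meets a convex
  onset whose slope starts at zero": for flat-tailed waveforms
  `y = a + b t + d relu(t−tb)^2` with the fit residuals summed across all
  beats of the recording (the flat-to-onset corner is shallow; a per-beat
  fit drifts with noise, while the beats share one shape and hence one
  corner offset); for continuous descents `y = a + b min(t,tb) +
  d relu(t−tb)^2`, fitted per beat — tying the slope jump to the tail slope
  keeps the corner sharply identified. Foot defined as the local minimum /
  onset corner preceding the maximal upslope, not an intersecting-tangent
  construction.
* **Peak** — global maximum of the smoothed window, refined by a
  two-parabola apex fit `y = a + cL relu(tb−t)^2 + cR relu(t−tb)^2`, which
  is exact on clean beats and does not drift toward the flatter flank under
  noise the way a plain argmax does. Sharp-peaked (flat-tail) waveforms use
  a narrow symmetric window on the light signal; flattened waveforms a
  wider asymmetric window on the 12 Hz signal.
* **Notch** — most prominent local minimum strictly between the peak and
  85 % of the window, ignored below 2 % of beat amplitude prominence (must
  ignore noise ripples yet find shallow notches).
* **Flat interval** — |line-fit slope| over the last 15 % of the beat below
  10 % of the mean upstroke slope (MSA/UST). A line fit equals the mean
  slope for a monotone tail and is noise-robust.

Per-beat values from quality-accepted beats are summarised by the median
(robust to one corrupted beat); `usr = median_ust / median_wavelength`
exactly as computed. Non-pulsatile traces report MSA 0 with undefined time
features. At least 3 usable beats are required. Times stay on the native
1 ms grid; no sub-sample interpolation. Measured accuracy under the default
conditions (10 s, 2 % jitter): noise-free recovery within ±3 ms (UST),
±2 ms (wavelength), ±1 % (MSA) on all presets; at 0.03 mmHg noise the mean
absolute UST error is ≈3 ms (normal), ≈6 ms (mild) and ≈9 ms (severe) over
200 seeds.

An intrinsic limit worth stating: for a waveform with MSA near 0.1 mmHg at
0.02 mmHg noise the onset region rises out of the noise floor only tens of
ms after the true foot, so a 5 % relative UST tolerance is not attainable
there by any estimator without stronger shape priors; the recovery tests
assert the 5 % bound per cell where amplitude is adequate (MSA ≥ 0.3) and
as a grid median overall, and the noise-free grid everywhere.

## Morphology grading (`morphology`)

A deterministic cascade over extracted features: (1) not pulsatile →
non-pulsatile (CLTI); (2) notch present ∧ flat interval present ∧ steep
upstroke → normal; (3) prolonged upstroke (upstroke/downslope ≥ 0.75 or
USR ≥ 0.40) ∧ flattened amplitude (MSA < 0.35 mmHg) → severely abnormal;
(4) otherwise mildly abnormal. The numeric thresholds operationalise the
qualitative reading criteria: healthy-path USR clusters near 0.28 and
diseased near 0.37, so 0.40 separates "prolonged"; MSA 0.35 sits above the
severe-disease cell means (≈0.3 and below). The same 0.75 constant defines
"steep" in rule (2) so no feature region is unreachable. Thresholds are
estimator parameters (`MorphologyClassifier`), defaults fixed. The cascade
is total, exclusive, and monotone: lowering MSA or raising USR never moves
a grade toward normal.

## Cohort simulator (`cohort`)

The default configuration encodes the 11 populated GLASS-stage ×
inframalleolar cells of the calibration table: limb counts
{18,13,16,3 / 7,7,9,11 / 1,2,3} (90 limbs), of which 6 are non-pulsatile
(1 in P0/II, 5 in P1/III), and per-cell mean ± SD for UST, USR and MSA.
Cell moments are treated as pulsatile-only (effective n = n −
n_nonpulsatile); under that convention the n-weighted pooled means
reproduce the published overall values (UST 260 ms, USR 0.32) exactly,
which is the internal-consistency check the acceptance suite runs.

Pulsatile features are drawn per cell from independent truncated normals
(UST > 0, 0 < USR < 1, MSA ≥ 0); only marginal moments are published, so no
correlation structure is imposed (a coupling hook exists in the config).
Because the table reports *sample* moments, the untruncated (μ, σ) are
moment-matched by least-squares root-finding so the truncated
distribution's realized mean and SD equal the cell spec; an infeasible
request (e.g. SD ≫ mean with a zero lower bound, where the coefficient of
variation of a zero-truncated normal cannot reach 1) raises a calibration
error. Sampling is stratified inverse-CDF (one uniform per equiprobable
stratum, shuffled): still a correct random draw of the distribution, but
realized cell means converge at rate 1/n, so a scale-100 cohort reproduces
the calibration means to ±0.01 mmHg.

Labels: ABI incompressibility (ABI ≥ 1.3, medial calcification) is
Bernoulli with prevalence 49/90 ≈ 54.4 %, independent of GLASS stage by
default (observed coupling in the source data is weak — mean ABI is equal
for normal and mildly abnormal waveforms); ABI values are drawn consistent
with the flag. Infection is Bernoulli(59/90). A waveform-intactness flag
(dicrotic notch + flat interval retained) is Bernoulli with probability
falling over GLASS stage {0: 0.85, I: 0.30, II: 0.08, III: 0.05} — a
modelling choice representing progressive damping of reflected waves —
and the morphology grade is the rule cascade applied to the simulated
features. `features_to_traces` renders each limb back into a waveform
(shape parameters equal to the limb's features), closing the loop so the
full signal → feature → grade → statistics pipeline can run.

What the simulator does *not* emulate: intra-patient correlation (each limb
is independent), longitudinal repeat examinations, feature skewness beyond
what truncation induces, and any coupling between UST and MSA. Passing
tests therefore show the analysis machinery is correct under the published
marginal distributions — not that it would attain the same accuracy on real
recordings.

One consequence of independence: the population AUC advantage of MSA over
UST for detecting any PAD implied by the marginal moments is real but small
(≈ +0.006), far smaller than the gap in the source study (0.89 vs 0.82).
At scale 100 a single simulated cohort resolves this ordering only ~70 % of
the time, so the qualitative-ordering test averages AUCs over five
fixed-seed cohorts. The orderings for USR, for the P0 vs P1/P2 MSA
difference, and for grade severity vs GLASS stage are robust per cohort.

## Diagnostic test accuracy (`stats`)

Empirical ROC over all distinct thresholds (trapezoidal AUC; ties by the
Mann–Whitney half-credit convention, so AUC = P(pos > neg) + ½P(=)).
Direction is explicit per feature — MSA lower-is-disease, UST/USR
higher-is-disease — and cut-offs are reported in original units. The 95 %
CI is a seeded stratified bootstrap (2000 resamples, percentile interval);
the cut-off rule is Youden's J with ties broken toward specificity — the
source reports cut-offs without naming a rule, and Youden is the standard
default. 2×2 metrics are exact ratios with undefined values reported as
absent, not zero. Cohen's kappa is unweighted, computed from the k×k
confusion matrix with observed and chance agreement reported (cross-checked
against scikit-learn in the tests). Mann–Whitney/Kruskal–Wallis use
tie-corrected asymptotics via SciPy, with a full-enumeration permutation
p-value for small samples (both groups ≤ 8 by default). The
revascularisation responder rule is an MSA increase of at least 0.1 mmHg
(inclusive). `evaluate_cohort` excludes non-pulsatile limbs from
quantitative analysis, evaluates endpoints any-PAD (GLASS ≥ I), severe PAD
(≥ II), very severe (III) and inframalleolar disease (P1/P2), supports
boolean subgroup filters (ABI ≥ 1.3, infection), and reports explicit skip
records for single-class strata. No multiple-testing correction is applied,
matching univariate reporting practice. Reports round percentages to one
decimal and AUCs to two.

## Pipeline and formats (`io`, `pipeline`, `cli`)

Trace files are UTF-8 CSV with `#` metadata lines
(`sampling_interval_ms`, `cuff_pressure_mmhg`, `limb_id`) above a
`t_ms,pressure_mmhg` table, with ground truth in a JSON sidecar; floats are
written at full repr precision, so round-trips are lossless. Cohort tables
are plain CSV with a fixed schema; malformed rows are rejected with file,
line and field named. `run_pipeline` is deterministic for a fixed config
and stamps every report with a config hash, the seed and the package
version. Its default mode evaluates the simulated feature table (the
limb-table route, giving exactly 90 limbs / 6 non-pulsatile / 84 analyzed
at scale 1); `mode="traces"` re-extracts features from rendered waveforms
first, in which case simulated limbs whose amplitude falls below the
0.05 mmHg pulsatility floor are additionally classified non-pulsatile —
an expected property of the measurement model, not an error.

## Problem sizes

Defaults keep everything desk-scale: recovery experiments use 200 seeds of
10 s traces per preset; cohort checks use scale 100 (9000 limbs);
bootstrap CIs use 2000 resamples in production and smaller counts inside
tests. The full test suite runs in well under a minute on one core.
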