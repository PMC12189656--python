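# pvrkit

Forefoot **pulse volume recording (PVR)** analysis for peripheral arterial
disease (PAD) screening in the diabetic foot: waveform simulation, fiducial
detection, quantitative feature extraction, rule-based morphology grading,
a calibrated limb-cohort simulator, and diagnostic-test-accuracy (DTA)
statistics against angiographic GLASS staging.

## The problem

In diabetic foot syndrome, medial arterial calcification makes ankle cuff
pressures unreliable (ankle–brachial index ≥ 1.3 in over half of limbs), so
standard ABI screening fails exactly where PAD detection matters most. PVRs
— pressure oscillations recorded by a forefoot cuff held at 50 mmHg — stay
interpretable in incompressible arteries. A recording is graded two ways:

* **semiquantitatively**, into four morphology classes (normal / mildly
  abnormal / severely abnormal / non-pulsatile), from the sharpness of the
  upstroke, the dicrotic notch and the flat interbeat interval;
* **quantitatively**, by three features of the averaged beat:

  | feature | definition | units |
  |---|---|---|
  | UST | foot → systolic peak time | ms |
  | USR | UST / total wavelength (foot-to-foot) | — |
  | MSA | peak minus preceding foot | mmHg |

Obstructive disease prolongs the upstroke (UST, USR ↑) and damps the pulse
(MSA ↓). The package evaluates these features as index tests against
angiographic severity (GLASS stages 0–III; inframalleolar descriptor
P0–P2): ROC curves with bootstrap CIs, Youden cut-offs,
sensitivity/specificity/PPV/NPV, Cohen's kappa for interrater agreement,
and a revascularisation responder rule (ΔMSA ≥ 0.1 mmHg). Because the
underlying clinical dataset is not public, a waveform simulator with exact
ground truth and a cohort simulator calibrated to the published per-cell
feature moments (90 limbs, 11 GLASS × inframalleolar cells) stand in for
the data; see `docs/methods.md` for the models and their limits.

## Worked example

Simulate the default 90-limb cohort, grade it, and evaluate all endpoints:

```bash
pvr run --scale 1 --seed 1 --n-boot 500 --out report.json
# limbs=90 non_pulsatile=6 analyzed=84 -> report.json
```

The report shows 90 limbs of which 6 are non-pulsatile (critical
limb-threatening ischemia), leaving 84 for quantitative analysis — the
exact structure of the reference cohort. For detection of any PAD
(GLASS ≥ I) on this single small cohort it contains, per feature
(AUC, Youden cut-off, sensitivity, specificity):

```
any_pad  msa_mmhg  AUC 0.82  cutoff 0.50 mmHg  sens 84.5%  spec 69.2%
any_pad  ust_ms    AUC 0.83  cutoff 259 ms     sens 63.8%  spec 88.5%
any_pad  usr       AUC 0.77  cutoff 0.31       sens 74.1%  spec 73.1%
```

i.e. a low-amplitude, slow-upstroke waveform strongly indicates angiographic
disease. At n = 84 the MSA-vs-UST ranking wobbles from seed to seed; on
large simulated cohorts (`--scale 100`) MSA has the highest AUC of the
three features, its mean is markedly lower in limbs with impaired
inframalleolar outflow (P1/P2 ≈ 0.35 vs P0 ≈ 0.63 mmHg), and the fraction
of severely-abnormal or non-pulsatile grades rises monotonically with
GLASS stage.

Library use mirrors scikit-learn conventions:

```python
from pvrkit import (TraceConfig, generate_trace, PVRFeatureExtractor,
                    MorphologyClassifier)

traces = [generate_trace(TraceConfig(seed=s), "mildly_abnormal") for s in range(3)]
features = PVRFeatureExtractor().fit().transform(traces)   # DataFrame
grades = MorphologyClassifier().fit().predict(features)    # array of class labels
```

## Layout

```
src/pvrkit/
  wavesim.py     beat/trace synthesis with ground-truth fiducials
  fiducials.py   smoothing, pulsatility, beat segmentation, UST/USR/MSA
  morphology.py  four-class rule cascade (sklearn-style classifier)
  cohort.py      calibrated limb-cohort simulator (truncated-normal cells)
  stats.py       ROC/AUC, Youden, 2x2 metrics, kappa, nonparametrics
  io.py          trace/cohort/report file formats
  pipeline.py    deterministic end-to-end runs with provenance
  cli.py         the `pvr` command
docs/methods.md  model assumptions, parameter rationale, limitations
```
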