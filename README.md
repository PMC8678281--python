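# ctgkit

A rule-based toolkit for cardiotocogram (CTG / electronic fetal monitoring,
EFM) analysis during labor. It is aimed at researchers building automated
fetal-surveillance or annotation pipelines: it encodes an operational set of
EFM pattern definitions as a deterministic rule engine, simulates labeled
intrapartum CTG scenarios for testing, renders records as scanned-strip-style
chart images with Pascal VOC bounding-box annotations (the input format used
by image-based object detectors), and scores detections with standard
IoU/precision/recall metrics.

## The clinical model

A CTG pairs the fetal heart rate (FHR, bpm) with the uterine-contraction
(UC) trace. Each fetus has an individual **basal rate** established at the
onset of labor; deviations are judged both absolutely and relative to it:

- **Tachycardia / bradycardia**: sustained (>10 min) baseline above 155 bpm
  or below 110 bpm (absolute), or shifted more than 15 bpm from the basal
  rate (relative).
- **Variability**: minute-scale peak-to-trough oscillation; decreased
  below 6 bpm, increased above 25 bpm.
- **Deceleration recovery**: the fetus's response to a deceleration. A
  *normal* recovery returns promptly to the prior baseline. Adverse
  morphologies: **overshoot** (a post-deceleration acceleration lasting
  ≥15 s), **delayed return** (recovery outlasting the contraction),
  **peaked return** (a terminal spike followed by a late deceleration).
- **Special patterns**: sinusoidal (regular 3–5 cycles/min undulation),
  sawtooth (≥20 cpm, <15 bpm), checkmark (repetitive asymmetric spikes),
  conversion (wholesale change of rate and variability within 1–2
  contractions).
- **Excessive uterine activity**: contraction frequency >5/10 min over two
  consecutive windows, duration >90 s, resting tone >20 mmHg, inter-peak
  interval <120 s, or rest time <50%.

Two intervention points compose these features:

- **Point A** — the earliest time deceleration recovery is no longer normal
  (criteria A–F: delayed return; post-deceleration increased variability
  >20 bpm at 5–10 cpm; overshoot; transient baseline rise ≥15 bpm; transient
  baseline fall ≥10 bpm; excessive uterine activity irrespective of the FHR
  pattern). Point A calls for conservative measures: reducing uterine
  activity or oxytocin, ceasing pushing, maternal position/oxygen/blood
  pressure support for late decelerations, and assessing the feasibility of
  safe vaginal delivery. The measures are deliberately unranked.
- **Point B** — presumptive fetal compromise: a sustained post-deceleration
  return to a diminished-variability, elevated baseline, or a rapid adverse
  change (conversion). Point B presupposes escalation through Point A.

Every numeric threshold lives in `RuleConfig` with these defaults.

## Worked example

Simulate a labor segment whose scripted deceleration at ~25 min recovers
only after its contraction has ended (a delayed return), then analyze it:

```python
from ctgkit import analyze_record
from ctgkit.simulate import criterion_scenario, simulate_scenario

record, truth = simulate_scenario(criterion_scenario("A", seed=7, noise_sd=2.0))
report = analyze_record(record)
print("assessment:", report.assessment.status)
print("point A time (s):", round(report.point_a.time, 1))
print("criteria fired:", report.point_a.criteria)
print("ground-truth time (s):", round(truth.point_a_time, 1))
print("measures:", report.measures)
```

prints

```
assessment: normal
point A time (s): 1542.6
criteria fired: ['A']
ground-truth time (s): 1542.5
measures: ['assess feasibility of safe vaginal delivery']
```

The tracing is normal at the outset (the deceleration comes later), Point A
fires on criterion A within a fraction of a second of the analytically known
onset, and — with no excessive uterine activity and no late decelerations —
the only recommended measure is the always-included delivery-feasibility
assessment.

The same pipeline is scriptable from the shell:

```
ctg simulate --seed 7 --out rec.csv --truth truth.json
ctg analyze points rec.csv --out report.json
ctg dataset build --records records/ --seed 7 --out dataset/
ctg evaluate --pred preds/ --truth dataset/annotations --out eval.json
```

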