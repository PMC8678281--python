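# Methods

This note documents the models, conventions and numerical choices behind
ctgkit, what the synthetic scenarios do and do not emulate, and the known
limitations.

## Signal model and conventions

Records are uniformly sampled at a default of 4 Hz per channel (the standard
digitization rate of bedside CTG monitors; every rule operates on physical
seconds, so any rate works). Time is seconds from record start; intervals
are half-open `[t_start, t_end)`. Missing or implausible FHR samples
(outside 30–240 bpm) are carried as a boolean quality mask, never
interpolated at read time; `clean_fhr` bridges dropouts up to 15 s by linear
interpolation and leaves longer gaps invalid. Analysis windows with more
than 20% invalid samples are reported as indeterminate rather than
classified. The UC channel records its transduction mode because
absolute-pressure thresholds (resting tone >20 mmHg) are meaningful only for
intrauterine catheter data; in external (relative) mode that flag is never
raised.

The CSV dialect (`time_s,fhr_bpm,uc`, optional `# fs=4` header) is a
package convention: clinical archives of this kind are typically stored as
rasterized chart PDFs and name no signal format.

## Baseline, basal rate, variability

The per-minute baseline is estimated iteratively: (1) 25%-trimmed mean per
minute; (2) exclusion of minutes deviating >15 bpm from the rolling 10-min
median; (3) nearest-neighbour fill of excluded minutes; at most 5 passes.
The basal rate takes the most stable half (lowest robust range) of the first
20 minutes' epochs, which excludes epochs disturbed by decelerations or
accelerations, and returns the median of their trimmed means.

Variability per minute is the 5th–95th percentile range of the
baseline-detrended trace (robust to single-sample artifacts, unlike raw
min–max), with samples inside decelerations excluded. The dominant cycle
frequency is the zero-crossing count divided by two; crossings are located
globally and binned by crossing time so that epoch boundaries never swallow
a crossing, and the crossing count uses a 1-s smoothed copy so broadband
measurement noise above the physiological band does not inflate it. For a
pure sinusoid of half-amplitude A the percentile range is
2·A·cos(0.05π) ≈ 1.975·A — the basis of the closed-form checks in the test
suite.

## Deceleration detection and recovery classification

A deceleration is a maximal interval with the smoothed detrended FHR below
−15 bpm for at least 15 s (an ACOG-style magnitude floor, configurable),
extended outward to the −5 bpm crossings; sub-threshold gaps ≤3 s within an
episode are tolerated. Detection is two-pass: a dip that fills most of a
minute drags that minute's trimmed mean down with it, muting the dip in the
detrended trace, so candidate dips (a lighter −10 bpm threshold) are masked
out, the affected epochs' baseline recomputed from clean samples only, and
episodes re-detected against the refined baseline.

Timing against the nearest contraction peak: *variable* when the nadir is
within ±15 s of the peak with a steep onset (≥3 bpm/s), *late* when the
nadir lags the peak by 20–90 s, *early* when coincident but gradual, and
*undefined* otherwise or with no contraction within 120 s.

Recovery morphology is classified against the **pre-deceleration epoch
level** (median of the last three clean epochs before onset) rather than
the running baseline, which a long recovery tail or a post-recovery
acceleration partially drags along. Precedence is fixed as
peaked return > overshoot > delayed return > normal — the order reflects
escalating severity; no tie rule is otherwise defined. A deceleration still
below the recovery edge at the record end is *unresolved*.

## Special patterns

Sinusoidal and sawtooth detection combine the cycle-frequency and amplitude
bands with a spectral-regularity gate: the in-band (0.03–0.5 Hz) spectral
flatness of the minute must fall below 0.25. Restricting flatness to
in-band bins is essential — out-of-band bins carry near-zero power for any
band-limited signal and would make everything look concentrated. Raw
periodogram bins of band-limited Gaussian noise give flatness ≈ e^(−γ) ≈
0.56, a regular oscillation <0.1, so 0.25 separates them cleanly. The gate
is applied to the sawtooth rule as well: pseudorandom variability has a
zero-crossing rate near 18–20 cpm and would otherwise occasionally trip the
≥20 cpm rule.

Checkmark detection is matched-filter correlation (Pearson r ≥ 0.8) of an
asymmetric 2-s-rise / 8-s-decay template against ≥10 bpm peaks, requiring at
least three recurrences about 0.5–2 per minute. The quantification of this
pattern (amplitude 15–25 bpm, those rise/decay constants) is a package
convention — the pattern is defined in the literature only pictorially.

Conversion is a step of ≥15 bpm between 5-min medians of the baseline with
a simultaneous variability-class change (below 6 / 6–25 / above 25 bpm),
completing within two median contraction intervals; its end time is the
first epoch settling within 2 bpm of the new level.

## Uterine activity

Contraction peaks are found by prominence (≥15 units above the resting
tone) on a 4-s smoothed trace; onset/offset at the 10%-of-amplitude
crossings define duration. Per sliding 10-min window (1-min step) the
analyzer computes frequency, mean duration, resting tone (5th percentile),
minimum inter-peak interval, and rest-time fraction (samples within 5 units
of the tone), and raises one excess flag per criterion. The frequency
criterion's doubling requirement is read as the excess persisting over two
consecutive windows (`ua_freq_windows`, configurable). The duration
criterion compares the window's *mean* contraction duration against 90 s.
Contraction intensity has no defined excess and raises no flag. Pushing is
not represented in the data model, so rest time reflects contraction absence
only — a documented simplification of the definition, which covers both.
The same predicate code evaluates ground-truth contraction labels, which is
what the oracle-equivalence tests exercise against an independent in-test
re-implementation.

## Point A / Point B

Criterion letters map to: A, any delayed-return deceleration (trigger at the
associated contraction's end — the first instant the return is known to be
delayed beyond it); B, a post-deceleration minute with variability >20 bpm
at 5–10 cpm (trigger at that minute's end); C, any overshoot (trigger at
recovery); D/E, a transient (≥1 min but not >10 min, after which it becomes
a sustained baseline event instead) epoch-mean shift of ≥15 bpm up / ≥10 bpm
down relative to the basal rate within 10 min of a deceleration (trigger
one minute into the run); F, any excessive-activity window (trigger at that
window's end, independent of the FHR). B, D and E are windowed to 10 min
after a deceleration because they describe deceleration recovery. The
report keeps *all* fired criteria (the measure mapping is feature-driven);
the time is the earliest trigger, ties broken A<B<…<F.

Point B route 1 requires a sustained (>10 min) post-deceleration run of
variability <6 bpm with the baseline ≥10 bpm above its pre-deceleration
level (trigger when the run exceeds 10 min); route 2 fires at a conversion's
completion. No clinical covariates are consulted. A Point B without a
preceding Point A is suppressed to preserve the escalation invariant; none
of the shipped scenario families can produce one. The 110–155 bpm band
defines outset normality while <100 bpm defines outset abnormality; values
in 100–110 bpm make the assessment abnormal with a "below normal band"
reason, and the bradycardia *event* threshold stays at 110 bpm — the two
cuts are deliberately distinct config fields, as are the criterion-B 20 bpm
and the increased-variability 25 bpm thresholds.

## Synthetic scenarios

The simulator is the package's test oracle. Contractions are raised-cosine
pulses whose 10%-of-amplitude width equals the nominal duration, placed by
integrating a (piecewise-constant) contraction rate, with optional uniform
jitter; defaults are the clinically average 3 per 10 min, 75 s, 50 mmHg
above a 15 mmHg tone. Variability is band-limited (0.03–0.5 Hz) Gaussian
noise scaled so its global 5–95 percentile range equals the requested
peak-to-trough amplitude (default 10 bpm) — a minimal model, chosen because
the rules consume only amplitude and cycle frequency, not beat-to-beat
dynamics. Decelerations are cosine dips aligned to the nearest contraction
(late dips lag the peak by a configurable 30 s); delayed returns recover
exponentially (τ = 45 s); overshoots add a plateau bump of amplitude
0.25×depth (capped at 25 bpm) whose duration grows with depth; peaked
returns add a narrow terminal spike and a following late deceleration.
Scenario scripts use 40 bpm decelerations — the depth at which every
morphology remains unambiguous against 10 bpm variability plus 2 bpm
measurement noise. Everything is deterministic given the seed; scripted
peaks are snapped to the sample grid so that continuous-time ground truth
and grid-quantized detection never disagree about window membership.

Ground-truth Point A/B times are computed from the constructed (noise-free)
waveform geometry and the scripted parameters by the same criterion
semantics, never by running the detectors on the noisy signal.

What the generator does **not** emulate: beat-to-beat RR dynamics and
accelerations, transducer loss/gain artifacts beyond simple dropouts,
maternal heart-rate intrusion, pushing artifacts in the tocogram, and drift
in the basal rate over hours. Passing tests therefore demonstrate that the
rules recover the patterns they define under controlled morphology and
noise — not clinical-grade performance on real tracings.

## Chart pipeline

Pages use a 3 cm/min paper speed, 30 bpm/cm vertical scale and 47 px/cm
(≈120 dpi) — standard US strip conventions, all configurable; a 10-min page
is 1410 px wide. The time↔pixel mapping is an exact affine transform
carried on each page and updated by cropping, so round trips are lossless.
Scan degradation applies blur, contrast loss, salt-and-pepper speckle and a
≤1° rotation scaled by a level in [0,1] (level 0 is the identity).
Auto-cropping locates grid columns (pixel columns inked over ≥30% of the
height) and keeps the row band where at least half of them are inked,
removing headers and footers. Event boxes span the padded event interval
horizontally and the full FHR panel vertically (the patterns are defined on
the whole trace context; a reproducible convention), split at page borders;
coordinates are 1-based inclusive, the classic Pascal VOC dialect.

The 80/20 split is page-level and seedable-random (chronological splitting
is not offered; page-level splitting can leak pages of one record across
sets — use one record per split side when that matters). The validation set
is drawn *out* of the test side so the three partitions are disjoint and
exhaustive; for 252 pages this yields 202 train and 50 held-out pages, 25 of
them validation. Augmentation emits exactly four variants per image —
{identity, horizontal flip} × {resolution-reduced, sharpened} — and never a
vertical flip, which would create physiologically impossible mirror
patterns; 202 → 808 and 50 → 200.

## Detection evaluation

IoU uses inclusive pixel areas. Matching is greedy by descending
prediction score with same-label constraint and an IoU ≥ 0.5 gate (the
threshold is configurable; published figures of this kind rarely state
one). `feature_accuracy` is the matched-truth fraction — the share of
annotated features the detector found — reported alongside precision and
recall so either convention is available. On instances of ≤6 boxes per
image the greedy matcher attains the exhaustive optimal matched count
(property-tested against full enumeration).

## Problem sizes

The shipped test and acceptance runs use 35-min records at 4 Hz (8,400
samples per channel), 100 seeds per scenario family for the stochastic
suites, 252 rendered pages (at a reduced 12 px/cm for the count
arithmetic, which is scale-invariant), 50 jitter-free simulations for the
activity-flag oracle and 500 random instances for the matcher oracle.

## Known limitations

- The rule engine is deterministic and threshold-based; it produces no
  probability or confidence for Point A.
- Variability between 15 and 25 bpm has no named class and is treated as
  normal.
- The checkmark quantification and the chart geometry are package
  conventions where the literature is qualitative.
- Real scanned strips (image → signal inversion) are out of scope; the
  image pipeline generates charts, it does not re-digitize them.
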