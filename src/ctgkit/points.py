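"""Intervention-point engine: initial assessment, Point A, Point B, measures.

Point A is the earliest moment at which deceleration recovery is no longer
normal — or uterine activity is excessive, irrespective of the heart-rate
pattern — and conservative measures are warranted.  Point B marks the
criteria for presumptive fetal neurological compromise.  Six Point A
criteria are evaluated:

A. delayed return to baseline (recovery outlasts the contraction);
B. post-deceleration increased variability, >20 bpm at 5–10 cycles/min;
C. overshoot (post-deceleration acceleration lasting 15 s or more);
D. transient (≥1 min, not sustained) return to a baseline ≥15 bpm higher;
E. transient (≥1 min) return to a baseline ≥10 bpm lower;
F. excessive uterine activity, regardless of FHR changes.

No clinical covariates enter either definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    EPOCH_S,
    InsufficientDataError,
    RecordFeatures,
    UA_WINDOW_S,
    extract_features,
)
from .signal import CTGRecord, EventKind, RuleConfig, TracingAssessment

MEASURE_ASSESS = "assess feasibility of safe vaginal delivery"
MEASURES_UA = (
    "diminish uterine activity (reduce contraction frequency)",
    "decrease oxytocin infusion",
    "diminish or cease pushing",
)
MEASURES_LATE = (
    "modify maternal position",
    "provide supplemental oxygen",
    "support maternal blood pressure",
)


@dataclass
class PointACall:
    time: float
    criteria: list            # fired letters, sorted A..F
    first_criterion: str
    contributing: dict = field(default_factory=dict)  # letter -> trigger time


@dataclass
class PointBCall:
    time: float
    basis: str                # sustained_low_variability_rise | rapid_adverse_change


@dataclass
class PointReport:
    assessment: TracingAssessment
    point_a: PointACall | None
    point_b: PointBCall | None
    measures: list

    def __post_init__(self):
        if self.point_b is not None:
            if self.point_a is None or self.point_a.time > self.point_b.time:
                raise ValueError("Point B requires an equal-or-earlier Point A")

    def to_dict(self) -> dict:
        return {
            "assessment": {"status": self.assessment.status,
                           "reasons": list(self.assessment.reasons)},
            "point_a": None if self.point_a is None else {
                "time_s": self.point_a.time,
                "criteria": list(self.point_a.criteria),
                "first_criterion": self.point_a.first_criterion,
                "contributing": dict(self.point_a.contributing),
            },
            "point_b": None if self.point_b is None else {
                "time_s": self.point_b.time, "basis": self.point_b.basis,
            },
            "measures": list(self.measures),
        }


# ---------------------------------------------------------------------------
# Initial assessment
# ---------------------------------------------------------------------------

def assess_initial(features: RecordFeatures, window_min: float = 20.0) -> TracingAssessment:
    """Classify the tracing at the outset of monitoring as normal/abnormal.

    Normal requires, over the first *window_min* minutes: every baseline
    epoch inside the normal band (110–155 bpm), moderate variability
    (6–25 bpm) in at least 80% of minutes, and no decelerations.  Reasons for
    abnormality follow the baseline / variability / deceleration taxonomy
    (baseline abnormality uses the <100 bpm outset cut, which is deliberately
    distinct from the 110 bpm bradycardia event threshold).
    """
    config = features.config
    if features.record.duration < window_min * 60 - 1e-9:
        raise InsufficientDataError("record shorter than assessment window")
    n_ep = int(window_min)
    reasons = []

    b = features.baseline.baseline[:n_ep]
    valid = features.baseline.epoch_validity[:n_ep]
    lo, hi = config.normal_baseline_bpm
    if (~valid).any() or not np.isfinite(b).all():
        reasons.append("baseline: unstable/indeterminate")
    finite = b[np.isfinite(b)]
    if finite.size:
        if (finite < config.abnormal_low_baseline_bpm).any():
            reasons.append("baseline: <100 bpm")
        elif (finite < lo).any():
            reasons.append("baseline: below normal band (100–110 bpm)")
        if (finite > hi).any():
            reasons.append("baseline: >155 bpm")
        if np.ptp(finite) > 25:
            reasons.append("baseline: unstable/indeterminate")

    amp = features.variability.amplitude[:n_ep]
    vvalid = features.variability.validity[:n_ep]
    ok = vvalid & (amp >= config.decreased_var_bpm) & (amp <= config.increased_var_bpm)
    if vvalid.sum() == 0 or ok.sum() < 0.8 * n_ep:
        if vvalid.any() and np.nanmedian(amp[vvalid]) < config.decreased_var_bpm:
            if np.nanmedian(amp[vvalid]) < 2.0:
                reasons.append("variability: absent")
            else:
                reasons.append("variability: decreased (<6 bpm)")
        elif vvalid.any() and np.nanmedian(amp[vvalid]) > config.increased_var_bpm:
            reasons.append("variability: increased (>25 bpm)")
        else:
            reasons.append("variability: indeterminate")

    window_end = window_min * 60
    timings = sorted({d.timing for d in features.decelerations if d.t_onset < window_end})
    for timing in timings:
        reasons.append(f"decelerations: {timing}")

    status = "normal" if not reasons else "abnormal"
    return TracingAssessment(status=status, reasons=reasons)


# ---------------------------------------------------------------------------
# Point A
# ---------------------------------------------------------------------------

def detect_point_a(features: RecordFeatures, config: RuleConfig | None = None) -> PointACall | None:
    """Evaluate the six Point A criteria and return the earliest trigger.

    All criteria fired anywhere in the record are retained (the measure
    mapping is feature-driven); ties in trigger time break by letter order.
    Criteria B, D and E are evaluated within 10 min of a deceleration, the
    window in which they describe deceleration recovery.
    """
    config = config or features.config
    candidates = []  # (time, letter)

    decel_ends = [d.t_end for d in features.decelerations]

    def post_decel(t0: float) -> bool:
        return any(e <= t0 <= e + 600.0 for e in decel_ends)

    for d in features.decelerations:
        if d.recovery == "delayed_return":
            tt = d.t_end
            if d.associated_contraction is not None and \
                    d.associated_contraction < len(features.contractions):
                tt = min(tt, features.contractions[d.associated_contraction].t_end)
            candidates.append((tt, "A"))
        elif d.recovery == "overshoot":
            candidates.append((d.t_end, "C"))

    var = features.variability
    lo, hi = config.pointA_var_cpm
    for i in range(len(var.epoch_starts)):
        t0 = float(var.epoch_starts[i])
        if not var.validity[i] or not post_decel(t0):
            continue
        if var.amplitude[i] > config.pointA_var_peak_trough_bpm and \
                lo <= var.frequency_cpm[i] <= hi:
            candidates.append((t0 + EPOCH_S, "B"))

    bl = features.baseline
    basal = bl.basal_rate
    if basal is not None:
        decel_ivals = [(d.t_onset, d.t_end) for d in features.decelerations]

        def overlaps_decel(t0, t1):
            return any(a < t1 and b > t0 for a, b in decel_ivals)

        for letter, cond in (
            ("D", bl.epoch_mean - basal >= config.pointA_up_shift_bpm),
            ("E", bl.epoch_mean - basal <= -config.pointA_down_shift_bpm),
        ):
            eligible = np.zeros(len(bl.epoch_starts), dtype=bool)
            for i, t0 in enumerate(bl.epoch_starts):
                if not bl.epoch_validity[i] or overlaps_decel(t0, t0 + EPOCH_S):
                    continue
                eligible[i] = bool(cond[i]) and post_decel(float(t0))
            # maximal runs; transient means >=1 min but not sustained
            i = 0
            while i < len(eligible):
                if eligible[i]:
                    j = i
                    while j < len(eligible) and eligible[j]:
                        j += 1
                    span = (j - i) * EPOCH_S
                    if config.pointA_transient_min_s <= span <= config.sustained_min * 60:
                        candidates.append((float(bl.epoch_starts[i]) +
                                           config.pointA_transient_min_s, letter))
                    i = j
                else:
                    i += 1

    ua = features.ua_stats
    excessive = ua.any_excessive()
    hit = np.flatnonzero(excessive)
    if hit.size:
        candidates.append((float(ua.window_starts[hit[0]] + UA_WINDOW_S), "F"))

    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    contributing = {}
    for tt, letter in candidates:
        contributing.setdefault(letter, tt)
    return PointACall(
        time=candidates[0][0],
        criteria=sorted(contributing),
        first_criterion=candidates[0][1],
        contributing=contributing,
    )


# ---------------------------------------------------------------------------
# Point B
# ---------------------------------------------------------------------------

def detect_point_b(features: RecordFeatures, point_a: PointACall | None,
                   config: RuleConfig | None = None) -> PointBCall | None:
    """Evaluate the two Point B routes and return the earlier trigger.

    Route 1: a sustained (>10 min) post-deceleration run of diminished
    variability (<6 bpm) with the baseline risen at least 10 bpm over its
    pre-deceleration level.  Route 2: a conversion — a wholesale change in
    rate and variability completed within a couple of contractions.  Point B
    presupposes the escalation through Point A; without a Point A no Point B
    is reported.
    """
    config = config or features.config
    if point_a is None:
        return None
    candidates = []

    var = features.variability
    bl = features.baseline
    decel_ends = [d.t_end for d in features.decelerations]
    low = var.validity & (var.amplitude < config.decreased_var_bpm)
    min_epochs = int(config.sustained_min) + 1
    i = 0
    while i < len(low):
        if low[i]:
            j = i
            while j < len(low) and low[j]:
                j += 1
            run_start = float(var.epoch_starts[i])
            if j - i >= min_epochs and any(e <= run_start <= e + 600 for e in decel_ends):
                pre = [
                    bl.epoch_mean[k] for k, t0 in enumerate(bl.epoch_starts)
                    if run_start - 600 <= t0 < run_start - 120 and bl.epoch_validity[k]
                ]
                during = bl.baseline[i:j]
                during = during[np.isfinite(during)]
                if pre and during.size and \
                        np.mean(during) >= np.median(pre) + config.pointA_down_shift_bpm:
                    candidates.append((run_start + config.sustained_min * 60,
                                       "sustained_low_variability_rise"))
            i = j
        else:
            i += 1

    for ev in features.special_events:
        if ev.kind is EventKind.CONVERSION:
            candidates.append((ev.t_end, "rapid_adverse_change"))

    candidates = [c for c in candidates if c[0] >= point_a.time]
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    return PointBCall(time=candidates[0][0], basis=candidates[0][1])


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------

def recommend_measures(point_a: PointACall | None, features: RecordFeatures) -> list:
    """Map the fired Point A criteria to conservative measures (unranked).

    Excessive uterine activity directs toward reducing uterine activity;
    late decelerations toward maternal position, oxygen and blood-pressure
    support; assessing the feasibility of safe vaginal delivery is always
    included.
    """
    if point_a is None:
        raise ValueError("recommend_measures requires a detected Point A")
    measures = []
    if "F" in point_a.criteria:
        measures.extend(MEASURES_UA)
    if any(d.timing == "late" for d in features.decelerations):
        measures.extend(MEASURES_LATE)
    measures.append(MEASURE_ASSESS)
    return measures


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def analyze_record(record: CTGRecord, config: RuleConfig | None = None) -> PointReport:
    """Full pipeline: cleaning → features → assessment → points → measures."""
    config = config or RuleConfig()
    features = extract_features(record, config)
    assessment = assess_initial(features)
    point_a = detect_point_a(features, config)
    point_b = detect_point_b(features, point_a, config)
    measures = recommend_measures(point_a, features) if point_a else []
    return PointReport(assessment=assessment, point_a=point_a,
                       point_b=point_b, measures=measures)
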