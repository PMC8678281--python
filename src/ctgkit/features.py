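"""Deterministic extraction of CTG patterns from a record.

The extractors work on one-minute epochs and physical seconds, never sample
counts, so any sampling rate works.  The overall flow is::

    clean FHR -> baseline estimate -> variability series
              -> decelerations (+ recovery morphology)
              -> baseline-rate events, variability events, special patterns
    UC trace  -> contraction peaks -> sliding-window uterine-activity stats

Everything is a pure function of (signals, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy.stats import trim_mean

from .signal import (
    CTGRecord,
    EventKind,
    EventLabel,
    FHRSeries,
    RuleConfig,
    UCMode,
    UCSeries,
    clean_fhr,
)

EPOCH_S = 60.0  # epoch length for baseline/variability estimates
UA_WINDOW_S = 600.0  # Table-style sliding uterine-activity window
UA_STEP_S = 60.0


class InsufficientDataError(ValueError):
    """Raised when a record is too short for the requested analysis."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BaselineEstimate:
    """Per-epoch FHR baseline.

    ``epoch_mean`` is the raw per-minute trimmed mean (used for transient
    baseline-shift detection); ``baseline`` is the outlier-excluded, filled
    estimate (used for sustained tachy-/bradycardia and assessment).
    """

    basal_rate: float | None
    epoch_starts: np.ndarray
    epoch_mean: np.ndarray
    baseline: np.ndarray
    epoch_validity: np.ndarray


@dataclass
class VariabilitySeries:
    """Per-minute variability amplitude (bpm peak-to-trough, robust 5–95
    percentile range of the detrended trace) and dominant cycle frequency
    (zero crossings / 2, in cycles per minute)."""

    epoch_starts: np.ndarray
    amplitude: np.ndarray
    frequency_cpm: np.ndarray
    flatness: np.ndarray
    validity: np.ndarray


@dataclass
class Deceleration:
    """A detected FHR deceleration with timing and recovery morphology."""

    t_onset: float
    t_nadir: float
    t_end: float
    depth: float
    recovery: str = "unresolved"  # normal|overshoot|delayed_return|peaked_return|unresolved
    timing: str = "undefined"     # early|late|variable|undefined
    associated_contraction: int | None = None


@dataclass
class ContractionStats:
    """Sliding 10-min-window uterine-activity statistics and excess flags."""

    window_starts: np.ndarray
    frequency: np.ndarray
    mean_duration_s: np.ndarray
    resting_tone: np.ndarray
    min_interval_s: np.ndarray
    rest_time_fraction: np.ndarray
    flags: dict               # name -> bool array per window
    indeterminate: np.ndarray
    peak_times: np.ndarray
    durations: np.ndarray
    mode: UCMode

    def any_excessive(self) -> np.ndarray:
        out = np.zeros(len(self.window_starts), dtype=bool)
        for arr in self.flags.values():
            out |= arr
        return out & ~self.indeterminate


@dataclass
class RecordFeatures:
    """Everything the intervention-point engine consumes."""

    record: CTGRecord
    config: RuleConfig
    fhr: FHRSeries                      # cleaned
    baseline: BaselineEstimate
    variability: VariabilitySeries
    decelerations: list
    contractions: list                  # contraction EventLabels
    rate_events: list
    variability_events: list
    special_events: list
    ua_stats: ContractionStats

    def all_events(self) -> list:
        out = list(self.contractions)
        out += self.rate_events + self.variability_events + self.special_events
        for d in self.decelerations:
            out.append(
                EventLabel(
                    kind=EventKind.DECELERATION,
                    t_start=d.t_onset,
                    t_end=d.t_end,
                    attributes={
                        "depth_bpm": d.depth,
                        "t_nadir": d.t_nadir,
                        "recovery": d.recovery,
                        "timing": d.timing,
                    },
                )
            )
        return sorted(out, key=lambda e: e.t_start)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def _epoch_slices(n: int, fs: float, epoch_s: float = EPOCH_S):
    per = int(round(epoch_s * fs))
    n_ep = n // per
    return per, n_ep


def _epoch_stats(fhr: FHRSeries, config: RuleConfig):
    """Per-epoch trimmed mean, robust range, and validity."""
    per, n_ep = _epoch_slices(fhr.n, fhr.fs)
    means = np.full(n_ep, np.nan)
    ranges = np.full(n_ep, np.nan)
    valid = np.zeros(n_ep, dtype=bool)
    for i in range(n_ep):
        seg = fhr.values[i * per:(i + 1) * per]
        q = fhr.quality[i * per:(i + 1) * per]
        if q.mean() >= 1 - config.max_invalid_fraction:
            v = seg[q]
            means[i] = trim_mean(v, 0.25)
            ranges[i] = np.percentile(v, 95) - np.percentile(v, 5)
            valid[i] = True
    starts = fhr.start_time + np.arange(n_ep) * EPOCH_S
    return starts, means, ranges, valid


def estimate_basal_rate(fhr: FHRSeries, window_min: float = 20.0,
                        config: RuleConfig | None = None) -> float | None:
    """Basal rate: the individual baseline at the start of monitoring.

    Uses the most stable (lowest robust per-minute range) half of the valid
    epochs in the first *window_min* minutes, which excludes epochs disturbed
    by decelerations or accelerations, and returns the median of their
    trimmed means.  Returns ``None`` (indeterminate) when more than 20% of
    the window is invalid.
    """
    config = config or RuleConfig()
    if fhr.duration < window_min * 60 - 1e-9:
        raise InsufficientDataError(
            f"record ({fhr.duration:.0f} s) shorter than basal-rate window")
    per = int(round(window_min * 60 * fhr.fs))
    head = FHRSeries(fhr.start_time, fhr.fs, fhr.values[:per], fhr.quality[:per])
    if head.quality.mean() < 1 - config.max_invalid_fraction:
        return None
    _, means, ranges, valid = _epoch_stats(head, config)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return None
    order = idx[np.argsort(ranges[idx], kind="stable")]
    keep = order[:max(1, len(idx) // 2)]
    return float(np.median(means[keep]))


def estimate_baseline(fhr: FHRSeries, config: RuleConfig | None = None) -> BaselineEstimate:
    """Iterative per-minute baseline estimate.

    (1) per-minute 25%-trimmed mean; (2) exclude minutes deviating more than
    15 bpm from the rolling 10-min median; (3) fill excluded minutes from the
    nearest retained minute; iterate to convergence (at most 5 passes).
    """
    config = config or RuleConfig()
    starts, means, _, valid = _epoch_stats(fhr, config)
    n_ep = len(starts)
    if n_ep == 0:
        raise InsufficientDataError("record shorter than one epoch")

    filled = means.copy()
    # seed invalid epochs from nearest valid neighbour
    if valid.any() and not valid.all():
        vi = np.flatnonzero(valid)
        nearest = vi[np.argmin(np.abs(np.arange(n_ep)[:, None] - vi[None, :]), axis=1)]
        filled[~valid] = means[nearest[~valid]]
    elif not valid.any():
        filled[:] = np.nan

    retained = valid.copy()
    half = 5  # 10-min centered median window
    for _ in range(5):
        rolmed = np.array([
            np.nanmedian(filled[max(0, i - half):i + half + 1]) for i in range(n_ep)
        ])
        new_retained = valid & (np.abs(means - rolmed) <= 15.0)
        if new_retained.sum() == 0:
            break
        vi = np.flatnonzero(new_retained)
        nearest = vi[np.argmin(np.abs(np.arange(n_ep)[:, None] - vi[None, :]), axis=1)]
        new_filled = np.where(new_retained, means, means[nearest])
        if np.array_equal(new_retained, retained) and np.allclose(
                new_filled, filled, equal_nan=True):
            break
        retained, filled = new_retained, new_filled

    try:
        basal = estimate_basal_rate(fhr, config=config) if fhr.duration >= 1200 else None
    except InsufficientDataError:
        basal = None
    return BaselineEstimate(
        basal_rate=basal,
        epoch_starts=starts,
        epoch_mean=means,
        baseline=filled,
        epoch_validity=valid,
    )


def _interp_baseline(baseline: BaselineEstimate, times: np.ndarray) -> np.ndarray:
    mids = baseline.epoch_starts + EPOCH_S / 2
    ok = np.isfinite(baseline.baseline)
    if not ok.any():
        return np.full_like(times, np.nan)
    return np.interp(times, mids[ok], baseline.baseline[ok])


# ---------------------------------------------------------------------------
# Variability
# ---------------------------------------------------------------------------

def _spectral_flatness_inband(x: np.ndarray, fs: float,
                              band=(0.03, 0.5)) -> float:
    """Geometric/arithmetic PSD mean ratio over the variability band only.

    Restricting to in-band bins is essential: out-of-band bins carry near-zero
    power for every band-limited signal and would drive the geometric mean to
    zero regardless of in-band structure.  A regular oscillation concentrates
    power in few bins (flatness near 0); pseudorandom band-limited variability
    spreads it (flatness near the white-noise value ~0.56 for raw periodogram
    bins).
    """
    f, p = scipy.signal.periodogram(x, fs=fs, detrend="constant")
    sel = (f >= band[0]) & (f <= band[1])
    p = p[sel]
    if p.size == 0 or p.sum() <= 0:
        return 1.0
    p = p + 1e-12 * p.max()
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def compute_variability(fhr: FHRSeries, baseline: BaselineEstimate,
                        config: RuleConfig | None = None) -> VariabilitySeries:
    """Per-minute peak-to-trough amplitude and dominant cycle frequency.

    The trace is detrended against the interpolated baseline; samples inside
    decelerations (detrended below the deceleration floor) are excluded so a
    deep dip does not masquerade as high variability.
    """
    config = config or RuleConfig()
    times = fhr.times()
    det = fhr.values - _interp_baseline(baseline, times)
    include = fhr.quality & (det > -config.decel_floor_bpm)
    # cycle counting uses a 1-s smoothed copy: broadband measurement noise
    # above the physiological variability band would otherwise inflate the
    # zero-crossing rate
    det_smooth = _smooth(det, fhr.fs, span_s=1.0)

    per, n_ep = _epoch_slices(fhr.n, fhr.fs)

    # zero crossings are located globally, then binned by crossing time, so
    # a crossing straddling an epoch boundary is never lost
    kept = np.flatnonzero(include & (np.abs(det_smooth) > 1e-12))
    cross_count = np.zeros(n_ep)
    if kept.size >= 2:
        s = np.sign(det_smooth[kept])
        flips = np.flatnonzero(np.diff(s) != 0)
        cross_idx = 0.5 * (kept[flips] + kept[flips + 1])
        for ci in cross_idx:
            ep = int(ci // per)
            if ep < n_ep:
                cross_count[ep] += 1

    amp = np.full(n_ep, np.nan)
    freq = np.full(n_ep, np.nan)
    flat = np.full(n_ep, np.nan)
    valid = np.zeros(n_ep, dtype=bool)
    for i in range(n_ep):
        sl = slice(i * per, (i + 1) * per)
        m = include[sl]
        if m.mean() < 1 - config.max_invalid_fraction:
            continue
        x = det[sl][m]
        amp[i] = np.percentile(x, 95) - np.percentile(x, 5)
        freq[i] = cross_count[i] / 2.0
        flat[i] = _spectral_flatness_inband(x, fhr.fs)
        valid[i] = True
    starts = fhr.start_time + np.arange(n_ep) * EPOCH_S
    return VariabilitySeries(starts, amp, freq, flat, valid)


# ---------------------------------------------------------------------------
# Run helpers
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """Maximal runs of True as (start_idx, stop_idx) half-open pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Baseline-rate and variability events
# ---------------------------------------------------------------------------

def classify_rate(baseline: BaselineEstimate, config: RuleConfig | None = None) -> list:
    """Tachy-/bradycardia events: sustained (>10 min) runs of baseline epochs
    beyond the absolute thresholds, or shifted >15 bpm from the basal rate
    (relative).  Absolute and relative events may coexist.  With an
    indeterminate basal rate only absolute events are emitted.
    """
    config = config or RuleConfig()
    b = baseline.baseline
    basal = baseline.basal_rate
    conditions = [
        (EventKind.TACHYCARDIA_ABSOLUTE, b > config.tachy_abs_bpm),
        (EventKind.BRADYCARDIA_ABSOLUTE, b < config.brady_abs_bpm),
    ]
    if basal is not None:
        conditions += [
            (EventKind.TACHYCARDIA_RELATIVE, b > basal + config.relative_shift_bpm),
            (EventKind.BRADYCARDIA_RELATIVE, b < basal - config.relative_shift_bpm),
        ]
    min_epochs = int(config.sustained_min) + 1  # strictly > sustained_min
    events = []
    for kind, mask in conditions:
        mask = mask & np.isfinite(b)
        for i, j in _runs(mask):
            if j - i >= min_epochs:
                events.append(EventLabel(
                    kind=kind,
                    t_start=float(baseline.epoch_starts[i]),
                    t_end=float(baseline.epoch_starts[j - 1] + EPOCH_S),
                    attributes={"mean_bpm": float(np.nanmean(b[i:j]))},
                ))
    return sorted(events, key=lambda e: e.t_start)


def classify_variability(var: VariabilitySeries, config: RuleConfig | None = None) -> list:
    """Decreased (<6 bpm, persistent) and increased (>25 bpm, persistent or
    transient) variability events."""
    config = config or RuleConfig()
    min_epochs = int(config.sustained_min)
    events = []
    dec = var.validity & (var.amplitude < config.decreased_var_bpm)
    for i, j in _runs(dec):
        if j - i >= min_epochs:
            events.append(EventLabel(
                kind=EventKind.DECREASED_VARIABILITY,
                t_start=float(var.epoch_starts[i]),
                t_end=float(var.epoch_starts[j - 1] + EPOCH_S),
                attributes={"mean_amplitude_bpm": float(np.nanmean(var.amplitude[i:j]))},
            ))
    inc = var.validity & (var.amplitude > config.increased_var_bpm)
    for i, j in _runs(inc):
        events.append(EventLabel(
            kind=EventKind.INCREASED_VARIABILITY,
            t_start=float(var.epoch_starts[i]),
            t_end=float(var.epoch_starts[j - 1] + EPOCH_S),
            attributes={
                "mean_amplitude_bpm": float(np.nanmean(var.amplitude[i:j])),
                "transient": bool(j - i < min_epochs),
            },
        ))
    return sorted(events, key=lambda e: e.t_start)


# ---------------------------------------------------------------------------
# Decelerations
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, fs: float, span_s: float = 2.5) -> np.ndarray:
    w = max(1, int(round(span_s * fs)))
    w += 1 - w % 2  # odd window: no half-sample phase shift
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _contraction_peaks(uc_events) -> np.ndarray:
    return np.array([
        e.attributes.get("peak_time", 0.5 * (e.t_start + e.t_end))
        for e in uc_events if e.kind is EventKind.CONTRACTION
    ])


def detect_decelerations(fhr: FHRSeries, baseline: BaselineEstimate,
                         uc_events, config: RuleConfig | None = None) -> list:
    """Detect decelerations and classify their timing against contractions.

    An episode is a maximal interval where the (lightly smoothed) detrended
    FHR stays below −15 bpm for at least 15 s, extended outward to the −5 bpm
    crossings.  Timing follows the nadir-to-contraction-peak lag: variable
    (coincident, steep onset), late (nadir 20–90 s after the peak), early
    (coincident, gradual), undefined otherwise or without a contraction
    within 120 s.
    """
    config = config or RuleConfig()
    times = fhr.times()

    def _episodes(sm):
        """Deep episodes on a smoothed detrended trace, extended to the
        −5 bpm crossings; brief (≤3 s) noise gaps inside an episode are
        tolerated."""
        deep_runs = _runs(sm < -config.decel_floor_bpm)
        gap_n = int(round(3.0 * fhr.fs))
        merged = []
        for i, j in deep_runs:
            if merged and i - merged[-1][1] <= gap_n:
                merged[-1] = (merged[-1][0], j)
            else:
                merged.append((i, j))
        min_n = int(round(config.decel_min_duration_s * fhr.fs))
        edge = -config.decel_edge_bpm
        out = []
        for i, j in merged:
            if j - i < min_n:
                continue
            a = i
            while a > 0 and sm[a - 1] < edge:
                a -= 1
            b = j
            while b < len(sm) and sm[b] < edge:
                b += 1
            if out and a <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], b))
            else:
                out.append((a, b))
        return out

    det = np.where(fhr.quality, fhr.values - _interp_baseline(baseline, times), 0.0)
    sm = _smooth(det, fhr.fs)
    intervals = _episodes(sm)

    # Second pass: a deceleration that fills most of a minute drags that
    # epoch's trimmed mean down with it, muting the dip.  Mark candidate
    # dips with a lighter threshold (−10 bpm, extended to −5), recompute the
    # affected epochs' baseline from their clean samples only, and re-detect
    # against the refined baseline.
    candidate = []
    edge = -config.decel_edge_bpm
    for i, j in _runs(sm < -10.0):
        a = i
        while a > 0 and sm[a - 1] < edge:
            a -= 1
        b = j
        while b < len(sm) and sm[b] < edge:
            b += 1
        candidate.append((a, b))
    if candidate:
        contaminated = np.zeros(fhr.n, dtype=bool)
        for a, b in candidate:
            contaminated[a:b] = True
        per = int(round(EPOCH_S * fhr.fs))
        refined = baseline.baseline.copy()
        for i in range(len(refined)):
            sl = slice(i * per, (i + 1) * per)
            clean = fhr.quality[sl] & ~contaminated[sl]
            if contaminated[sl].any() and clean.mean() >= 0.25:
                refined[i] = trim_mean(fhr.values[sl][clean], 0.25)
        mids = baseline.epoch_starts + EPOCH_S / 2
        ok = np.isfinite(refined)
        base2 = np.interp(times, mids[ok], refined[ok]) if ok.any() else np.full_like(times, np.nan)
        sm = _smooth(np.where(fhr.quality, fhr.values - base2, 0.0), fhr.fs)
        intervals = _episodes(sm)

    peaks = _contraction_peaks(uc_events)
    peak_ends = np.array([
        e.t_end for e in uc_events if e.kind is EventKind.CONTRACTION
    ])

    decels = []
    for a, b in intervals:
        seg = sm[a:b]
        k = int(np.argmin(seg))
        t_onset = float(times[a])
        t_nadir = float(times[a + k])
        t_end = float(times[min(b, len(times) - 1)])
        depth = float(-seg[k])

        timing, assoc = "undefined", None
        if peaks.size:
            ci = int(np.argmin(np.abs(peaks - t_nadir)))
            lag = t_nadir - peaks[ci]
            if abs(lag) <= 120:
                assoc = ci
                slope = depth / max(t_nadir - t_onset, 1e-9)
                if abs(lag) <= 15 and slope >= 3.0:
                    timing = "variable"
                elif 20 <= lag <= 90:
                    timing = "late"
                elif abs(lag) <= 15:
                    timing = "early"
        decels.append(Deceleration(
            t_onset=t_onset, t_nadir=t_nadir, t_end=t_end, depth=depth,
            timing=timing, associated_contraction=assoc,
        ))
    return decels


def classify_recovery(decel: Deceleration, fhr: FHRSeries,
                      baseline: BaselineEstimate, uc_events,
                      config: RuleConfig | None = None,
                      all_decels=None) -> str:
    """Classify a deceleration's recovery morphology.

    Precedence: peaked_return > overshoot > delayed_return > normal; a
    deceleration truncated by the record end is unresolved.
    """
    config = config or RuleConfig()
    times = fhr.times()
    t_last = times[-1]

    # All recovery tests reference the pre-deceleration epoch level, not the
    # running baseline estimate: a long recovery tail (or a post-recovery
    # acceleration) partially drags the per-minute trimmed mean with it, which
    # would mute the very excursions being classified.
    pre_epochs = [
        baseline.epoch_mean[k]
        for k, t0 in enumerate(baseline.epoch_starts)
        if t0 + EPOCH_S <= decel.t_onset and baseline.epoch_validity[k]
    ]
    if pre_epochs:
        ref = float(np.median(pre_epochs[-3:]))
    else:
        b = baseline.baseline[np.isfinite(baseline.baseline)]
        ref = float(np.median(b)) if b.size else float(np.median(fhr.values))
    exc = _smooth(np.where(fhr.quality, fhr.values, ref), fhr.fs) - ref

    if decel.t_end >= t_last - 1.5 / fhr.fs and exc[-1] < -config.decel_edge_bpm:
        return "unresolved"

    # peaked return: a narrow >=10 bpm spike at the end of the deceleration
    # followed by another (late) deceleration within 120 s
    spike_win = (times >= decel.t_end - 10) & (times <= decel.t_end + 12)
    spike = False
    if spike_win.any():
        seg, segt = exc[spike_win], times[spike_win]
        if seg.max() >= 10.0:
            for i, j in _runs(seg > 5.0):
                if seg[i:j].max() >= 10.0 and (segt[j - 1] - segt[i]) <= 12.0:
                    spike = True
    if spike and all_decels is not None:
        for d in all_decels:
            if decel.t_end < d.t_onset <= decel.t_end + 120:
                return "peaked_return"

    # overshoot: accelerative excursion above +10 bpm starting within 30 s of
    # recovery and spanning at least the configured minimum; brief sub-
    # threshold dips (<=5 s) within the excursion are tolerated
    post = (times >= decel.t_end) & (times <= decel.t_end + 120)
    if post.any():
        seg, segt = exc[post], times[post]
        merged = []
        for i, j in _runs(seg > 10.0):
            if merged and segt[i] - segt[merged[-1][1] - 1] <= 5.0:
                merged[-1] = (merged[-1][0], j)
            else:
                merged.append((i, j))
        for i, j in merged:
            if segt[i] <= decel.t_end + 30 and segt[j - 1] - segt[i] >= config.pointA_overshoot_min_s:
                return "overshoot"

    # delayed return: the return to within 5 bpm of the previously normal
    # baseline happens only after the associated contraction has ended, or
    # takes more than 60 s from the nadir
    t_return = decel.t_end
    after = times > decel.t_nadir
    recovered = after & (exc >= -config.decel_edge_bpm)
    hold = int(round(5 * fhr.fs))  # noise blips do not count as recovery
    for k in np.flatnonzero(recovered):
        j = k
        while j < len(exc) and exc[j] >= -config.decel_edge_bpm:
            j += 1
        if j - k >= hold or j == len(exc):
            t_return = float(times[k])
            break
    if decel.associated_contraction is not None:
        c_ends = [e.t_end for e in uc_events if e.kind is EventKind.CONTRACTION]
        if decel.associated_contraction < len(c_ends):
            if t_return > c_ends[decel.associated_contraction]:
                return "delayed_return"
    if t_return - decel.t_nadir > 60.0:
        return "delayed_return"
    return "normal"


# ---------------------------------------------------------------------------
# Special patterns
# ---------------------------------------------------------------------------

def _checkmark_template(fs: float, rise_s: float = 2.0, decay_s: float = 8.0) -> np.ndarray:
    n_r = max(2, int(round(rise_s * fs)))
    n_d = max(2, int(round(decay_s * fs)))
    rise = np.linspace(0.0, 1.0, n_r, endpoint=False)
    decay = np.exp(-np.arange(n_d) / (decay_s * fs / 3.0))
    return np.concatenate([rise, decay])


def detect_special_patterns(fhr: FHRSeries, baseline: BaselineEstimate,
                            var: VariabilitySeries, uc_events,
                            config: RuleConfig | None = None) -> list:
    """Sinusoidal, sawtooth, checkmark, and conversion patterns.

    Sinusoidal and sawtooth require both the cycle-frequency/amplitude bands
    and spectral regularity (low in-band flatness) so that pseudorandom
    band-limited variability is never mistaken for a regular oscillation.
    """
    config = config or RuleConfig()
    events = []
    flat_thresh = 0.25

    sin_ok = (
        var.validity
        & (var.frequency_cpm >= config.sinusoidal_cpm[0])
        & (var.frequency_cpm <= config.sinusoidal_cpm[1])
        & (var.amplitude >= 5.0) & (var.amplitude <= 15.0)
        & (var.flatness < flat_thresh)
    )
    for i, j in _runs(sin_ok):
        if j - i >= 3:
            events.append(EventLabel(
                kind=EventKind.SINUSOIDAL,
                t_start=float(var.epoch_starts[i]),
                t_end=float(var.epoch_starts[j - 1] + EPOCH_S),
                attributes={"mean_cpm": float(np.nanmean(var.frequency_cpm[i:j]))},
            ))

    saw_ok = (
        var.validity
        & (var.frequency_cpm >= config.sawtooth_min_cpm)
        & (var.amplitude < config.sawtooth_max_amp_bpm)
        & (var.amplitude >= 2.0)
        & (var.flatness < flat_thresh)
    )
    for i, j in _runs(saw_ok):
        if j - i >= 2:
            events.append(EventLabel(
                kind=EventKind.SAWTOOTH,
                t_start=float(var.epoch_starts[i]),
                t_end=float(var.epoch_starts[j - 1] + EPOCH_S),
                attributes={"mean_cpm": float(np.nanmean(var.frequency_cpm[i:j]))},
            ))

    # checkmark: matched-filter correlation against the asymmetric
    # rise/decay template, recurring at least three times
    times = fhr.times()
    det = fhr.values - _interp_baseline(baseline, times)
    det = np.where(fhr.quality, det, 0.0)
    sm = _smooth(det, fhr.fs, span_s=1.0)
    template = _checkmark_template(fhr.fs)
    tz = (template - template.mean())
    tnorm = np.sqrt((tz ** 2).sum())
    pk_idx, _ = scipy.signal.find_peaks(sm, height=10.0, prominence=8.0,
                                        distance=int(10 * fhr.fs))
    match_times = []
    lead = int(round(2.0 * fhr.fs))  # template peak position
    for p in pk_idx:
        a = p - lead
        b = a + len(template)
        if a < 0 or b > len(sm):
            continue
        seg = sm[a:b]
        sz = seg - seg.mean()
        denom = np.sqrt((sz ** 2).sum()) * tnorm
        if denom <= 0:
            continue
        if float((sz * tz).sum() / denom) >= 0.8:
            match_times.append(times[p])
    if len(match_times) >= 3:
        gaps = np.diff(match_times)
        ok = gaps <= 130.0  # recurrence at roughly 0.5–2 per minute
        for i, j in _runs(ok):
            if j - i >= 2:  # >=3 consecutive matches
                events.append(EventLabel(
                    kind=EventKind.CHECKMARK,
                    t_start=float(match_times[i] - 5.0) if match_times[i] >= 5 else 0.0,
                    t_end=float(match_times[j] + 10.0),
                    attributes={"n_matches": int(j - i + 1)},
                ))

    events += _detect_conversion(baseline, var, uc_events, config)
    return sorted(events, key=lambda e: e.t_start)


def _var_class(amp: float, config: RuleConfig) -> int:
    if not np.isfinite(amp):
        return -1
    if amp < config.decreased_var_bpm:
        return 0
    if amp > config.increased_var_bpm:
        return 2
    return 1


def _detect_conversion(baseline: BaselineEstimate, var: VariabilitySeries,
                       uc_events, config: RuleConfig) -> list:
    """Conversion: a wholesale step (>=15 bpm) in baseline together with a
    variability-class change, completed within at most two contraction
    intervals."""
    b = baseline.baseline
    n = len(b)
    if n < 12:
        return []
    peaks = _contraction_peaks(uc_events)
    median_interval = float(np.median(np.diff(peaks))) if peaks.size >= 2 else 180.0
    max_span_s = config.conversion_max_contractions * median_interval + EPOCH_S

    pre_w, post_w = 5, 5
    cand = np.zeros(n, dtype=bool)
    delta = np.zeros(n)
    for m in range(pre_w, n - post_w):
        pre = np.nanmedian(b[m - pre_w:m])
        post = np.nanmedian(b[m + 1:m + 1 + post_w])
        delta[m] = post - pre
        if abs(delta[m]) >= 15.0:
            pre_cls = [
                _var_class(a, config) for a in var.amplitude[m - pre_w:m]
            ]
            post_cls = [
                _var_class(a, config) for a in var.amplitude[m + 1:m + 1 + post_w]
            ]
            pre_mode = max(set(pre_cls), key=pre_cls.count)
            post_mode = max(set(post_cls), key=post_cls.count)
            if pre_mode != post_mode and pre_mode >= 0 and post_mode >= 0:
                cand[m] = True

    events = []
    for i, j in _runs(cand):
        span = (j - i) * EPOCH_S
        if span <= max_span_s:
            events.append(EventLabel(
                kind=EventKind.CONVERSION,
                t_start=float(baseline.epoch_starts[i]),
                t_end=float(baseline.epoch_starts[j - 1] + 2 * EPOCH_S),
                attributes={"delta_bpm": float(delta[i:j].mean())},
            ))
    return events


# ---------------------------------------------------------------------------
# Uterine activity
# ---------------------------------------------------------------------------

def ua_window_flags(peak_times: np.ndarray, durations: np.ndarray,
                    resting_tone: np.ndarray | float,
                    rest_fraction: np.ndarray,
                    window_starts: np.ndarray,
                    config: RuleConfig, mode: UCMode,
                    window_s: float = UA_WINDOW_S) -> dict:
    """Evaluate the five excessive-uterine-activity predicates per window.

    Shared by the signal-side analyzer and the label-side (ground-truth)
    evaluation so that both apply identical semantics:

    - frequency: more than 5 contractions per 10-min window, persisting over
      ``ua_freq_windows`` consecutive windows (the doubling requirement);
    - duration: mean contraction duration in the window above 90 s;
    - resting tone above 20 mmHg (intrauterine pressure mode only);
    - minimum inter-peak interval below 120 s;
    - rest time below 50% of the window.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    durations = np.asarray(durations, dtype=float)
    nw = len(window_starts)
    tone = np.broadcast_to(np.asarray(resting_tone, dtype=float), (nw,))

    counts = np.zeros(nw, dtype=int)
    mean_dur = np.zeros(nw)
    min_int = np.full(nw, np.inf)
    for w, t0 in enumerate(window_starts):
        sel = (peak_times >= t0) & (peak_times < t0 + window_s)
        counts[w] = sel.sum()
        if sel.any():
            mean_dur[w] = durations[sel].mean()
        pk = peak_times[sel]
        if pk.size >= 2:
            min_int[w] = np.diff(pk).min()

    over = counts > config.ua_freq_excessive
    k = max(1, int(config.ua_freq_windows))
    freq_flag = over.copy()
    for back in range(1, k):
        shifted = np.concatenate([np.zeros(back, dtype=bool), over[:-back]]) if back < nw else np.zeros(nw, dtype=bool)
        freq_flag &= shifted

    flags = {
        "frequency": freq_flag,
        "duration": mean_dur > config.ua_duration_excessive_s,
        "resting_tone": (tone > config.ua_resting_tone_mmHg)
                        if mode is UCMode.INTRAUTERINE_MMHG
                        else np.zeros(nw, dtype=bool),
        "interval": min_int < config.ua_interval_excessive_s,
        "rest_time": np.asarray(rest_fraction) < config.ua_rest_time_fraction,
    }
    return flags


def label_rest_fraction(contractions, window_starts: np.ndarray,
                        window_s: float = UA_WINDOW_S) -> np.ndarray:
    """Fraction of each window not covered by contraction intervals."""
    ivals = [(e.t_start, e.t_end) for e in contractions
             if e.kind is EventKind.CONTRACTION]
    out = np.ones(len(window_starts))
    for w, t0 in enumerate(window_starts):
        t1 = t0 + window_s
        covered = sum(max(0.0, min(b, t1) - max(a, t0)) for a, b in ivals)
        out[w] = 1.0 - covered / window_s
    return out


def analyze_uterine_activity(uc: UCSeries, config: RuleConfig | None = None) -> ContractionStats:
    """Detect contractions and compute sliding-window activity statistics.

    Contraction peaks are found by prominence (≥15 units above the resting
    tone); onset/offset at the 10%-of-amplitude crossings define duration.
    Per sliding 10-min window (1-min step): frequency, mean duration,
    resting tone (5th percentile), minimum inter-peak interval, and rest-time
    fraction (samples within 5 units of the resting tone), plus the
    per-criterion excess flags.
    """
    config = config or RuleConfig()
    fs = uc.fs
    x = uc.values
    t = uc.times()
    dur_total = uc.duration
    finite = np.isfinite(x)
    xs = np.where(finite, x, 0.0)

    global_tone = float(np.percentile(xs[finite], 5)) if finite.any() else 0.0
    pk_idx, props = scipy.signal.find_peaks(
        _smooth(xs, fs, span_s=4.0), prominence=15.0, distance=int(30 * fs))
    peak_times, durations = [], []
    sm = _smooth(xs, fs, span_s=4.0)
    for p in pk_idx:
        amp = sm[p] - global_tone
        if amp <= 0:
            continue
        thr = global_tone + 0.1 * amp
        a = p
        while a > 0 and sm[a - 1] > thr:
            a -= 1
        b = p
        while b < len(sm) - 1 and sm[b + 1] > thr:
            b += 1
        peak_times.append(t[p])
        durations.append((b - a + 1) / fs)
    peak_times = np.array(peak_times)
    durations = np.array(durations)

    if dur_total < UA_WINDOW_S:
        window_starts = np.array([0.0])
    else:
        window_starts = np.arange(0.0, dur_total - UA_WINDOW_S + 1e-9, UA_STEP_S)

    nw = len(window_starts)
    frequency = np.zeros(nw)
    mean_dur = np.zeros(nw)
    tone = np.zeros(nw)
    min_int = np.full(nw, np.inf)
    rest = np.zeros(nw)
    indet = np.zeros(nw, dtype=bool)
    for w, t0 in enumerate(window_starts):
        sel = (t >= t0) & (t < t0 + UA_WINDOW_S)
        seg = x[sel]
        fin = np.isfinite(seg)
        if fin.mean() < 1 - config.max_invalid_fraction:
            indet[w] = True
            tone[w] = np.nan
            rest[w] = np.nan
            continue
        tone[w] = float(np.percentile(seg[fin], 5))
        rest[w] = float(np.mean(seg[fin] <= tone[w] + 5.0))
        psel = (peak_times >= t0) & (peak_times < t0 + UA_WINDOW_S)
        frequency[w] = psel.sum()
        if psel.any():
            mean_dur[w] = durations[psel].mean()
        pk = peak_times[psel]
        if pk.size >= 2:
            min_int[w] = float(np.diff(pk).min())

    flags = ua_window_flags(peak_times, durations, tone, rest,
                            window_starts, config, uc.mode)
    for name in flags:
        flags[name] = flags[name] & ~indet

    return ContractionStats(
        window_starts=window_starts,
        frequency=frequency,
        mean_duration_s=mean_dur,
        resting_tone=tone,
        min_interval_s=min_int,
        rest_time_fraction=rest,
        flags=flags,
        indeterminate=indet,
        peak_times=peak_times,
        durations=durations,
        mode=uc.mode,
    )


def contraction_events_from_stats(stats: ContractionStats) -> list:
    """Contraction EventLabels (onset→offset at 10% amplitude) from detected
    peaks."""
    out = []
    for pt, d in zip(stats.peak_times, stats.durations):
        t0 = max(0.0, pt - d / 2)
        out.append(EventLabel(
            kind=EventKind.CONTRACTION, t_start=t0, t_end=pt + d / 2,
            attributes={"peak_time": float(pt), "duration_s": float(d)},
        ))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def extract_features(record: CTGRecord, config: RuleConfig | None = None) -> RecordFeatures:
    """Run the full feature-extraction chain on a record."""
    config = config or RuleConfig()
    fhr = clean_fhr(record.fhr)
    baseline = estimate_baseline(fhr, config)
    variability = compute_variability(fhr, baseline, config)
    ua_stats = analyze_uterine_activity(record.uc, config)
    contractions = contraction_events_from_stats(ua_stats)
    decels = detect_decelerations(fhr, baseline, contractions, config)
    for d in decels:
        d.recovery = classify_recovery(d, fhr, baseline, contractions, config,
                                       all_decels=decels)
    rate_events = classify_rate(baseline, config)
    var_events = classify_variability(variability, config)
    special = detect_special_patterns(fhr, baseline, variability, contractions, config)
    return RecordFeatures(
        record=record, config=config, fhr=fhr, baseline=baseline,
        variability=variability, decelerations=decels,
        contractions=contractions, rate_events=rate_events,
        variability_events=var_events, special_events=special,
        ua_stats=ua_stats,
    )
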