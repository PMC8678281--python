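"""Synthetic intrapartum CTG scenario simulator with ground truth.

Produces records with a basal rate plus band-limited pseudorandom
variability, contraction trains with configurable frequency/duration/
intensity/resting tone, contraction-coupled decelerations with the four
recovery morphologies (normal, delayed return, overshoot, peaked return),
the special baseline patterns (sinusoidal, sawtooth, checkmark, conversion),
and scripted baseline shifts — each with analytically known event times, so
every rule can be tested without clinical data.

Ground-truth intervention-point times are computed from the script geometry
(the deterministic constructed waveforms before noise), never by running the
detectors on the noisy signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.signal

from .signal import CTGRecord, EventKind, EventLabel, FHRSeries, RuleConfig, UCMode, UCSeries
from .features import (
    UA_STEP_S,
    UA_WINDOW_S,
    _checkmark_template,
    label_rest_fraction,
    ua_window_flags,
)

DEFAULT_FS = 4.0  # Hz, standard CTG digitization rate

# raised-cosine pulse geometry: full base width so that the width at 10% of
# peak amplitude equals the nominal contraction duration
_THETA10 = math.acos(-0.8)
_W_FACTOR = math.pi / _THETA10  # ≈ 1.2576

_SCRIPTABLE = set(EventKind) - {EventKind.POINT_A, EventKind.POINT_B, EventKind.CONTRACTION}


class ScenarioError(ValueError):
    """Raised for physically impossible or self-contradictory scenario specs."""


@dataclass
class UAProfile:
    """Uterine-contraction train parameters (clinically average defaults)."""

    frequency_per_10min: float = 3.0
    duration_s: float = 75.0
    intensity: float = 50.0        # peak pressure above resting tone
    resting_tone: float = 15.0     # mmHg
    jitter: float = 0.0            # fraction of the inter-peak interval


@dataclass
class ScriptedEvent:
    """A scripted pattern with its interval and kind-specific parameters.

    ``params`` keys by kind (all optional, sensible defaults):

    - deceleration: depth_bpm, recovery (normal|delayed_return|overshoot|
      peaked_return), timing (variable|late|early), lag_s, tau_s
    - tachycardia_* / bradycardia_*: shift_bpm (sign enforced by kind)
    - decreased_variability / increased_variability: amplitude_bpm
      (peak-to-trough) and, for increased, an optional cpm giving a regular
      oscillation instead of scaled noise
    - sinusoidal: amplitude_bpm (± half-amplitude), cpm
    - sawtooth: amplitude_bpm (peak-to-trough), cpm
    - checkmark: amplitude_bpm, per_min
    - conversion: shift_bpm, new_variability_bpm
    - excessive_uterine_activity: frequency_per_10min, duration_s, intensity
    """

    kind: EventKind
    t_start: float
    t_end: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.kind = EventKind(self.kind)
        if self.kind not in _SCRIPTABLE:
            raise ScenarioError(f"{self.kind.value} cannot be scripted directly")
        if not 0 <= self.t_start < self.t_end:
            raise ScenarioError("scripted event times must satisfy 0 <= t_start < t_end")


@dataclass
class ScenarioSpec:
    """Complete description of a simulated labor segment."""

    duration_min: float = 35.0
    basal_rate: float = 140.0
    variability_amplitude: float = 10.0   # bpm peak-to-trough
    ua: UAProfile = field(default_factory=UAProfile)
    script: list = field(default_factory=list)
    noise_sd: float = 0.0                 # extra white measurement noise, bpm
    seed: int = 0
    fs: float = DEFAULT_FS

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ScenarioError("duration must be positive")
        if not 100 <= self.basal_rate <= 170:
            raise ScenarioError("basal rate must lie in [100, 170] bpm")
        if self.ua.frequency_per_10min < 0:
            raise ScenarioError("contraction frequency must be non-negative")
        for ev in self.script:
            if ev.t_end > self.duration_min * 60 + 1e-9:
                raise ScenarioError("scripted event extends past record end")

    @property
    def duration_s(self) -> float:
        return self.duration_min * 60.0

    def to_dict(self) -> dict:
        d = asdict(self)
        for ev in d["script"]:
            ev["kind"] = ev["kind"].value if isinstance(ev["kind"], EventKind) else ev["kind"]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d["ua"] = UAProfile(**d.get("ua", {}))
        d["script"] = [ScriptedEvent(**ev) for ev in d.get("script", [])]
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class GroundTruth:
    """Scripted events (plus per-contraction labels) and the analytically
    derived intervention-point times under default rule thresholds."""

    events: list
    point_a_time: float | None = None
    point_a_criterion: str | None = None
    point_a_criteria: set = field(default_factory=set)
    point_b_time: float | None = None
    point_b_basis: str | None = None


# ---------------------------------------------------------------------------
# Uterine activity
# ---------------------------------------------------------------------------

def _ua_local(spec: ScenarioSpec, key: str, t: float, default):
    """UA parameter at time *t*, honoring scripted excessive-UA overrides."""
    for ev in spec.script:
        if ev.kind is EventKind.EXCESSIVE_UTERINE_ACTIVITY and ev.t_start <= t < ev.t_end:
            return ev.params.get(key, default)
    return getattr(spec.ua, key)


def simulate_uc(spec: ScenarioSpec, seed: int | None = None):
    """Simulate the uterine-contraction channel.

    Returns the UC series (resting tone plus raised-cosine pulses) and one
    contraction label per pulse spanning the 10%-of-amplitude onset→offset.
    Scripted excessive-uterine-activity windows locally override the pulse
    frequency/duration/intensity.  Deterministic given the seed.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(seed) % (2 ** 31), 101])
    fs, T = spec.fs, spec.duration_s
    n = int(round(T * fs))
    t = np.arange(n) / fs

    # place peaks by integrating the (piecewise) contraction rate
    freq = np.array([
        _ua_local(spec, "frequency_per_10min", ti, 6.0) for ti in t[:: int(fs)]
    ])  # per-second resolution is enough
    lam = np.repeat(freq, int(fs))[:n] / 600.0
    phase = np.cumsum(lam) / fs
    n_peaks = int(math.floor(phase[-1] + 0.5)) if n else 0
    peaks = np.interp(np.arange(n_peaks) + 0.5, phase, t)

    uc = np.full(n, spec.ua.resting_tone, dtype=float)
    labels = []
    peak_list = []
    for p in peaks:
        d = _ua_local(spec, "duration_s", p, 90.0)
        interval = 600.0 / max(_ua_local(spec, "frequency_per_10min", p, 6.0), 1e-9)
        p = p + rng.uniform(-1, 1) * spec.ua.jitter * interval
        p = round(p * fs) / fs  # peaks live on the sample grid
        if p - d / 2 < 0 or p + d / 2 > T:
            continue
        peak_list.append((p, d, _ua_local(spec, "intensity", p, 50.0)))

    for i in range(1, len(peak_list)):
        gap = peak_list[i][0] - peak_list[i - 1][0]
        if gap < 0.5 * (peak_list[i][1] + peak_list[i - 1][1]):
            raise ScenarioError("contraction frequency too high: pulses overlap")

    for p, d, amp in peak_list:
        W = d * _W_FACTOR
        sel = np.abs(t - p) < W / 2
        uc[sel] += amp * 0.5 * (1 + np.cos(2 * np.pi * (t[sel] - p) / W))
        labels.append(EventLabel(
            kind=EventKind.CONTRACTION,
            t_start=float(p - d / 2), t_end=float(p + d / 2),
            attributes={"peak_time": float(p), "duration_s": float(d),
                        "amplitude": float(amp)},
        ))

    series = UCSeries(start_time=0.0, fs=fs, values=uc, mode=UCMode.INTRAUTERINE_MMHG)
    return series, labels


# ---------------------------------------------------------------------------
# FHR components
# ---------------------------------------------------------------------------

def _cos_ramp(t, t0, t1):
    """0→1 half-cosine ramp over [t0, t1]."""
    x = np.clip((t - t0) / max(t1 - t0, 1e-9), 0, 1)
    return 0.5 * (1 - np.cos(np.pi * x))


def _band_noise(rng, n, fs, amplitude):
    """Band-limited (0.03–0.5 Hz) Gaussian variability scaled so the global
    5th–95th percentile range equals *amplitude* (peak-to-trough bpm)."""
    white = rng.standard_normal(n + 400)
    sos = scipy.signal.butter(2, [0.03, 0.5], btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos, white)[200:-200]
    span = np.percentile(x, 95) - np.percentile(x, 5)
    return x * (amplitude / max(span, 1e-12))


def _decel_component(spec, ev, t, contractions):
    """Build one deceleration's waveform and its realized geometry.

    Returns (component array, attributes dict).  The component is the exact
    noise-free contribution of this deceleration (dip, plus any overshoot /
    peaked-return follow-up), from which onset / nadir / −5 bpm recovery
    times are measured analytically.
    """
    p = ev.params
    depth = float(p.get("depth_bpm", 30.0))
    if depth > spec.basal_rate - 30.0:
        raise ScenarioError(
            f"deceleration depth {depth} bpm exceeds basal−30 physiologic floor")
    recovery = p.get("recovery", "normal")
    timing = p.get("timing", "variable")
    mid = 0.5 * (ev.t_start + ev.t_end)

    peak_time = contraction_end = None
    if contractions:
        peaks = np.array([c.attributes["peak_time"] for c in contractions])
        ci = int(np.argmin(np.abs(peaks - mid)))
        if abs(peaks[ci] - mid) <= 180:
            peak_time = float(peaks[ci])
            contraction_end = float(contractions[ci].t_end)

    if timing == "late":
        lag = float(p.get("lag_s", 30.0))
        t_nadir = (peak_time + lag) if peak_time is not None else mid
    else:
        t_nadir = peak_time if peak_time is not None else mid

    if timing == "variable":
        fall = float(p.get("fall_s", max(10.0, depth / 3.5)))  # steep: >=3 bpm/s
    else:
        fall = float(p.get("fall_s", 30.0))
    rise = float(p.get("rise_s", 20.0 if timing == "variable" else 25.0))

    comp = np.zeros_like(t)
    tau_rel = t - t_nadir

    sel = (tau_rel >= -fall) & (tau_rel < 0)
    comp[sel] = -depth * 0.5 * (1 + np.cos(np.pi * tau_rel[sel] / fall))

    if recovery == "delayed_return":
        tau = float(p.get("tau_s", 45.0))
        rec_len = float(p.get("recovery_len_s", max(150.0, tau * math.log(depth / 2.0))))
        sel = (tau_rel >= 0) & (tau_rel <= rec_len)
        x = -depth * np.exp(-tau_rel[sel] / tau)
        fade = 1 - _cos_ramp(tau_rel[sel], rec_len - 20.0, rec_len)
        comp[sel] = x * fade
    else:
        sel = (tau_rel >= 0) & (tau_rel <= rise)
        comp[sel] = -depth * 0.5 * (1 + np.cos(np.pi * tau_rel[sel] / rise))
        rec_end = t_nadir + rise
        if recovery == "overshoot":
            amp_o = min(0.25 * depth, 25.0)
            dur_o = max(20.0, 0.6 * depth)   # duration grows with decel depth
            # plateau bump: 5 s shoulders around a flat top
            tb = t - rec_end
            shape = np.zeros_like(t)
            s1 = (tb >= 0) & (tb < 5)
            shape[s1] = _cos_ramp(tb[s1], 0, 5)
            s2 = (tb >= 5) & (tb < 5 + dur_o)
            shape[s2] = 1.0
            s3 = (tb >= 5 + dur_o) & (tb < 10 + dur_o)
            shape[s3] = 1 - _cos_ramp(tb[s3], 5 + dur_o, 10 + dur_o)
            comp += amp_o * shape
        elif recovery == "peaked_return":
            spike_amp = float(p.get("spike_bpm", 15.0))
            sw = 8.0
            sel = np.abs(t - rec_end - sw / 2) < sw / 2
            comp[sel] += spike_amp * 0.5 * (
                1 + np.cos(2 * np.pi * (t[sel] - rec_end - sw / 2) / sw))
            d2 = float(p.get("second_depth_bpm", 30.0))
            n2 = rec_end + float(p.get("second_lag_s", 60.0))
            sel = np.abs(t - n2) < 30
            comp[sel] += -d2 * 0.5 * (1 + np.cos(np.pi * (t[sel] - n2) / 30.0))

    below = np.flatnonzero(comp <= -5.0)
    fs = spec.fs
    attrs = {
        "depth_bpm": depth, "recovery": recovery, "timing": timing,
        "t_nadir": float(t_nadir),
        "t_onset": float(below[0] / fs) if below.size else float(t_nadir - fall),
        "t_recovery": float((below[-1] + 1) / fs) if below.size else float(t_nadir),
        "contraction_peak": peak_time,
        "contraction_end": contraction_end,
    }
    return comp, attrs


def simulate_fhr(spec: ScenarioSpec, uc: UCSeries, seed: int | None = None,
                 contractions: list | None = None):
    """Simulate the FHR channel on top of a simulated UC channel.

    Returns the FHR series and the scripted events as labels enriched with
    their realized geometry (nadir / recovery times, associated contraction).
    Deterministic given the seed.
    """
    seed = spec.seed if seed is None else seed
    if contractions is None:
        _, contractions = simulate_uc(spec, seed)
    rng = np.random.default_rng([int(seed) % (2 ** 31), 202])
    fs, T = spec.fs, spec.duration_s
    n = int(round(T * fs))
    t = np.arange(n) / fs

    peaks = [c.attributes["peak_time"] for c in contractions]
    mean_interval = float(np.median(np.diff(peaks))) if len(peaks) >= 2 else 200.0

    baseline = np.full(n, spec.basal_rate, dtype=float)
    var_scale = np.ones(n)
    pattern = np.zeros(n)
    pattern_mask = np.zeros(n, dtype=bool)
    out_events = []

    noise = _band_noise(rng, n, fs, spec.variability_amplitude)

    shift_kinds = {
        EventKind.TACHYCARDIA_ABSOLUTE: +1, EventKind.TACHYCARDIA_RELATIVE: +1,
        EventKind.BRADYCARDIA_ABSOLUTE: -1, EventKind.BRADYCARDIA_RELATIVE: -1,
    }

    for ev in spec.script:
        attrs = dict(ev.params)
        if ev.kind in shift_kinds:
            sign = shift_kinds[ev.kind]
            shift = sign * abs(float(ev.params.get("shift_bpm", 18.0)))
            ramp = 15.0
            baseline += shift * (_cos_ramp(t, ev.t_start, ev.t_start + ramp)
                                 - _cos_ramp(t, ev.t_end - ramp, ev.t_end))
            attrs["shift_bpm"] = shift
        elif ev.kind is EventKind.CONVERSION:
            shift = float(ev.params.get("shift_bpm", -20.0))
            new_var = float(ev.params.get("new_variability_bpm", 3.0))
            # the change completes comfortably within the 1–2 contraction bound
            max_ramp = 1.5 * mean_interval if len(peaks) >= 2 else 300.0
            ramp_s = min(ev.t_end - ev.t_start, max_ramp)
            baseline += shift * _cos_ramp(t, ev.t_start, ev.t_start + ramp_s)
            ratio = new_var / spec.variability_amplitude
            var_scale *= 1 + (ratio - 1) * _cos_ramp(t, ev.t_start, ev.t_start + ramp_s)
            attrs["t_transition_end"] = float(ev.t_start + ramp_s)
        elif ev.kind is EventKind.DECREASED_VARIABILITY:
            amp = float(ev.params.get("amplitude_bpm", 4.0))
            sel = (t >= ev.t_start) & (t < ev.t_end)
            var_scale[sel] = amp / spec.variability_amplitude
            attrs["amplitude_bpm"] = amp
        elif ev.kind is EventKind.INCREASED_VARIABILITY:
            amp = float(ev.params.get("amplitude_bpm", 28.0))
            sel = (t >= ev.t_start) & (t < ev.t_end)
            if "cpm" in ev.params:
                # regular oscillation at the requested cycle frequency,
                # scaled so the 5–95 percentile range equals amplitude_bpm
                cpm = float(ev.params["cpm"])
                A = amp / (2 * math.cos(0.05 * math.pi))
                pattern[sel] += A * np.sin(2 * np.pi * cpm / 60.0 * (t[sel] - ev.t_start))
                pattern_mask |= sel
            else:
                var_scale[sel] = amp / spec.variability_amplitude
            attrs["amplitude_bpm"] = amp
        elif ev.kind is EventKind.SINUSOIDAL:
            A = float(ev.params.get("amplitude_bpm", 7.0))
            cpm = float(ev.params.get("cpm", 4.0))
            sel = (t >= ev.t_start) & (t < ev.t_end)
            pattern[sel] += A * np.sin(2 * np.pi * cpm / 60.0 * (t[sel] - ev.t_start))
            pattern_mask |= sel
        elif ev.kind is EventKind.SAWTOOTH:
            amp = float(ev.params.get("amplitude_bpm", 8.0))
            cpm = float(ev.params.get("cpm", 25.0))
            sel = (t >= ev.t_start) & (t < ev.t_end)
            pattern[sel] += (amp / 2.0) * scipy.signal.sawtooth(
                2 * np.pi * cpm / 60.0 * (t[sel] - ev.t_start), width=0.85)
            pattern_mask |= sel
        elif ev.kind is EventKind.CHECKMARK:
            amp = float(ev.params.get("amplitude_bpm", 20.0))
            per_min = float(ev.params.get("per_min", 1.0))
            template = _checkmark_template(fs)
            sel = (t >= ev.t_start) & (t < ev.t_end)
            var_scale[sel] = np.minimum(var_scale[sel], 0.3)
            t_spike = ev.t_start + 20.0
            spike_times = []
            while t_spike + len(template) / fs < ev.t_end:
                i0 = int(round(t_spike * fs))
                pattern[i0:i0 + len(template)] += amp * template
                spike_times.append(t_spike)
                t_spike += 60.0 / per_min
            attrs["spike_times"] = spike_times
        elif ev.kind is EventKind.DECELERATION:
            comp, dattrs = _decel_component(spec, ev, t, contractions)
            pattern += comp
            attrs.update(dattrs)
        elif ev.kind is EventKind.EXCESSIVE_UTERINE_ACTIVITY:
            pass  # handled by simulate_uc
        out_events.append(EventLabel(kind=ev.kind, t_start=ev.t_start,
                                     t_end=ev.t_end, attributes=attrs))

    values = baseline + noise * var_scale * (~pattern_mask) + pattern
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, n)
    values = np.clip(values, 30.0, 240.0)
    series = FHRSeries(start_time=0.0, fs=fs, values=values,
                       quality=np.ones(n, dtype=bool))
    return series, out_events


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _truth_point_a(spec, contractions, scripted, config: RuleConfig):
    """Earliest Point A trigger implied by the script, per criterion."""
    candidates = []  # (time, letter)
    decel_recoveries = [
        ev.attributes["t_recovery"] for ev in scripted
        if ev.kind is EventKind.DECELERATION
    ]

    def after_decel(t0):
        return any(r <= t0 <= r + 600.0 for r in decel_recoveries)

    for ev in scripted:
        a = ev.attributes
        if ev.kind is EventKind.DECELERATION:
            if a["recovery"] == "delayed_return":
                tt = a["contraction_end"] if a["contraction_end"] is not None else a["t_recovery"]
                candidates.append((tt, "A"))
            elif a["recovery"] == "overshoot":
                candidates.append((a["t_recovery"], "C"))
        elif ev.kind is EventKind.INCREASED_VARIABILITY:
            amp = a.get("amplitude_bpm", 0.0)
            cpm = a.get("cpm")
            if (amp > config.pointA_var_peak_trough_bpm and cpm is not None
                    and config.pointA_var_cpm[0] <= cpm <= config.pointA_var_cpm[1]
                    and after_decel(ev.t_start)):
                candidates.append((ev.t_start + 60.0, "B"))
        elif ev.kind in (EventKind.TACHYCARDIA_ABSOLUTE, EventKind.TACHYCARDIA_RELATIVE):
            shift = a.get("shift_bpm", 0.0)
            span = ev.t_end - ev.t_start
            if (shift >= config.pointA_up_shift_bpm
                    and config.pointA_transient_min_s <= span <= config.sustained_min * 60
                    and after_decel(ev.t_start)):
                candidates.append((ev.t_start + config.pointA_transient_min_s, "D"))
        elif ev.kind in (EventKind.BRADYCARDIA_ABSOLUTE, EventKind.BRADYCARDIA_RELATIVE):
            shift = a.get("shift_bpm", 0.0)
            span = ev.t_end - ev.t_start
            if (shift <= -config.pointA_down_shift_bpm
                    and config.pointA_transient_min_s <= span <= config.sustained_min * 60
                    and after_decel(ev.t_start)):
                candidates.append((ev.t_start + config.pointA_transient_min_s, "E"))

    # F: excessive uterine activity, from the ground-truth contraction labels
    T = spec.duration_s
    if T >= UA_WINDOW_S and contractions:
        windows = np.arange(0.0, T - UA_WINDOW_S + 1e-9, UA_STEP_S)
        peaks = np.array([c.attributes["peak_time"] for c in contractions])
        durs = np.array([c.attributes["duration_s"] for c in contractions])
        rest = label_rest_fraction(contractions, windows)
        flags = ua_window_flags(peaks, durs, spec.ua.resting_tone, rest,
                                windows, config, UCMode.INTRAUTERINE_MMHG)
        any_flag = np.zeros(len(windows), dtype=bool)
        for arr in flags.values():
            any_flag |= arr
        hit = np.flatnonzero(any_flag)
        if hit.size:
            candidates.append((float(windows[hit[0]] + UA_WINDOW_S), "F"))

    if not candidates:
        return None, None, set()
    candidates.sort(key=lambda c: (c[0], c[1]))
    letters = {c[1] for c in candidates}
    return candidates[0][0], candidates[0][1], letters


def _truth_point_b(spec, scripted, config: RuleConfig):
    candidates = []
    decel_recoveries = [
        ev.attributes["t_recovery"] for ev in scripted
        if ev.kind is EventKind.DECELERATION
    ]
    for ev in scripted:
        if ev.kind is EventKind.CONVERSION:
            candidates.append((ev.attributes["t_transition_end"], "rapid_adverse_change"))
        elif ev.kind is EventKind.DECREASED_VARIABILITY:
            amp = ev.attributes.get("amplitude_bpm", 10.0)
            span = ev.t_end - ev.t_start
            follows = any(r <= ev.t_start <= r + 600 for r in decel_recoveries)
            rise = any(
                o.kind in (EventKind.TACHYCARDIA_ABSOLUTE, EventKind.TACHYCARDIA_RELATIVE)
                and o.attributes.get("shift_bpm", 0) >= 10
                and o.t_start < ev.t_end and o.t_end > ev.t_start
                for o in scripted)
            if amp < config.decreased_var_bpm and span > config.sustained_min * 60 \
                    and follows and rise:
                candidates.append((ev.t_start + config.sustained_min * 60,
                                   "sustained_low_variability_rise"))
    if not candidates:
        return None, None
    candidates.sort(key=lambda c: c[0])
    return candidates[0]


def simulate_scenario(spec: ScenarioSpec):
    """Simulate a full scenario: record plus ground truth."""
    uc, contractions = simulate_uc(spec, spec.seed)
    fhr, scripted = simulate_fhr(spec, uc, spec.seed, contractions)
    record = CTGRecord(record_id=f"sim-{spec.seed}", fhr=fhr, uc=uc)

    config = RuleConfig()
    pa_time, pa_letter, pa_set = _truth_point_a(spec, contractions, scripted, config)
    pb_time, pb_basis = _truth_point_b(spec, scripted, config)
    truth = GroundTruth(
        events=contractions + scripted,
        point_a_time=pa_time, point_a_criterion=pa_letter,
        point_a_criteria=pa_set,
        point_b_time=pb_time, point_b_basis=pb_basis,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Canonical scenario families (the study conditions used by the test suites)
# ---------------------------------------------------------------------------

def normal_scenario(seed: int, noise_sd: float = 2.0,
                    duration_min: float = 35.0) -> ScenarioSpec:
    """An uneventful labor segment: average contraction train, normal basal
    rate and variability, no scripted adversity."""
    return ScenarioSpec(duration_min=duration_min, basal_rate=140.0,
                        variability_amplitude=10.0,
                        ua=UAProfile(jitter=0.05),
                        noise_sd=noise_sd, seed=seed)


def criterion_scenario(letter: str, seed: int, noise_sd: float = 2.0) -> ScenarioSpec:
    """A scenario scripted to first trigger Point A via one criterion A–F."""
    ua = UAProfile(jitter=0.03)
    script: list

    if letter == "A":
        script = [ScriptedEvent(EventKind.DECELERATION, 1450, 1650,
                                {"depth_bpm": 40, "recovery": "delayed_return"})]
    elif letter == "B":
        script = [
            ScriptedEvent(EventKind.DECELERATION, 1260, 1380,
                          {"depth_bpm": 40, "recovery": "normal"}),
            ScriptedEvent(EventKind.INCREASED_VARIABILITY, 1440, 1680,
                          {"amplitude_bpm": 26, "cpm": 7.0}),
        ]
    elif letter == "C":
        script = [ScriptedEvent(EventKind.DECELERATION, 1450, 1600,
                                {"depth_bpm": 60, "recovery": "overshoot"})]
    elif letter == "D":
        script = [
            ScriptedEvent(EventKind.DECELERATION, 1260, 1380,
                          {"depth_bpm": 40, "recovery": "normal"}),
            ScriptedEvent(EventKind.TACHYCARDIA_RELATIVE, 1440, 1680,
                          {"shift_bpm": 20}),
        ]
    elif letter == "E":
        script = [
            ScriptedEvent(EventKind.DECELERATION, 1260, 1380,
                          {"depth_bpm": 40, "recovery": "normal"}),
            ScriptedEvent(EventKind.BRADYCARDIA_RELATIVE, 1440, 1680,
                          {"shift_bpm": 13}),
        ]
    elif letter == "F":
        script = [ScriptedEvent(EventKind.EXCESSIVE_UTERINE_ACTIVITY, 1200, 2100,
                                {"frequency_per_10min": 6.0, "duration_s": 75.0})]
        ua = UAProfile(jitter=0.0)
    else:
        raise ValueError(f"unknown criterion letter {letter!r}")

    return ScenarioSpec(duration_min=35.0, basal_rate=140.0,
                        variability_amplitude=10.0, ua=ua,
                        script=script, noise_sd=noise_sd, seed=seed)


def point_b_scenario(basis: str, seed: int, noise_sd: float = 1.0) -> ScenarioSpec:
    """Scenarios reaching Point B (after an earlier Point A)."""
    if basis == "sustained_low_variability_rise":
        script = [
            ScriptedEvent(EventKind.DECELERATION, 850, 1000,
                          {"depth_bpm": 40, "recovery": "delayed_return"}),
            ScriptedEvent(EventKind.DECREASED_VARIABILITY, 1020, 2090,
                          {"amplitude_bpm": 3.0}),
            ScriptedEvent(EventKind.TACHYCARDIA_RELATIVE, 1020, 2090,
                          {"shift_bpm": 12}),
        ]
    elif basis == "rapid_adverse_change":
        script = [
            ScriptedEvent(EventKind.DECELERATION, 1150, 1300,
                          {"depth_bpm": 40, "recovery": "delayed_return"}),
            ScriptedEvent(EventKind.CONVERSION, 1700, 2090,
                          {"shift_bpm": -20, "new_variability_bpm": 3.0}),
        ]
    else:
        raise ValueError(f"unknown Point B basis {basis!r}")
    return ScenarioSpec(duration_min=35.0, basal_rate=140.0,
                        variability_amplitude=10.0, ua=UAProfile(jitter=0.03),
                        script=script, noise_sd=noise_sd, seed=seed)
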