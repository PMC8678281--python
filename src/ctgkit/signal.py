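"""Core domain types and I/O for cardiotocogram (CTG) records.

A CTG record pairs a fetal heart rate (FHR) trace in beats per minute with a
uterine contraction (UC) trace, uniformly sampled.  Sample validity is carried
as an explicit boolean mask rather than sentinel values: downstream rules skip
invalid samples, and analysis windows with too much missing data are reported
as indeterminate instead of being classified.

All times are seconds from the start of the record; intervals are half-open
``[t_start, t_end)``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FHR_MIN_BPM",
    "FHR_MAX_BPM",
    "UCMode",
    "EventKind",
    "FHRSeries",
    "UCSeries",
    "CTGRecord",
    "EventLabel",
    "RuleConfig",
    "TracingAssessment",
    "CTGFormatError",
    "read_ctg_csv",
    "write_ctg_csv",
    "clean_fhr",
    "read_events_json",
    "write_events_json",
]

#: Physiological plausibility range for FHR samples (bpm).  Samples outside
#: this range are flagged invalid at read time, never silently altered.
FHR_MIN_BPM = 30.0
FHR_MAX_BPM = 240.0


class CTGFormatError(ValueError):
    """Raised when a CTG CSV / events JSON file violates the expected format."""


class UCMode(str, enum.Enum):
    """How the uterine contraction channel was transduced.

    Absolute-pressure thresholds (resting tone in mmHg) only apply to
    intrauterine pressure catheter data; an external tocodynamometer yields
    relative units.
    """

    INTRAUTERINE_MMHG = "intrauterine_mmHg"
    EXTERNAL_RELATIVE = "external_relative"


class EventKind(str, enum.Enum):
    """Closed vocabulary of CTG patterns and intervention points."""

    CONTRACTION = "contraction"
    DECELERATION = "deceleration"
    OVERSHOOT = "overshoot"
    DELAYED_RETURN = "delayed_return"
    PEAKED_RETURN = "peaked_return"
    TACHYCARDIA_ABSOLUTE = "tachycardia_absolute"
    TACHYCARDIA_RELATIVE = "tachycardia_relative"
    BRADYCARDIA_ABSOLUTE = "bradycardia_absolute"
    BRADYCARDIA_RELATIVE = "bradycardia_relative"
    DECREASED_VARIABILITY = "decreased_variability"
    INCREASED_VARIABILITY = "increased_variability"
    SINUSOIDAL = "sinusoidal"
    SAWTOOTH = "sawtooth"
    CHECKMARK = "checkmark"
    CONVERSION = "conversion"
    EXCESSIVE_UTERINE_ACTIVITY = "excessive_uterine_activity"
    POINT_A = "point_a"
    POINT_B = "point_b"


@dataclass
class FHRSeries:
    """Uniformly sampled fetal heart rate trace.

    Parameters
    ----------
    start_time : float
        Seconds relative to the record start (0 for a full record).
    fs : float
        Sampling rate in Hz.
    values : ndarray of float
        Heart rate in bpm, one entry per sample.
    quality : ndarray of bool
        Per-sample validity mask; invalid samples must be ignored by rules.
    """

    start_time: float
    fs: float
    values: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.quality is None:
            in_range = (self.values >= FHR_MIN_BPM) & (self.values <= FHR_MAX_BPM)
            self.quality = in_range & np.isfinite(self.values)
        self.quality = np.asarray(self.quality, dtype=bool)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.values.shape != self.quality.shape:
            raise ValueError("values and quality must have the same length")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return self.start_time + np.arange(self.n) / self.fs


@dataclass
class UCSeries:
    """Uniformly sampled uterine activity trace (mmHg or relative units)."""

    start_time: float
    fs: float
    values: np.ndarray
    mode: UCMode = UCMode.INTRAUTERINE_MMHG

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mode = UCMode(self.mode)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("uterine activity values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs


@dataclass
class CTGRecord:
    """A paired FHR + UC recording — the unit of analysis."""

    record_id: str
    fhr: FHRSeries
    uc: UCSeries

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("record duration must be positive")
        # Channels must cover the same span within one sample period.
        if abs(self.fhr.duration - self.uc.duration) > 1.0 / min(self.fhr.fs, self.uc.fs) + 1e-9:
            raise ValueError("FHR and UC channels cover different time spans")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return min(self.fhr.duration, self.uc.duration)


@dataclass
class EventLabel:
    """A typed, time-bounded pattern or event on a record."""

    kind: EventKind
    t_start: float
    t_end: float
    attributes: dict = field(default_factory=dict)
    confidence: float = 1.0

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        if not 0 <= self.t_start < self.t_end:
            raise ValueError(f"invalid event interval [{self.t_start}, {self.t_end})")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must lie in [0, 1]")
        if self.kind is EventKind.POINT_A and "criterion_letter" in self.attributes:
            if self.attributes["criterion_letter"] not in set("ABCDEF"):
                raise ValueError("point_a criterion_letter must be one of A–F")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class RuleConfig:
    """Every numeric threshold used by the pattern rules, with clinical defaults.

    Baseline-rate rules
    -------------------
    tachy_abs_bpm / brady_abs_bpm
        Absolute tachycardia (>155 bpm) / bradycardia (<110 bpm) baselines.
    relative_shift_bpm
        Shift from the individual basal rate defining *relative*
        tachycardia/bradycardia (15 bpm).
    sustained_min
        Minutes a baseline or variability change must persist (strictly
        greater than) to count as "sustained" (10 min).

    Variability rules
    -----------------
    decreased_var_bpm / increased_var_bpm
        Peak-to-trough amplitude bounds (<6 bpm decreased, >25 bpm increased).
    sinusoidal_cpm
        Cycle-frequency band of the sinusoidal pattern (3–5 cycles/min).
    sawtooth_min_cpm / sawtooth_max_amp_bpm
        Sawtooth pattern: 20+ cycles/min at <15 bpm amplitude.

    Excessive uterine activity (any one flag suffices)
    --------------------------------------------------
    ua_freq_excessive            >5 contractions per 10-min window,
                                 over ``ua_freq_windows`` consecutive windows.
    ua_duration_excessive_s      contraction duration >90 s.
    ua_resting_tone_mmHg         resting tone >20 mmHg (intrauterine mode only).
    ua_interval_excessive_s      interval between peaks <120 s.
    ua_rest_time_fraction        rest time <50% of the window.

    Point A / Point B
    -----------------
    pointA_var_peak_trough_bpm / pointA_var_cpm
        Criterion B: post-deceleration variability >20 bpm at 5–10 cycles/min.
    pointA_overshoot_min_s
        Criterion C: post-deceleration acceleration lasting 15 s or more.
    pointA_up_shift_bpm / pointA_down_shift_bpm
        Criteria D/E: transient baseline shift ≥15 bpm up / ≥10 bpm down.
    pointA_transient_min_s
        Minimum duration of a transient shift (1 min).
    pointB_window_min
        Point B route 2: adverse change completing within 5–10 min.

    Initial assessment
    ------------------
    normal_baseline_bpm
        Normal stable baseline band (110–155 bpm).
    abnormal_low_baseline_bpm
        Outset-abnormality low cut (<100 bpm; distinct from the 110 bpm
        bradycardia event threshold).
    conversion_max_contractions
        Conversion pattern completes within 1–2 contractions.
    """

    tachy_abs_bpm: float = 155.0
    brady_abs_bpm: float = 110.0
    relative_shift_bpm: float = 15.0
    sustained_min: float = 10.0
    decreased_var_bpm: float = 6.0
    increased_var_bpm: float = 25.0
    sinusoidal_cpm: tuple = (3.0, 5.0)
    sawtooth_min_cpm: float = 20.0
    sawtooth_max_amp_bpm: float = 15.0
    ua_freq_excessive: float = 5.0
    ua_freq_windows: int = 2
    ua_duration_excessive_s: float = 90.0
    ua_resting_tone_mmHg: float = 20.0
    ua_interval_excessive_s: float = 120.0
    ua_rest_time_fraction: float = 0.50
    pointA_var_peak_trough_bpm: float = 20.0
    pointA_var_cpm: tuple = (5.0, 10.0)
    pointA_overshoot_min_s: float = 15.0
    pointA_up_shift_bpm: float = 15.0
    pointA_down_shift_bpm: float = 10.0
    pointA_transient_min_s: float = 60.0
    pointB_window_min: tuple = (5.0, 10.0)
    normal_baseline_bpm: tuple = (110.0, 155.0)
    abnormal_low_baseline_bpm: float = 100.0
    conversion_max_contractions: int = 2
    # Detection conventions (ACOG-style deceleration floor; not pattern
    # definitions from the rule tables).
    decel_floor_bpm: float = 15.0
    decel_min_duration_s: float = 15.0
    decel_edge_bpm: float = 5.0
    max_invalid_fraction: float = 0.20

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive")
            if isinstance(v, (tuple, list)):
                v = tuple(float(x) for x in v)
                if len(v) != 2 or not v[0] < v[1]:
                    raise ValueError(f"interval {f.name} must be ordered (low, high)")
                setattr(self, f.name, v)

    def to_dict(self) -> dict:
        return {f.name: list(v) if isinstance(v, tuple) else v
                for f in fields(self) for v in [getattr(self, f.name)]}

    @classmethod
    def from_dict(cls, d: dict) -> "RuleConfig":
        return cls(**d)

    def replace(self, **kw) -> "RuleConfig":
        return replace(self, **kw)


@dataclass
class TracingAssessment:
    """Outset normal/abnormal call with the reasons for abnormality."""

    status: str
    reasons: list

    def __post_init__(self) -> None:
        if self.status not in ("normal", "abnormal"):
            raise ValueError("status must be 'normal' or 'abnormal'")
        if (self.status == "normal") != (len(self.reasons) == 0):
            raise ValueError("status is normal iff reasons is empty")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_ctg_csv(path, fs_override: float | None = None) -> CTGRecord:
    """Read a CTG record from a ``time_s,fhr_bpm,uc`` CSV file.

    An optional ``# fs=4`` comment line declares the sampling rate; otherwise
    it is inferred from the median time step (or taken from *fs_override*).
    Irregular timestamps are resampled onto a uniform grid by linear
    interpolation.  FHR samples outside the physiological range, or missing,
    are flagged invalid but retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    fs_comment = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.lstrip("#").replace(",", " ").split():
            if tok.startswith("fs="):
                fs_comment = float(tok[3:])

    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise CTGFormatError(f"empty CTG file: {path}")
    missing = {"time_s", "fhr_bpm", "uc"} - set(df.columns)
    if missing:
        raise CTGFormatError(f"missing columns {sorted(missing)} in {path}")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise CTGFormatError("need at least two samples")
    if np.any(np.diff(t) <= 0):
        raise CTGFormatError("time_s must be strictly increasing")

    fs = fs_override or fs_comment or 1.0 / float(np.median(np.diff(t)))

    n = int(round((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs

    fhr_in = df["fhr_bpm"].to_numpy(dtype=float)
    uc_in = df["uc"].to_numpy(dtype=float)

    fhr_valid_in = np.isfinite(fhr_in) & (fhr_in >= FHR_MIN_BPM) & (fhr_in <= FHR_MAX_BPM)
    # Interpolate only across valid support; samples mapping to invalid or
    # missing input stay flagged.
    if fhr_valid_in.any():
        fhr = np.interp(grid, t[fhr_valid_in], fhr_in[fhr_valid_in])
    else:
        fhr = np.full(n, np.nan)
    # A grid sample is valid iff its nearest input sample is valid.
    nearest = np.clip(np.searchsorted(t, grid), 0, len(t) - 1)
    left = np.clip(nearest - 1, 0, len(t) - 1)
    use_left = np.abs(t[left] - grid) < np.abs(t[nearest] - grid)
    nearest = np.where(use_left, left, nearest)
    quality = fhr_valid_in[nearest]

    uc_ok = np.isfinite(uc_in)
    uc = np.interp(grid, t[uc_ok], uc_in[uc_ok]) if uc_ok.any() else np.zeros(n)
    uc = np.clip(uc, 0.0, None)

    mode = UCMode.INTRAUTERINE_MMHG
    return CTGRecord(
        record_id=path.stem,
        fhr=FHRSeries(start_time=0.0, fs=fs, values=fhr, quality=quality),
        uc=UCSeries(start_time=0.0, fs=fs, values=uc, mode=mode),
    )


def write_ctg_csv(record: CTGRecord, path) -> None:
    """Write a record as ``time_s,fhr_bpm,uc`` CSV with an ``# fs=`` header.

    Invalid FHR samples are written as empty fields so that a round trip
    preserves the quality mask.
    """
    t = record.fhr.times()
    fhr = record.fhr.values.copy()
    fhr[~record.fhr.quality] = np.nan
    df = pd.DataFrame({"time_s": t, "fhr_bpm": fhr, "uc": record.uc.values})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={record.fhr.fs:g}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Signal cleaning
# ---------------------------------------------------------------------------

def clean_fhr(fhr: FHRSeries, max_gap_s: float = 15.0, max_jump_bpm: float = 25.0) -> FHRSeries:
    """Remove dropout artifacts from an FHR trace.

    Samples following an inter-sample jump larger than *max_jump_bpm* are
    invalidated (transducer slips), then runs of invalid samples no longer
    than *max_gap_s* are bridged by linear interpolation between the flanking
    valid samples and re-marked valid.  Longer gaps remain invalid.  The
    operation is idempotent and preserves length.
    """
    values = fhr.values.copy()
    quality = fhr.quality.copy()

    valid_idx = np.flatnonzero(quality)
    if valid_idx.size >= 2:
        jumps = np.abs(np.diff(values[valid_idx]))
        bad = valid_idx[1:][jumps > max_jump_bpm]
        quality[bad] = False

    max_gap_n = int(round(max_gap_s * fhr.fs))
    valid_idx = np.flatnonzero(quality)
    if valid_idx.size >= 2:
        for a, b in zip(valid_idx[:-1], valid_idx[1:]):
            gap = b - a - 1
            if 0 < gap <= max_gap_n:
                # chord between the flanking valid samples
                values[a + 1:b] = np.interp(np.arange(a + 1, b), [a, b], [values[a], values[b]])
                quality[a + 1:b] = True

    return FHRSeries(start_time=fhr.start_time, fs=fhr.fs, values=values, quality=quality)


# ---------------------------------------------------------------------------
# Events JSON I/O
# ---------------------------------------------------------------------------

def write_events_json(events, path) -> None:
    """Serialize events as a JSON array (lossless round trip)."""
    payload = [
        {
            "kind": e.kind.value,
            "t_start": e.t_start,
            "t_end": e.t_end,
            "confidence": e.confidence,
            "attributes": e.attributes,
        }
        for e in events
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_events_json(path):
    """Read an event list written by :func:`write_events_json`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    out = []
    for obj in payload:
        try:
            kind = EventKind(obj["kind"])
        except (ValueError, KeyError) as exc:
            raise CTGFormatError(f"unknown event kind: {obj.get('kind')!r}") from exc
        out.append(
            EventLabel(
                kind=kind,
                t_start=obj["t_start"],
                t_end=obj["t_end"],
                confidence=obj.get("confidence", 1.0),
                attributes=obj.get("attributes", {}),
            )
        )
    return out
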