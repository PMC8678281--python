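"""Pattern extraction: baseline, variability, decelerations, special
patterns, uterine activity."""

import numpy as np
import pytest

from ctgkit.features import (
    BaselineEstimate,
    InsufficientDataError,
    analyze_uterine_activity,
    classify_rate,
    classify_variability,
    compute_variability,
    detect_special_patterns,
    estimate_basal_rate,
    estimate_baseline,
    extract_features,
    label_rest_fraction,
    ua_window_flags,
    UA_WINDOW_S,
)
from ctgkit.signal import EventKind, FHRSeries, RuleConfig, UCMode
from ctgkit.simulate import (
    ScenarioSpec,
    ScriptedEvent,
    UAProfile,
    simulate_scenario,
    simulate_uc,
)

from conftest import make_flat_record


def _fhr(values, fs=4.0):
    values = np.asarray(values, dtype=float)
    return FHRSeries(0.0, fs, values, np.ones(len(values), bool))


def _mk_baseline(epoch_values, basal):
    v = np.asarray(epoch_values, dtype=float)
    return BaselineEstimate(basal, np.arange(len(v)) * 60.0, v, v.copy(),
                            np.ones(len(v), bool))


class TestBasalRate:
    def test_flat_trace(self):
        assert estimate_basal_rate(_fhr(np.full(4800, 140.0))) == pytest.approx(140.0)

    def test_decelerations_excluded_by_stability_selection(self):
        spec = ScenarioSpec(
            duration_min=30, basal_rate=140, noise_sd=1.0, seed=2,
            ua=UAProfile(jitter=0.0),
            script=[ScriptedEvent(EventKind.DECELERATION, 250, 400,
                                  {"depth_bpm": 40}),
                    ScriptedEvent(EventKind.DECELERATION, 650, 800,
                                  {"depth_bpm": 40})])
        rec, _ = simulate_scenario(spec)
        assert estimate_basal_rate(rec.fhr) == pytest.approx(140.0, abs=2.0)

    def test_all_invalid_window_is_indeterminate(self):
        n = 4800
        s = FHRSeries(0.0, 4.0, np.full(n, 140.0), np.zeros(n, bool))
        assert estimate_basal_rate(s) is None

    def test_short_record_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_basal_rate(_fhr(np.full(400, 140.0)))


class TestBaseline:
    def test_constant_trace(self):
        bl = estimate_baseline(_fhr(np.full(4 * 1800, 130.0)))
        assert np.allclose(bl.baseline, 130.0)

    def test_single_deceleration_does_not_bend_baseline(self):
        spec = ScenarioSpec(
            duration_min=30, basal_rate=130, noise_sd=0.0, seed=0,
            script=[ScriptedEvent(EventKind.DECELERATION, 900, 1000,
                                  {"depth_bpm": 40})])
        rec, _ = simulate_scenario(spec)
        bl = estimate_baseline(rec.fhr)
        assert np.nanmax(np.abs(bl.baseline - 130.0)) < 8.0

    def test_sustained_step_tracked_within_two_epochs(self):
        t = np.arange(4 * 3600) / 4.0
        vals = np.where(t < 1800, 130.0, 150.0)
        bl = estimate_baseline(_fhr(vals))
        # by epoch 32 (two past the step) the estimate sits at the new level
        assert bl.baseline[32] == pytest.approx(150.0, abs=2.0)
        assert bl.baseline[28] == pytest.approx(130.0, abs=2.0)


class TestVariability:
    def test_sinusoid_closed_form(self):
        """±10 bpm at 1 cpm: robust range ≈ 2·10·cos(0.05π) ≈ 19.75, 1 cpm."""
        t = np.arange(4 * 1200) / 4.0
        vals = 130 + 10 * np.sin(2 * np.pi * t / 60.0)
        fhr = _fhr(vals)
        var = compute_variability(fhr, estimate_baseline(fhr))
        assert np.nanmedian(var.amplitude) == pytest.approx(19.75, abs=1.0)
        assert np.nanmedian(var.frequency_cpm) == pytest.approx(1.0, abs=0.25)

    def test_flat_trace_zero_amplitude(self):
        fhr = _fhr(np.full(4 * 1200, 140.0))
        var = compute_variability(fhr, estimate_baseline(fhr))
        assert np.nanmax(var.amplitude) == pytest.approx(0.0, abs=1e-9)

    def test_simulated_amplitude_recovered(self):
        spec = ScenarioSpec(duration_min=30, variability_amplitude=10.0,
                            noise_sd=0.0, seed=7)
        rec, _ = simulate_scenario(spec)
        var = compute_variability(rec.fhr, estimate_baseline(rec.fhr))
        amps = var.amplitude[var.validity]
        assert np.mean((amps >= 7) & (amps <= 13)) >= 0.90


class TestRateEvents:
    def test_absolute_and_relative_tachycardia_coexist(self):
        ev = classify_rate(_mk_baseline([140] * 10 + [160] * 12 + [140] * 10, 140.0))
        kinds = sorted(e.kind.value for e in ev)
        assert kinds == ["tachycardia_absolute", "tachycardia_relative"]

    def test_relative_only_when_below_absolute_cut(self):
        ev = classify_rate(_mk_baseline([130] * 10 + [150] * 12 + [130] * 10, 130.0))
        assert [e.kind for e in ev] == [EventKind.TACHYCARDIA_RELATIVE]

    def test_short_run_not_sustained(self):
        assert classify_rate(_mk_baseline([140] * 10 + [160] * 8 + [140] * 10, 140.0)) == []

    def test_indeterminate_basal_gives_absolute_only(self):
        ev = classify_rate(_mk_baseline([160] * 12, None))
        assert [e.kind for e in ev] == [EventKind.TACHYCARDIA_ABSOLUTE]

    def test_bradycardia_thresholds(self):
        ev = classify_rate(_mk_baseline([105] * 12, 140.0))
        kinds = {e.kind for e in ev}
        assert kinds == {EventKind.BRADYCARDIA_ABSOLUTE, EventKind.BRADYCARDIA_RELATIVE}

    def test_robust_to_added_variability(self):
        """Rate events are unchanged by zero-mean variability ≤10 bpm."""
        spec_lo = ScenarioSpec(duration_min=35, variability_amplitude=2.0, seed=3,
                               script=[ScriptedEvent(EventKind.TACHYCARDIA_ABSOLUTE,
                                                     600, 1500, {"shift_bpm": 25})])
        spec_hi = ScenarioSpec(duration_min=35, variability_amplitude=10.0, seed=3,
                               script=spec_lo.script)
        for spec in (spec_lo, spec_hi):
            rec, _ = simulate_scenario(spec)
            ev = classify_rate(estimate_baseline(rec.fhr))
            assert EventKind.TACHYCARDIA_ABSOLUTE in {e.kind for e in ev}


class TestVariabilityEvents:
    def _mk_var(self, amps):
        from ctgkit.features import VariabilitySeries
        amps = np.asarray(amps, dtype=float)
        n = len(amps)
        return VariabilitySeries(np.arange(n) * 60.0, amps,
                                 np.full(n, 15.0), np.full(n, 0.5),
                                 np.ones(n, bool))

    def test_persistent_decreased(self):
        ev = classify_variability(self._mk_var([10] * 5 + [4] * 12 + [10] * 5))
        assert [e.kind for e in ev] == [EventKind.DECREASED_VARIABILITY]

    def test_transient_increased_kept_and_flagged(self):
        ev = classify_variability(self._mk_var([10] * 5 + [30] * 3 + [10] * 5))
        assert [e.kind for e in ev] == [EventKind.INCREASED_VARIABILITY]
        assert ev[0].attributes["transient"] is True

    def test_uniform_moderate_variability_silent(self):
        assert classify_variability(self._mk_var([10] * 20)) == []


class TestDecelerations:
    def test_late_timing_recovered(self):
        spec = ScenarioSpec(
            duration_min=30, noise_sd=1.0, seed=1, ua=UAProfile(jitter=0.0),
            script=[ScriptedEvent(EventKind.DECELERATION, 850, 1000,
                                  {"depth_bpm": 35, "timing": "late"})])
        rec, truth = simulate_scenario(spec)
        feats = extract_features(rec)
        assert len(feats.decelerations) == 1
        assert feats.decelerations[0].timing == "late"

    def test_shallow_dip_below_floor_ignored(self):
        spec = ScenarioSpec(
            duration_min=30, noise_sd=0.0, seed=1,
            script=[ScriptedEvent(EventKind.DECELERATION, 850, 1000,
                                  {"depth_bpm": 10 + 4})])
        rec, _ = simulate_scenario(spec)
        assert extract_features(rec).decelerations == []

    def test_two_scripted_decels_found_exactly(self):
        spec = ScenarioSpec(
            duration_min=35, noise_sd=0.0, seed=5, ua=UAProfile(jitter=0.0),
            script=[ScriptedEvent(EventKind.DECELERATION, 850, 1000,
                                  {"depth_bpm": 35}),
                    ScriptedEvent(EventKind.DECELERATION, 1450, 1600,
                                  {"depth_bpm": 45})])
        rec, truth = simulate_scenario(spec)
        feats = extract_features(rec)
        assert len(feats.decelerations) == 2
        truth_nadirs = sorted(e.attributes["t_nadir"] for e in truth.events
                              if e.kind is EventKind.DECELERATION)
        det_nadirs = sorted(d.t_nadir for d in feats.decelerations)
        assert np.allclose(det_nadirs, truth_nadirs, atol=5.0)

    @pytest.mark.parametrize("recovery", ["normal", "delayed_return",
                                          "overshoot", "peaked_return"])
    def test_recovery_morphologies_classified(self, recovery):
        spec = ScenarioSpec(
            duration_min=35, noise_sd=1.0, seed=8, ua=UAProfile(jitter=0.0),
            script=[ScriptedEvent(EventKind.DECELERATION, 1450, 1600,
                                  {"depth_bpm": 45, "recovery": recovery})])
        rec, _ = simulate_scenario(spec)
        recs = [d.recovery for d in extract_features(rec).decelerations]
        assert recovery in recs

    def test_truncated_decel_unresolved(self):
        spec = ScenarioSpec(
            duration_min=30, noise_sd=0.0, seed=1, ua=UAProfile(jitter=0.0),
            script=[ScriptedEvent(EventKind.DECELERATION, 1650, 1800,
                                  {"depth_bpm": 40, "recovery": "delayed_return",
                                   "recovery_len_s": 300.0, "tau_s": 70.0})])
        rec, _ = simulate_scenario(spec)
        feats = extract_features(rec)
        assert feats.decelerations[-1].recovery == "unresolved"


class TestSpecialPatterns:
    def _run(self, kind, params, seed=1):
        spec = ScenarioSpec(duration_min=35, noise_sd=1.0, seed=seed,
                            ua=UAProfile(jitter=0.03),
                            script=[ScriptedEvent(kind, 1200, 1560, params)])
        rec, _ = simulate_scenario(spec)
        return extract_features(rec).special_events

    def test_sinusoidal_covers_scripted_span(self):
        ev = [e for e in self._run(EventKind.SINUSOIDAL,
                                   {"amplitude_bpm": 7, "cpm": 4})
              if e.kind is EventKind.SINUSOIDAL]
        assert len(ev) == 1
        overlap = min(ev[0].t_end, 1560) - max(ev[0].t_start, 1200)
        assert overlap >= 0.8 * 360

    def test_sawtooth_detected(self):
        ev = self._run(EventKind.SAWTOOTH, {"amplitude_bpm": 8, "cpm": 25})
        assert EventKind.SAWTOOTH in {e.kind for e in ev}

    def test_checkmark_detected(self):
        ev = self._run(EventKind.CHECKMARK, {"amplitude_bpm": 20, "per_min": 1})
        assert EventKind.CHECKMARK in {e.kind for e in ev}

    def test_no_false_patterns_on_normal_variability(self):
        from ctgkit.simulate import normal_scenario
        for seed in range(20):
            rec, _ = simulate_scenario(normal_scenario(seed))
            assert extract_features(rec).special_events == []


class TestUterineActivityAnalysis:
    def test_frequency_flag_needs_two_windows(self):
        spec = ScenarioSpec(duration_min=30,
                            ua=UAProfile(frequency_per_10min=6, duration_s=75,
                                         jitter=0))
        uc, _ = simulate_uc(spec, 0)
        st = analyze_uterine_activity(uc)
        assert st.flags["frequency"].any()
        first = np.flatnonzero(st.flags["frequency"])[0]
        # the window one minute earlier already exceeds 5, per the doubling rule
        assert st.frequency[first - 1] > 5

    def test_average_parameters_raise_no_flags(self):
        spec = ScenarioSpec(duration_min=30,
                            ua=UAProfile(frequency_per_10min=3, duration_s=70,
                                         resting_tone=15, jitter=0))
        uc, _ = simulate_uc(spec, 0)
        st = analyze_uterine_activity(uc)
        assert not st.any_excessive().any()

    def test_short_interpeak_interval_flagged(self):
        spec = ScenarioSpec(duration_min=30,
                            ua=UAProfile(frequency_per_10min=6, duration_s=90,
                                         jitter=0))
        uc, _ = simulate_uc(spec, 0)
        st = analyze_uterine_activity(uc)
        assert st.flags["interval"].any()

    def test_long_duration_flagged(self):
        spec = ScenarioSpec(duration_min=30,
                            ua=UAProfile(frequency_per_10min=3, duration_s=100,
                                         jitter=0))
        uc, _ = simulate_uc(spec, 0)
        st = analyze_uterine_activity(uc)
        assert st.flags["duration"].any()

    def test_high_resting_tone_flagged_only_in_mmhg_mode(self):
        spec = ScenarioSpec(duration_min=30,
                            ua=UAProfile(resting_tone=25, jitter=0))
        uc, _ = simulate_uc(spec, 0)
        assert analyze_uterine_activity(uc).flags["resting_tone"].any()
        uc.mode = UCMode.EXTERNAL_RELATIVE
        assert not analyze_uterine_activity(uc).flags["resting_tone"].any()

    def test_flags_match_label_side_oracle(self):
        """Signal-side flags equal the predicates evaluated on ground-truth
        contraction labels (jitter-free)."""
        config = RuleConfig()
        profiles = [
            UAProfile(frequency_per_10min=3, duration_s=75, jitter=0),
            UAProfile(frequency_per_10min=6, duration_s=75, jitter=0),
            UAProfile(frequency_per_10min=3, duration_s=100, jitter=0),
            UAProfile(frequency_per_10min=3, duration_s=75, resting_tone=25, jitter=0),
            UAProfile(frequency_per_10min=5.5, duration_s=80, jitter=0),
        ]
        for k, ua in enumerate(profiles):
            spec = ScenarioSpec(duration_min=30, ua=ua, seed=k)
            uc, labels = simulate_uc(spec, k)
            st = analyze_uterine_activity(uc, config)
            peaks = np.array([e.attributes["peak_time"] for e in labels])
            durs = np.array([e.attributes["duration_s"] for e in labels])
            rest = label_rest_fraction(labels, st.window_starts)
            oracle = ua_window_flags(peaks, durs, ua.resting_tone, rest,
                                     st.window_starts, config, uc.mode)
            for name in oracle:
                assert np.array_equal(st.flags[name], oracle[name]), \
                    f"profile {k}: flag {name} diverges from label oracle"


class TestInitialWindowOnFlat(object):
    def test_flat_record_features(self, flat_record):
        feats = extract_features(flat_record)
        assert feats.baseline.basal_rate == pytest.approx(140.0)
        assert feats.decelerations == []
        assert feats.contractions == []
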