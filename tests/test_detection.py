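import numpy as np
import pytest

from colomotor.detection import (
    ClassificationThresholds,
    EventCandidate,
    Transient,
    classify_candidate,
    detect_events,
    detect_transients,
    estimate_baseline,
    estimate_velocity,
    event_parameters,
    gas_association,
    group_transients,
    sphincter_association,
)
from colomotor.recording_io import PhaseWindow
from colomotor.synthetic import (
    ArtifactSpec,
    IsolatedTransientSpec,
    PropagatingWaveSpec,
    ScenarioConfig,
    SphincterSpec,
    SPWTrainSpec,
    generate_recording,
)

from conftest import add_pulse, make_recording

FS = 10.0


class TestBaseline:
    def test_constant_trace(self):
        base = estimate_baseline(np.full(2000, 10.0), FS)
        assert np.allclose(base, 10.0)

    def test_short_pulse_does_not_lift_baseline(self):
        trace = np.full(2000, 10.0)
        trace[1000:1050] += 20.0  # 5-s pulse inside a 60-s window
        base = estimate_baseline(trace, FS)
        assert np.all(np.abs(base[1000:1050] - 10.0) < 0.5)

    def test_tracks_linear_drift(self):
        t = np.arange(6000) / FS
        trace = 0.02 * t
        base = estimate_baseline(trace, FS)
        # rolling 10th percentile of a ramp sits 40% of a window below the signal
        mid = slice(1000, 5000)
        lag = trace[mid] - base[mid]
        assert np.all(lag < 0.02 * 60)

    def test_percentile_oracle(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 1, 1200)
        base = estimate_baseline(trace, FS, window_s=60.0)
        i = 600
        w = 600
        expected = np.percentile(trace[i - w // 2 : i + w // 2], 10)
        assert base[i] == pytest.approx(expected, abs=0.2)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.full(100, np.nan), FS)


class TestDetectTransients:
    def test_pulse_detected_with_amplitude(self):
        rec = make_recording(n_sensors=4, tone=10.0)
        add_pulse(rec, 2, 60.0, 10.0, 5.0)
        out = detect_transients(rec)
        assert [len(lst) for lst in out] == [0, 1, 0, 0]
        tr = out[1][0]
        assert tr.amplitude == pytest.approx(10.0, abs=0.5)
        assert tr.onset_s < tr.peak_s <= tr.offset_s

    def test_subthreshold_pulse_ignored(self):
        rec = make_recording(n_sensors=4)
        add_pulse(rec, 2, 60.0, 4.0, 5.0)
        assert all(len(lst) == 0 for lst in detect_transients(rec))

    def test_close_pulses_merged(self):
        rec = make_recording(n_sensors=1)
        add_pulse(rec, 1, 60.0, 10.0, 4.0)
        add_pulse(rec, 1, 65.0, 12.0, 4.0)  # 1-s gap
        out = detect_transients(rec)
        assert len(out[0]) == 1
        assert out[0][0].amplitude == pytest.approx(12.0, abs=0.5)

    def test_distant_pulses_kept_separate(self):
        rec = make_recording(n_sensors=1)
        add_pulse(rec, 1, 40.0, 10.0, 4.0)
        add_pulse(rec, 1, 80.0, 10.0, 4.0)
        assert len(detect_transients(rec)[0]) == 2

    def test_masked_onsets_dropped(self):
        rec = make_recording(n_sensors=1)
        add_pulse(rec, 1, 60.0, 10.0, 4.0)
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[550:650] = True
        assert detect_transients(rec, mask=mask) == [[]]

    def test_broken_sensor_skipped(self):
        rec = make_recording(n_sensors=2)
        add_pulse(rec, 1, 60.0, 10.0, 4.0)
        rec.functional_mask[0] = False
        assert detect_transients(rec)[0] == []


class TestGroupTransients:
    def _transients(self, spec):
        """spec: list of (sensor, onset)"""
        per = [[] for _ in range(36)]
        for s, t in spec:
            per[s - 1].append(Transient(s, t, t + 5.0, t + 1.0, 20.0))
        return per

    def test_simultaneous_full_array_one_candidate(self):
        per = self._transients([(s, 100.0 + 0.01 * s) for s in range(1, 37)])
        cands = group_transients(per)
        assert len(cands) == 1 and len(cands[0].sensors) == 36

    def test_disjoint_sensors_stay_separate(self):
        per = self._transients([(5, 100.0), (20, 100.0)])
        assert len(group_transients(per)) == 2

    def test_staircase_chains_across_sensors(self):
        per = self._transients([(s, 100.0 + 0.2 * s) for s in range(10, 25)])
        cands = group_transients(per)
        assert len(cands) == 1 and len(cands[0].sensors) == 15

    def test_gap_beyond_window_breaks_chain(self):
        per = self._transients([(10, 100.0), (11, 103.0)])
        assert len(group_transients(per)) == 2

    def test_each_transient_in_exactly_one_candidate(self):
        per = self._transients(
            [(s, 100.0) for s in range(1, 20)] + [(s, 101.0) for s in range(5, 15)]
        )
        cands = group_transients(per)
        total = sum(len(c.members) for c in cands)
        assert total == 19 + 10


class TestEstimateVelocity:
    def _candidate(self, onsets):
        members = [Transient(s, t, t + 5, t + 1, 20.0) for s, t in onsets.items()]
        return EventCandidate(members)

    def test_antegrade_five_cm_per_s(self):
        onsets = {s: 100.0 + (30 - s) * 0.2 for s in range(10, 31)}
        v = estimate_velocity(self._candidate(onsets), 1.0)
        assert v == pytest.approx(5.0, rel=1e-6)

    def test_retrograde_one_cm_per_s(self):
        onsets = {s: 100.0 + (s - 10) * 1.0 for s in range(10, 21)}
        v = estimate_velocity(self._candidate(onsets), 1.0)
        assert v == pytest.approx(-1.0, rel=1e-6)

    def test_identical_onsets_simultaneous(self):
        onsets = {s: 100.0 for s in range(1, 37)}
        assert estimate_velocity(self._candidate(onsets), 1.0) == "simultaneous"

    def test_random_onsets_simultaneous(self):
        rng = np.random.default_rng(0)
        onsets = {s: 100.0 + rng.uniform(0, 0.3) for s in range(1, 37)}
        assert estimate_velocity(self._candidate(onsets), 1.0) == "simultaneous"

    def test_fast_wave_reported_simultaneous(self):
        onsets = {s: 100.0 + (36 - s) * 0.05 for s in range(1, 37)}  # 20 cm/s
        assert estimate_velocity(self._candidate(onsets), 1.0) == "simultaneous"

    def test_two_sensors_undefined(self):
        onsets = {10: 100.0, 11: 100.5}
        assert estimate_velocity(self._candidate(onsets), 1.0) is None


class TestClassification:
    def _cand(self, sensors, amp=20.0, dur=15.0, onset=100.0):
        members = [Transient(s, onset, onset + dur, onset + 2, amp) for s in sensors]
        return EventCandidate(members)

    def test_simultaneous_wide_long_event_is_spw(self):
        evs = classify_candidate(self._cand(range(1, 37), amp=14.0), "simultaneous")
        assert [e.kind for e in evs] == ["SPW"]
        assert evs[0].span_cm == 35.0

    def test_propagating_event_is_apw(self):
        evs = classify_candidate(self._cand(range(10, 22), amp=30.0), 5.0)
        assert [e.kind for e in evs] == ["APW"]

    def test_negative_velocity_is_rpw(self):
        evs = classify_candidate(self._cand(range(10, 22), amp=30.0), -2.0)
        assert [e.kind for e in evs] == ["RPW"]

    def test_high_amplitude_takes_precedence(self):
        evs = classify_candidate(self._cand(range(10, 16), amp=120.0), 1.0)
        assert [e.kind for e in evs] == ["HAPW"]

    def test_single_sensor_is_isolated(self):
        evs = classify_candidate(self._cand([7], amp=60.0), None)
        assert [e.kind for e in evs] == ["isolated_transient"]

    def test_short_simultaneous_falls_back_to_isolated(self):
        evs = classify_candidate(self._cand(range(1, 37), dur=1.0), "simultaneous")
        assert all(e.kind == "isolated_transient" for e in evs)
        assert len(evs) == 36

    def test_narrow_simultaneous_falls_back(self):
        evs = classify_candidate(self._cand(range(10, 18)), "simultaneous")
        assert all(e.kind == "isolated_transient" for e in evs)

    def test_classes_exhaustive(self):
        # every candidate yields at least one event of a known class
        for sensors, v in [(range(1, 37), "simultaneous"), ([5], None), (range(4, 9), 2.0)]:
            evs = classify_candidate(self._cand(sensors), v)
            assert evs and all(
                e.kind in ("SPW", "APW", "RPW", "HAPW", "isolated_transient") for e in evs
            )


class TestEventParameters:
    def test_span_and_mean_amplitude(self):
        rec = make_recording()
        amps = np.linspace(10, 20, 15)
        for i, s in enumerate(range(5, 20)):
            add_pulse(rec, s, 60.0, amps[i], 10.0)
        res = detect_events(rec, artifact_mode="none")
        evs = [e for e in res.events if len(e.members) > 1]
        assert len(evs) == 1
        ev = evs[0]
        assert ev.span_cm == 14.0
        assert ev.amplitude_mean == pytest.approx(15.0, abs=1.0)
        assert ev.amplitude_max == pytest.approx(20.0, abs=0.5)


class TestVelocityAccuracy:
    @pytest.mark.parametrize("v", [0.6, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    def test_relative_error_within_ten_percent(self, v):
        cfg = ScenarioConfig(
            duration_s=120, seed=0, noise_sd=0,
            pattern_specs=[PropagatingWaveSpec(velocity=v, times=[40], span=(5, 30), amplitude=30, amplitude_cv=0)],
        )
        rec, _, _ = generate_recording(cfg)
        evs = [e for e in detect_events(rec, artifact_mode="none").events if e.kind == "APW"]
        assert len(evs) == 1
        assert abs(abs(evs[0].velocity) - v) / v <= 0.10

    @pytest.mark.parametrize("v", [10.0, 20.0, 100.0])
    def test_fast_waves_reported_simultaneous(self, v):
        cfg = ScenarioConfig(
            duration_s=120, seed=0, noise_sd=0,
            pattern_specs=[PropagatingWaveSpec(velocity=v, times=[40], span=(1, 36), amplitude=20, amplitude_cv=0, rise_s=4, decay_s=8)],
        )
        rec, _, _ = generate_recording(cfg)
        evs = detect_events(rec, artifact_mode="none").events
        assert all(e.velocity == "simultaneous" for e in evs)


class TestOffsetInvariance:
    def test_constant_offset_does_not_change_classification(self):
        cfg = ScenarioConfig(
            duration_s=180, seed=3, noise_sd=1.0,
            pattern_specs=[
                SPWTrainSpec(times=[50], gas_fraction=0),
                PropagatingWaveSpec(velocity=3.0, times=[120], span=(10, 24)),
            ],
        )
        rec, _, _ = generate_recording(cfg)
        kinds1 = [e.kind for e in detect_events(rec, artifact_mode="none").events]
        rec.pressures += 40.0
        kinds2 = [e.kind for e in detect_events(rec, artifact_mode="none").events]
        assert kinds1 == kinds2 and "SPW" in kinds1


class TestSphincterAssociation:
    def _pullback_scenario(self, with_cough=False):
        dur = 400.0
        specs = [SPWTrainSpec(times=[100.0, 200.0, 300.0], gas_fraction=0)]
        if with_cough:
            specs.append(ArtifactSpec(subtype="cough", times=[150.0]))
        return ScenarioConfig(
            duration_s=dur, seed=2, noise_sd=1.0,
            phases=[PhaseWindow("sphincter_pullback", 0.0, dur)],
            sphincter=SphincterSpec(),
            pattern_specs=specs,
        )

    def test_spws_marked_relaxing(self):
        rec, _, _ = generate_recording(self._pullback_scenario())
        res = detect_events(rec, artifact_mode="none")
        spws = [e for e in res.events if e.kind == "SPW"]
        assert len(spws) == 3
        assert all(e.sphincter_relaxation == "yes" for e in spws)

    def test_without_pullback_phase_undetermined(self):
        cfg = ScenarioConfig(
            duration_s=200, seed=2, noise_sd=1.0,
            pattern_specs=[SPWTrainSpec(times=[100.0], gas_fraction=0)],
        )
        rec, _, _ = generate_recording(cfg)
        res = detect_events(rec, artifact_mode="none")
        spws = [e for e in res.events if e.kind == "SPW"]
        assert spws and all(e.sphincter_relaxation == "undetermined" for e in spws)


class TestGasAssociation:
    def test_constructed_fractions(self):
        times = [30.0 + 35.0 * k for k in range(32)]
        cfg = ScenarioConfig(
            duration_s=1200, seed=4, noise_sd=1.0,
            pattern_specs=[SPWTrainSpec(times=times, gas_fraction=9 / 32)],
        )
        rec, _, ann = generate_recording(cfg)
        res = detect_events(rec, annotations=ann, artifact_mode="none")
        assert res.gas_summary["n_spw"] == 32
        assert res.gas_summary["frac_spws_gas_associated"] == pytest.approx(9 / 32)
        assert res.gas_summary["frac_gas_with_spw"] == 1.0

    def test_orphan_gas_annotation_lowers_converse_fraction(self):
        from colomotor.recording_io import Annotation, AnnotationLog

        cfg = ScenarioConfig(
            duration_s=300, seed=4, noise_sd=1.0,
            pattern_specs=[SPWTrainSpec(times=[100.0], gas_fraction=0)],
        )
        rec, _, _ = generate_recording(cfg)
        log = AnnotationLog([Annotation(250.0, "gas_expulsion", "")])
        res = detect_events(rec, annotations=log, artifact_mode="none")
        assert res.gas_summary["frac_gas_with_spw"] == 0.0
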