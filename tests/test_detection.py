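import itertools

import numpy as np
import pytest

from hintspy.detection import (
    CENTRAL_PATTERN,
    CatchUpResult,
    HeadImpulse,
    INDETERMINATE,
    NYSTAGMUS_NONE,
    NYSTAGMUS_UNIDIRECTIONAL,
    NYSTAGMUS_VERTICAL,
    NystagmusFinding,
    PERIPHERAL_PATTERN,
    SkewFinding,
    characterize_nystagmus,
    classify_hints,
    detect_catch_up_saccades,
    detect_head_impulses,
    detect_saccades,
    detect_skew,
    direction_change_across_gaze,
)
from hintspy.errors import AlignmentError, ContractError, InsufficientDataError
from hintspy.kinematics import (
    FeatureSeries,
    eye_horizontal_velocity,
    gaze_component,
    head_yaw_velocity,
    vertical_position_by_eye,
)
from hintspy.recording_io import trim_initial
from hintspy.simulate import (
    ORIGIN_SCALE,
    SimulationProfile,
    simulate_cover_test,
    simulate_fixation,
    simulate_head_impulse_stage,
)


def _vel(values, rate=60.0, units="deg/s"):
    values = np.asarray(values, float)
    return FeatureSeries(np.arange(len(values)) / rate, values, units)


class TestDetectSaccades:
    def test_zero_series_empty(self):
        assert detect_saccades(_vel(np.zeros(100))) == []

    def test_wrong_units_contract_error(self):
        s = FeatureSeries(np.arange(5) / 60, np.zeros(5), "m")
        with pytest.raises(ContractError):
            detect_saccades(s)

    def test_fixed_mode_needs_threshold(self):
        with pytest.raises(ContractError):
            detect_saccades(_vel(np.zeros(10)), threshold_mode="fixed")

    def test_single_injected_event(self):
        v = np.zeros(200)
        v[100:104] = [50.0, 120.0, 80.0, 30.0]
        events = detect_saccades(_vel(v), threshold_mode="fixed", threshold=20.0)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(101 / 60, abs=1 / 60)
        assert events[0].peak_velocity == pytest.approx(120.0)
        assert events[0].direction == 1

    def test_five_injected_events_counted(self):
        v = np.zeros(600)
        for k in range(5):
            v[50 + 100 * k: 53 + 100 * k] = 100.0 * (-1) ** k
        events = detect_saccades(_vel(v), threshold_mode="fixed", threshold=30.0)
        assert len(events) == 5
        assert [e.direction for e in events] == [1, -1, 1, -1, 1]

    def test_gap_of_one_frame_merged(self):
        v = np.zeros(100)
        v[40:43] = 100.0
        v[43] = 0.0
        v[44:46] = 100.0
        events = detect_saccades(_vel(v), threshold_mode="fixed", threshold=30.0)
        assert len(events) == 1

    def test_time_reversal_reflects_events(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 400)
        v[100:104] += 60.0
        v[300:303] -= 45.0
        t = np.arange(400) / 60
        fwd = detect_saccades(_vel(v), threshold_mode="fixed", threshold=20.0)
        rev = detect_saccades(
            FeatureSeries(t, -v[::-1], "deg/s"),
            threshold_mode="fixed", threshold=20.0,
        )
        T = t[-1]
        assert len(fwd) == len(rev)
        for f, r in zip(fwd, reversed(rev)):
            assert r.onset == pytest.approx(T - f.offset, abs=1e-9)
            assert r.offset == pytest.approx(T - f.onset, abs=1e-9)
            assert r.direction == -f.direction
            assert r.peak_velocity == pytest.approx(f.peak_velocity)

    def test_adaptive_threshold_scale_free(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1.0, 1000)
        base[500:504] += 30.0
        for scale in (1.0, 1000.0):
            events = detect_saccades(_vel(base * scale))
            assert len(events) == 1


class TestDetectHeadImpulses:
    def _impulse_series(self, peak):
        rec, _ = simulate_head_impulse_stage(
            SimulationProfile.healthy(noise_sd=0), "left",
            n_impulses=1, peak_velocity=peak, seed=0,
        )
        return head_yaw_velocity(trim_initial(rec, 2.0))

    def test_peak_160_is_adequate(self):
        imps = detect_head_impulses(self._impulse_series(160.0))
        assert len(imps) == 1 and imps[0].adequate

    def test_peak_140_is_inadequate(self):
        imps = detect_head_impulses(self._impulse_series(140.0))
        assert len(imps) == 1 and not imps[0].adequate

    def test_stationary_head_empty(self):
        assert detect_head_impulses(_vel(np.zeros(300))) == []

    def test_wrong_units_rejected(self):
        with pytest.raises(ContractError):
            detect_head_impulses(_vel(np.zeros(10), units="m/s"))

    def test_adequacy_boundary_bisects_to_threshold(self):
        """Bisection over the generator peak localizes the 150 deg/s
        adequacy boundary to within 1 deg/s."""

        def adequate(peak):
            imps = detect_head_impulses(self._impulse_series(peak))
            return len(imps) == 1 and imps[0].adequate

        lo, hi = 120.0, 180.0
        assert not adequate(lo) and adequate(hi)
        while hi - lo > 0.5:
            mid = 0.5 * (lo + hi)
            if adequate(mid):
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(150.0, abs=1.0)


class TestCatchUpSaccades:
    @staticmethod
    def _analyze(profile, side):
        rec, gt = simulate_head_impulse_stage(profile, side, seed=0)
        rec = trim_initial(rec, 2.0)
        head = head_yaw_velocity(rec)
        eye = eye_horizontal_velocity(rec)
        imps = detect_head_impulses(head)
        return imps, detect_catch_up_saccades(eye, imps), gt

    def test_peripheral_ipsilesional_catch_up_every_impulse(self):
        prof = SimulationProfile.peripheral(noise_sd=0)  # left lesion
        imps, result, gt = self._analyze(prof, "left")
        assert len(imps) == 5
        for i, imp in enumerate(imps):
            assert imp.adequate
            assert len(result.by_impulse[i]) >= 1
            sac = result.by_impulse[i][0]
            assert sac.direction == -imp.direction

    def test_peripheral_contralesional_none(self):
        prof = SimulationProfile.peripheral(noise_sd=0)
        _, result, _ = self._analyze(prof, "right")
        assert not result.any_catch_up()

    def test_healthy_no_catch_up(self):
        _, result, _ = self._analyze(SimulationProfile.healthy(noise_sd=0), "left")
        assert not result.any_catch_up()
        assert not result.not_testable

    def test_inadequate_impulses_not_testable(self):
        prof = SimulationProfile.healthy(noise_sd=0, impulse_peak_velocity=140.0)
        _, result, _ = self._analyze(prof, "left")
        assert result.not_testable
        assert not result.any_catch_up()


class TestCharacterizeNystagmus:
    def test_flat_noise_absent(self):
        rng = np.random.default_rng(2)
        t = np.arange(480) / 60
        s = FeatureSeries(t, rng.normal(0, 0.002, 480), "unit-vector component")
        f = characterize_nystagmus(s, "horizontal")
        assert not f.present

    def test_sawtooth_parameter_recovery(self):
        spv, freq = 0.08, 2.0
        prof = SimulationProfile.peripheral(spv=spv, beat_frequency=freq)
        rec, _ = simulate_fixation(prof, "spontaneous", 10.0, seed=11)
        rec = trim_initial(rec, 2.0)
        series = gaze_component(rec, "horizontal-x", "left-plus-right")
        f = characterize_nystagmus(series, "horizontal")
        assert f.present
        assert f.beat_frequency == pytest.approx(freq, rel=0.10)
        # the left-plus-right series drifts at twice the single-eye SPV
        assert f.slow_phase_velocity == pytest.approx(2 * spv, rel=0.15)
        assert f.beat_direction == 1

    def test_downbeat_recognized_in_vertical_plane(self):
        prof = SimulationProfile.central(variant="downbeat", noise_sd=0)
        rec, _ = simulate_fixation(prof, "spontaneous", 10.0, seed=3)
        rec = trim_initial(rec, 2.0)
        series = gaze_component(rec, "vertical-y", "left-plus-right")
        f = characterize_nystagmus(series, "vertical")
        assert f.present
        assert f.plane == "vertical"
        assert f.beat_direction == "down"

    def test_short_series_rejected(self):
        s = FeatureSeries(np.arange(60) / 60, np.zeros(60), "unit-vector component")
        with pytest.raises(InsufficientDataError):
            characterize_nystagmus(s, "horizontal")


class TestDirectionChange:
    @staticmethod
    def _finding(present, direction):
        return NystagmusFinding(
            present=present, plane="horizontal", beat_direction=direction,
            slow_phase_velocity=0.1 if present else 0.0,
            beat_frequency=2.0 if present else 0.0,
        )

    def test_central_gaze_evoked_true(self):
        findings = {
            "gaze_left": self._finding(True, -1),
            "gaze_right": self._finding(True, 1),
        }
        assert direction_change_across_gaze(findings) is True

    def test_peripheral_fixed_direction_false(self):
        findings = {
            "gaze_left": self._finding(True, 1),
            "gaze_right": self._finding(True, 1),
        }
        assert direction_change_across_gaze(findings) is False

    def test_absent_both_false(self):
        findings = {
            "gaze_left": self._finding(False, None),
            "gaze_right": self._finding(False, None),
        }
        assert direction_change_across_gaze(findings) is False

    def test_missing_stage_not_testable(self):
        assert direction_change_across_gaze(
            {"gaze_left": self._finding(True, 1)}
        ) is None


class TestDetectSkew:
    @staticmethod
    def _series(profile, seed=0):
        rec, gt = simulate_cover_test(profile, seed=seed)
        rec = trim_initial(rec, 2.0)
        off = rec.quality.trim_offset
        cover = [c - off for c in gt.cover_switches if c - off >= 0]
        left_y, right_y = vertical_position_by_eye(rec)
        return left_y, right_y, cover, gt

    def test_healthy_absent(self):
        left_y, right_y, cover, _ = self._series(SimulationProfile.healthy())
        f = detect_skew(left_y, right_y, cover, floor=0.00025)
        assert not f.present

    def test_skew_recovered_with_refixations(self):
        delta = 0.02  # 5x the direction-channel noise SD at default noise
        prof = SimulationProfile.central(skew_offset=delta)
        left_y, right_y, cover, gt = self._series(prof, seed=4)
        f = detect_skew(left_y, right_y, cover, floor=0.00025)
        assert f.present
        assert f.vertical_disparity == pytest.approx(delta * ORIGIN_SCALE, rel=0.25)
        assert f.matched_switch_fraction >= 0.8

    def test_empty_cover_times_zero_disparity_absent(self):
        t = np.arange(300) / 60
        z = FeatureSeries(t, np.zeros(300), "m")
        f = detect_skew(z, z, cover_times=[], floor=1e-4)
        assert not f.present

    def test_misaligned_series_rejected(self):
        a = FeatureSeries(np.arange(10) / 60, np.zeros(10), "m")
        b = FeatureSeries(np.arange(9) / 60, np.zeros(9), "m")
        with pytest.raises(AlignmentError):
            detect_skew(a, b)


def _mk_impulses(adequate=True, n=2):
    return [
        HeadImpulse(
            onset=1.0 + 3 * i, offset=1.2 + 3 * i, peak_time=1.1 + 3 * i,
            peak_angular_velocity=200.0 if adequate else 100.0,
            direction=1, adequate=adequate,
        )
        for i in range(n)
    ]


def _mk_catch_up(impulses, present):
    sac = None
    if present:
        from hintspy.detection import SaccadeEvent

        sac = SaccadeEvent(
            onset=1.3, offset=1.35, peak_time=1.32, peak_velocity=100.0,
            amplitude=-0.1, direction=-1, threshold=10.0,
        )
    return CatchUpResult(
        by_impulse={
            i: ([sac] if present else []) for i in range(len(impulses))
        },
        not_testable=not any(im.adequate for im in impulses),
    )


def _mk_nystagmus(kind):
    mk = TestDirectionChange._finding
    if kind == NYSTAGMUS_NONE:
        return {"gaze_left": mk(False, None), "gaze_right": mk(False, None)}
    if kind == NYSTAGMUS_UNIDIRECTIONAL:
        return {"gaze_left": mk(True, 1), "gaze_right": mk(True, 1)}
    if kind == "direction-changing":
        return {"gaze_left": mk(True, -1), "gaze_right": mk(True, 1)}
    if kind == NYSTAGMUS_VERTICAL:
        f = NystagmusFinding(
            present=True, plane="vertical", beat_direction="down",
            slow_phase_velocity=0.1, beat_frequency=2.0,
        )
        return {"gaze_left": f, "gaze_right": f}
    raise ValueError(kind)


def _mk_skew(present):
    if present is None:
        return None
    return SkewFinding(present=present, vertical_disparity=0.001 if present else 0.0)


class TestClassifyHints:
    def test_peripheral_triad(self):
        imps = _mk_impulses(adequate=True)
        res = classify_hints(
            imps, _mk_catch_up(imps, True),
            _mk_nystagmus(NYSTAGMUS_UNIDIRECTIONAL), _mk_skew(False),
        )
        assert res.triage == PERIPHERAL_PATTERN
        assert res.predicted_group == "peripheral"

    def test_normal_hit_with_nystagmus_is_central(self):
        imps = _mk_impulses(adequate=True)
        res = classify_hints(
            imps, _mk_catch_up(imps, False),
            _mk_nystagmus(NYSTAGMUS_UNIDIRECTIONAL), _mk_skew(False),
        )
        assert res.triage == CENTRAL_PATTERN

    def test_skew_forces_central_regardless(self):
        imps = _mk_impulses(adequate=True)
        res = classify_hints(
            imps, _mk_catch_up(imps, True),
            _mk_nystagmus(NYSTAGMUS_UNIDIRECTIONAL), _mk_skew(True),
        )
        assert res.triage == CENTRAL_PATTERN

    def test_vertical_nystagmus_forces_central(self):
        imps = _mk_impulses(adequate=True)
        res = classify_hints(
            imps, _mk_catch_up(imps, True),
            _mk_nystagmus(NYSTAGMUS_VERTICAL), _mk_skew(False),
        )
        assert res.triage == CENTRAL_PATTERN

    def test_no_findings_maps_to_healthy(self):
        imps = _mk_impulses(adequate=True)
        res = classify_hints(
            imps, _mk_catch_up(imps, False),
            _mk_nystagmus(NYSTAGMUS_NONE), _mk_skew(False),
        )
        assert res.triage == INDETERMINATE
        assert res.predicted_group == "healthy"

    def test_nothing_testable_indeterminate_with_reason(self):
        imps = _mk_impulses(adequate=False)
        res = classify_hints(
            imps, _mk_catch_up(imps, False),
            _mk_nystagmus(NYSTAGMUS_NONE), _mk_skew(None),
        )
        assert res.triage == INDETERMINATE
        assert "reason" in res.evidence

    def test_abnormal_hit_without_skew_test_stays_cautious(self):
        imps = _mk_impulses(adequate=True)
        res = classify_hints(
            imps, _mk_catch_up(imps, True),
            _mk_nystagmus(NYSTAGMUS_UNIDIRECTIONAL), _mk_skew(None),
        )
        assert res.triage == INDETERMINATE

    def test_safety_monotonicity(self):
        """Flipping any single finding from benign to dangerous never moves
        the triage from central toward peripheral."""
        rank = {PERIPHERAL_PATTERN: 0, INDETERMINATE: 1, CENTRAL_PATTERN: 2}
        hit_options = [(True, True), (True, False), (False, False)]
        nyst_options = [
            NYSTAGMUS_NONE, NYSTAGMUS_UNIDIRECTIONAL,
            "direction-changing", NYSTAGMUS_VERTICAL,
        ]
        skew_options = [False, True, None]
        danger_steps = {
            "nystagmus": [(NYSTAGMUS_UNIDIRECTIONAL, NYSTAGMUS_VERTICAL),
                          (NYSTAGMUS_UNIDIRECTIONAL, "direction-changing")],
            "skew": [(False, True)],
            "hit": [((True, True), (True, False))],
        }

        def triage(hit, nyst, skew):
            adequate, catch = hit
            imps = _mk_impulses(adequate=adequate)
            return classify_hints(
                imps, _mk_catch_up(imps, catch), _mk_nystagmus(nyst),
                _mk_skew(skew),
            ).triage

        for hit, nyst, skew in itertools.product(
            hit_options, nyst_options, skew_options
        ):
            base = triage(hit, nyst, skew)
            for a, b in danger_steps["nystagmus"]:
                if nyst == a:
                    assert rank[triage(hit, b, skew)] >= rank[base]
            for a, b in danger_steps["skew"]:
                if skew == a:
                    assert rank[triage(hit, nyst, b)] >= rank[base]
            for a, b in danger_steps["hit"]:
                if hit == a and nyst != NYSTAGMUS_NONE:
                    assert rank[triage(b, nyst, skew)] >= rank[base]
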