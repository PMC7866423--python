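"""Cycle detection, time normalization, kinematic and phase statistics."""

import numpy as np
import pytest

from strokekin.body import JointAngleSeries
from strokekin.simulate import StrokeParams, gen_joint_trajectory
from strokekin.stroke import (
    PHASES,
    UNLABELED,
    PhaseSegmentation,
    detect_cycles,
    kinematic_summary,
    mean_cycle_curve,
    phase_durations,
    symmetry_correlation,
    time_normalize,
)
from tests.conftest import zero_noise_params


def sinusoid_series(freq=1.0, fs=100.0, dur=10.0, mean=60.0, amp=30.0):
    t = np.arange(int(dur * fs)) / fs
    x = mean + amp * np.sin(2 * np.pi * freq * t)
    return JointAngleSeries(
        sample_rate_hz=fs,
        channels={c: x.copy() for c in JointAngleSeries.CHANNELS})


class TestDetectCycles:
    def test_one_hz_sinusoid_yields_nine_cycles(self):
        cycles = detect_cycles(sinusoid_series(), "left")
        assert len(cycles) == 9
        lengths = [b - a for a, b in cycles.intervals]
        np.testing.assert_allclose(lengths, 100, atol=1)

    def test_constant_signal_yields_empty(self):
        series = JointAngleSeries(
            sample_rate_hz=100.0,
            channels={c: np.full(500, 42.0)
                      for c in JointAngleSeries.CHANNELS})
        with pytest.warns(UserWarning, match="peaks"):
            cycles = detect_cycles(series, "right")
        assert len(cycles) == 0

    def test_simulator_script_cycle_count(self):
        params = zero_noise_params(n_cycles=10)
        series, _ = gen_joint_trajectory(params)
        cycles = detect_cycles(series, "left")
        assert 9 <= len(cycles) <= 10

    def test_count_scales_with_recording_length(self):
        c1 = detect_cycles(sinusoid_series(dur=10.0), "left")
        c2 = detect_cycles(sinusoid_series(dur=20.0), "left")
        assert len(c2) == 2 * len(c1) + 1  # 19 vs 9 full periods


class TestTimeNormalize:
    def test_linear_ramp_exact(self):
        x = np.linspace(0.0, 50.0, 200)
        curve = time_normalize(x, (0, 200), n_points=101)
        np.testing.assert_allclose(curve, np.linspace(0, 50, 101) *
                                   (x[199] / 50.0), atol=1e-9)
        assert curve[0] == x[0] and curve[-1] == x[199]

    def test_output_length(self):
        curve = time_normalize(np.sin(np.arange(50) / 5), (5, 45))
        assert len(curve) == 101

    def test_two_stage_resampling_consistency(self):
        # one stroke-like period per cycle
        x = 60 + 20 * np.sin(2 * np.pi * np.arange(300) / 280.0)
        direct = time_normalize(x, (10, 290), n_points=101)
        half = time_normalize(x, (10, 290), n_points=51)
        again = time_normalize(half, (0, 51), n_points=101)
        assert np.max(np.abs(direct - again)) < 0.1

    def test_degenerate_cycle_rejected(self):
        with pytest.raises(ValueError, match="short"):
            time_normalize(np.arange(10.0), (4, 6))


class TestKinematicSummary:
    def test_constant_signal(self):
        series = JointAngleSeries(
            sample_rate_hz=100.0,
            channels={c: np.full(400, 90.0)
                      for c in JointAngleSeries.CHANNELS})
        cycles = {"left": type(detect_cycles(series, "left"))(
            side="left", intervals=[(0, 200), (200, 400)],
            sample_rate_hz=100.0)}
        out = kinematic_summary(series, cycles)
        stats = out["left"]["EFl"]
        assert stats["ROM"]["mean"] == 0
        assert stats["MAX"]["mean"] == stats["MIN"]["mean"] == 90.0

    def test_sinusoid_closed_form(self):
        series = sinusoid_series(mean=100.0, amp=25.0)
        cycles = {"left": detect_cycles(series, "left")}
        out = kinematic_summary(series, cycles)
        stats = out["left"]["SFl"]
        assert stats["ROM"]["mean"] == pytest.approx(50.0, abs=0.1)
        assert stats["MEAN"]["mean"] == pytest.approx(100.0, abs=0.5)

    def test_rom_equals_max_minus_min(self, small_bundle):
        series = small_bundle.truth_angles
        cycles = {s: detect_cycles(series, s) for s in ("left", "right")}
        out = kinematic_summary(series, cycles)
        for side in out:
            for ch, stats in out[side].items():
                assert stats["MIN"]["mean"] <= stats["MEAN"]["mean"] <= \
                    stats["MAX"]["mean"]
                # mean ROM equals mean(MAX) - mean(MIN) by linearity
                assert stats["ROM"]["mean"] == pytest.approx(
                    stats["MAX"]["mean"] - stats["MIN"]["mean"], abs=1e-9)

    def test_invariant_to_time_shift(self):
        series = sinusoid_series()
        shifted = JointAngleSeries(
            sample_rate_hz=series.sample_rate_hz,
            channels={c: x.copy() for c, x in series.channels.items()})
        cycles = detect_cycles(series, "left")
        shift_cycles = type(cycles)(
            side="left",
            intervals=[(a + 100, b + 100) for a, b in cycles.intervals[:-1]],
            sample_rate_hz=100.0)
        out1 = kinematic_summary(series, {"left": type(cycles)(
            side="left", intervals=cycles.intervals[:-1],
            sample_rate_hz=100.0)})
        out2 = kinematic_summary(shifted, {"left": shift_cycles})
        assert out1["left"]["EFl"]["ROM"]["mean"] == pytest.approx(
            out2["left"]["EFl"]["ROM"]["mean"], abs=1e-6)


class TestSymmetry:
    def test_identical_curves(self):
        c = np.sin(np.linspace(0, 2 * np.pi, 101)) + 5
        curves = {ch: c.copy() for ch in JointAngleSeries.CHANNELS}
        out = symmetry_correlation(curves, curves)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_negated_curve(self):
        c = np.sin(np.linspace(0, 2 * np.pi, 101))
        left = {ch: 50 + c for ch in JointAngleSeries.CHANNELS}
        right = {ch: 50 - c for ch in JointAngleSeries.CHANNELS}
        out = symmetry_correlation(left, right)
        assert all(v == pytest.approx(-1.0) for v in out.values())

    def test_zero_variance_reported_nan(self):
        flat = {ch: np.full(101, 3.0) for ch in JointAngleSeries.CHANNELS}
        out = symmetry_correlation(flat, flat)
        assert all(np.isnan(v) for v in out.values())

    def test_asymmetry_sweep_decreases_correlation(self):
        # symmetric study conditions: same durations/extremes on both sides
        sym_dur = {"left": {"entry": (124.0, 0.0), "pull": (396.0, 0.0),
                            "exit": (116.0, 0.0), "recovery": (388.0, 0.0)}}
        sym_dur["right"] = sym_dur["left"]
        sym_ext = {"EFl": (145.2, 167.0), "EFr": (145.2, 167.0),
                   "SFl": (25.8, 99.9), "SFr": (25.8, 99.9)}
        corr = []
        for alpha in (0.0, 0.35, 0.7):
            params = StrokeParams(
                phase_durations_ms=sym_dur, extremes_deg=sym_ext,
                asymmetry=alpha, jitter_scale=0.0, n_cycles=6, seed=0)
            series, _ = gen_joint_trajectory(params)
            cyc = {s: detect_cycles(series, s) for s in ("left", "right")}
            left = {c: mean_cycle_curve(series, c, cyc["left"])
                    for c in JointAngleSeries.CHANNELS}
            right = {c: mean_cycle_curve(series, c, cyc["right"])
                     for c in JointAngleSeries.CHANNELS}
            out = symmetry_correlation(left, right)
            corr.append(out["EFl:EFr"])
        assert corr[0] == pytest.approx(1.0, abs=1e-3)
        assert corr[0] > corr[1] > corr[2]


def make_segmentation(durs_ms, n_cycles=3, fs=1000.0, sides=("left",)):
    labels = []
    for _ in range(n_cycles):
        for code, p in enumerate(PHASES):
            labels.extend([code] * int(round(durs_ms[p] * fs / 1000)))
    arr = np.array(labels, dtype=int)
    return PhaseSegmentation(sample_rate_hz=fs,
                             labels={s: arr.copy() for s in sides})


class TestPhaseDurations:
    def test_printed_subject_row_propulsion_fraction(self):
        # entry 124, pull 396, exit 116, recovery 388 ms
        seg = make_segmentation(
            {"entry": 124, "pull": 396, "exit": 116, "recovery": 388})
        out = phase_durations(seg)
        assert out["left"]["propulsion_fraction"] * 100 == pytest.approx(
            62.1, abs=0.05)  # 636/1024
        assert out["left"]["durations_ms"]["pull"]["mean"] == pytest.approx(
            396, abs=1)

    def test_all_recovery_gives_zero_propulsion(self):
        seg = PhaseSegmentation(
            sample_rate_hz=100.0, labels={"left": np.full(500, 3, dtype=int)})
        out = phase_durations(seg)
        assert out["left"]["propulsion_fraction"] == 0.0

    def test_scripted_durations_recovered(self):
        params = zero_noise_params(n_cycles=8)
        _, seg = gen_joint_trajectory(params)
        out = phase_durations(seg)
        period_ms = 1000.0 / params.sample_rate_hz
        for side in ("left", "right"):
            for p in PHASES:
                configured = params.phase_durations_ms[side][p][0]
                assert out[side]["durations_ms"][p]["mean"] == pytest.approx(
                    configured, abs=period_ms)

    def test_phase_partition_sums_to_cycle(self):
        seg = make_segmentation(
            {"entry": 111, "pull": 222, "exit": 133, "recovery": 244},
            n_cycles=4)
        out = phase_durations(seg)
        total = sum(out["left"]["durations_ms"][p]["mean"] for p in PHASES)
        assert total == pytest.approx(111 + 222 + 133 + 244, abs=1e-9)
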