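"""Movement segmentation, center of mass, and gait metrics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from gravimetrics.io_signals import MarkerTrajectory, SampledSignal
from gravimetrics.kinematics import (
    WINTER_TABLE,
    AnthropometricTable,
    compute_com,
    detect_bounds_displacement,
    detect_bounds_velocity,
    gait_metrics,
    movement_amplitude,
)
from gravimetrics.synthetic import minimum_jerk


def _mj_profile(rate=200.0, dur=1.0, amp=1.0, pre=1.0, post=1.0):
    n = int(round((pre + dur + post) * rate)) + 1
    t = np.arange(n) / rate
    u = (t - pre) / dur
    return SampledSignal(amp * minimum_jerk(np.clip(u, 0, 1)), rate=rate), t, pre


class TestBoundsDisplacement:
    def test_constant_signal_rejected(self):
        s = SampledSignal(np.ones(1000), rate=200.0)
        with pytest.raises(ValueError, match="no movement"):
            detect_bounds_displacement(s, "fast")

    def test_minimum_jerk_brackets_thresholds(self):
        # independent oracle: exact 5%/95% crossing times of the quintic
        s, t, pre = _mj_profile()
        b = detect_bounds_displacement(s, "fast")
        d = s.values
        amp = 1.0
        assert d[b.onset_idx - 1] / amp <= 0.05 < d[b.onset_idx] / amp + 1e-12
        assert d[b.offset_idx] / amp > 0.95 >= d[b.offset_idx - 1] / amp - 1e-12
        u05 = brentq(lambda u: 10 * u**3 - 15 * u**4 + 6 * u**5 - 0.05, 0, 1)
        u95 = brentq(lambda u: 10 * u**3 - 15 * u**4 + 6 * u**5 - 0.95, 0, 1)
        assert b.onset_s == pytest.approx(pre + u05, abs=1.5 / 200.0)
        assert b.offset_s == pytest.approx(pre + u95, abs=1.5 / 200.0)

    def test_step_function_degenerate(self):
        v = np.concatenate([np.zeros(200), np.ones(200)])
        with pytest.raises(ValueError):
            detect_bounds_displacement(SampledSignal(v, rate=200.0), "fast")

    def test_slow_uses_3d_distance(self):
        s, _, _ = _mj_profile(dur=2.0, pre=1.0, post=1.0)
        xyz = np.column_stack([s.values, s.values, s.values]) / np.sqrt(3)
        b = detect_bounds_displacement(SampledSignal(xyz, rate=200.0), "slow")
        assert b.onset_s < b.offset_s


class TestBoundsVelocity:
    def test_triangular_closed_form(self):
        rate = 200.0
        t = np.arange(int(rate) + 1) / rate
        v = 1.0 - np.abs(2 * t - 1.0)  # peak 1 m/s at t = 0.5
        b = detect_bounds_velocity(SampledSignal(v, rate=rate))
        assert b.onset_s == pytest.approx(0.025, abs=1.5 / rate)
        assert b.offset_s == pytest.approx(0.975, abs=1.5 / rate)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            detect_bounds_velocity(SampledSignal(np.zeros(100), rate=200.0))

    def test_two_equal_peaks_bracket_first(self):
        # ties break toward the earlier peak
        tri = 1.0 - np.abs(np.linspace(-1, 1, 81))
        v = np.zeros(400)
        v[60:141] = tri
        v[260:341] = tri
        b = detect_bounds_velocity(SampledSignal(v, rate=200.0))
        assert b.onset_idx <= 100 <= b.offset_idx < 260


class TestMovementAmplitude:
    def test_clean_step(self):
        v = np.concatenate([np.zeros(200), np.linspace(0, 1, 50), np.ones(200)])
        assert movement_amplitude(SampledSignal(v, rate=200.0), "fast") == pytest.approx(1.0)

    def test_noisy_plateaus_within_se(self, rng):
        sd, n = 0.001, 100
        v = np.concatenate([np.zeros(n), np.linspace(0, 1, 50), np.ones(n)])
        v = v + rng.normal(0, sd, v.size)
        amp = movement_amplitude(SampledSignal(v, rate=200.0), "slow")
        assert amp == pytest.approx(1.0, abs=6 * sd / np.sqrt(n))

    def test_slow_3d_diagonal(self):
        col = np.concatenate([np.zeros(200), np.linspace(0, 1, 50), np.ones(200)])
        xyz = np.column_stack([col, col, col])
        amp = movement_amplitude(SampledSignal(xyz, rate=200.0), "slow")
        assert amp == pytest.approx(np.sqrt(3.0), rel=1e-9)


def _brute_force_com(segments, table):
    """Independent mass-weighted average (the oracle: plain loops)."""
    total = sum(table.mass_fraction.values())
    acc = 0.0
    for name in table.mass_fraction:
        prox, dist = segments[name]
        c = table.com_fraction[name]
        seg_com = (1 - c) * np.asarray(prox) + c * np.asarray(dist)
        acc = acc + table.mass_fraction[name] / total * seg_com
    return acc


class TestComputeCom:
    def test_single_segment_lies_at_com_fraction(self):
        table = AnthropometricTable(
            mass_fraction={"Trunk": 0.999},
            length_fraction={"Trunk": 0.5},
            com_fraction={"Trunk": 0.3},
        )
        prox = np.tile([0.0, 0.0, 1.0], (50, 1))
        dist = np.tile([0.0, 0.0, 0.0], (50, 1))
        com = compute_com({"Trunk": (prox, dist)}, table, filter_hz=None)
        np.testing.assert_allclose(com.xyz.values[:, 2], 0.7, atol=1e-12)

    def test_mirrored_segments_cancel(self):
        table = AnthropometricTable(
            mass_fraction={"A": 0.5, "B": 0.5},
            length_fraction={"A": 0.5, "B": 0.5},
            com_fraction={"A": 0.4, "B": 0.4},
        )
        p = np.tile([1.0, 2.0, 3.0], (30, 1))
        d = np.tile([2.0, 1.0, -1.0], (30, 1))
        com = compute_com({"A": (p, d), "B": (-p, -d)}, table, filter_hz=None)
        np.testing.assert_allclose(com.xyz.values, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        segments = {
            name: (rng.normal(size=(40, 3)), rng.normal(size=(40, 3)))
            for name in WINTER_TABLE.segments
        }
        com = compute_com(segments, WINTER_TABLE, filter_hz=None)
        np.testing.assert_allclose(
            com.xyz.values, _brute_force_com(segments, WINTER_TABLE), atol=1e-12
        )

    def test_com_inside_convex_hull_bounds(self, rng):
        segments = {
            name: (rng.uniform(0, 1, size=(20, 3)), rng.uniform(0, 1, size=(20, 3)))
            for name in WINTER_TABLE.segments
        }
        com = compute_com(segments, WINTER_TABLE, filter_hz=None)
        allpts = np.concatenate([np.concatenate(v) for v in segments.values()])
        assert np.all(com.xyz.values >= allpts.min(axis=0) - 1e-12)
        assert np.all(com.xyz.values <= allpts.max(axis=0) + 1e-12)

    def test_scaling_homogeneity(self, rng):
        base = {
            name: (rng.normal(size=(400, 3)), rng.normal(size=(400, 3)))
            for name in WINTER_TABLE.segments
        }
        k = 2.5
        scaled = {n: (k * p, k * d) for n, (p, d) in base.items()}
        c1 = compute_com(base, WINTER_TABLE, height=1.7)
        c2 = compute_com(scaled, WINTER_TABLE, height=1.7)
        assert c2.peak_velocity == pytest.approx(k * c1.peak_velocity, rel=1e-9)

    def test_missing_segment_named(self):
        with pytest.raises(ValueError, match="Hand"):
            compute_com(
                {s: (np.zeros((5, 3)), np.ones((5, 3))) for s in WINTER_TABLE.segments if s != "Hand"},
                WINTER_TABLE,
            )


class TestGaitMetrics:
    def _feet(self, freq=0.8, amp=0.25, spacing=0.2, rate=200.0, dur=20.0):
        t = np.arange(int(dur * rate)) / rate
        rx = amp * np.sin(2 * np.pi * freq * t)
        z = np.zeros_like(t)
        right = MarkerTrajectory(
            "rf", SampledSignal(np.column_stack([rx, np.full_like(t, -spacing / 2), z]), rate=rate)
        )
        left = MarkerTrajectory(
            "lf", SampledSignal(np.column_stack([-rx, np.full_like(t, spacing / 2), z]), rate=rate)
        )
        return left, right

    def test_step_rate_matches_generator(self):
        left, right = self._feet(freq=0.8)
        gm = gait_metrics(left, right)
        assert gm.step_rate == pytest.approx(0.8, rel=0.01)

    def test_feet_spacing(self):
        left, right = self._feet(spacing=0.2)
        assert gait_metrics(left, right).feet_spacing == pytest.approx(0.2, abs=1e-12)

    def test_step_length_is_sinusoid_prominence(self):
        # interior peaks of a sinusoid have prominence 2a; the one or two
        # edge peaks pull the mean down slightly over a long window
        left, right = self._feet(amp=0.25, dur=60.0)
        gm = gait_metrics(left, right)
        assert gm.step_length_mean == pytest.approx(0.5, rel=0.02)

    def test_too_few_peaks_rejected(self):
        left, right = self._feet(dur=1.0)
        with pytest.raises(ValueError):
            gait_metrics(left, right)
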