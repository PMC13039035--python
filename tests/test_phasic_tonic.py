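"""Cutting, time normalization, tonic templates, fast-pair averaging, phasic."""

import numpy as np
import pytest

from gravimetrics.io_signals import EmgTrial, SampledSignal
from gravimetrics.kinematics import MovementBounds
from gravimetrics.phasic_tonic import (
    TonicTemplate,
    average_fast_pairs,
    build_tonic_template,
    compute_phasic,
    cut_trial_window,
    preprocess_emg,
    time_normalize,
)


def _trial(values, rate=1000.0, speed="fast", direction="up", muscle="VL", flag="ok"):
    return EmgTrial(
        muscle=muscle, side="right", task="STS_BTS", speed=speed,
        direction=direction, signal=SampledSignal(values, rate=rate),
        quality_flag=flag,
    )


class TestCutTrialWindow:
    def test_fast_margins_arithmetic(self):
        sig = SampledSignal(np.arange(3000.0), rate=1000.0)
        b = MovementBounds(1000, 1500, 1000.0)
        cut = cut_trial_window(sig, b, "fast")
        # window [0.760, 1.590] s inclusive -> 831 samples
        assert len(cut) == 831
        assert cut.t0 == pytest.approx(0.760)
        assert cut.values[0] == 760.0

    def test_slow_margins_arithmetic(self):
        sig = SampledSignal(np.arange(3000.0), rate=1000.0)
        cut = cut_trial_window(sig, MovementBounds(1000, 1500, 1000.0), "slow")
        assert cut.t0 == pytest.approx(0.925)
        assert cut.times[-1] == pytest.approx(1.575)

    def test_insufficient_preroll(self):
        sig = SampledSignal(np.zeros(2000), rate=1000.0)
        with pytest.raises(ValueError, match="pre-roll"):
            cut_trial_window(sig, MovementBounds(100, 500, 1000.0), "fast")


class TestTimeNormalize:
    def test_linear_ramp_exact(self):
        out = time_normalize(np.linspace(2.0, 5.0, 777), L=100)
        np.testing.assert_allclose(out, np.linspace(2.0, 5.0, 100), atol=1e-12)

    def test_idempotent_at_length_L(self, rng):
        v = rng.normal(size=250)
        np.testing.assert_allclose(time_normalize(v, L=250), v, atol=1e-12)

    def test_sine_matches_analytic(self):
        x = np.sin(2 * np.pi * np.linspace(0, 1, 777))
        out = time_normalize(x, L=1000)
        ref = np.sin(2 * np.pi * np.linspace(0, 1, 1000))
        assert np.sqrt(np.mean((out - ref) ** 2)) < 1e-3

    def test_bad_L(self):
        with pytest.raises(ValueError):
            time_normalize(np.zeros(10), L=1)


def _bounds_for(n, rate=1000.0, frac=(0.3, 0.7)):
    return MovementBounds(int(frac[0] * n), int(frac[1] * n), rate)


class TestTonicTemplate:
    def test_identical_traces_give_template(self, rng):
        v = np.abs(rng.normal(size=3000)) + 1.0
        trials = [_trial(v, speed="slow") for _ in range(6)]
        bounds = [_bounds_for(3000) for _ in range(6)]
        tpl = build_tonic_template(trials, bounds, L=200, preprocessed=True)
        one = build_tonic_template(trials[:1], bounds[:1], L=200, preprocessed=True)
        np.testing.assert_allclose(tpl.values, one.values, atol=1e-12)
        assert tpl.source_count == 6

    def test_cancelling_traces_give_zero(self):
        c = np.full(3000, 2.0)
        trials = [_trial(c, speed="slow"), _trial(-c, speed="slow")]
        bounds = [_bounds_for(3000)] * 2
        tpl = build_tonic_template(trials, bounds, L=100, preprocessed=True)
        np.testing.assert_allclose(tpl.values, 0.0, atol=1e-12)

    def test_mean_matches_brute_force(self, rng):
        traces = [np.abs(rng.normal(size=3000)) for _ in range(6)]
        trials = [_trial(v, speed="slow") for v in traces]
        bounds = [_bounds_for(3000)] * 6
        tpl = build_tonic_template(trials, bounds, L=300, preprocessed=True)
        cut = [time_normalize(cut_trial_window(t.signal, b, "slow").values, 300)
               for t, b in zip(trials, bounds)]
        oracle = sum(cut) / len(cut)  # independent arithmetic mean
        np.testing.assert_allclose(tpl.values, oracle, atol=1e-12)

    def test_defective_excluded_and_empty_rejected(self, rng):
        v = np.abs(rng.normal(size=3000))
        ok = _trial(v, speed="slow")
        bad = _trial(v * 100, speed="slow", flag="defective")
        tpl = build_tonic_template([ok, bad], [_bounds_for(3000)] * 2, L=100, preprocessed=True)
        assert tpl.source_count == 1
        with pytest.raises(ValueError):
            build_tonic_template([bad], [_bounds_for(3000)], L=100, preprocessed=True)


class TestAverageFastPairs:
    def _trials(self, n, rng):
        trials = [_trial(np.abs(rng.normal(size=3000))) for _ in range(n)]
        bounds = [_bounds_for(3000)] * n
        return trials, bounds

    def test_sorted_consecutive_pairs(self, rng):
        trials, bounds = self._trials(12, rng)
        vels = list(range(12, 0, -1))  # reversed order on input
        pairs = average_fast_pairs(trials, bounds, vels, L=100, preprocessed=True)
        assert len(pairs) == 6
        # pair 0 must average the two slowest trials (velocities 1 and 2)
        expected = np.mean(
            [time_normalize(cut_trial_window(trials[i].signal, bounds[i], "fast").values, 100)
             for i in (11, 10)],
            axis=0,
        )
        np.testing.assert_allclose(pairs[0]["values"], expected, atol=1e-12)

    def test_two_identical_trials(self, rng):
        v = np.abs(rng.normal(size=3000))
        trials = [_trial(v), _trial(v)]
        bounds = [_bounds_for(3000)] * 2
        pairs = average_fast_pairs(trials, bounds, [1.0, 1.0], L=100, preprocessed=True)
        ref = time_normalize(cut_trial_window(trials[0].signal, bounds[0], "fast").values, 100)
        np.testing.assert_allclose(pairs[0]["values"], ref, atol=1e-12)

    def test_pair_duration_is_mean(self, rng):
        trials, _ = self._trials(2, rng)
        bounds = [MovementBounds(1000, 1400, 1000.0), MovementBounds(1000, 1600, 1000.0)]
        pairs = average_fast_pairs(trials, bounds, [1.0, 2.0], L=100, preprocessed=True)
        assert pairs[0]["duration_s"] == pytest.approx(0.5)

    def test_odd_count_drops_fastest(self, rng):
        trials, bounds = self._trials(5, rng)
        pairs = average_fast_pairs(trials, bounds, [1, 2, 3, 4, 5], L=100, preprocessed=True)
        assert len(pairs) == 2  # trial with velocity 5 dropped

    def test_shuffle_invariance(self, rng):
        trials, bounds = self._trials(8, rng)
        vels = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.0, 3.5]
        ref = average_fast_pairs(trials, bounds, vels, L=100, preprocessed=True)
        perm = rng.permutation(8)
        shuf = average_fast_pairs(
            [trials[i] for i in perm], [bounds[i] for i in perm],
            [vels[i] for i in perm], L=100, preprocessed=True,
        )
        for a, b in zip(ref, shuf):
            np.testing.assert_allclose(a["values"], b["values"], atol=1e-12)

    def test_too_few_rejected(self, rng):
        trials, bounds = self._trials(1, rng)
        with pytest.raises(ValueError):
            average_fast_pairs(trials, bounds, [1.0], L=100, preprocessed=True)


class TestComputePhasic:
    def _template(self, values):
        return TonicTemplate(muscle="VL", task="STS_BTS", values=values, source_count=6)

    def test_exact_compensation_gives_zero(self, rng):
        v = np.abs(rng.normal(size=100)) + 0.5
        fast = {"values": v.copy(), "duration_s": 0.5, "window_s": 0.8}
        ph = compute_phasic(fast, self._template(v), task_max=v.max())
        np.testing.assert_allclose(ph.values, 0.0, atol=1e-12)

    def test_zero_template(self, rng):
        v = np.abs(rng.normal(size=100))
        fast = {"values": v, "duration_s": 0.5, "window_s": 0.8}
        ph = compute_phasic(fast, self._template(np.zeros(100)), task_max=2.0)
        np.testing.assert_allclose(ph.values, v / 2.0, atol=1e-12)

    def test_doubled_template_elementwise(self, rng):
        tpl = np.abs(rng.normal(size=100)) + 0.1
        fast = {"values": 2 * tpl, "duration_s": 0.5, "window_s": 0.8}
        ph = compute_phasic(fast, self._template(tpl), task_max=float(tpl.max()))
        np.testing.assert_allclose(ph.values, tpl / tpl.max(), atol=1e-12)

    def test_reconstruction_identity(self, rng):
        tpl = np.abs(rng.normal(size=100)) + 0.1
        v = np.abs(rng.normal(size=100)) + 0.2
        fast = {"values": v, "duration_s": 0.5, "window_s": 0.8}
        ph = compute_phasic(fast, self._template(tpl), task_max=3.7)
        np.testing.assert_allclose(ph.norm_constant * ph.values + tpl, v, atol=1e-12)

    def test_nonpositive_task_max_rejected(self):
        fast = {"values": np.ones(10), "duration_s": 0.5, "window_s": 0.8}
        with pytest.raises(ValueError):
            compute_phasic(fast, self._template(np.ones(10)), task_max=0.0)


class TestPreprocessEmg:
    def test_recovers_envelope_scale_shape(self, rng):
        # amplitude-modulated broadband carrier: the processing chain must
        # recover a signal proportional to the modulating envelope
        rate = 1000.0
        t = np.arange(4000) / rate
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 0.5 * t)
        raw = env * rng.normal(size=t.size)
        out = preprocess_emg(SampledSignal(raw, rate=rate)).values
        core = slice(500, 3500)
        corr = np.corrcoef(out[core], env[core])[0, 1]
        assert corr > 0.95
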