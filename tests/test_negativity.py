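"""Negative-epoch detection and the four negativity metrics."""

import numpy as np
import pandas as pd
import pytest

from gravimetrics.negativity import (
    NegativityEpoch,
    aggregate_negativity,
    detect_negative_epochs,
    epoch_metrics,
    trial_negativity,
)
from gravimetrics.phasic_tonic import PhasicTrace


def make_phasic(values, tonic, duration_s=1.0, window_s=1.0, norm=1.0, pre_frac=0.0):
    return PhasicTrace(
        muscle="VL", task="STS_BTS", direction="down",
        values=np.asarray(values, float), duration_s=duration_s,
        window_s=window_s, norm_constant=norm,
        tonic=np.asarray(tonic, float) * norm, pre_margin_frac=pre_frac,
    )


def square_pulse(L, start_frac, len_frac, depth):
    """Pulse whose edges land exactly on the normalized grid."""
    v = np.zeros(L)
    i0 = int(round(start_frac * (L - 1)))
    i1 = i0 + int(round(len_frac * (L - 1)))
    v[i0 : i1 + 1] = -depth
    return v


class TestDetection:
    def test_nonnegative_phasic_gives_empty(self):
        ph = make_phasic(np.abs(np.sin(np.linspace(0, 6, 500))), np.ones(500))
        assert detect_negative_epochs(ph, pre_sd=0.01) == []

    def test_39ms_pulse_rejected_50ms_accepted(self):
        L = 1001
        for frac, expected in ((0.039, 0), (0.050, 1)):
            v = square_pulse(L, 0.4, frac, depth=1.0)
            ph = make_phasic(v, np.ones(L), duration_s=1.0, window_s=1.0)
            epochs = detect_negative_epochs(ph, pre_sd=0.1)
            assert len(epochs) == expected

    def test_accepted_pulse_T(self):
        L = 1001
        v = square_pulse(L, 0.4, 0.050, depth=1.0)
        ph = make_phasic(v, np.ones(L))
        (iv,) = detect_negative_epochs(ph, pre_sd=0.1)
        e = epoch_metrics(iv, ph)
        assert e.T == pytest.approx(0.05, abs=1e-9)

    def test_threshold_is_minus_three_sd(self):
        L = 1001
        v = square_pulse(L, 0.3, 0.2, depth=0.29)
        ph = make_phasic(v, np.ones(L))
        assert detect_negative_epochs(ph, pre_sd=0.1) == []  # -0.29 > -0.3
        v2 = square_pulse(L, 0.3, 0.2, depth=0.31)
        ph2 = make_phasic(v2, np.ones(L))
        assert len(detect_negative_epochs(ph2, pre_sd=0.1)) == 1


class TestEpochMetrics:
    def test_hand_oracle_rectangle_case(self):
        # duration 1 s, epoch length 0.2, phasic = -1, tonic = 2:
        # T = 0.2, NA = -0.2, TA = 0.4, index = -0.1, amplitude = -50
        L = 1001
        v = square_pulse(L, 0.4, 0.2, depth=1.0)
        ph = make_phasic(v, np.full(L, 2.0))
        (iv,) = detect_negative_epochs(ph, pre_sd=0.01)
        e = epoch_metrics(iv, ph)
        assert e.T == pytest.approx(0.2, abs=1e-9)
        assert e.NA == pytest.approx(-0.2, abs=1e-9)
        assert e.TA == pytest.approx(0.4, abs=1e-9)
        assert e.index == pytest.approx(-0.1, abs=1e-9)
        assert e.amplitude == pytest.approx(-50.0, abs=1e-9)

    def test_full_silence_is_minus_100(self):
        # fast EMG fully silent over the epoch: phasic = -tonic -> -100
        L = 1001
        tonic = np.full(L, 0.8)
        v = square_pulse(L, 0.3, 0.3, depth=0.8)
        ph = make_phasic(v, tonic)
        (iv,) = detect_negative_epochs(ph, pre_sd=0.05)
        assert epoch_metrics(iv, ph).amplitude == pytest.approx(-100.0, abs=1e-9)

    def test_exact_compensation_is_zero(self):
        # phasic identically 0 on the epoch, tonic positive -> amplitude 0
        L = 101
        ph = make_phasic(np.zeros(L), np.ones(L))
        e = epoch_metrics((30, 60), ph)
        assert e.amplitude == pytest.approx(0.0, abs=1e-12)
        assert e.index == pytest.approx(0.0, abs=1e-12)

    def test_silent_tonic_discarded_with_warning(self):
        L = 101
        ph = make_phasic(-np.ones(L), np.zeros(L))
        with pytest.warns(UserWarning, match="tonic"):
            assert epoch_metrics((30, 60), ph) is None


class TestInvariants:
    def test_deepening_never_increases_index(self):
        L = 1001
        tonic = np.ones(L)
        prev = 0.0
        for depth in (0.5, 1.0, 2.0, 4.0):
            v = square_pulse(L, 0.4, 0.2, depth)
            ph = make_phasic(v, tonic)
            (iv,) = detect_negative_epochs(ph, pre_sd=0.05)
            idx = epoch_metrics(iv, ph).index
            assert idx <= prev
            prev = idx

    def test_index_scales_linearly_with_epoch_length(self):
        # NA and TA are both integrated over the epoch, so for fixed depth
        # and tonic NA/TA is constant and index = T*NA/TA grows linearly in T
        L = 2001
        tonic = np.ones(L)
        vals = {}
        for Tlen in (0.1, 0.2, 0.4):
            v = square_pulse(L, 0.25, Tlen, depth=1.0)
            ph = make_phasic(v, tonic)
            (iv,) = detect_negative_epochs(ph, pre_sd=0.05)
            vals[Tlen] = epoch_metrics(iv, ph).index
        assert vals[0.2] / vals[0.1] == pytest.approx(2.0, rel=1e-6)
        assert vals[0.4] / vals[0.2] == pytest.approx(2.0, rel=1e-6)

    def test_metrics_invariant_to_task_max(self):
        # same raw fast/tonic signals normalized by different task maxima:
        # index and amplitude are ratios and must not change
        L = 1001
        raw_tonic = np.full(L, 0.5)
        raw_diff = square_pulse(L, 0.4, 0.2, depth=0.4)
        out = []
        for norm in (1.0, 7.3):
            ph = PhasicTrace(
                muscle="VL", task="STS_BTS", direction="down",
                values=raw_diff / norm, duration_s=1.0, window_s=1.0,
                norm_constant=norm, tonic=raw_tonic,
            )
            (iv,) = detect_negative_epochs(ph, pre_sd=0.05 / norm)
            e = epoch_metrics(iv, ph)
            out.append((e.index, e.amplitude))
        assert out[0][0] == pytest.approx(out[1][0], rel=1e-12)
        assert out[0][1] == pytest.approx(out[1][1], rel=1e-12)

    def test_occurrence_counts_trials_with_epochs(self):
        L = 1001
        tonic = np.ones(L)
        with_epoch = make_phasic(square_pulse(L, 0.4, 0.2, 1.0), tonic)
        without = make_phasic(np.zeros(L), tonic)
        flags = [
            trial_negativity(p, pre_sd=0.05)["occurrence"]
            for p in (with_epoch, without, with_epoch, without, without)
        ]
        assert np.mean(flags) == pytest.approx(2.0 / 5.0)

    def test_epoch_invariant_validation(self):
        with pytest.raises(ValueError):
            NegativityEpoch(onset_n=0.2, offset_n=0.4, NA=0.1, TA=1.0, T=0.2,
                            index=0.0, amplitude=0.0)


class TestTrialAndAggregation:
    def test_no_epochs_yields_zeros(self):
        L = 501
        ph = make_phasic(np.zeros(L), np.ones(L))
        rec = trial_negativity(ph, pre_sd=0.05)
        assert rec["index"] == 0.0 and rec["occurrence"] == 0 and rec["duration"] == 0.0
        assert np.isnan(rec["amplitude"])

    def test_multiple_epochs_sum(self):
        L = 2001
        v = square_pulse(L, 0.1, 0.1, 1.0) + square_pulse(L, 0.6, 0.1, 1.0)
        ph = make_phasic(v, np.ones(L))
        rec = trial_negativity(ph, pre_sd=0.05)
        assert rec["n_epochs"] == 2
        assert rec["duration"] == pytest.approx(0.2, abs=1e-9)
        single = trial_negativity(make_phasic(square_pulse(L, 0.1, 0.1, 1.0), np.ones(L)), pre_sd=0.05)
        assert rec["index"] == pytest.approx(2 * single["index"], rel=1e-9)

    def _table(self, rows):
        cols = ["participant", "group", "task", "muscle", "trial",
                "index", "occurrence", "duration", "amplitude"]
        return pd.DataFrame(rows, columns=cols)

    def test_single_trial_aggregate_is_identity(self):
        t = self._table([["p1", "young", "ARM", "DA", 0, -2.0, 1, 0.3, -40.0]])
        agg = aggregate_negativity(t)
        row = agg[agg["task_group"] == "ARM"].iloc[0]
        assert row["index"] == -2.0 and row["amplitude"] == -40.0

    def test_muscle_mean(self):
        t = self._table([
            ["p1", "young", "STS_BTS", "VL", 0, -2.0, 1, 0.2, -30.0],
            ["p1", "young", "STS_BTS", "ESL1", 0, -4.0, 1, 0.4, -50.0],
        ])
        agg = aggregate_negativity(t)
        row = agg[agg["task_group"] == "WB"].iloc[0]
        assert row["index"] == pytest.approx(-3.0)

    def test_empty_cells_stay_missing(self):
        t = self._table([["p1", "young", "ARM", "DA", 0, -2.0, 1, 0.3, -40.0]])
        agg = aggregate_negativity(t)
        assert "WB" not in agg["task_group"].values  # not zero-filled
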