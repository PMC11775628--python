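import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stnlfp import (
    SimConfig,
    conditional_accuracy,
    delta_plot,
    final_delta_slope,
    paired_t,
    quantile_bins,
    simulate_behavior,
    trim_rts,
)
from stnlfp.behavior import condition_summary, simon_effects
from stnlfp.datamodel import NumericalError, SchemaError


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "block", "depth", "stim_onset_s", "stim_side",
            "correct_side", "response_side", "rt_ms", "correspondence",
            "accuracy", "iti_prev_ms",
        ],
    )


def _row(tid, rt, corr="Cs", acc="correct", depth="dorsal"):
    stim = "left"
    correct = "left" if corr == "Cs" else "right"
    resp = correct if acc == "correct" else stim
    return [tid, 0, depth, 5.0 + tid, stim, correct, resp, rt, corr, acc, 1000.0]


class TestTrim:
    def test_hard_150ms_cutoff(self):
        t = _table([_row(0, 120.0), _row(1, 400.0), _row(2, 450.0)])
        out = trim_rts(t)
        assert sorted(out["rt_ms"]) == [400.0, 450.0]

    def test_mean_plus_3sd_rule(self):
        rows = [_row(i, 400.0 + (i % 5)) for i in range(50)] + [_row(50, 5000.0)]
        out = trim_rts(_table(rows))
        assert 5000.0 not in out["rt_ms"].to_numpy()
        assert len(out) == 50

    def test_equal_rts_all_kept(self):
        t = _table([_row(i, 400.0) for i in range(10)])
        assert len(trim_rts(t)) == 10

    def test_never_removes_inlier(self):
        rows = [_row(i, rt) for i, rt in enumerate([150.0, 300.0, 400.0, 500.0])]
        out = trim_rts(_table(rows))
        assert len(out) == 4


class TestConditionSummary:
    def test_toy_means_and_simon_rt(self):
        rows = [
            _row(0, 500.0, "Cs"), _row(1, 600.0, "Cs"),
            _row(2, 540.0, "NC"), _row(3, 660.0, "NC"),
        ]
        s = condition_summary(_table(rows))
        cs = s[s["correspondence"] == "Cs"]["mean_rt_ms"].iloc[0]
        nc = s[s["correspondence"] == "NC"]["mean_rt_ms"].iloc[0]
        assert (cs, nc) == (550.0, 600.0)
        assert simon_effects(s)["simon_rt_ms"].iloc[0] == 50.0

    def test_accuracy_percentages(self):
        rows = [_row(i, 400.0, "Cs", "correct") for i in range(9)]
        rows += [_row(9, 400.0, "Cs", "error")]
        rows += [_row(10 + i, 400.0, "NC", "correct") for i in range(8)]
        rows += [_row(18, 400.0, "NC", "error"), _row(19, 400.0, "NC", "error")]
        s = condition_summary(_table(rows))
        acc = s.set_index("correspondence")["accuracy_pct"]
        assert (acc["Cs"], acc["NC"]) == (90.0, 80.0)
        assert simon_effects(s)["simon_acc_pct"].iloc[0] == 10.0


class TestQuantileBins:
    def test_even_split(self):
        bins = quantile_bins(np.arange(8.0))
        assert np.array_equal(bins, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_remainder_goes_to_early_bins(self):
        bins = quantile_bins(np.arange(10.0))
        sizes = [np.sum(bins == b) for b in (1, 2, 3, 4)]
        assert sizes == [3, 3, 2, 2]

    def test_ties_keep_input_order(self):
        rts = np.array([300.0, 300.0, 300.0, 300.0, 200.0, 400.0, 400.0, 500.0])
        bins = quantile_bins(rts)
        tied = bins[:4]
        assert np.array_equal(np.sort(tied), tied)  # earlier input -> earlier bin

    def test_too_few_trials(self):
        with pytest.raises(SchemaError):
            quantile_bins(np.array([1.0, 2.0]), 4)

    @given(st.lists(st.floats(100, 1000), min_size=4, max_size=60))
    @settings(max_examples=50, derandomize=True)
    def test_bins_partition_and_are_rank_contiguous(self, rts):
        rts = np.asarray(rts)
        bins = quantile_bins(rts)
        assert sum(np.sum(bins == b) for b in (1, 2, 3, 4)) == len(rts)
        order = np.argsort(rts, kind="stable")
        assert np.array_equal(bins[order], np.sort(bins))


class TestDeltaPlot:
    CS = np.repeat([400.0, 450.0, 500.0, 600.0], 2)
    NC = np.repeat([450.0, 510.0, 560.0, 620.0], 2)

    def test_hand_computed_slope(self):
        d = delta_plot(self.CS, self.NC)
        assert np.allclose(d["interference"], [50.0, 60.0, 60.0, 20.0])
        assert np.allclose(d["mean_rt"], [425.0, 480.0, 530.0, 610.0])
        assert final_delta_slope(d) == pytest.approx(-0.5)

    def test_identical_distributions_flat(self):
        d = delta_plot(self.CS, self.CS)
        assert np.allclose(d["interference"], 0.0)
        assert final_delta_slope(d) == 0.0

    def test_antisymmetric_under_label_swap(self, rng):
        cs = rng.uniform(300, 700, 40)
        nc = rng.uniform(350, 800, 40)
        d1 = delta_plot(cs, nc)
        d2 = delta_plot(nc, cs)
        assert np.allclose(d1["interference"], -d2["interference"])
        assert final_delta_slope(d1) == pytest.approx(-final_delta_slope(d2))

    def test_degenerate_slope_rejected(self):
        d = pd.DataFrame({"bin": [3, 4], "mean_rt": [500.0, 500.0],
                          "interference": [10.0, 20.0]})
        with pytest.raises(NumericalError):
            final_delta_slope(d)

    def test_late_suppression_generator_yields_negative_slope(self):
        hits = 0
        for seed in range(20):
            t = simulate_behavior(
                SimConfig(suppression_gain=2.0, simon_rt_shift_ms=80.0,
                          trials_per_block=190, seed=seed)
            )
            ok = t[(t["accuracy"] == "correct")]
            cs = ok.loc[ok["correspondence"] == "Cs", "rt_ms"].to_numpy()
            nc = ok.loc[ok["correspondence"] == "NC", "rt_ms"].to_numpy()
            hits += final_delta_slope(delta_plot(cs, nc)) < 0
        assert hits >= 18


class TestConditionalAccuracy:
    def test_counts_in_fastest_bin(self):
        rows = [_row(i, 200.0 + i, "NC", "error") for i in range(3)]
        rows += [_row(3 + i, 300.0 + i, "NC", "correct") for i in range(7)]
        rows += [_row(10 + i, 600.0 + i, "NC", "correct") for i in range(30)]
        caf = conditional_accuracy(_table(rows))
        bin1 = caf[(caf["correspondence"] == "NC") & (caf["bin"] == 1)]
        assert bin1["accuracy_pct"].iloc[0] == 70.0

    def test_error_free_table_is_100(self):
        rows = [_row(i, 300.0 + 10 * i, "Cs") for i in range(8)]
        caf = conditional_accuracy(_table(rows))
        assert (caf["accuracy_pct"] == 100.0).all()

    def test_impulse_generator_depresses_fast_nc_bin(self):
        hits = 0
        for seed in range(20):
            t = simulate_behavior(SimConfig(p_impulse_error=0.3, seed=seed))
            nc = t[(t["response_side"] != "none") & (t["correspondence"] == "NC")]
            caf = conditional_accuracy(nc)
            caf = caf.set_index("bin")["accuracy_pct"]
            hits += caf[1] < caf[4]
        assert hits == 20


class TestPairedT:
    def test_zero_differences(self):
        t, p, d = paired_t(np.ones(6), np.ones(6))
        assert (t, p, d) == (0.0, 1.0, 0.0)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(NumericalError):
            paired_t(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(10, 2, 15)
        b = rng.normal(9, 2, 15)
        t, p, d = paired_t(a, b)
        diff = a - b
        t_ref = diff.mean() / (diff.std(ddof=1) / np.sqrt(15))
        d_ref = diff.mean() / diff.std(ddof=1)
        from scipy.stats import t as tdist

        p_ref = 2 * tdist.sf(abs(t_ref), 14)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)
        assert d == pytest.approx(d_ref)
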