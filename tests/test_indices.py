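"""08:00-anchored segmentation, the eight sleep indices, model means,
sensitivity approaches and reporting arithmetic."""

import numpy as np
import pandas as pd
import pytest

from cardiosleep.concordance import CONCORDANT, DISCORDANT
from cardiosleep.core import MISSING
from cardiosleep.indices import (
    mean_indices,
    patient_aggregate,
    report_percent_change,
    segment,
    sensitivity_select,
    sleep_indices,
)

from conftest import make_hypnogram

EPOCHS_PER_H = 120


def _all_conc(n):
    return np.array([CONCORDANT] * n, dtype=object)


class TestSegmentation:
    def test_48h_from_2000_gives_three_segments(self):
        n = 48 * EPOCHS_PER_H
        a = make_hypnogram(["N2"] * n)
        b = make_hypnogram(["N2"] * n)
        segs = segment(a, b)
        assert [s.available_h for s in segs] == [12.0, 24.0, 12.0]

    def test_single_day_single_segment(self):
        a = make_hypnogram(["N2"] * 240, start=pd.Timestamp("2000-01-01 10:00"))
        b = make_hypnogram(["N2"] * 240, start=pd.Timestamp("2000-01-01 10:00"))
        assert len(segment(a, b)) == 1

    def test_0800_epoch_opens_new_segment(self):
        start = pd.Timestamp("2000-01-01 07:59:30")
        a = make_hypnogram(["N2", "N2"], start=start)
        b = make_hypnogram(["N2", "N2"], start=start)
        segs = segment(a, b)
        assert len(segs) == 2
        assert segs[1].hyp_hrv.start == pd.Timestamp("2000-01-01 08:00:00")


class TestSleepIndices:
    def test_worked_hand_oracle(self):
        # [W,N1,N2,N3,N2,R,W,W]: 5 sleep epochs = 0.041667 h;
        # qualifying fragmentation transition: R->W (N3->N2 does not
        # count: N2 is not in {N1,W}); wake transition: R->W
        hyp = make_hypnogram(["W", "N1", "N2", "N3", "N2", "R", "W", "W"])
        rec = sleep_indices(hyp, _all_conc(8))
        assert rec.tst_h == pytest.approx(5 * 30 / 3600.0)
        assert rec.sfi == pytest.approx(1 / rec.tst_h)  # 24 per hour
        assert rec.wake_trans_per_h == pytest.approx(24.0)
        assert rec.stage_pct["N2"] == pytest.approx(100 * 2 / 5)
        assert rec.stage_pct["N2N3"] == pytest.approx(100 * 3 / 5)

    def test_six_sleep_epoch_oracle_gives_20_per_hour(self):
        # 6 sleep epochs = 0.05 h; one R->W transition -> SFI 20/h
        hyp = make_hypnogram(
            ["W", "N1", "N2", "N3", "N2", "N2", "R", "W", "W"]
        )
        rec = sleep_indices(hyp, _all_conc(9))
        assert rec.tst_h == pytest.approx(0.05)
        assert rec.sfi == pytest.approx(20.0)
        assert rec.wake_trans_per_h == pytest.approx(20.0)

    def test_all_wake_yields_zero_durations_missing_rates(self):
        rec = sleep_indices(make_hypnogram(["W"] * 10), _all_conc(10))
        assert rec.tst_h == 0.0
        assert rec.concordant_sleep_h == 0.0
        assert np.isnan(rec.sfi) and np.isnan(rec.wake_trans_per_h)
        assert all(np.isnan(v) for v in rec.stage_pct.values())

    def test_continuous_n2_block(self):
        rec = sleep_indices(make_hypnogram(["N2"] * 240), _all_conc(240))
        assert rec.tst_h == pytest.approx(2.0)
        assert rec.sleep_fraction_pct == pytest.approx(100.0)
        assert rec.stage_pct["N2"] == pytest.approx(100.0)
        assert rec.sfi == 0.0 and rec.wake_trans_per_h == 0.0

    def test_concordant_plus_discordant_equals_total(self):
        rng = np.random.default_rng(1)
        stages = rng.choice(["W", "N1", "N2", "N3", "R"], 500)
        labels = rng.choice([CONCORDANT, DISCORDANT], 500)
        rec = sleep_indices(make_hypnogram(stages), labels)
        assert rec.concordant_sleep_h + rec.discordant_sleep_h == pytest.approx(
            rec.tst_h
        )

    def test_concordant_basis_equals_total_when_fully_concordant(self):
        rng = np.random.default_rng(2)
        stages = rng.choice(["W", "N1", "N2", "N3", "R"], 400)
        hyp = make_hypnogram(stages)
        a = sleep_indices(hyp, _all_conc(400), basis="total")
        b = sleep_indices(hyp, _all_conc(400), basis="concordant")
        pd.testing.assert_series_equal(a.to_series(), b.to_series())

    def test_transitions_not_counted_across_missing_gaps(self):
        hyp = make_hypnogram(["N2", MISSING, "W", "N2", "N2"])
        rec = sleep_indices(hyp, _all_conc(5))
        # the only N2->W adjacency spans a MISSING epoch: not counted
        assert rec.sfi == 0.0 and rec.wake_trans_per_h == 0.0

    def test_flanking_wake_leaves_rates_unchanged(self):
        # wake-bounded core: extra leading/trailing W adds only W->W
        # adjacencies, so no new qualifying transitions appear
        core = ["W", "N2", "N3", "R", "W", "N2", "W"]
        a = sleep_indices(make_hypnogram(core), _all_conc(7))
        padded = ["W"] * 3 + core + ["W"] * 3
        b = sleep_indices(make_hypnogram(padded), _all_conc(13))
        assert b.tst_h == a.tst_h
        assert b.sfi == a.sfi
        assert b.wake_trans_per_h == a.wake_trans_per_h


class TestMeanIndices:
    def _rec(self, stages, labels=None):
        hyp = make_hypnogram(stages)
        return sleep_indices(hyp, labels if labels is not None
                             else _all_conc(len(stages)))

    def test_reported_tst_pair_averages(self):
        a = self._rec(["N2"] * 780)  # 6.5 h
        b = self._rec(["N2"] * 1416)  # 11.8 h
        # records must share a segment grid in practice; here only the
        # arithmetic is exercised
        a2 = self._rec(["N2"] * 780 + ["W"] * 636)
        b2 = self._rec(["N2"] * 1416)
        m = mean_indices(a2, b2)
        assert m.tst_h == pytest.approx((6.5 + 11.8) / 2)

    def test_identical_records_unchanged(self):
        r = self._rec(["W", "N1", "N2", "N3", "R"] * 10)
        m = mean_indices(r, r)
        pd.testing.assert_series_equal(
            m.to_series(), r.to_series(), check_names=False
        )

    def test_missing_component_propagates(self):
        r = self._rec(["N2"] * 10)
        w = self._rec(["W"] * 10)  # SFI missing
        assert np.isnan(mean_indices(r, w).sfi)

    def test_symmetric_in_arguments(self):
        a = self._rec(["N2"] * 100 + ["W"] * 20)
        b = self._rec(["N3"] * 60 + ["W"] * 60)
        pd.testing.assert_series_equal(
            mean_indices(a, b).to_series(), mean_indices(b, a).to_series()
        )

    def test_basis_mismatch_rejected(self):
        hyp = make_hypnogram(["N2"] * 10)
        a = sleep_indices(hyp, _all_conc(10), basis="total")
        b = sleep_indices(hyp, _all_conc(10), basis="concordant")
        with pytest.raises(ValueError, match="bases"):
            mean_indices(a, b)


def _segment_with_concordant_sleep(hours, start="2000-01-01 08:00"):
    """One 24-h segment whose concordant sleep is exactly ``hours``."""
    n_sleep = int(hours * EPOCHS_PER_H)
    n = 24 * EPOCHS_PER_H
    stages = ["N2"] * n_sleep + ["W"] * (n - n_sleep)
    a = make_hypnogram(stages, start=pd.Timestamp(start))
    b = make_hypnogram(stages, start=pd.Timestamp(start))
    return segment(a, b)[0]


class TestSensitivityApproaches:
    def test_inclusion_thresholds(self):
        segs = [
            _segment_with_concordant_sleep(h) for h in (0.0, 1.9, 2.0, 6.0)
        ]
        a1 = sensitivity_select(segs, "A1")
        a2 = sensitivity_select(segs, "A2")
        a3 = sensitivity_select(segs, "A3")
        assert [s.concordant_sleep_h for s, _ in a1] == [1.9, 2.0, 6.0]
        assert [s.concordant_sleep_h for s, _ in a2] == [2.0, 6.0]
        assert [(s.start, s.concordant_sleep_h) for s, _ in a3] == [
            (s.start, s.concordant_sleep_h) for s, _ in a2
        ]

    def test_a3_uses_concordant_basis(self):
        seg = _segment_with_concordant_sleep(6.0)
        (_, recs), = sensitivity_select([seg], "A3")
        assert recs["hrv"].basis == "concordant"

    def test_unknown_approach_rejected(self):
        with pytest.raises(ValueError, match="approach"):
            sensitivity_select([], "A4")


class TestAggregationAndReporting:
    def test_single_record_identity(self):
        hyp = make_hypnogram(["N2"] * 120)
        r = sleep_indices(hyp, _all_conc(120))
        agg = patient_aggregate([r])
        pd.testing.assert_series_equal(agg.to_series(), r.to_series())

    def test_mean_across_segments(self):
        r6 = sleep_indices(make_hypnogram(["N2"] * 720), _all_conc(720))
        r8 = sleep_indices(make_hypnogram(["N2"] * 960), _all_conc(960))
        assert patient_aggregate([r6, r8]).tst_h == pytest.approx(7.0)

    def test_missing_skipped_per_index(self):
        r = sleep_indices(make_hypnogram(["N2"] * 120), _all_conc(120))
        w = sleep_indices(make_hypnogram(["W"] * 120), _all_conc(120))
        agg = patient_aggregate([r, w])
        assert agg.tst_h == pytest.approx(0.5)  # (1 + 0)/2
        assert agg.sfi == 0.0  # only the defined record contributes

    @pytest.mark.parametrize(
        "ref,new,expected",
        [(6.5, 11.8, 81.5), (4.9, 5.7, 16.3), (7.0, 7.0, 0.0)],
    )
    def test_percent_change(self, ref, new, expected):
        assert report_percent_change(ref, new) == pytest.approx(expected)

    def test_percent_change_requires_positive_reference(self):
        with pytest.raises(ValueError, match="positive"):
            report_percent_change(0.0, 5.0)
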