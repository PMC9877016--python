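import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedyn.dynamics import (
    classify_interval,
    density_table,
    dynamics_table,
    fate_fractions,
    normalize_density,
    spine_density,
    transient_fraction,
    turnover_ratio,
)
from conftest import series_from_matrix

presence_matrices = st.integers(1, 6).flatmap(
    lambda n: st.integers(2, 5).flatmap(
        lambda m: st.lists(
            st.lists(st.booleans(), min_size=m, max_size=m),
            min_size=n,
            max_size=n,
        )
    )
)


class TestClassifyInterval:
    def test_toy_first_interval(self, toy_roi):
        ev = classify_interval(toy_roi, 4, 7)
        assert ev.stable_ids == {"A", "B"}
        assert ev.lost_ids == {"C"}
        assert ev.gained_ids == {"D"}
        assert (ev.n_prev, ev.n_next) == (3, 3)

    def test_toy_second_interval(self, toy_roi):
        ev = classify_interval(toy_roi, 7, 10)
        assert ev.stable_ids == {"A"}
        assert ev.lost_ids == {"B", "D"}
        assert ev.gained_ids == set()

    def test_identical_sessions_all_stable(self):
        s = series_from_matrix(np.ones((3, 2), dtype=bool))
        ev = classify_interval(s, 1, 2)
        assert len(ev.stable_ids) == 3
        assert not ev.gained_ids and not ev.lost_ids
        assert turnover_ratio(ev) == 0.0

    def test_non_consecutive_sessions_rejected(self, toy_roi):
        with pytest.raises(ValueError):
            classify_interval(toy_roi, 4, 10)
        with pytest.raises(ValueError):
            classify_interval(toy_roi, 4, 5)

    def test_skips_unobserved_sessions(self):
        # day 2 not imaged: (1, 3) is a consecutive *observed* pair
        s = series_from_matrix(
            np.array([[1, 0, 1]], dtype=bool), observed_days=(1, 3)
        )
        ev = classify_interval(s, 1, 3)
        assert ev.stable_ids == {"s0"}


class TestTurnoverAndFractions:
    def test_toy_turnover_one_third(self, toy_roi):
        ev = classify_interval(toy_roi, 4, 7)
        assert turnover_ratio(ev) == pytest.approx((1 + 1) / (3 + 3))

    def test_complete_replacement_is_one(self):
        s = series_from_matrix(np.array([[1, 0], [1, 0], [0, 1]], dtype=bool))
        assert turnover_ratio(classify_interval(s, 1, 2)) == 1.0

    def test_empty_interval_is_missing(self):
        s = series_from_matrix(np.zeros((1, 2), dtype=bool))
        assert math.isnan(turnover_ratio(classify_interval(s, 1, 2)))
        fr = fate_fractions(classify_interval(s, 1, 2))
        assert math.isnan(fr.lost)

    def test_toy_fractions(self, toy_roi):
        fr = fate_fractions(classify_interval(toy_roi, 4, 7))
        assert fr.lost == pytest.approx(1 / 3)
        assert fr.stable == pytest.approx(2 / 3)
        assert fr.gained == pytest.approx(1 / 3)

    def test_gained_denominator_option(self, toy_roi):
        ev = classify_interval(toy_roi, 7, 10)  # n_prev 3, n_next 1
        assert fate_fractions(ev, "n_prev").gained == 0.0
        s = series_from_matrix(np.array([[1, 1], [0, 1]], dtype=bool))
        ev2 = classify_interval(s, 1, 2)
        assert fate_fractions(ev2, "n_prev").gained == pytest.approx(1.0)
        assert fate_fractions(ev2, "n_next").gained == pytest.approx(0.5)

    @settings(max_examples=150, derandomize=True)
    @given(presence_matrices)
    def test_partition_and_convention_properties(self, matrix):
        s = series_from_matrix(np.array(matrix, dtype=bool))
        days = s.schedule.session_days
        for a, b in zip(days, days[1:]):
            ev = classify_interval(s, a, b)
            present_prev = s.present_ids(a)
            present_next = s.present_ids(b)
            # partition invariants
            assert ev.stable_ids | ev.lost_ids == present_prev
            assert ev.stable_ids | ev.gained_ids == present_next
            assert not ev.gained_ids & ev.lost_ids
            # conservation: n_next = n_prev - lost + gained
            assert len(present_next) == len(present_prev) - len(
                ev.lost_ids
            ) + len(ev.gained_ids)
            t = turnover_ratio(ev)
            fr = fate_fractions(ev)
            if ev.n_prev + ev.n_next == 0:
                assert math.isnan(t)
                continue
            assert 0.0 <= t <= 1.0
            assert (t == 0.0) == (not ev.gained_ids and not ev.lost_ids)
            assert (t == 1.0) == (not ev.stable_ids)
            if ev.n_prev > 0:
                # stable and lost fractions are complementary
                assert fr.stable + fr.lost == pytest.approx(1.0)


class TestTransient:
    def test_toy_transient(self, toy_roi):
        # D gained in (4,7) and lost in (7,10): 1 of 3 spines at day 7
        assert transient_fraction(toy_roi, 4, 7, 10) == pytest.approx(1 / 3)

    def test_no_gains_means_zero(self):
        s = series_from_matrix(np.array([[1, 1, 0], [1, 1, 1]], dtype=bool))
        assert transient_fraction(s, 1, 2, 3) == 0.0

    def test_all_gained_then_lost(self):
        s = series_from_matrix(np.array([[0, 1, 0], [0, 1, 0]], dtype=bool))
        assert transient_fraction(s, 1, 2, 3) == pytest.approx(1.0)

    def test_empty_middle_session_missing(self):
        s = series_from_matrix(np.array([[1, 0, 0]], dtype=bool))
        assert math.isnan(transient_fraction(s, 1, 2, 3))


class TestDensity:
    def test_three_spines_thirty_micron(self):
        s = series_from_matrix(np.ones((3, 2), dtype=bool), segment_length=30.0)
        assert spine_density(s, 1) == pytest.approx(0.1)

    def test_zero_spines(self):
        s = series_from_matrix(np.zeros((1, 2), dtype=bool))
        assert spine_density(s, 1) == 0.0

    def test_doubling_length_halves_density(self):
        m = np.ones((4, 2), dtype=bool)
        a = series_from_matrix(m, segment_length=20.0)
        b = series_from_matrix(m, segment_length=40.0)
        assert spine_density(a, 1) == pytest.approx(2 * spine_density(b, 1))

    def test_normalization_arithmetic(self):
        # baselines 0.10 and 0.12, later density 0.132 -> 1.2
        df = pd.DataFrame(
            {
                "mouse_id": "m1",
                "roi_id": "r1",
                "age": "young",
                "treatment": "vehicle",
                "session_day": [-7, -1, 56],
                "density": [0.10, 0.12, 0.132],
            }
        )
        out = normalize_density(df, baseline_days=[-7, -1])
        assert out.loc[out.session_day == 56, "normalized_density"].iloc[
            0
        ] == pytest.approx(1.2)

    def test_constant_density_normalizes_to_one(self):
        s = series_from_matrix(np.ones((5, 3), dtype=bool), days=(-1, 7, 10))
        out = normalize_density(density_table([s]), baseline_days=[-1])
        assert np.allclose(out["normalized_density"], 1.0)

    def test_single_baseline_session_used_alone(self):
        df = pd.DataFrame(
            {
                "mouse_id": "m1",
                "roi_id": "r1",
                "age": "old",
                "treatment": "THC",
                "session_day": [-1, 7],
                "density": [0.2, 0.3],
            }
        )
        out = normalize_density(df, baseline_days=[-7, -4, -1])
        assert out["normalized_density"].tolist() == pytest.approx([1.0, 1.5])

    def test_no_usable_baseline_excluded(self, caplog):
        df = pd.DataFrame(
            {
                "mouse_id": "m1",
                "roi_id": "r1",
                "age": "old",
                "treatment": "THC",
                "session_day": [7, 10],
                "density": [0.2, 0.3],
            }
        )
        out = normalize_density(df, baseline_days=[-1])
        assert len(out) == 0


class TestDynamicsTable:
    def test_two_rois_match_hand_computation(self, toy_roi):
        other = series_from_matrix(
            np.array([[1, 1, 1], [1, 1, 1]], dtype=bool),
            days=(4, 7, 10),
            roi_id="roi2",
            mouse_id="m2",
            segment_length=20.0,
        )
        dyn, dens, summary = dynamics_table(
            [toy_roi, other], baseline_days=[4]
        )
        r1 = dyn[(dyn.roi_id == "roi1") & (dyn.day == 7)].iloc[0]
        assert r1.turnover_ratio == pytest.approx(1 / 3)
        assert r1.frac_lost == pytest.approx(1 / 3)
        assert r1.frac_transient == pytest.approx(1 / 3)
        r2 = dyn[(dyn.roi_id == "roi2") & (dyn.day == 10)].iloc[0]
        assert r2.turnover_ratio == 0.0
        d1 = dens[(dens.roi_id == "roi1") & (dens.session_day == 10)].iloc[0]
        assert d1.density == pytest.approx(1 / 30)
        assert d1.normalized_density == pytest.approx((1 / 30) / (3 / 30))
        # transient is only defined where a following interval exists
        assert math.isnan(
            dyn[(dyn.roi_id == "roi1") & (dyn.day == 10)].frac_transient.iloc[0]
        )

    def test_identical_rois_have_zero_sem(self):
        m = np.array([[1, 1, 0], [0, 1, 1]], dtype=bool)
        rois = [
            series_from_matrix(m, roi_id=f"r{i}", mouse_id=f"m{i}")
            for i in range(3)
        ]
        _, _, summary = dynamics_table(rois, baseline_days=[1])
        assert (summary["sem"].dropna() == 0).all()

    def test_missing_session_contributes_no_row(self):
        full = series_from_matrix(
            np.ones((2, 3), dtype=bool), roi_id="full", mouse_id="m1"
        )
        partial = series_from_matrix(
            np.ones((2, 3), dtype=bool),
            roi_id="partial",
            mouse_id="m2",
            observed_days=(1, 3),
        )
        dyn, dens, _ = dynamics_table([full, partial], baseline_days=[1])
        assert set(dens[dens.roi_id == "partial"].session_day) == {1, 3}
        # the partial ROI's single interval is (1, 3), attributed to day 3
        assert dyn[dyn.roi_id == "partial"].day.tolist() == [3]
        assert dyn[dyn.roi_id == "full"].day.tolist() == [2, 3]
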