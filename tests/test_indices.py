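import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foragemetrics import (BoutList, SimulationParams, compute_am_as,
                           compute_cpm, compute_mpm_naive, compute_ptm,
                           correct_mpm, parse_binary_string, predicted_bias,
                           run_length_encode, simulate_sequence,
                           study_level_correction, summarize)
from conftest import (many_short_moves_sequence, one_long_move_sequence,
                      periodic_two_stop_sequence)


class TestPTM:
    def test_one_long_move_gives_point_four(self):
        assert compute_ptm(one_long_move_sequence()) == pytest.approx(0.4)

    def test_sixteen_short_moves_give_same_ptm(self):
        assert compute_ptm(many_short_moves_sequence()) == pytest.approx(0.4)

    def test_all_stop_is_zero(self):
        assert compute_ptm(parse_binary_string("0" * 60)) == 0.0


class TestNaiveMPM:
    @pytest.mark.parametrize("minutes, expected", [(5, 0.6), (10, 0.5),
                                                   (20, 0.45)])
    def test_periodic_animal_mpm_depends_on_window(self, minutes, expected):
        """Two brief stops per 5 min: naive MPM falls as the window grows
        because the edge fragments are amortized over more minutes."""
        seq = periodic_two_stop_sequence(minutes)
        assert compute_mpm_naive(seq) == pytest.approx(expected)

    def test_distinguishes_equal_ptm_animals(self):
        assert compute_mpm_naive(one_long_move_sequence()) == pytest.approx(0.1)
        assert compute_mpm_naive(many_short_moves_sequence()) == pytest.approx(1.6)


class TestCPM:
    def test_constant_sequence_is_zero(self):
        assert compute_cpm(parse_binary_string("1" * 50)) == 0.0

    @pytest.mark.parametrize("text, expected", [("110011", 24.0),
                                                ("1010", 60.0)])
    def test_transition_counting(self, text, expected):
        assert compute_cpm(parse_binary_string(text)) == pytest.approx(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 time units"):
            compute_cpm(parse_binary_string("1"))

    @given(st.text(alphabet="01", min_size=2, max_size=400))
    @settings(max_examples=200, derandomize=True)
    def test_mpm_within_edge_effects_of_cpm_half(self, text):
        """Move count differs from change-count/2 only by edge effects."""
        seq = parse_binary_string(text)
        mpm = compute_mpm_naive(seq)
        cpm_half = compute_cpm(seq) / 2.0
        od = seq.od_minutes
        assert cpm_half - 0.5 / od - 1e-9 <= mpm <= cpm_half + 1.0 / od + 1e-9


class TestAMAS:
    def test_interior_bouts_only(self):
        bouts = BoutList([(0, 5), (1, 10), (0, 20), (1, 10), (0, 5)])
        am, as_ = compute_am_as(bouts)
        assert am == pytest.approx(10 / 60)
        assert as_ == pytest.approx(20 / 60)

    def test_single_bout_has_no_interior(self):
        am, as_ = compute_am_as(BoutList([(1, 30)]))
        assert math.isnan(am) and math.isnan(as_)

    def test_state_with_only_edge_bouts_unavailable(self):
        am, as_ = compute_am_as(BoutList([(1, 3), (0, 6), (1, 3)]))
        assert math.isnan(am)
        assert as_ == pytest.approx(6 / 60)

    def test_long_run_am_as_match_ptm_over_mpm(self):
        """On long stationary sequences AM -> PTM/MPM and AS -> (1-PTM)/MPM."""
        M, S, n = 10.0, 20.0, 200_000
        seq = simulate_sequence(SimulationParams(
            mean_move_s=M, mean_stop_s=S, length_units=n, seed=7))
        am, as_ = compute_am_as(run_length_encode(seq))
        true_mpm = 60.0 / (M + S)
        ptm = M / (M + S)
        assert am == pytest.approx(ptm / true_mpm, rel=0.05)
        assert as_ == pytest.approx((1 - ptm) / true_mpm, rel=0.05)


class TestCorrection:
    @pytest.mark.parametrize("mpm, ptm, od, expected", [
        (0.6, 0.4, 2.0, 0.4),
        (0.7, 0.0, 5.0, 0.7),
        (0.5, 1.0, 10.0, 0.4),
    ])
    def test_arithmetic(self, mpm, ptm, od, expected):
        assert correct_mpm(mpm, ptm, od) == pytest.approx(expected)

    def test_negative_result_warned_not_clamped(self):
        with pytest.warns(UserWarning, match="negative"):
            assert correct_mpm(0.1, 0.9, 2.0) == pytest.approx(-0.35)

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            correct_mpm(0.5, 0.5, 0.0)

    def test_study_level_same_arithmetic(self):
        assert study_level_correction(0.6, 0.4, 2.0) == pytest.approx(0.4)
        assert study_level_correction(0.6, 0.0, 2.0) == pytest.approx(0.6)

    def test_study_level_never_adds_bias_under_heterogeneous_od(self):
        """Correcting study means with the arithmetic mean OD removes part
        of the bias (reciprocal of arithmetic mean <= reciprocal of
        harmonic mean) and never over-corrects into extra bias."""
        M, S = 10.0, 20.0
        true_mpm = 60.0 / (M + S)
        rng_seeds = np.random.SeedSequence(42).spawn(1800)
        ods_min = [2.0, 5.0, 10.0]
        mpms, ptms, ods = [], [], []
        for i, child in enumerate(rng_seeds):
            od = ods_min[i % 3]
            seq = simulate_sequence(SimulationParams(
                mean_move_s=M, mean_stop_s=S, length_units=int(od * 60),
                seed=int(child.generate_state(1)[0] % 2**31)))
            mpms.append(compute_mpm_naive(seq))
            ptms.append(compute_ptm(seq))
            ods.append(od)
        bias_before = np.mean(mpms) - true_mpm
        corrected = study_level_correction(float(np.mean(mpms)),
                                           float(np.mean(ptms)),
                                           float(np.mean(ods)))
        bias_after = corrected - true_mpm
        se = np.std(mpms) / np.sqrt(len(mpms))
        assert abs(bias_after) <= abs(bias_before) + 2 * se
        assert bias_before > 0  # the naive mean really is biased upward


class TestPredictedBias:
    def test_relative_is_am_over_od(self):
        assert predicted_bias(0.5, 0.2, 3.0).relative == pytest.approx(1 / 6)

    def test_absolute_is_ptm_over_od(self):
        assert predicted_bias(0.5, 0.4, 2.0).absolute == pytest.approx(0.2)

    def test_zero_am_zero_relative(self):
        assert predicted_bias(0.0, 0.4, 2.0).relative == 0.0


class TestSummarize:
    def test_all_stop_sequence(self):
        idx = summarize(parse_binary_string("0" * 600))
        assert idx.ptm == 0.0
        assert idx.mpm_naive == 0.0
        assert idx.cpm == 0.0
        assert idx.n_moves == 0 and idx.n_stops == 1 and idx.n_changes == 0

    def test_periodic_animal(self):
        idx = summarize(periodic_two_stop_sequence(5))
        assert idx.mpm_naive == pytest.approx(0.6)
        assert idx.mpm_corrected == pytest.approx(0.6 - idx.ptm / 5.0)

    def test_fields_agree_with_individual_operations(self):
        seq = parse_binary_string("110011")
        idx = summarize(seq)
        assert idx.ptm == compute_ptm(seq)
        assert idx.mpm_naive == compute_mpm_naive(seq)
        assert idx.cpm == compute_cpm(seq)
        assert idx.cpm_half == idx.cpm / 2.0
        assert idx.n_changes == 2
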