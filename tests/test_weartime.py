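"""Non-wear detectors against worked examples and brute-force oracles."""

from __future__ import annotations

from datetime import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actipipe import (
    NonWearEpisode,
    SimulationConfig,
    SpuriousCounts,
    WearAlgorithmParams,
    detect_nonwear,
    detect_nonwear_choi,
    detect_nonwear_nhanes,
    detect_nonwear_zero20,
    detection_accuracy,
    reintegrate,
    simulate_recording,
    wear_minutes_per_day,
)
from conftest import START, make_series
from oracles import choi_oracle, nhanes_oracle, random_sparse_stream, zero20_oracle


class TestZero20:
    def test_full_day_of_zeros(self):
        s = make_series([0] * 1440, epoch_length=60)
        mask = detect_nonwear_zero20(s)
        assert not mask.flags.any()
        assert mask.nonwear_intervals == [(0, 1440, 0)]

    def test_runs_below_threshold_stay_wear(self):
        """19 zero minutes, one active minute, 19 zero minutes: no run
        reaches 20 minutes, so the whole stream is wear."""
        s = make_series([0] * 19 + [500] + [0] * 19, epoch_length=60)
        mask = detect_nonwear_zero20(s)
        assert mask.flags.all()

    def test_exact_threshold_flags(self):
        s = make_series([0] * 20, epoch_length=60)
        assert not detect_nonwear_zero20(s).flags.any()

    def test_45_min_block_recovered_at_every_epoch(self):
        """A 45-min true non-wear block is detected in full at each of the
        six epoch lengths (no allowance to interfere)."""
        config = SimulationConfig(
            n_subjects=1,
            n_days=1,
            seed=21,
            wear_schedule=(
                NonWearEpisode(start=time(14, 0), duration_min=45, probability=1.0),
            ),
            spurious_nonwear=SpuriousCounts(rate_per_hour=0.0),
        )
        series, truth = simulate_recording(config, 0)
        expected = (~truth.wear).sum() / 60  # 45, by construction
        assert expected == 45
        for epoch in (1, 5, 10, 15, 30, 60):
            mask = detect_nonwear_zero20(reintegrate(series, epoch))
            # block boundaries are minute-aligned, so detection is exact up
            # to zero seconds bordering the block at fine epochs
            detected = mask.nonwear_seconds() / 60
            assert detected >= 45
            sens, spec = detection_accuracy(mask, truth)
            assert sens == 1.0
            assert spec >= 0.99

    def test_empty_series(self):
        mask = detect_nonwear_zero20(make_series([], epoch_length=60))
        assert mask.n_epochs == 0
        assert mask.nonwear_intervals == []


class TestNhanes:
    def test_allowance_seconds_at_10s_epochs(self):
        """One 7-count epoch inside two hours of zeros consumes 10 s of the
        2-min allowance at 10-s epochs."""
        a1 = np.zeros(720, dtype=int)
        a1[360] = 7
        s = make_series(a1, epoch_length=10)
        mask = detect_nonwear_nhanes(s)
        assert mask.nonwear_intervals == [(0, 720, 10)]
        assert not mask.flags.any()

    def test_allowance_seconds_after_reintegration_to_60s(self):
        """The same 7 counts consume a full 60 s once reintegrated."""
        a1 = np.zeros(720, dtype=int)
        a1[360] = 7
        s60 = reintegrate(make_series(a1, epoch_length=10), 60)
        mask = detect_nonwear_nhanes(s60)
        assert mask.nonwear_intervals == [(0, 120, 60)]
        assert not mask.flags.any()

    def test_budget_exhaustion_terminates_candidate(self):
        """Three separated 50-count minutes in two hours of zeros: the first
        two drain the 120-s budget, the third terminates the candidate."""
        a1 = np.zeros(120, dtype=int)
        a1[[30, 60, 90]] = 50
        s = make_series(a1, epoch_length=60)
        mask = detect_nonwear_nhanes(s)
        wear_oracle, intervals_oracle = nhanes_oracle(a1, 60)
        np.testing.assert_array_equal(mask.flags, wear_oracle)
        assert mask.nonwear_intervals == intervals_oracle
        # candidate closed at the third nonzero epoch with the budget spent
        first = mask.nonwear_intervals[0]
        assert first[1] == 90
        assert first[2] == 120

    def test_count_above_band_terminates(self):
        """A single epoch above the allowance band splits the zeros into two
        qualifying intervals with no allowance consumed."""
        a1 = np.zeros(150, dtype=int)
        a1[75] = 101
        s = make_series(a1, epoch_length=60)
        mask = detect_nonwear_nhanes(s)
        assert mask.nonwear_intervals == [(0, 75, 0), (76, 150, 0)]
        assert mask.flags[75]

    def test_unscaled_band_option(self):
        """With scaling off, a 7-count second is allowance-eligible even at
        1-s epochs and consumes only one second."""
        a1 = np.zeros(7200, dtype=int)
        a1[3600] = 7
        s = make_series(a1, epoch_length=1)
        params = WearAlgorithmParams(algorithm="nhanes", scale_allowance_band=False)
        mask = detect_nonwear_nhanes(s, params)
        assert mask.nonwear_intervals == [(0, 7200, 1)]
        # with the default scaled band the same second terminates the
        # candidate; the remaining 3599 s fall short of the 60-min window
        scaled = detect_nonwear_nhanes(s)
        assert scaled.nonwear_intervals == [(0, 3600, 0)]

    def test_anti_monotone_in_added_counts(self):
        """Raising an epoch inside a detected interval above the band never
        enlarges the detected non-wear."""
        a1 = np.zeros(120, dtype=int)
        a1[40] = 60
        base = detect_nonwear_nhanes(make_series(a1, epoch_length=60))
        spiked = a1.copy()
        spiked[40] = 500
        after = detect_nonwear_nhanes(make_series(spiked, epoch_length=60))
        assert after.nonwear_seconds() <= base.nonwear_seconds()


class TestChoi:
    def test_all_zero_day_fully_nonwear(self):
        for epoch in (1, 15, 60):
            s = make_series([0] * (86400 // epoch), epoch_length=epoch)
            mask = detect_nonwear_choi(s)
            assert not mask.flags.any()
            assert wear_minutes_per_day(mask, START)["wear_min"].iloc[0] == 0.0

    def test_allowance_spell_with_clean_flanks(self):
        """100 zero minutes, one 40-count minute, 100 zero minutes: a single
        201-min non-wear interval (flanks are clean)."""
        a1 = np.zeros(201, dtype=int)
        a1[100] = 40
        s = make_series(a1, epoch_length=60)
        mask = detect_nonwear_choi(s)
        assert mask.nonwear_intervals == [(0, 201, 60)]
        np.testing.assert_array_equal(mask.flags, choi_oracle(a1, 60))

    def test_dirty_flank_rejects_spell(self):
        """A second nonzero minute 10 minutes after the spell makes both
        flanks dirty; neither side reaches 90 eligible minutes alone."""
        a1 = np.zeros(180, dtype=int)
        a1[80] = 40
        a1[90] = 40
        s = make_series(a1, epoch_length=60)
        mask = detect_nonwear_choi(s)
        np.testing.assert_array_equal(mask.flags, choi_oracle(a1, 60))
        assert mask.flags[80] and mask.flags[90]

    def test_wear_minutes_identical_across_epochs(self, default_recording):
        """Choi collapses to 60-s epochs internally, so daily wear minutes
        are identical whatever the input epoch length."""
        series, _ = default_recording
        tables = []
        for epoch in (1, 5, 10, 15, 30, 60):
            mask = detect_nonwear_choi(reintegrate(series, epoch))
            tables.append(wear_minutes_per_day(mask, series.start_time))
        for tab in tables[1:]:
            assert tab["wear_min"].tolist() == tables[0]["wear_min"].tolist()


class TestWearMinutesPerDay:
    def test_full_day_wear_is_1440(self):
        s = make_series([10] * 1440, epoch_length=60)
        mask = detect_nonwear_zero20(s)
        assert wear_minutes_per_day(mask, START)["wear_min"].iloc[0] == 1440.0

    def test_epoch_scaling(self):
        s = make_series([10] * (86400 // 15), epoch_length=15)
        mask = detect_nonwear_zero20(s)
        assert wear_minutes_per_day(mask, START)["wear_min"].iloc[0] == 1440.0

    def test_one_45_min_interval_leaves_1395(self):
        a1 = np.array([10] * 600 + [0] * 45 + [10] * 795)
        s = make_series(a1, epoch_length=60)
        mask = detect_nonwear_zero20(s)
        assert mask.nonwear_seconds() == 45 * 60
        assert wear_minutes_per_day(mask, START)["wear_min"].iloc[0] == 1395.0

    def test_midnight_crossing_interval_split_between_days(self):
        """An interval straddling midnight contributes to each day."""
        a1 = np.concatenate([np.full(1410, 10), np.zeros(60, int), np.full(1410, 10)])
        s = make_series(a1, epoch_length=60)
        mask = detect_nonwear_zero20(s)
        wt = wear_minutes_per_day(mask, START)
        assert wt["wear_min"].tolist() == [1410.0, 1410.0]


class TestDetectionAccuracy:
    def test_perfect_and_inverted_masks(self):
        truth_wear = np.array([True] * 3600 + [False] * 3600)
        from actipipe import WearMask

        perfect = WearMask(60, np.array([True] * 60 + [False] * 60))
        assert detection_accuracy(perfect, truth_wear) == (1.0, 1.0)
        inverted = WearMask(60, np.array([False] * 60 + [True] * 60))
        assert detection_accuracy(inverted, truth_wear) == (0.0, 0.0)

    def test_no_true_nonwear_warns_nan(self):
        from actipipe import WearMask

        mask = WearMask(60, np.ones(60, dtype=bool))
        with pytest.warns(UserWarning, match="sensitivity"):
            sens, spec = detection_accuracy(mask, np.ones(3600, dtype=bool))
        assert np.isnan(sens)
        assert spec == 1.0

    def test_choi_on_120_min_block(self):
        config = SimulationConfig(
            n_subjects=1,
            n_days=1,
            seed=77,
            wear_schedule=(
                NonWearEpisode(start=time(13, 0), duration_min=120, probability=1.0),
            ),
            spurious_nonwear=SpuriousCounts(rate_per_hour=0.0),
        )
        series, truth = simulate_recording(config, 0)
        sens, spec = detection_accuracy(detect_nonwear_choi(series), truth)
        assert sens >= 0.95
        assert spec >= 0.95


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    epoch=st.sampled_from([10, 15, 30, 60]),
    hours=st.integers(2, 24),
)
def test_detectors_match_oracles_property(seed, epoch, hours):
    """Each detector reproduces its brute-force reference on random
    zero-dominated streams of up to 24 hours."""
    rng = np.random.default_rng(seed)
    n = hours * 3600 // epoch
    counts = random_sparse_stream(rng, epoch, n)
    s = make_series(counts, epoch_length=epoch)
    np.testing.assert_array_equal(
        detect_nonwear_zero20(s).flags, zero20_oracle(counts, epoch)
    )
    wear, intervals = nhanes_oracle(counts, epoch)
    mask = detect_nonwear_nhanes(s)
    np.testing.assert_array_equal(mask.flags, wear)
    assert mask.nonwear_intervals == intervals
    np.testing.assert_array_equal(
        detect_nonwear_choi(s).flags, choi_oracle(counts, epoch)
    )


def test_minimum_window_invariant(default_recording):
    """Every detected interval spans at least its algorithm's window."""
    series, _ = default_recording
    day = make_series(series.axis1[:86400], epoch_length=1)
    minimums = {"zero20": 20, "nhanes": 60, "choi": 90}
    for algo, min_minutes in minimums.items():
        mask = detect_nonwear(day, algo)
        for s_idx, e_idx, _ in mask.nonwear_intervals:
            assert (e_idx - s_idx) * mask.epoch_length >= min_minutes * 60
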