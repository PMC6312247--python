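"""Unit and property tests for the nonwear classifier and its oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nciwear import (
    ClassifierParams,
    CountSeries,
    ReclassParams,
    WearLabels,
    classify_wear,
    max_nonwear_hour_counts,
    nonwear_oracle,
    reclassify_nonwear,
)
from nciwear.synthetic import PATTERN_A

from conftest import random_count_series


def series(counts, offset=0):
    return CountSeries("t", np.asarray(counts, dtype=np.int64), offset)


class TestCountSeries:
    def test_rejects_empty_negative_and_fractional(self):
        with pytest.raises(ValueError):
            series([])
        with pytest.raises(ValueError):
            series([0, -1, 0])
        with pytest.raises(ValueError):
            CountSeries("t", np.array([0.5, 1.0]))

    def test_rejects_bad_offset(self):
        with pytest.raises(ValueError):
            series([0], offset=1440)

    def test_accepts_integral_floats(self):
        assert series(np.array([0.0, 2.0])).counts.dtype == np.int64


class TestClassifyWear:
    def test_scenario_a_two_trailing_wear_minutes(self, scenario_a, labels_a):
        # A day of (0, 100, 100) is one long bout ending at the last zero:
        # only the final two 100-count minutes are wear.
        assert labels_a.wear_minutes == 2
        assert labels_a.bouts == ((0, 1438),)
        assert labels_a.wear[1438:].all()

    def test_scenario_b_entirely_wear(self, scenario_b, labels_b):
        # Three consecutive 1-count minutes per hour break every candidate
        # below the 60-minute window: the whole day is wear.
        assert labels_b.wear_minutes == 1440
        assert labels_b.bouts == ()

    @pytest.mark.parametrize(
        "counts, wear_minutes, bouts",
        [
            ([0] * 1440, 0, ((0, 1440),)),
            ([0] * 60, 0, ((0, 60),)),
            ([0] * 59, 59, ()),
            # a terminator splits zero runs below the window
            ([0] * 30 + [101] + [0] * 30, 61, ()),
            # exactly-at-window bout flanked by terminators
            ([500] + [0] * 60 + [500], 2, ((1, 61),)),
            # two allowance minutes inside a bout are tolerated
            ([0] * 30 + [100, 100] + [0] * 30, 0, ((0, 62),)),
            # three consecutive allowance minutes break the candidate
            ([0] * 30 + [1, 1, 1] + [0] * 30, 63, ()),
        ],
    )
    def test_canonical_patterns(self, counts, wear_minutes, bouts):
        lab = classify_wear(series(counts))
        assert lab.wear_minutes == wear_minutes
        assert lab.bouts == bouts

    def test_three_allowance_run_between_long_zero_runs(self):
        # both zero runs clear the window on their own, the run is wear
        lab = classify_wear(series([0] * 60 + [1, 1, 1] + [0] * 60))
        assert lab.bouts == ((0, 60), (63, 123))
        assert lab.wear[60:63].all()

    def test_custom_window(self):
        lab = classify_wear(series([0] * 10), ClassifierParams(window_minutes=10))
        assert lab.nonwear_minutes == 10

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ClassifierParams(window_minutes=0)
        with pytest.raises(ValueError):
            ClassifierParams(max_consecutive_allowance=60)
        with pytest.raises(ValueError):
            ClassifierParams(allowance_max_counts=200, terminate_above_counts=100)


class TestOracle:
    def test_pattern_a_two_hours(self):
        lab = nonwear_oracle(series(PATTERN_A * 2))
        assert lab.bouts == ((0, 118),)
        assert lab.wear[118:].all()

    def test_exact_window_all_zero(self):
        assert nonwear_oracle(series([0] * 60)).bouts == ((0, 60),)

    def test_terminator_splits_below_window(self):
        assert nonwear_oracle(series([0] * 30 + [101] + [0] * 30)).bouts == ()

    def test_length_cap(self):
        with pytest.raises(ValueError):
            nonwear_oracle(series([0] * 10), max_minutes=5)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        counts=st.lists(
            st.sampled_from([0, 0, 0, 0, 1, 2, 50, 99, 100, 101, 500]),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_classifier_on_stratified_random_series(self, counts):
        s = series(counts)
        assert np.array_equal(classify_wear(s).wear, nonwear_oracle(s).wear)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        counts=st.lists(
            st.sampled_from([0, 0, 0, 1, 5, 10, 49, 50, 51]),
            min_size=1,
            max_size=150,
        ),
        window=st.integers(5, 80),
        max_run=st.integers(0, 4),
    )
    def test_matches_classifier_under_varied_params(self, counts, window, max_run):
        params = ClassifierParams(
            window_minutes=window,
            max_consecutive_allowance=min(max_run, window - 1),
            allowance_max_counts=50,
            terminate_above_counts=50,
        )
        s = series(counts)
        assert np.array_equal(
            classify_wear(s, params).wear, nonwear_oracle(s, params).wear
        )


class TestBoutInvariants:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_bout_structure(self, seed):
        rng = np.random.default_rng(seed)
        s = series(random_count_series(rng))
        lab = classify_wear(s)
        params = ClassifierParams()
        assert lab.n_minutes == s.n_minutes
        # bouts are exactly the maximal False-runs
        assert lab.bouts == WearLabels.from_wear(lab.wear).bouts
        for start, end in lab.bouts:
            chunk = s.counts[start:end]
            assert end - start >= params.window_minutes
            assert chunk[0] == 0 and chunk[-1] == 0
            assert chunk.max() <= params.terminate_above_counts
            # no run of 3 consecutive allowance minutes inside a bout
            nz = (chunk > 0).astype(int)
            run = 0
            for v in nz:
                run = run + 1 if v else 0
                assert run <= params.max_consecutive_allowance

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_minutes_above_terminator_are_wear(self, seed):
        rng = np.random.default_rng(seed)
        s = series(random_count_series(rng))
        lab = classify_wear(s)
        assert lab.wear[s.counts > 100].all()


class TestReclassify:
    def test_threshold_4001_is_identity(self, scenario_a, labels_a):
        out = reclassify_nonwear(scenario_a, labels_a, ReclassParams(4001))
        assert np.array_equal(out.wear, labels_a.wear)

    def test_threshold_4000_flips_full_hours(self, scenario_a, labels_a):
        # hours 0-22 are fully nonwear at 4,000 counts each; hour 23 is
        # mixed (its last two minutes are wear) and stays untouched
        out = reclassify_nonwear(scenario_a, labels_a, ReclassParams(4000))
        assert out.wear[: 23 * 60].all()
        assert not out.wear[23 * 60 : 1438].any()

    def test_threshold_zero_means_no_nonwear(self, scenario_a, labels_a):
        out = reclassify_nonwear(scenario_a, labels_a, ReclassParams(0))
        assert out.wear.all()
        assert out.bouts == ()

    def test_bouts_recomputed_without_minimum_length(self):
        # a high-count hour plus a 10-minute zero tail form one bout;
        # flipping the hour leaves a sub-window nonwear remnant
        s = series(list(PATTERN_A) + [0] * 10)
        lab = classify_wear(s)
        assert lab.bouts == ((0, 70),)
        out = reclassify_nonwear(s, lab, ReclassParams(1))
        assert out.bouts == ((60, 70),)

    def test_partial_hour_nonwear_untouched(self):
        # bout spans 90 minutes with counts only in its first clock hour;
        # the second (mixed) hour is not reclassified
        counts = [0, 100, 100] * 20 + [0] * 30 + [500] * 30
        s = series(counts)
        lab = classify_wear(s)
        out = reclassify_nonwear(s, lab, ReclassParams(100))
        assert out.wear[:60].all()
        assert not out.wear[60:90].any()

    def test_respects_clock_alignment(self):
        # same counts, shifted start: hour blocks move with the clock
        counts = [0] * 120
        aligned = series(counts, offset=0)
        shifted = series(counts, offset=30)
        la = reclassify_nonwear(aligned, classify_wear(aligned), ReclassParams(1))
        ls = reclassify_nonwear(shifted, classify_wear(shifted), ReclassParams(1))
        # zero-count hours never reach T=1, so both stay nonwear; sanity only
        assert la.wear.sum() == 0 and ls.wear.sum() == 0
        # hour with counts: offset 30 puts the clock boundary mid-series
        counts = [0] * 30 + list(PATTERN_A) + [0] * 30
        s = series(counts, offset=30)
        lab = classify_wear(s)
        out = reclassify_nonwear(s, lab, ReclassParams(4000))
        assert out.wear[30:90].all()  # the aligned clock hour
        assert not out.wear[:30].any()

    def test_misaligned_labels_rejected(self, scenario_a):
        with pytest.raises(ValueError):
            reclassify_nonwear(
                scenario_a, WearLabels.from_wear(np.ones(10, bool)), ReclassParams(1)
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), t_pair=st.tuples(st.integers(0, 5000), st.integers(0, 5000)))
    def test_monotone_in_threshold(self, seed, t_pair):
        t_hi, t_lo = max(t_pair), min(t_pair)
        rng = np.random.default_rng(seed)
        s = series(random_count_series(rng))
        lab = classify_wear(s)
        wear_hi = reclassify_nonwear(s, lab, ReclassParams(t_hi)).wear
        wear_lo = reclassify_nonwear(s, lab, ReclassParams(t_lo)).wear
        # lowering T only adds wear minutes
        assert np.all(wear_lo | ~wear_hi)


class TestMaxNonwearHourCounts:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (ClassifierParams(), 4000),
            (ClassifierParams(max_consecutive_allowance=0), 0),
            (
                ClassifierParams(allowance_max_counts=50, terminate_above_counts=50),
                2000,
            ),
            (ClassifierParams(max_consecutive_allowance=1), 3000),
        ],
    )
    def test_search_results(self, params, expected):
        assert max_nonwear_hour_counts(params) == expected

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_bound_holds_on_fully_nonwear_hours(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_count_series(rng, max_len=300)
        s = CountSeries("t", counts)
        lab = classify_wear(s)
        bound = max_nonwear_hour_counts()
        for h in range(0, s.n_minutes - 59, 60):
            if not lab.wear[h : h + 60].any():
                assert s.counts[h : h + 60].sum() <= bound
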