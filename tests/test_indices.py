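import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethoindex import (
    DurationProfile,
    ai,
    duration_summary,
    index_report,
    index_vector,
    mbi,
    mmai,
    mmpi,
    near_tie_fraction,
    pairing_means,
)

from conftest import make_encounter, make_group

# random kill-free profiles (scores -4..4, at least one nonzero second)
kill_free_profiles = (
    st.dictionaries(
        st.integers(min_value=-4, max_value=4),
        st.integers(min_value=1, max_value=60),
        min_size=1,
        max_size=9,
    )
    .filter(lambda d: any(s != 0 for s in d))
    .map(DurationProfile)
)


class TestAI:
    def test_hand_computed_weighted_mean(self, mixed_profile):
        # (-2*100 + 3*10) / 110 — ignoring excluded from both sums
        assert ai(mixed_profile) == pytest.approx(-170 / 110)

    def test_single_behaviour(self):
        assert ai(DurationProfile({1: 170})) == 1.0

    def test_all_ignoring_is_missing_not_zero(self):
        assert math.isnan(ai(DurationProfile({0: 170})))

    def test_killing_seconds_enter_numerator_and_denominator(self):
        assert ai(DurationProfile({5: 100, 0: 70})) == 5.0


class TestExtremes:
    def test_mmai_of_constant_peaceful_series_is_negative(self):
        assert mmai(DurationProfile({-4: 170})) == -4

    def test_mmai_mmpi_of_mixed_profile(self, mixed_profile):
        assert mmai(mixed_profile) == 3
        assert mmpi(mixed_profile) == -2

    def test_zero_duration_scores_not_counted(self):
        prof = DurationProfile({-2: 10, 4: 0})
        assert mmai(prof) == -2

    def test_mmpi_of_pure_aggression_is_positive(self):
        assert mmpi(DurationProfile({1: 170})) == 1


class TestDurationSummary:
    def test_partitions_by_sign(self, mixed_profile):
        d = duration_summary(mixed_profile)
        assert (d.d_pcf, d.d_ignore, d.d_agg, d.killed) == (100, 60, 10, False)
        assert d.total_seconds == 170

    def test_killing_counts_as_aggression(self):
        d = duration_summary(DurationProfile({5: 170}))
        assert (d.d_agg, d.killed) == (170, True)

    def test_all_ignoring(self):
        d = duration_summary(DurationProfile({0: 170}))
        assert (d.d_agg, d.d_pcf, d.d_ignore) == (0, 0, 170)


class TestMBICascade:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (15, -2.0),   # peace dominates: d_pcf=100 > 15, d_agg=10 <= 15
            (5, 0.5),     # both exceed t: midrange of (3, -2)
            (120, 0.0),   # neither exceeds t: ignoring dominates
        ],
    )
    def test_hand_traced_cascade(self, mixed_profile, t, expected):
        assert mbi(mixed_profile, t) == expected

    def test_killing_short_circuits_any_threshold(self):
        prof = DurationProfile({-4: 100, 5: 70})
        for t in (0, 50, 170):
            assert mbi(prof, t) == 5.0

    def test_threshold_out_of_range(self, mixed_profile):
        with pytest.raises(ValueError, match="outside"):
            mbi(mixed_profile, 171)
        with pytest.raises(ValueError, match="outside"):
            mbi(mixed_profile, -1)

    def test_strict_comparison_at_boundary(self):
        # d_agg == t is NOT "larger than t"
        prof = DurationProfile({2: 10, 0: 160})
        assert mbi(prof, 10) == 0.0
        assert mbi(prof, 9) == 2.0

    @given(kill_free_profiles)
    @settings(max_examples=100, deadline=None)
    def test_full_length_threshold_gives_zero_for_kill_free(self, prof):
        assert mbi(prof, prof.total_seconds) == 0.0

    @given(kill_free_profiles, st.integers(min_value=0, max_value=100))
    @settings(max_examples=150, deadline=None)
    def test_score_negation_symmetry(self, prof, t):
        t = min(t, prof.total_seconds)
        neg = DurationProfile({-s: d for s, d in prof.durations.items()})
        assert mmai(neg) == -mmpi(prof)
        assert mmpi(neg) == -mmai(prof)
        assert ai(neg) == pytest.approx(-ai(prof))
        assert mbi(neg, t) == pytest.approx(-mbi(prof, t))

    @given(kill_free_profiles.filter(lambda p: 0 not in p.durations))
    @settings(max_examples=100, deadline=None)
    def test_monotone_coherence_without_ignoring(self, prof):
        assert mmpi(prof) <= ai(prof) <= mmai(prof)


class TestAggregation:
    def test_identical_workers_equal_single_worker(self):
        enc2 = make_encounter([{-2: 100, 0: 60, 3: 10}] * 2)
        enc1 = make_encounter([{-2: 100, 0: 60, 3: 10}])
        v2, v1 = index_vector(enc2, 10, 10), index_vector(enc1, 10, 10)
        assert v2.as_dict() == v1.as_dict()

    def test_workers_averaged_with_equal_weight(self):
        enc = make_encounter([{3: 170}, {1: 170}])
        assert index_vector(enc, 10, 10).mmai == 2.0

    def test_nan_ai_worker_dropped_from_encounter_mean(self):
        enc = make_encounter([{0: 170}, {2: 170}])
        assert index_vector(enc, 10, 10).ai == 2.0

    def test_pairing_means_over_replicates(self):
        group = make_group([[{5: 170}]] * 4)
        assert pairing_means(group, 10, 10).mmai == 5.0
        group = make_group([[{s: 170}] for s in (4, 3, 2, 1)])
        assert pairing_means(group, 10, 10).mmai == 2.5
        single = make_group([[{-3: 170}]])
        assert pairing_means(single, 10, 10).mmpi == -3.0

    def test_index_report_columns_and_levels(self):
        group = make_group([[{1: 170}], [{-1: 170}]])
        report = index_report([group], 10, 20, include_encounters=True)
        assert list(report.columns) == [
            "pairing_id", "level", "mmai", "mbi_agg", "ai", "mbi_pcf", "mmpi",
            "n_replicates", "t_agg", "t_pcf",
        ]
        assert list(report["level"]) == ["encounter", "encounter", "pairing_mean"]
        assert report[report.level == "pairing_mean"].iloc[0].n_replicates == 2


class TestNearTies:
    def test_strictly_within_delta_counted(self):
        near = DurationProfile({2: 50, -2: 45, 0: 75})
        far = DurationProfile({2: 60, -2: 45, 0: 65})
        assert near_tie_fraction([near]) == 1.0
        assert near_tie_fraction([far]) == 0.0
        assert near_tie_fraction([near, far]) == 0.5

    def test_exact_delta_not_counted(self):
        prof = DurationProfile({2: 55, -2: 45, 0: 70})
        assert near_tie_fraction([prof], delta=10) == 0.0

    def test_encounter_durations_summed_over_workers(self):
        enc = make_encounter([{2: 50, 0: 120}, {-2: 45, 0: 125}])
        assert near_tie_fraction([enc]) == 1.0
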