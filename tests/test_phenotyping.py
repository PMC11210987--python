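import numpy as np
import pytest

from ckdflow.errors import ContractViolationError, InvalidInputError
from ckdflow.phenotyping import (
    IncidentCkdRecord,
    classify_substage,
    detect_category_drop,
    detect_kidney_failure,
    detect_rapid_progression,
    find_incident_ckd_g3,
    fit_egfr_slope,
    resolve_outcome,
)

from conftest import random_series
from oracles import (
    oracle_category_drop,
    oracle_incident,
    oracle_kidney_failure,
    oracle_ols_slope,
    oracle_outcome,
    oracle_rapid,
    oracle_substage,
)


def make_record(index_time=0.0, inclusion=56.0, substage="G3a"):
    return IncidentCkdRecord("p", index_time, inclusion, substage)


class TestCaseFinding:
    def test_pair_at_90_days(self):
        rec = find_incident_ckd_g3([0.0, 90.0], [55.0, 52.0], -100.0, 400.0)
        assert rec is not None
        assert rec.index_time == 90.0
        assert rec.inclusion_egfr == 52.0

    def test_gap_89_days_fails(self):
        assert find_incident_ckd_g3([0.0, 89.0], [55.0, 52.0], -100.0, 400.0) is None

    def test_prevalent_pair_blocks_later_incident(self):
        # qualifying pair completes during lookback -> excluded even though a
        # later pair completes inside the window
        times = [0.0, 100.0, 500.0, 600.0]
        egfr = [55.0, 52.0, 50.0, 48.0]
        rec, reason = find_incident_ckd_g3(times, egfr, 400.0, 800.0, return_reason=True)
        assert rec is None and reason == "prevalent"

    def test_krt_before_index_excludes(self):
        rec, reason = find_incident_ckd_g3(
            [0.0, 100.0], [55.0, 52.0], -100.0, 400.0, krt_time=50.0, return_reason=True
        )
        assert rec is None and reason == "prior_krt"

    def test_after_window_excludes(self):
        rec, reason = find_incident_ckd_g3(
            [500.0, 600.0], [55.0, 52.0], -100.0, 400.0, return_reason=True
        )
        assert rec is None and reason == "after_window"

    def test_egfr_60_is_out_of_band(self):
        assert find_incident_ckd_g3([0.0, 100.0], [60.0, 52.0], -100.0, 400.0) is None

    def test_unsorted_rejected(self):
        with pytest.raises(ContractViolationError):
            find_incident_ckd_g3([10.0, 0.0], [50.0, 50.0], -100.0, 400.0)

    def test_fuzz_against_all_pairs_oracle(self, rng):
        for _ in range(2000):
            times, egfr = random_series(rng, t_max=1500, low=20, high=80)
            krt = float(rng.uniform(0, 1500)) if rng.uniform() < 0.2 else None
            rec, reason = find_incident_ckd_g3(
                times, egfr, 400.0, 1200.0, krt_time=krt, return_reason=True
            )
            expected, expected_reason = oracle_incident(
                list(times), list(egfr), 400.0, 1200.0, krt_time=krt
            )
            assert reason == expected_reason
            if expected is None:
                assert rec is None
            else:
                assert (rec.index_time, rec.inclusion_egfr) == expected


class TestSubstage:
    def test_two_band_values_100_days_apart(self):
        assert classify_substage([0.0, 100.0], [40.0, 42.0], 100.0) == "G3b"

    def test_single_band_value(self):
        assert classify_substage([0.0, 100.0], [40.0, 55.0], 100.0) == "G3a"

    def test_89_days_is_g3a(self):
        assert classify_substage([0.0, 89.0], [40.0, 44.0], 89.0) == "G3a"

    def test_only_measurements_at_or_before_index_count(self):
        assert classify_substage([0.0, 100.0, 200.0], [40.0, 55.0, 42.0], 100.0) == "G3a"

    def test_fuzz_against_oracle(self, rng):
        for _ in range(2000):
            times, egfr = random_series(rng, t_max=600, low=25, high=65)
            index = float(rng.uniform(0, 600))
            assert classify_substage(times, egfr, index) == oracle_substage(
                list(times), list(egfr), index
            )


class TestSlope:
    def test_two_point_line(self):
        fit = fit_egfr_slope([0.0, 365.25], [50.0, 44.0])
        assert fit.slope == pytest.approx(-6.0)
        assert fit.n_points == 2

    def test_exact_collinear(self):
        t = np.array([0.0, 180.0, 365.25])
        y = 60.0 - 5.0 * t / 365.25
        fit = fit_egfr_slope(t, y)
        assert fit.slope == pytest.approx(-5.0)
        assert fit.intercept == pytest.approx(60.0)

    def test_noisy_cloud_matches_closed_form(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 8))
            t = np.sort(rng.uniform(0, 900, size=n))
            if np.ptp(t) == 0:
                continue
            y = rng.uniform(20, 80, size=n)
            fit = fit_egfr_slope(t, y)
            slope, intercept = oracle_ols_slope(list(t), list(y))
            assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)

    def test_degenerate(self):
        with pytest.raises(InvalidInputError):
            fit_egfr_slope([5.0, 5.0], [50.0, 40.0])
        with pytest.raises(InvalidInputError):
            fit_egfr_slope([5.0], [50.0])


# a trajectory exercising every clause: inclusion 56 at day 0, decline to
# m1 = 48 at day 200 (earlier values stay above 51 so m1 is the first
# candidate), confirmation candidates appended per test
BASE_T = [0.0, 60.0, 130.0, 200.0]
BASE_E = [56.0, 54.0, 51.5, 48.0]


class TestRapidProgression:
    def test_confirmed_event_at_first_confirmatory_measurement(self):
        t = BASE_T + [260.0]
        e = BASE_E + [47.0]
        rec = make_record()
        assert detect_rapid_progression(t, e, rec, True) == 260.0
        assert oracle_rapid(t, e, 0.0, 56.0, True) == 260.0

    def test_flat_series_no_event(self):
        rec = make_record()
        t = [0.0, 100.0, 200.0, 300.0]
        e = [56.0, 56.0, 56.0, 56.0]
        assert detect_rapid_progression(t, e, rec, True) is None
        assert detect_rapid_progression(t, e, rec, False) is None

    @pytest.mark.parametrize(
        "offset,expected_confirmed",
        [(29.0, None), (30.0, 230.0), (180.0, 380.0), (181.0, None)],
    )
    def test_confirmation_window_boundaries(self, offset, expected_confirmed):
        t = BASE_T + [200.0 + offset]
        e = BASE_E + [47.0]
        rec = make_record()
        assert detect_rapid_progression(t, e, rec, True) == expected_confirmed
        # potential mode never needs the confirmation
        assert detect_rapid_progression(t, e, rec, False) == 200.0

    def test_confirmation_by_higher_value_satisfying_criteria(self):
        # confirmatory value above m1 but itself satisfying all clauses
        t = BASE_T + [260.0]
        e = BASE_E + [48.5]  # > m1's 48 but <= 51 and on a steep slope
        rec = make_record()
        got = detect_rapid_progression(t, e, rec, True)
        assert got == 260.0
        assert oracle_rapid(t, e, 0.0, 56.0, True) == 260.0

    def test_drop_less_than_5_never_qualifies(self):
        rec = make_record()
        t = [0.0, 100.0, 200.0, 300.0]
        e = [56.0, 54.0, 52.0, 51.5]  # all > 51
        assert detect_rapid_progression(t, e, rec, False) is None

    def test_shallow_slope_fails(self):
        # drop >= 5 with 3 points in the trailing year, but slope ~ -3/yr
        rec = make_record()
        t = [0.0, 740.0, 900.0, 1095.0]
        e = [56.0, 54.0, 52.0, 50.9]
        assert detect_rapid_progression(t, e, rec, False) is None
        assert oracle_rapid(t, e, 0.0, 56.0, False) is None

    def test_window_needs_three_points(self):
        rec = make_record()
        # only m1 and one other point inside its trailing year
        t = [0.0, 500.0, 640.0]
        e = [56.0, 54.0, 45.0]
        assert detect_rapid_progression(t, e, rec, False) is None

    def test_span_needs_90_days(self):
        rec = make_record()
        t = [0.0, 400.0, 440.0, 480.0]
        e = [56.0, 54.0, 50.0, 45.0]  # window points span 80 days only
        assert detect_rapid_progression(t, e, rec, False) is None
        assert oracle_rapid(t, e, 0.0, 56.0, False) is None

    def test_failed_candidate_does_not_block_later_candidate(self):
        # first candidate at 200 never confirmed (next point 181+ days later),
        # second candidate at 390 confirmed at 450
        t = BASE_T + [390.0, 450.0]
        e = BASE_E + [44.0, 43.0]
        rec = make_record()
        got = detect_rapid_progression(t, e, rec, True)
        assert got == oracle_rapid(t, e, 0.0, 56.0, True)
        assert got is not None

    def test_fuzz_against_step_oracle(self, rng):
        for _ in range(1500):
            times, egfr = random_series(rng, n_min=2, n_max=15, t_max=900, low=25, high=65)
            inclusion = float(rng.uniform(30, 59.9))
            rec = make_record(index_time=0.0, inclusion=inclusion)
            times = times - times.min()  # keep index at 0 with history at index
            for confirm in (True, False):
                got = detect_rapid_progression(times, egfr, rec, confirm)
                want = oracle_rapid(list(times), list(egfr), 0.0, inclusion, confirm)
                assert got == want

    def test_confirmed_subset_of_potential(self, rng):
        for _ in range(500):
            times, egfr = random_series(rng, n_min=3, n_max=15, t_max=900, low=25, high=65)
            rec = make_record(inclusion=float(rng.uniform(30, 59.9)))
            confirmed = detect_rapid_progression(times, egfr, rec, True)
            potential = detect_rapid_progression(times, egfr, rec, False)
            if confirmed is not None:
                assert potential is not None
                assert potential <= confirmed


class TestCategoryDrop:
    def test_forced_event(self):
        rec = make_record(inclusion=56.0)
        assert detect_category_drop([0.0, 50.0], [56.0, 41.0], rec) == 50.0

    def test_category_change_without_25pct_drop(self):
        rec = make_record(inclusion=56.0)
        assert detect_category_drop([0.0, 50.0], [56.0, 44.0], rec) is None

    def test_g3b_inclusion_to_g4(self):
        rec = make_record(inclusion=32.0, substage="G3b")
        assert detect_category_drop([0.0, 50.0], [32.0, 24.0], rec) == 50.0

    def test_fuzz_against_oracle(self, rng):
        for _ in range(2000):
            times, egfr = random_series(rng, t_max=900, low=5, high=70)
            inclusion = float(rng.uniform(30, 59.9))
            rec = make_record(inclusion=inclusion)
            got = detect_category_drop(times, egfr, rec)
            assert got == oracle_category_drop(list(times), list(egfr), 0.0, inclusion)


class TestKidneyFailure:
    def test_pair_90_days(self):
        assert detect_kidney_failure([0.0, 95.0], [14.0, 13.0]) == 95.0

    def test_single_low_value(self):
        assert detect_kidney_failure([0.0], [10.0]) is None

    def test_krt_earlier_than_pair(self):
        assert detect_kidney_failure([0.0, 120.0], [14.0, 13.0], krt_time=50.0) == 50.0

    def test_fuzz_against_oracle(self, rng):
        for _ in range(2000):
            times, egfr = random_series(rng, t_max=900, low=5, high=40)
            krt = float(rng.uniform(0, 900)) if rng.uniform() < 0.3 else None
            got = detect_kidney_failure(times, egfr, krt_time=krt)
            assert got == oracle_kidney_failure(list(times), list(egfr), krt_time=krt)


class TestOutcomeResolution:
    def test_event_before_death(self):
        rec = resolve_outcome("p", "rapid", 0.0, 100.0, 200.0, None, 1000.0)
        assert (rec.time, rec.code) == (100.0, 1)

    def test_death_without_event(self):
        rec = resolve_outcome("p", "rapid", 0.0, None, 100.0, None, 1000.0)
        assert (rec.time, rec.code) == (100.0, 2)

    def test_emigration_before_event(self):
        rec = resolve_outcome("p", "rapid", 0.0, 80.0, None, 50.0, 1000.0)
        assert (rec.time, rec.code) == (50.0, 0)

    def test_event_before_index_rejected(self):
        with pytest.raises(ContractViolationError):
            resolve_outcome("p", "rapid", 100.0, 50.0, None, None, 1000.0)

    def test_enumeration_of_all_orderings(self):
        # every ordering of {event, death, emigration, admin} incl. absences/ties
        grid = [None, 50.0, 100.0, 150.0]
        for event in grid:
            for death in grid:
                for emigration in grid:
                    for admin in (100.0, 200.0):
                        rec = resolve_outcome("p", "o", 0.0, event, death, emigration, admin)
                        time, code = oracle_outcome(0.0, event, death, emigration, admin)
                        assert (rec.time, rec.code) == (time, code)
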