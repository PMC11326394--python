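"""Acuity phenotyping: cohort filters, window grids, the rolling
transfusion flag, state/transition/onset labels, transition matrices."""

import numpy as np
import pytest

from icuacuity import (
    ClinicalEvent,
    PhenotypeConfig,
    StayRecord,
    TherapyInterval,
    apply_cohort_filters,
    build_window_grid,
    label_onsets,
    label_states,
    label_stay,
    label_transitions,
    rolling_bt_flag,
    transition_matrix,
)
from icuacuity.records import REQUIRED_VITALS

CFG = PhenotypeConfig()


def make_stay(
    los=48.0,
    therapies=(),
    bt_events=(),
    disposition="discharged_alive",
    vitals=REQUIRED_VITALS,
    stay_id="s1",
):
    events = [ClinicalEvent(1.0 + 0.1 * i, v, 100.0) for i, v in enumerate(vitals)]
    return StayRecord(
        stay_id=stay_id,
        events=events,
        static={"age": 60.0, "sex": 1.0},
        therapies=list(therapies),
        bt_events=sorted(bt_events),
        disposition=disposition,
        disposition_time_hours=los,
    )


class TestCohortFilters:
    @pytest.mark.parametrize(
        "los,expected_reason",
        [(7.9, "los_below_min"), (31 * 24.0, "los_above_max")],
    )
    def test_length_of_stay_bounds(self, los, expected_reason):
        kept, excluded = apply_cohort_filters([make_stay(los=los)], CFG)
        assert kept == []
        assert excluded[0][1] == expected_reason

    def test_boundary_los_values_kept(self):
        kept, _ = apply_cohort_filters(
            [make_stay(los=8.0), make_stay(los=30 * 24.0)], CFG
        )
        assert len(kept) == 2

    def test_missing_vital_excluded_with_name(self):
        stay = make_stay(vitals=[v for v in REQUIRED_VITALS if v != "SPO2"])
        kept, excluded = apply_cohort_filters([stay], CFG)
        assert kept == []
        assert excluded[0][1] == "missing_vital:SPO2"

    def test_missing_static_excluded(self):
        stay = make_stay()
        stay.static["age"] = float("nan")
        _, excluded = apply_cohort_filters([stay], CFG)
        assert excluded[0][1] == "missing_static:age"

    def test_complete_stay_kept(self):
        kept, excluded = apply_cohort_filters([make_stay(los=48.0)], CFG)
        assert len(kept) == 1 and excluded == []


class TestWindowGrid:
    def test_16h_stay_tiles_into_three_prediction_windows(self):
        grid = build_window_grid(make_stay(los=16.0), CFG)
        assert [(p, q) for _, _, p, q in grid] == [(4.0, 8.0), (8.0, 12.0), (12.0, 16.0)]
        assert [(o, p) for o, p, _, _ in grid] == [(0.0, 4.0), (4.0, 8.0), (8.0, 12.0)]

    def test_minimum_stay_has_one_window(self):
        grid = build_window_grid(make_stay(los=8.0), CFG)
        assert [(p, q) for _, _, p, q in grid] == [(4.0, 8.0)]

    def test_short_stay_gives_empty_grid(self):
        assert build_window_grid(make_stay(los=7.0), CFG) == []

    def test_final_partial_window_kept(self):
        grid = build_window_grid(make_stay(los=14.5), CFG)
        assert grid[-1][2:] == (12.0, 14.5)

    def test_half_open_event_assignment(self):
        # an event at exactly t=8 belongs to the window starting at 8
        obs = [(o_lo, o_hi) for o_lo, o_hi, _, _ in build_window_grid(make_stay(16.0), CFG)]
        containing = [i for i, (lo, hi) in enumerate(obs) if lo <= 8.0 < hi]
        assert containing == [2]

    def test_24h_windows_scale_grid_down(self):
        stay = make_stay(los=240.0)
        grid4 = build_window_grid(stay, PhenotypeConfig(window_hours=4.0))
        grid24 = build_window_grid(stay, PhenotypeConfig(window_hours=24.0))
        assert abs(len(grid4) / 6 - len(grid24)) <= 1


class TestRollingBtFlag:
    def test_ten_units_within_trailing_day(self):
        events = [(float(h), 1.0) for h in range(1, 11)]
        assert rolling_bt_flag(events, 12.0, CFG) == 1

    def test_units_outside_trailing_day_ignored(self):
        assert rolling_bt_flag([(0.0, 10.0)], 25.0, CFG) == 0
        assert rolling_bt_flag([(0.0, 10.0)], 20.0, CFG) == 1

    def test_negative_units_rejected(self):
        with pytest.raises(ValueError, match="units"):
            rolling_bt_flag([(1.0, -2.0)], 2.0, CFG)

    def test_matches_brute_force_on_random_draws(self, rng):
        for _ in range(500):
            n = rng.integers(0, 20)
            events = sorted(
                (float(t), float(u))
                for t, u in zip(rng.uniform(0, 72, n), rng.integers(1, 5, n))
            )
            t = float(rng.uniform(0, 72))
            brute = sum(u for ti, u in events if t - 24.0 < ti <= t) >= 10
            assert rolling_bt_flag(events, t, CFG) == int(brute)


class TestStateLabels:
    def test_no_therapy_discharged(self):
        stay = make_stay(los=16.0)
        grid = build_window_grid(stay, CFG)
        assert label_states(stay, grid, CFG) == ["stable", "stable", "discharge"]

    def test_mv_interval_marks_overlapping_windows(self):
        stay = make_stay(los=16.0, therapies=[TherapyInterval("MV", 5.0, 9.0)])
        grid = build_window_grid(stay, CFG)
        assert label_states(stay, grid, CFG) == ["unstable", "unstable", "discharge"]

    def test_terminal_deceased_overrides_active_therapy(self):
        stay = make_stay(
            los=16.0,
            therapies=[TherapyInterval("VP", 5.0, 16.0)],
            disposition="deceased",
        )
        grid = build_window_grid(stay, CFG)
        assert label_states(stay, grid, CFG) == ["unstable", "unstable", "deceased"]

    def test_zero_length_vp_push_fills_enclosing_window(self):
        stay = make_stay(los=16.0, therapies=[TherapyInterval("VP", 9.5, 9.5)])
        grid = build_window_grid(stay, CFG)
        assert label_states(stay, grid, CFG) == ["stable", "unstable", "discharge"]

    def test_bt_flag_marks_windows(self):
        # 10 units over hours 1..10 -> trailing sum reaches 10 at hour 10
        stay = make_stay(los=40.0, bt_events=[(float(h), 1.0) for h in range(1, 11)])
        grid = build_window_grid(stay, CFG)
        states = label_states(stay, grid, CFG)
        # flag stays on until hour 25 (first unit expires at 1+24)
        assert states[1] == "unstable"  # window [8,12) contains hour 10
        assert states[5] == "unstable"  # window [24,28): still >=10 at t=24.9? no: flag at lo=24
        assert states[-1] == "discharge"

    def test_therapy_outside_stay_is_data_error(self):
        stay = make_stay(los=16.0)
        stay.therapies.append(TherapyInterval("MV", 20.0, 22.0))
        with pytest.raises(ValueError, match="outside"):
            label_states(stay, build_window_grid(stay, CFG), CFG)


class TestTransitions:
    def test_stable_to_unstable(self):
        out = label_transitions(["stable", "unstable", "unstable"])
        assert [o["stable_to_unstable"] for o in out] == [None, 1, 0]

    def test_unstable_to_stable(self):
        out = label_transitions(["unstable", "stable"])
        assert [o["unstable_to_stable"] for o in out] == [None, 1]

    def test_all_stable_has_no_transitions(self):
        out = label_transitions(["stable"] * 5)
        assert all(o["stable_to_unstable"] == 0 for o in out[1:])
        assert all(o["unstable_to_stable"] == 0 for o in out[1:])


class TestOnsets:
    def test_mv_start_in_second_window(self):
        stay = make_stay(los=12.0, therapies=[TherapyInterval("MV", 9.0, 11.0)])
        grid = build_window_grid(stay, CFG)
        onsets = label_onsets(stay, grid, CFG)
        assert [o["mv_onset"] for o in onsets] == [0, 1]

    def test_continuous_vp_from_admission_never_onsets(self):
        stay = make_stay(los=24.0, therapies=[TherapyInterval("VP", 0.0, 24.0)])
        grid = build_window_grid(stay, CFG)
        onsets = label_onsets(stay, grid, CFG)
        assert all(o["vp_onset"] == 0 for o in onsets)

    def test_two_separated_crrt_intervals_give_two_onsets(self):
        stay = make_stay(
            los=40.0,
            therapies=[
                TherapyInterval("CRRT", 5.0, 7.0),
                TherapyInterval("CRRT", 25.0, 30.0),
            ],
        )
        grid = build_window_grid(stay, CFG)
        onsets = [o["crrt_onset"] for o in label_onsets(stay, grid, CFG)]
        assert sum(onsets) == 2

    def test_restart_within_next_window_is_not_an_onset(self):
        # second interval starts while therapy ran during the previous window
        stay = make_stay(
            los=24.0,
            therapies=[
                TherapyInterval("MV", 5.0, 7.0),
                TherapyInterval("MV", 9.0, 11.0),
            ],
        )
        grid = build_window_grid(stay, CFG)
        onsets = [o["mv_onset"] for o in label_onsets(stay, grid, CFG)]
        assert onsets == [1, 0, 0, 0, 0]


class TestLabelStay:
    def test_one_hot_primary_and_terminal_only_final(self):
        stay = make_stay(los=20.0, therapies=[TherapyInterval("MV", 6.0, 10.0)])
        windows = label_stay(stay, CFG)
        for w in windows:
            primaries = [w.labels[s] for s in ("discharge", "stable", "unstable", "deceased")]
            assert sum(primaries) == 1
        assert all(w.labels["discharge"] == 0 for w in windows[:-1])
        assert windows[-1].labels["discharge"] == 1

    def test_first_window_transition_masked(self):
        windows = label_stay(make_stay(los=20.0), CFG)
        assert windows[0].mask["stable_to_unstable"] == 0
        assert windows[0].mask["unstable_to_stable"] == 0
        assert all(w.mask["stable_to_unstable"] == 1 for w in windows[1:])


class TestTransitionMatrix:
    def test_hand_counted_cohort(self):
        # 8 stable->stable and 2 stable->unstable consecutive pairs
        cohort = [["stable", "stable", "stable"]] * 4 + [
            ["stable", "unstable", "stable"]
        ]
        # pairs: 4*2 stable->stable; 1 stable->unstable; 1 unstable->stable
        tm = transition_matrix(cohort)
        assert tm.loc["stable", "stable"] == pytest.approx(8 / 9)
        assert tm.loc["stable", "unstable"] == pytest.approx(1 / 9)
        assert tm.loc["unstable", "stable"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        cohort = [
            ["stable", "unstable", "unstable", "stable", "discharge"],
            ["unstable", "stable", "deceased"],
        ]
        tm = transition_matrix(cohort)
        np.testing.assert_allclose(tm.sum(axis=1).to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_always_stable_row(self):
        tm = transition_matrix([["stable", "stable", "stable", "unstable", "unstable"]])
        assert tm.loc["stable", "stable"] == pytest.approx(2 / 3)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            transition_matrix([["stable"]])
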