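"""Patient movement, orientation transitions, the cue automaton, and nurses."""

import math

import numpy as np
import pytest

from wardsim import IATParams, NurseParams, PatientParams, parse_policy
from wardsim.agents import (
    CANCELLED,
    CUE_FAIL,
    CUE_ISSUED,
    CUE_SUCCESS,
    DETECT,
    NURSE_CALLED,
    Guidance,
    NurseState,
    NurseTask,
    Orientation,
    PatientState,
    Policy,
    PolicyVariant,
    disoriented_move,
    iat_step,
    nurse_step,
    oriented_move,
    sample_step_length,
    set_route,
    transition_orientation,
)
from wardsim.errors import ConfigError
from wardsim.world import Position, cell_center, path_length, shortest_route

from conftest import corridor_plan


def make_patient(plan, dest="B", pos=None, **kw) -> PatientState:
    dest_cell = plan.destinations[dest]
    patient = PatientState(
        id="p0",
        position=pos or cell_center(plan.destinations["A"]),
        destination=dest,
        dest_cell=dest_cell,
        **kw,
    )
    return patient


class TestStepSampler:
    def test_zero_sd_is_degenerate(self):
        params = PatientParams(dis_level=0, mean_step=0.7, sd_step=0.0)
        rng = np.random.default_rng(0)
        assert all(sample_step_length(params, rng) == 0.7 for _ in range(10))

    def test_empirical_sd_matches_declared(self):
        params = PatientParams(dis_level=0, mean_step=1.0, sd_step=0.2)
        rng = np.random.default_rng(1)
        draws = np.array([sample_step_length(params, rng) for _ in range(50_000)])
        # truncation at 0 is a 5-sigma event here; sd is effectively untouched
        assert abs(draws.std() - 0.2) / 0.2 < 0.05
        assert abs(draws.mean() - 1.0) < 0.01

    def test_truncation_bound(self):
        params = PatientParams(dis_level=0, mean_step=0.1, sd_step=5.0)
        rng = np.random.default_rng(2)
        assert min(sample_step_length(params, rng) for _ in range(1000)) >= 0.0


class TestOrientedMove:
    def test_clamps_at_destination(self):
        plan = corridor_plan(10)
        params = PatientParams(dis_level=0, mean_step=1.0, sd_step=0.0)
        patient = make_patient(plan, pos=Position(10.3, 1.5))
        patient.waypoints = [cell_center((1, 10))]  # 0.2 cells away
        reached = oriented_move(patient, params, np.random.default_rng(0))
        assert reached and patient.position == cell_center((1, 10))

    def test_deterministic_corridor_takes_route_length_ticks(self):
        # route of total length 10 at unit step: exactly 10 ticks
        plan = corridor_plan(11)
        params = PatientParams(dis_level=0, mean_step=1.0, sd_step=0.0)
        patient = make_patient(plan)
        set_route(patient, plan)
        ticks = 0
        while True:
            ticks += 1
            if oriented_move(patient, params, np.random.default_rng(0)):
                break
        assert ticks == 10

    def test_empty_route_away_from_destination_is_inconsistent(self):
        plan = corridor_plan(10)
        params = PatientParams(dis_level=0)
        patient = make_patient(plan)
        patient.waypoints = []
        from wardsim.errors import WardSimError

        with pytest.raises(WardSimError):
            oriented_move(patient, params, np.random.default_rng(0))


class TestDisorientedMove:
    def test_boxed_in_patient_stays(self):
        plan = corridor_plan(1, destinations={"A": 0, "B": 0})
        # single walkable cell; only destination constraint relaxed via same cell
        patient = make_patient(plan, dest="A", pos=cell_center((1, 1)))
        patient.orientation = Orientation.DISORIENTED
        params = PatientParams(dis_level=0, mean_step=1.0, sd_step=0.0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            disoriented_move(patient, plan, params, rng)
            assert patient.position == cell_center((1, 1))

    def test_wandering_never_enters_walls(self, ward):
        patient = make_patient(ward, dest="dining", pos=cell_center((5, 5)))
        patient.orientation = Orientation.DISORIENTED
        params = PatientParams(dis_level=0)
        rng = np.random.default_rng(4)
        for _ in range(2000):
            disoriented_move(patient, ward, params, rng)
            assert ward.is_walkable_position(patient.position)

    def test_zero_turn_range_walks_straight(self):
        plan = corridor_plan(60)
        params = PatientParams(dis_level=0, mean_step=1.0, sd_step=0.0, turn_range=0.0)
        patient = make_patient(plan, pos=cell_center((1, 1)))
        patient.orientation = Orientation.DISORIENTED
        patient.heading = 0.0  # along the corridor
        rng = np.random.default_rng(5)
        traj = [patient.position]
        for _ in range(30):
            disoriented_move(patient, plan, params, rng)
            traj.append(patient.position)
        assert path_length(traj) == pytest.approx(30 * 1.0)


class TestOrientationTransitions:
    def test_zero_dis_level_never_disorients(self):
        plan = corridor_plan(10)
        patient = make_patient(plan)
        params = PatientParams(dis_level=0.0)
        rng = np.random.default_rng(6)
        assert all(
            transition_orientation(patient, params, rng) is None for _ in range(1000)
        )

    def test_certain_disorientation_fires_first_tick(self):
        plan = corridor_plan(10)
        patient = make_patient(plan)
        params = PatientParams(dis_level=1.0)
        assert transition_orientation(patient, params, np.random.default_rng(7)) == "DISORIENT"
        assert patient.orientation is Orientation.DISORIENTED

    def test_disorientation_rate_within_99pct_binomial_interval(self):
        # 10_000 independent decision points at dis_level 0.25
        plan = corridor_plan(10)
        params = PatientParams(dis_level=0.25)
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(10_000):
            patient = make_patient(plan)
            if transition_orientation(patient, params, rng) == "DISORIENT":
                hits += 1
        assert 0.238 <= hits / 10_000 <= 0.262

    def test_guided_patients_never_transition(self):
        plan = corridor_plan(10)
        patient = make_patient(plan)
        patient.orientation = Orientation.DISORIENTED
        patient.guidance = Guidance.NURSE_GUIDED
        params = PatientParams(dis_level=1.0, reorient_prob=1.0)
        assert transition_orientation(patient, params, np.random.default_rng(9)) is None


class TestCueAutomaton:
    def _disoriented_patient(self, plan):
        patient = make_patient(plan)
        patient.orientation = Orientation.DISORIENTED
        return patient

    def test_no_help_policy_is_vacuous(self):
        plan = corridor_plan(10)
        patient = self._disoriented_patient(plan)
        iat = IATParams(p_detect=1.0, p_cue_success=1.0, cue_cooldown=1)
        policy = Policy(PolicyVariant.NO_HELP)
        rng = np.random.default_rng(10)
        assert all(iat_step(patient, iat, policy, rng) == [] for _ in range(50))

    def test_nhelp_zero_calls_on_detection_tick(self):
        plan = corridor_plan(10)
        patient = self._disoriented_patient(plan)
        iat = IATParams(p_detect=1.0, p_cue_success=0.0, cue_cooldown=1)
        policy = parse_policy("smart_watch:0")
        events = iat_step(patient, iat, policy, np.random.default_rng(11))
        assert events == [DETECT, NURSE_CALLED]

    def test_deterministic_automaton_sequence(self):
        # p_detect=1, p_cue_success=0, n_help=2, cooldown=1
        plan = corridor_plan(10)
        patient = self._disoriented_patient(plan)
        iat = IATParams(p_detect=1.0, p_cue_success=0.0, cue_cooldown=1)
        policy = parse_policy("smart_watch:2")
        rng = np.random.default_rng(12)
        seq = []
        for _ in range(10):
            seq.extend(iat_step(patient, iat, policy, rng))
        assert seq == [DETECT, CUE_ISSUED, CUE_FAIL, CUE_ISSUED, CUE_FAIL, NURSE_CALLED]

    @pytest.mark.parametrize("n_help", [0, 1, 3, 5])
    def test_exactly_nhelp_cue_fails_per_episode(self, n_help):
        plan = corridor_plan(10)
        iat = IATParams(p_detect=1.0, p_cue_success=0.0, cue_cooldown=1)
        policy = parse_policy(f"smart_watch:{n_help}")
        for seed in range(100):
            patient = self._disoriented_patient(plan)
            rng = np.random.default_rng(seed)
            events = []
            for _ in range(5 * (n_help + 2)):
                events.extend(iat_step(patient, iat, policy, rng))
            assert events.count(CUE_FAIL) == n_help
            assert events.count(NURSE_CALLED) == 1
            assert patient.failed_cues <= n_help + 1

    def test_cue_success_resets_episode(self):
        plan = corridor_plan(10)
        patient = self._disoriented_patient(plan)
        iat = IATParams(p_detect=1.0, p_cue_success=1.0, cue_cooldown=1)
        policy = parse_policy("smart_watch:5")
        rng = np.random.default_rng(13)
        seq = []
        for _ in range(3):
            seq.extend(iat_step(patient, iat, policy, rng))
        assert CUE_SUCCESS in seq
        assert patient.orientation is Orientation.ORIENTED
        assert patient.failed_cues == 0 and not patient.detected


class TestNurses:
    def test_arrival_after_distance_over_speed_ticks(self):
        # straight corridor, nurse 6 cells from the patient, speed 2 -> 3 ticks
        plan = corridor_plan(12)
        params = NurseParams(speed=2.0)
        patient = make_patient(plan, pos=cell_center((1, 8)))
        patient.orientation = Orientation.DISORIENTED
        nurse = NurseState(
            id="n0",
            position=cell_center((1, 2)),
            station=(1, 2),
            task=NurseTask.RESPONDING,
            assigned_patient="p0",
        )
        policy = parse_policy("smart_watch:0")
        assigned = {"p0"}
        ticks = 0
        while nurse.task is NurseTask.RESPONDING:
            ticks += 1
            nurse_step(nurse, params, plan, {"p0": patient}, policy, assigned)
        assert ticks == math.ceil(6 / 2.0)
        assert nurse.task is NurseTask.GUIDING

    def test_discovery_within_radius_same_tick(self):
        plan = corridor_plan(12)
        params = NurseParams(discovery_radius=5.0)
        patient = make_patient(plan, pos=Position(2.0, 1.5))
        patient.orientation = Orientation.DISORIENTED
        nurse = NurseState(id="n0", position=Position(2.5, 1.5), station=(1, 1))
        policy = parse_policy("nurse_only")
        events = nurse_step(nurse, params, plan, {"p0": patient}, policy, set())
        assert ("p0", "DISCOVERED") in events

    def test_no_discovery_under_smart_watch(self):
        plan = corridor_plan(12)
        params = NurseParams(discovery_radius=5.0)
        patient = make_patient(plan, pos=Position(2.0, 1.5))
        patient.orientation = Orientation.DISORIENTED
        nurse = NurseState(id="n0", position=Position(2.5, 1.5), station=(1, 2))
        policy = parse_policy("smart_watch:0")
        events = nurse_step(nurse, params, plan, {"p0": patient}, policy, set())
        assert events == []

    def test_responding_to_reoriented_patient_cancels(self):
        plan = corridor_plan(12)
        patient = make_patient(plan)  # oriented
        nurse = NurseState(
            id="n0",
            position=cell_center((1, 1)),
            station=(1, 1),
            task=NurseTask.RESPONDING,
            assigned_patient="p0",
        )
        events = nurse_step(
            nurse, NurseParams(), plan, {"p0": patient}, parse_policy("smart_watch:0"), {"p0"}
        )
        assert ("p0", CANCELLED) in events
        assert nurse.task is NurseTask.ROUTINE and nurse.assigned_patient is None


class TestPolicyParsing:
    @pytest.mark.parametrize(
        "text,label",
        [
            ("smart_watch:0", "Nhelp=0"),
            ("smart_watch:5", "Nhelp=5"),
            ("nurse_only", "Nurse Only"),
            ("no_help", "No Help"),
        ],
    )
    def test_roundtrip_and_labels(self, text, label):
        policy = parse_policy(text)
        assert str(policy) == text and policy.label == label

    @pytest.mark.parametrize("bad", ["smart_watch", "smart_watch:x", "watch:1", ""])
    def test_bad_policy_strings(self, bad):
        with pytest.raises(ConfigError):
            parse_policy(bad)

    def test_n_help_only_with_smart_watch(self):
        with pytest.raises(ConfigError):
            Policy(PolicyVariant.NO_HELP, n_help=2)
        with pytest.raises(ConfigError):
            Policy(PolicyVariant.SMART_WATCH)
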