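"""Agent behavior: disoriented residents, nurses, and the smart-watch device.

Residents walk between named destinations along shortest routes.  At every
en-route tick an oriented resident may lose orientation (probability
``dis_level``); a disoriented resident wanders as a correlated random walk
until a smart-watch cue succeeds, a nurse delivers them, or they spontaneously
reorient.  The smart watch detects an ongoing disorientation with a per-tick
probability, then issues orientation cues; after ``n_help`` failed cues it
escalates and calls a nurse (``n_help = 0`` calls immediately on detection).
Nurses idle at their station doing other caregiving, respond to calls, and
escort patients to their destination; under the nurse-only condition they
instead have to discover wandering patients within a discovery radius.

Step lengths are drawn from a normal distribution truncated below at zero.
All functions mutate the passed state objects in place and return the event
kinds they emitted; the engine stamps tick numbers and agent ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConfigError, WardSimError
from .world import (
    Cell,
    FloorPlan,
    Position,
    Route,
    cell_center,
    shortest_route,
    straight_line_distance,
)

# Event kinds (the complete protocol vocabulary)
DISORIENT = "DISORIENT"
REORIENT = "REORIENT"
DETECT = "DETECT"
CUE_ISSUED = "CUE_ISSUED"
CUE_SUCCESS = "CUE_SUCCESS"
CUE_FAIL = "CUE_FAIL"
NURSE_CALLED = "NURSE_CALLED"
CANCELLED = "CANCELLED"
NURSE_ARRIVED = "NURSE_ARRIVED"
DISCOVERED = "DISCOVERED"
GUIDE_START = "GUIDE_START"
GUIDE_END = "GUIDE_END"
DEST_REACHED = "DEST_REACHED"

EVENT_KINDS = frozenset(
    {
        DISORIENT,
        REORIENT,
        DETECT,
        CUE_ISSUED,
        CUE_SUCCESS,
        CUE_FAIL,
        NURSE_CALLED,
        CANCELLED,
        NURSE_ARRIVED,
        DISCOVERED,
        GUIDE_START,
        GUIDE_END,
        DEST_REACHED,
    }
)


class Orientation(str, Enum):
    ORIENTED = "O"
    DISORIENTED = "D"


class Guidance(str, Enum):
    NONE = "N"
    NURSE_GUIDED = "G"


class NurseTask(str, Enum):
    ROUTINE = "R"
    RESPONDING = "S"
    GUIDING = "G"


class PolicyVariant(str, Enum):
    SMART_WATCH = "smart_watch"
    NURSE_ONLY = "nurse_only"
    NO_HELP = "no_help"


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class PatientParams:
    """Resident movement and disorientation parameters.

    dis_level      probability per en-route decision point (tick) of losing
                   orientation
    mean_step      mean step length, cells per tick
    sd_step        step-length standard deviation, cells
    reorient_prob  per-tick probability of spontaneous reorientation while
                   disoriented and unguided
    turn_range     half-width (radians) of the uniform heading perturbation of
                   the disoriented correlated random walk
    """

    dis_level: float
    mean_step: float = 1.0
    sd_step: float = 0.2
    reorient_prob: float = 0.005
    turn_range: float = math.pi / 2

    def __post_init__(self):
        for name in ("dis_level", "reorient_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mean_step <= 0:
            raise ConfigError(f"mean_step must be > 0, got {self.mean_step}")
        if self.sd_step < 0:
            raise ConfigError(f"sd_step must be >= 0, got {self.sd_step}")


@dataclass(frozen=True)
class IATParams:
    """Smart-watch sensing and cueing parameters.

    p_detect       per-tick probability of detecting an ongoing disorientation
    p_cue_success  probability that one cue restores orientation
    cue_cooldown   ticks between consecutive cue attempts (>= 1)
    """

    p_detect: float
    p_cue_success: float
    cue_cooldown: int

    def __post_init__(self):
        for name in ("p_detect", "p_cue_success"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.cue_cooldown < 1:
            raise ConfigError(f"cue_cooldown must be >= 1, got {self.cue_cooldown}")


@dataclass(frozen=True)
class NurseParams:
    """Caregiver movement parameters.

    speed             cells per tick while responding to a call or returning
    guide_speed       cells per tick while escorting a patient (a guided walk
                      goes at the patient's pace, typically below ``speed``)
    discovery_radius  cells; nurse-only condition: a routine nurse this close
                      to an unguided disoriented patient discovers them
    """

    speed: float = 2.0
    guide_speed: float = 0.6
    discovery_radius: float = 2.0

    def __post_init__(self):
        if self.speed <= 0 or self.guide_speed <= 0:
            raise ConfigError("nurse speeds must be > 0")
        if self.discovery_radius < 0:
            raise ConfigError("discovery_radius must be >= 0")


@dataclass(frozen=True)
class Policy:
    """Assistive-technology decision rule.

    ``SMART_WATCH`` carries ``n_help``: how many failed cues are tolerated
    before a nurse is called (0 = call immediately upon detection).
    """

    variant: PolicyVariant
    n_help: int | None = None

    def __post_init__(self):
        if self.variant is PolicyVariant.SMART_WATCH:
            if self.n_help is None or self.n_help < 0:
                raise ConfigError("smart_watch policy requires n_help >= 0")
        elif self.n_help is not None:
            raise ConfigError(f"{self.variant.value} policy takes no n_help")

    @property
    def label(self) -> str:
        if self.variant is PolicyVariant.SMART_WATCH:
            return f"Nhelp={self.n_help}"
        if self.variant is PolicyVariant.NURSE_ONLY:
            return "Nurse Only"
        return "No Help"

    def __str__(self) -> str:
        if self.variant is PolicyVariant.SMART_WATCH:
            return f"smart_watch:{self.n_help}"
        return self.variant.value


def parse_policy(text: str) -> Policy:
    """Parse ``smart_watch:<n_help>`` / ``nurse_only`` / ``no_help``."""
    text = text.strip()
    if text == "nurse_only":
        return Policy(PolicyVariant.NURSE_ONLY)
    if text == "no_help":
        return Policy(PolicyVariant.NO_HELP)
    if text.startswith("smart_watch:"):
        try:
            n_help = int(text.split(":", 1)[1])
        except ValueError:
            raise ConfigError(f"bad smart_watch n_help in policy {text!r}")
        return Policy(PolicyVariant.SMART_WATCH, n_help=n_help)
    raise ConfigError(
        f"unknown policy {text!r}; expected smart_watch:<n>, nurse_only or no_help"
    )


# ---------------------------------------------------------------------------
# States


@dataclass
class PatientState:
    id: str
    position: Position
    destination: str
    dest_cell: Cell
    orientation: Orientation = Orientation.ORIENTED
    guidance: Guidance = Guidance.NONE
    failed_cues: int = 0
    heading: float = 0.0
    # smart-watch episode bookkeeping
    detected: bool = False
    escalated: bool = False
    ticks_since_cue: int | None = None
    # remaining oriented-route waypoints (cell centers ahead of the patient)
    waypoints: list[Position] = field(default_factory=list)

    def reset_episode(self) -> None:
        """End the current disorientation episode (by any means)."""
        self.orientation = Orientation.ORIENTED
        self.guidance = Guidance.NONE
        self.detected = False
        self.escalated = False
        self.failed_cues = 0
        self.ticks_since_cue = None


@dataclass
class NurseState:
    id: str
    position: Position
    station: Cell
    task: NurseTask = NurseTask.ROUTINE
    assigned_patient: str | None = None
    # remaining escort waypoints while guiding
    waypoints: list[Position] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary moves


def sample_step_length(params: PatientParams, rng: np.random.Generator) -> float:
    """One step length: Normal(mean_step, sd_step) truncated below at 0."""
    if params.sd_step == 0.0:
        return params.mean_step
    return max(0.0, params.mean_step + params.sd_step * rng.standard_normal())


def _advance_along(pos: Position, waypoints: list[Position], step: float) -> Position:
    """Advance ``step`` cell units along the waypoint chain, consuming reached
    waypoints from the front; clamps at the final waypoint (no overshoot)."""
    while step > 0.0 and waypoints:
        target = waypoints[0]
        d = straight_line_distance(pos, target)
        if d <= step:
            pos = target
            step -= d
            waypoints.pop(0)
        else:
            f = step / d
            pos = Position(pos[0] + (target[0] - pos[0]) * f,
                           pos[1] + (target[1] - pos[1]) * f)
            step = 0.0
    return pos


def set_route(patient: PatientState, plan: FloorPlan) -> None:
    """Give the patient a fresh shortest route to their current destination."""
    route = shortest_route(plan, patient.position, cell_center(patient.dest_cell))
    waypoints = list(route.waypoints)
    # the first waypoint is the center of the cell the patient is in; head
    # straight for the next one (the segment stays inside the two-cell union)
    if len(waypoints) > 1:
        waypoints = waypoints[1:]
    patient.waypoints = waypoints


def oriented_move(
    patient: PatientState,
    params: PatientParams,
    rng: np.random.Generator,
    route: Route | None = None,
) -> bool:
    """Advance an oriented patient along their route by one sampled step.

    Returns True when the destination (final waypoint) has been reached this
    tick; the caller records DEST_REACHED and assigns the next destination.
    Passing ``route`` replaces the patient's remaining waypoints first.
    """
    if route is not None:
        patient.waypoints = list(route.waypoints)
    if not patient.waypoints:
        dest = cell_center(patient.dest_cell)
        if straight_line_distance(patient.position, dest) > 1e-9:
            raise WardSimError(
                f"patient {patient.id} has an empty route but is not at "
                f"destination {patient.destination!r}"
            )
        return True
    step = sample_step_length(params, rng)
    patient.position = _advance_along(patient.position, patient.waypoints, step)
    return not patient.waypoints


def disoriented_move(
    patient: PatientState,
    plan: FloorPlan,
    params: PatientParams,
    rng: np.random.Generator,
) -> None:
    """One correlated-random-walk step of an unguided disoriented patient.

    The heading is perturbed by a uniform turn in +-turn_range; a move that
    would land in (or cross into) a non-walkable cell resamples the heading
    up to 8 times, after which the patient stays in place for this tick.
    """
    step = sample_step_length(params, rng)
    heading = patient.heading + rng.uniform(-params.turn_range, params.turn_range)
    for attempt in range(8):
        if attempt > 0:
            heading = rng.uniform(0.0, 2.0 * math.pi)
        cand = Position(
            patient.position[0] + step * math.cos(heading),
            patient.position[1] + step * math.sin(heading),
        )
        mid = Position(
            (patient.position[0] + cand[0]) / 2.0,
            (patient.position[1] + cand[1]) / 2.0,
        )
        if plan.is_walkable_position(cand) and plan.is_walkable_position(mid):
            patient.heading = heading
            patient.position = cand
            return
    patient.heading = heading  # boxed in: turn on the spot


def transition_orientation(
    patient: PatientState,
    params: PatientParams,
    rng: np.random.Generator,
) -> str | None:
    """Per-tick orientation transitions for an unguided patient.

    Oriented, en route -> disoriented with probability ``dis_level``;
    disoriented -> spontaneous reorientation with ``reorient_prob``.  Guided
    patients never transition here (release happens at guide end).  Returns
    the emitted event kind or None.  The caller resets the route after a
    reorientation.
    """
    if patient.guidance is Guidance.NURSE_GUIDED:
        return None
    if patient.orientation is Orientation.ORIENTED:
        if params.dis_level > 0.0 and rng.random() < params.dis_level:
            patient.orientation = Orientation.DISORIENTED
            patient.heading = rng.uniform(0.0, 2.0 * math.pi)
            patient.waypoints = []
            return DISORIENT
        return None
    if params.reorient_prob > 0.0 and rng.random() < params.reorient_prob:
        patient.reset_episode()
        return REORIENT
    return None


# ---------------------------------------------------------------------------
# Smart-watch automaton


def iat_step(
    patient: PatientState,
    iat: IATParams,
    policy: Policy,
    rng: np.random.Generator,
) -> list[str]:
    """One tick of the smart watch for one patient; returns emitted events.

    Detection state, failed-cue count and cue cooldown live on the patient
    state.  While the patient is disoriented, unguided and undetected, DETECT
    fires with probability ``p_detect`` per tick.  Once detected: if
    ``failed_cues >= n_help`` the watch escalates (one NURSE_CALLED per
    episode); otherwise cue attempts go out every ``cue_cooldown`` ticks,
    the first one cooldown interval after detection.  A cue succeeds with
    probability ``p_cue_success`` (CUE_SUCCESS + REORIENT, episode reset) or
    fails (CUE_FAIL, failed_cues increments).  Non-smart-watch policies emit
    nothing.
    """
    if policy.variant is not PolicyVariant.SMART_WATCH:
        return []
    if patient.orientation is Orientation.ORIENTED:
        return []
    if patient.guidance is Guidance.NURSE_GUIDED:
        return []
    events: list[str] = []
    if not patient.detected:
        if rng.random() < iat.p_detect:
            patient.detected = True
            patient.ticks_since_cue = 0
            events.append(DETECT)
        else:
            return events
    if patient.escalated:
        return events
    if patient.failed_cues >= (policy.n_help or 0):
        patient.escalated = True
        events.append(NURSE_CALLED)
        return events
    patient.ticks_since_cue = (patient.ticks_since_cue or 0) + 1
    if patient.ticks_since_cue >= iat.cue_cooldown:
        events.append(CUE_ISSUED)
        patient.ticks_since_cue = 0
        if rng.random() < iat.p_cue_success:
            patient.reset_episode()
            events.append(CUE_SUCCESS)
            events.append(REORIENT)
        else:
            patient.failed_cues += 1
            events.append(CUE_FAIL)
    return events


# ---------------------------------------------------------------------------
# Nurses


def assign_calls(
    nurses: list[NurseState],
    pending_calls: list[str],
    patients: dict[str, PatientState],
    plan: FloorPlan,
    assigned_ids: set[str],
) -> list[tuple[str, str]]:
    """Match pending calls (oldest first) to the nearest routine nurse.

    Stale calls — the patient already reoriented, is being guided, or already
    has a nurse on the way — are dropped with a CANCELLED event, which keeps
    the one-nurse-per-patient invariant.  Returns (patient_id, event_kind)
    pairs; mutates the queue, the nurse states and ``assigned_ids``.
    """
    events: list[tuple[str, str]] = []
    while pending_calls:
        pid = pending_calls[0]
        patient = patients[pid]
        if (
            patient.orientation is Orientation.ORIENTED
            or patient.guidance is Guidance.NURSE_GUIDED
            or pid in assigned_ids
        ):
            pending_calls.pop(0)
            events.append((pid, CANCELLED))
            continue
        free = [n for n in nurses if n.task is NurseTask.ROUTINE]
        if not free:
            break
        target = patient.position.cell
        nurse = min(
            free, key=lambda n: (plan.grid_distance(n.position.cell, target), n.id)
        )
        nurse.task = NurseTask.RESPONDING
        nurse.assigned_patient = pid
        assigned_ids.add(pid)
        pending_calls.pop(0)
    return events


def _pursue(nurse: NurseState, target: Position, plan: FloorPlan, speed: float) -> None:
    """Move up to ``speed`` cells along the shortest cell path toward target,
    stopping once within one cell of it."""
    budget = speed
    while budget > 1e-9:
        if straight_line_distance(nurse.position, target) <= 1.0:
            return
        here = nurse.position.cell
        goal = target.cell
        if here == goal:
            nxt = target
        else:
            nxt = cell_center(plan.next_cell_toward(here, goal))
        d = straight_line_distance(nurse.position, nxt)
        if d <= budget:
            nurse.position = nxt
            budget -= d
            if d < 1e-9:
                return
        else:
            f = budget / d
            nurse.position = Position(
                nurse.position[0] + (nxt[0] - nurse.position[0]) * f,
                nurse.position[1] + (nxt[1] - nurse.position[1]) * f,
            )
            return


def nurse_step(
    nurse: NurseState,
    params: NurseParams,
    plan: FloorPlan,
    patients: dict[str, PatientState],
    policy: Policy,
    assigned_ids: set[str],
) -> list[tuple[str, str]]:
    """One tick for one nurse; returns (agent_id, event_kind) pairs.

    Routine nurses stay at (or return to) their station; under the nurse-only
    policy they discover unguided disoriented patients within the discovery
    radius.  Responding nurses pursue their patient and start guiding on
    arrival (within one cell).  Guiding nurses escort the patient — whose
    position follows the nurse — along the shortest route to the patient's
    destination at ``guide_speed``; on arrival the patient reorients
    (GUIDE_END) and the nurse returns to routine duty.  Under no-help this
    function only ever walks the nurse back to its station.
    """
    events: list[tuple[str, str]] = []

    if nurse.task is NurseTask.ROUTINE:
        if policy.variant is PolicyVariant.NURSE_ONLY:
            candidates = [
                p
                for p in patients.values()
                if p.orientation is Orientation.DISORIENTED
                and p.guidance is Guidance.NONE
                and p.id not in assigned_ids
                and straight_line_distance(nurse.position, p.position)
                <= params.discovery_radius
            ]
            if candidates:
                target = min(
                    candidates,
                    key=lambda p: (
                        straight_line_distance(nurse.position, p.position),
                        p.id,
                    ),
                )
                nurse.task = NurseTask.RESPONDING
                nurse.assigned_patient = target.id
                assigned_ids.add(target.id)
                events.append((target.id, DISCOVERED))
        if nurse.task is NurseTask.ROUTINE:
            station = cell_center(nurse.station)
            if nurse.position != station:
                _pursue(nurse, station, plan, params.speed)
                if straight_line_distance(nurse.position, station) <= 1.0:
                    nurse.position = station
            return events

    if nurse.task is NurseTask.RESPONDING:
        patient = patients[nurse.assigned_patient]
        if (
            patient.orientation is Orientation.ORIENTED
            or patient.guidance is Guidance.NURSE_GUIDED
        ):
            events.append((patient.id, CANCELLED))
            assigned_ids.discard(patient.id)
            nurse.task = NurseTask.ROUTINE
            nurse.assigned_patient = None
            return events
        _pursue(nurse, patient.position, plan, params.speed)
        if straight_line_distance(nurse.position, patient.position) <= 1.0:
            events.append((patient.id, NURSE_ARRIVED))
            events.append((patient.id, GUIDE_START))
            nurse.task = NurseTask.GUIDING
            nurse.position = patient.position
            patient.guidance = Guidance.NURSE_GUIDED
            route = shortest_route(
                plan, patient.position, cell_center(patient.dest_cell)
            )
            waypoints = list(route.waypoints)
            if len(waypoints) > 1:
                waypoints = waypoints[1:]
            nurse.waypoints = waypoints
        return events

    # GUIDING
    patient = patients[nurse.assigned_patient]
    nurse.position = _advance_along(nurse.position, nurse.waypoints, params.guide_speed)
    patient.position = nurse.position
    if not nurse.waypoints:
        dest = cell_center(patient.dest_cell)
        if straight_line_distance(nurse.position, dest) <= 1e-9:
            events.append((patient.id, GUIDE_END))
            patient.reset_episode()
            assigned_ids.discard(patient.id)
            nurse.task = NurseTask.ROUTINE
            nurse.assigned_patient = None
    return events
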