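"""Discrete-time simulation loop and batch runner.

Each run executes a fixed number of ticks.  Within a tick the update order is
fixed — orientation transitions, then the smart watch, then nurses, then
patient movement — and all randomness flows from a single seeded generator,
so a protocol's serialized bytes are a pure function of (config, seed).
Batches derive run ``i``'s seed as ``base_seed + i``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import yaml

from .agents import (
    CANCELLED,
    CUE_SUCCESS,
    DEST_REACHED,
    GUIDE_END,
    NURSE_CALLED,
    REORIENT,
    Guidance,
    IATParams,
    NurseParams,
    NurseState,
    NurseTask,
    Orientation,
    PatientParams,
    PatientState,
    Policy,
    PolicyVariant,
    assign_calls,
    disoriented_move,
    iat_step,
    nurse_step,
    oriented_move,
    parse_policy,
    set_route,
    transition_orientation,
)
from .errors import ConfigError, EmptySampleError
from .protocol import (
    Event,
    GUIDE_CODE,
    ORI_CODE,
    RunProtocol,
    TASK_CODE,
)
from .world import FloorPlan, Position, cell_center, load_floorplan


@dataclass(frozen=True)
class SimConfig:
    """Everything one simulation run depends on, apart from the seed."""

    floorplan: FloorPlan
    patient_params: PatientParams
    iat_params: IATParams
    nurse_params: NurseParams
    policy: Policy
    n_patients: int = 3
    n_nurses: int = 2
    horizon: int = 2000
    seed: int = 0
    schedule_shuffle: bool = True
    floorplan_path: str | None = None

    def __post_init__(self):
        if self.horizon < 1:
            raise ConfigError(f"horizon must be >= 1, got {self.horizon}")
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_nurses < 0:
            raise ConfigError(f"n_nurses must be >= 0, got {self.n_nurses}")
        if self.n_nurses == 0 and self.policy.variant is PolicyVariant.NURSE_ONLY:
            raise ConfigError("nurse_only policy requires at least one nurse")
        if self.n_nurses > 0 and not self.floorplan.nurse_stations:
            raise ConfigError("floor plan has no nurse stations but n_nurses > 0")

    def digest(self) -> str:
        """Content hash of the run condition; excludes the seed, so paired
        runs of one condition share a digest."""
        p, i, n = self.patient_params, self.iat_params, self.nurse_params
        doc = {
            "floorplan": self.floorplan.digest(),
            "patients": {
                "dis_level": p.dis_level,
                "mean_step": p.mean_step,
                "sd_step": p.sd_step,
                "reorient_prob": p.reorient_prob,
                "turn_range": p.turn_range,
            },
            "iat": {
                "p_detect": i.p_detect,
                "p_cue_success": i.p_cue_success,
                "cue_cooldown": i.cue_cooldown,
            },
            "nurses": {
                "speed": n.speed,
                "guide_speed": n.guide_speed,
                "discovery_radius": n.discovery_radius,
            },
            "policy": str(self.policy),
            "n_patients": self.n_patients,
            "n_nurses": self.n_nurses,
            "horizon": self.horizon,
            "schedule_shuffle": self.schedule_shuffle,
        }
        blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path) -> tuple[SimConfig, int]:
    """Load a YAML configuration file; returns (config, n_runs).

    Relative floor-plan paths resolve against the config file's directory.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} does not hold a mapping")

    def section(name: str) -> dict:
        if name not in doc:
            raise ConfigError(f"missing config section {name!r}")
        return dict(doc[name])

    world = section("world")
    for key in ("map", "locations"):
        if key not in world:
            raise ConfigError(f"missing config key world.{key}")
    map_path = (path.parent / world["map"]).resolve()
    sidecar_path = (path.parent / world["locations"]).resolve()
    plan = load_floorplan(map_path.read_text(), sidecar_path.read_text())

    patients = section("patients")
    nurses = section("nurses")
    iat = section("iat")
    run = section("run")
    if "policy" not in doc:
        raise ConfigError("missing config key 'policy'")
    if "dis_level" not in patients:
        raise ConfigError("missing config key patients.dis_level")
    if "horizon" not in run:
        raise ConfigError("missing config key run.horizon")

    try:
        config = SimConfig(
            floorplan=plan,
            floorplan_path=str(map_path),
            patient_params=PatientParams(
                dis_level=float(patients["dis_level"]),
                mean_step=float(patients.get("mean_step", 1.0)),
                sd_step=float(patients.get("sd_step", 0.2)),
                reorient_prob=float(patients.get("reorient_prob", 0.005)),
                turn_range=float(patients.get("turn_range", math.pi / 2)),
            ),
            iat_params=IATParams(
                p_detect=float(iat.get("p_detect", 0.1)),
                p_cue_success=float(iat.get("p_cue_success", 0.25)),
                cue_cooldown=int(iat.get("cue_cooldown", 4)),
            ),
            nurse_params=NurseParams(
                speed=float(nurses.get("speed", 2.0)),
                guide_speed=float(nurses.get("guide_speed", 0.6)),
                discovery_radius=float(nurses.get("discovery_radius", 2.0)),
            ),
            policy=parse_policy(str(doc["policy"])),
            n_patients=int(patients.get("count", 3)),
            n_nurses=int(nurses.get("count", 2)),
            horizon=int(run["horizon"]),
            seed=int(run.get("seed", 0)),
            schedule_shuffle=bool(run.get("schedule_shuffle", True)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad value in {path}: {exc}") from exc
    return config, int(run.get("n_runs", 1))


# ---------------------------------------------------------------------------
# The loop


def run_simulation(config: SimConfig, seed: int | None = None) -> RunProtocol:
    """Execute one seeded run and return its protocol."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    plan = config.floorplan
    policy = config.policy
    pparams = config.patient_params
    nparams = config.nurse_params
    iat = config.iat_params
    horizon = config.horizon

    dest_names = sorted(plan.destinations)
    if len(dest_names) < 2:
        raise ConfigError("need at least 2 destinations to schedule activities")

    patients: dict[str, PatientState] = {}
    schedules: dict[str, list[str]] = {}
    sched_pos: dict[str, int] = {}
    agents_meta: list[dict] = []
    for i in range(config.n_patients):
        pid = f"p{i}"
        if config.schedule_shuffle:
            order = [dest_names[j] for j in rng.permutation(len(dest_names))]
        else:
            k = i % len(dest_names)
            order = dest_names[k:] + dest_names[:k]
        start = order[0]
        patient = PatientState(
            id=pid,
            position=cell_center(plan.destinations[start]),
            destination=order[1],
            dest_cell=plan.destinations[order[1]],
        )
        set_route(patient, plan)
        patients[pid] = patient
        schedules[pid] = order
        sched_pos[pid] = 1
        agents_meta.append({"id": pid, "kind": "patient", "start": start})

    nurses: list[NurseState] = []
    for j in range(config.n_nurses):
        nid = f"n{j}"
        station = plan.nurse_stations[j % len(plan.nurse_stations)]
        nurses.append(NurseState(id=nid, position=cell_center(station), station=station))
        agents_meta.append({"id": nid, "kind": "nurse", "start": list(station)})

    n_agents = len(agents_meta)
    n_rec = horizon * n_agents
    col_t = np.empty(n_rec, dtype=np.int32)
    col_agent = np.empty(n_rec, dtype=np.int16)
    col_x = np.empty(n_rec, dtype=np.float64)
    col_y = np.empty(n_rec, dtype=np.float64)
    col_ori = np.full(n_rec, -1, dtype=np.int8)
    col_guide = np.full(n_rec, -1, dtype=np.int8)
    col_task = np.full(n_rec, -1, dtype=np.int8)

    events: list[Event] = []
    pending_calls: list[str] = []
    assigned_ids: set[str] = set()
    patient_list = list(patients.values())

    def advance_schedule(patient: PatientState, tick: int) -> None:
        """Record arrival and hand the patient their next destination."""
        events.append(
            Event(tick, patient.id, DEST_REACHED, {"dest": patient.destination})
        )
        order = schedules[patient.id]
        sched_pos[patient.id] = (sched_pos[patient.id] + 1) % len(order)
        nxt = order[sched_pos[patient.id]]
        if nxt == patient.destination:  # consecutive duplicates cannot occur
            nxt = order[(sched_pos[patient.id] + 1) % len(order)]
        patient.destination = nxt
        patient.dest_cell = plan.destinations[nxt]
        set_route(patient, plan)

    rec = 0
    for t in range(horizon):
        # 1. orientation transitions
        for patient in patient_list:
            kind = transition_orientation(patient, pparams, rng)
            if kind is not None:
                events.append(Event(t, patient.id, kind))
                if kind == REORIENT:
                    set_route(patient, plan)

        # 2. smart watch
        if policy.variant is PolicyVariant.SMART_WATCH:
            for patient in patient_list:
                for kind in iat_step(patient, iat, policy, rng):
                    events.append(Event(t, patient.id, kind))
                    if kind == NURSE_CALLED:
                        pending_calls.append(patient.id)
                    elif kind == CUE_SUCCESS:
                        set_route(patient, plan)

        # 3. nurses
        if nurses and policy.variant is not PolicyVariant.NO_HELP:
            for pid, kind in assign_calls(
                nurses, pending_calls, patients, plan, assigned_ids
            ):
                events.append(Event(t, pid, kind))
            for nurse in nurses:
                for pid, kind in nurse_step(
                    nurse, nparams, plan, patients, policy, assigned_ids
                ):
                    events.append(Event(t, pid, kind, {"nurse": nurse.id}))
                    if kind == GUIDE_END:
                        advance_schedule(patients[pid], t)

        # 4. patient movement
        for patient in patient_list:
            if patient.guidance is Guidance.NURSE_GUIDED:
                continue  # moved with the escorting nurse
            if patient.orientation is Orientation.ORIENTED:
                if oriented_move(patient, pparams, rng):
                    advance_schedule(patient, t)
            else:
                disoriented_move(patient, plan, pparams, rng)

        # 5. record post-update state
        for i, patient in enumerate(patient_list):
            col_t[rec] = t
            col_agent[rec] = i
            col_x[rec] = patient.position[0]
            col_y[rec] = patient.position[1]
            col_ori[rec] = ORI_CODE[patient.orientation.value]
            col_guide[rec] = GUIDE_CODE[patient.guidance.value]
            rec += 1
        for j, nurse in enumerate(nurses):
            col_t[rec] = t
            col_agent[rec] = len(patient_list) + j
            col_x[rec] = nurse.position[0]
            col_y[rec] = nurse.position[1]
            col_task[rec] = TASK_CODE[nurse.task.value]
            rec += 1

    protocol = RunProtocol(
        config_digest=config.digest(),
        floorplan_digest=plan.digest(),
        seed=seed,
        horizon=horizon,
        agents=agents_meta,
        states={
            "t": col_t,
            "agent": col_agent,
            "x": col_x,
            "y": col_y,
            "ori": col_ori,
            "guide": col_guide,
            "task": col_task,
        },
        events=events,
    )
    protocol.validate()
    return protocol


def iter_batch(
    config: SimConfig, n_runs: int, base_seed: int | None = None
) -> Iterator[RunProtocol]:
    """Lazily yield ``n_runs`` independent runs seeded base_seed + i."""
    if n_runs < 1:
        raise ConfigError(f"n_runs must be >= 1, got {n_runs}")
    base_seed = config.seed if base_seed is None else base_seed
    for i in range(n_runs):
        yield run_simulation(config, seed=base_seed + i)


def run_batch(
    config: SimConfig, n_runs: int, base_seed: int | None = None
) -> list[RunProtocol]:
    """Run ``n_runs`` independent simulations; run i uses seed base_seed + i."""
    return list(iter_batch(config, n_runs, base_seed))


# ---------------------------------------------------------------------------
# Run-protocol analyses


class StepCountEstimate(NamedTuple):
    mean_ticks: float
    n_legs: int


class Leg(NamedTuple):
    """One completed walk between two destinations."""

    patient_id: str
    origin: str
    dest: str
    start_tick: int  # tick of the previous arrival (-1 for the first leg)
    end_tick: int
    duration: int


def completed_legs(
    protocol: RunProtocol, patient_filter: Callable[[str], bool] | Sequence[str] | None = None
) -> list[Leg]:
    """All completed origin->destination legs recorded in a protocol.

    Leg duration counts movement ticks: the first leg runs from tick 0 through
    its arrival tick inclusive; later legs span consecutive arrival ticks.
    """
    if patient_filter is None:
        accept = lambda pid: True
    elif callable(patient_filter):
        accept = patient_filter
    else:
        allowed = set(patient_filter)
        accept = lambda pid: pid in allowed
    legs: list[Leg] = []
    for meta in protocol.agents:
        if meta["kind"] != "patient" or not accept(meta["id"]):
            continue
        pid = meta["id"]
        prev_name = meta["start"]
        prev_tick = -1
        for e in protocol.events_for(pid, {DEST_REACHED}):
            name = (e.payload or {}).get("dest", "?")
            legs.append(
                Leg(pid, prev_name, name, prev_tick, e.tick, e.tick - prev_tick)
            )
            prev_name, prev_tick = name, e.tick
    return legs


def expected_step_count(
    protocols: Iterable[RunProtocol],
    patient_filter: Callable[[str], bool] | Sequence[str] | None = None,
    origin: str | None = None,
    dest: str | None = None,
) -> StepCountEstimate:
    """Mean ticks per completed leg, estimated across run protocols.

    ``origin``/``dest`` restrict to legs between two named destinations
    (None matches any).  Raises EmptySampleError when no leg matches —
    an empty average is a failure, not zero.
    """
    durations: list[int] = []
    for protocol in protocols:
        for leg in completed_legs(protocol, patient_filter):
            if origin is not None and leg.origin != origin:
                continue
            if dest is not None and leg.dest != dest:
                continue
            durations.append(leg.duration)
    if not durations:
        raise EmptySampleError(
            f"no completed legs match origin={origin!r}, dest={dest!r}"
        )
    return StepCountEstimate(float(np.mean(durations)), len(durations))
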