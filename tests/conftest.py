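"""Shared fixtures: tiny floor plans, configs, and a hand-built protocol."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from wardsim import (
    IATParams,
    NurseParams,
    PatientParams,
    SimConfig,
    load_floorplan,
    parse_policy,
)
from wardsim.demo import demo_config, demo_floorplan
from wardsim.protocol import (
    Event,
    GUIDE_CODE,
    ORI_CODE,
    RunProtocol,
    TASK_CODE,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def corridor_plan(n_cells: int, destinations: dict[str, int] | None = None):
    """A 1-row corridor of ``n_cells`` walkable cells (plus wall padding)."""
    if destinations is None:
        destinations = {"A": 0, "B": n_cells - 1}
    map_text = "\n".join(["#" * (n_cells + 2), "#" + "." * n_cells + "#", "#" * (n_cells + 2)]) + "\n"
    sidecar = {
        "cell_size_m": 1.0,
        "destinations": {k: [1, 1 + c] for k, c in destinations.items()},
        "nurse_stations": [[1, 1]],
    }
    return load_floorplan(map_text, sidecar)


@pytest.fixture
def corridor10():
    return corridor_plan(10)


@pytest.fixture
def ward():
    return demo_floorplan()


@pytest.fixture
def demo_cfg():
    return demo_config()


def make_config(plan, policy="no_help", **kw) -> SimConfig:
    """Small config factory with quiet defaults for unit tests."""
    defaults = dict(
        floorplan=plan,
        patient_params=PatientParams(dis_level=0.0, sd_step=0.0, reorient_prob=0.0),
        iat_params=IATParams(p_detect=0.1, p_cue_success=0.25, cue_cooldown=4),
        nurse_params=NurseParams(),
        policy=parse_policy(policy),
        n_patients=1,
        n_nurses=0,
        horizon=50,
        seed=0,
        schedule_shuffle=False,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def build_fixture_protocol() -> RunProtocol:
    """Hand-built 100-tick protocol with known score ingredients.

    One patient: disoriented ticks 10..29 (20 ticks), the last 5 of which
    (25..29) are nurse-guided.  One nurse: responding ticks 15..24 and
    30..44, guiding 25..29 — 30 busy ticks of 100.  Events mirror the state
    table so the event-derived disorientation count matches it.
    """
    horizon = 100
    agents = [
        {"id": "p0", "kind": "patient", "start": "A"},
        {"id": "n0", "kind": "nurse", "start": [1, 1]},
    ]
    n = horizon * 2
    t = np.repeat(np.arange(horizon, dtype=np.int32), 2)
    agent = np.tile(np.array([0, 1], dtype=np.int16), horizon)
    x = np.full(n, 1.5)
    y = np.full(n, 1.5)
    ori = np.full(n, -1, dtype=np.int8)
    guide = np.full(n, -1, dtype=np.int8)
    task = np.full(n, -1, dtype=np.int8)
    for tick in range(horizon):
        pi, ni = 2 * tick, 2 * tick + 1
        disoriented = 10 <= tick <= 29
        guided = 25 <= tick <= 29
        ori[pi] = ORI_CODE["D"] if disoriented else ORI_CODE["O"]
        guide[pi] = GUIDE_CODE["G"] if guided else GUIDE_CODE["N"]
        if 15 <= tick <= 24 or 30 <= tick <= 44:
            task[ni] = TASK_CODE["S"]
        elif guided:
            task[ni] = TASK_CODE["G"]
        else:
            task[ni] = TASK_CODE["R"]
    events = [
        Event(10, "p0", "DISORIENT"),
        Event(14, "p0", "DETECT"),
        Event(15, "p0", "NURSE_CALLED"),
        Event(25, "p0", "NURSE_ARRIVED", {"nurse": "n0"}),
        Event(25, "p0", "GUIDE_START", {"nurse": "n0"}),
        Event(30, "p0", "GUIDE_END", {"nurse": "n0"}),
        Event(30, "p0", "DEST_REACHED", {"dest": "B"}),
    ]
    protocol = RunProtocol(
        config_digest="fixture-digest",
        floorplan_digest="fixture-plan",
        seed=0,
        horizon=horizon,
        agents=agents,
        states={"t": t, "agent": agent, "x": x, "y": y, "ori": ori, "guide": guide, "task": task},
        events=events,
    )
    protocol.validate()
    return protocol


@pytest.fixture
def fixture_protocol() -> RunProtocol:
    return build_fixture_protocol()
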