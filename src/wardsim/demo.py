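"""The shipped demo ward and its calibrated study configuration.

The geometry of the care facility the simulation concept was developed
around is not public, so the package ships a synthetic stand-in built here:
a central corridor spine with six resident rooms (three per side, connected
by doorways), a lounge and a dining area at the corridor ends, and two nurse
stations on the corridor.  The builder is deterministic, so the generated
map/sidecar pair doubles as a byte-stable serialization fixture.

``demo_config`` carries the calibrated default condition used throughout the
documentation and the reproduction scripts; see docs/methods.md for how the
parameter values were chosen.
"""

from __future__ import annotations

import json
from pathlib import Path

from .agents import IATParams, NurseParams, PatientParams, Policy, parse_policy
from .engine import SimConfig
from .world import FloorPlan, load_floorplan

# Calibrated demo condition (rationale in docs/methods.md)
DEMO_PARAMS = {
    "patients": {
        "count": 3,
        "dis_level": 0.01,
        "mean_step": 1.0,
        "sd_step": 0.2,
        "reorient_prob": 0.005,
    },
    "nurses": {"count": 2, "speed": 2.0, "guide_speed": 0.6, "discovery_radius": 2.0},
    "iat": {"p_detect": 0.1, "p_cue_success": 0.25, "cue_cooldown": 4},
    "run": {"horizon": 2000, "seed": 0, "n_runs": 200},
    "policy": "smart_watch:0",
}

# The six escalation policies compared in the demo sweep, in plot order.
DEMO_POLICIES = [
    "smart_watch:0",
    "smart_watch:1",
    "smart_watch:3",
    "smart_watch:5",
    "nurse_only",
    "no_help",
]

_ROOM_W = 7  # interior width of each resident room
_ROOM_H = 3  # interior height
_N_COLS = 3  # rooms per corridor side


def build_demo_ward() -> tuple[str, dict]:
    """Generate the demo ward as (ASCII map text, sidecar mapping)."""
    width = 1 + _N_COLS * (_ROOM_W + 1)  # walls between and around rooms
    height = 2 * (_ROOM_H + 1) + 3  # rooms above/below + corridor + outer walls
    corridor_row = _ROOM_H + 2
    grid = [["#"] * width for _ in range(height)]

    # corridor spine
    for c in range(1, width - 1):
        grid[corridor_row][c] = "."

    destinations: dict[str, list[int]] = {}
    for side, rows in (("a", range(1, 1 + _ROOM_H)), ("b", range(corridor_row + 2, corridor_row + 2 + _ROOM_H))):
        for k in range(_N_COLS):
            c0 = 1 + k * (_ROOM_W + 1)
            for r in rows:
                for c in range(c0, c0 + _ROOM_W):
                    grid[r][c] = "."
            door_col = c0 + _ROOM_W // 2
            door_row = corridor_row - 1 if side == "a" else corridor_row + 1
            grid[door_row][door_col] = "."
            room_center = [rows.start + _ROOM_H // 2, door_col]
            destinations[f"room_{side}{k + 1}"] = room_center

    destinations["lounge"] = [corridor_row, 1]
    destinations["dining"] = [corridor_row, width - 2]
    stations = [[corridor_row, width // 3], [corridor_row, 2 * width // 3]]

    map_text = "\n".join("".join(row) for row in grid) + "\n"
    sidecar = {
        "cell_size_m": 1.0,
        "destinations": {k: v for k, v in sorted(destinations.items())},
        "nurse_stations": stations,
    }
    return map_text, sidecar


def demo_floorplan() -> FloorPlan:
    map_text, sidecar = build_demo_ward()
    return load_floorplan(map_text, sidecar)


def demo_config(policy: str | Policy = "smart_watch:0", **overrides) -> SimConfig:
    """The calibrated demo condition as a ready-to-run SimConfig.

    ``overrides`` replace top-level SimConfig fields (horizon, seed,
    n_patients, ...) or whole parameter objects (patient_params, ...).
    """
    if isinstance(policy, str):
        policy = parse_policy(policy)
    p = DEMO_PARAMS
    config = SimConfig(
        floorplan=demo_floorplan(),
        patient_params=PatientParams(
            dis_level=p["patients"]["dis_level"],
            mean_step=p["patients"]["mean_step"],
            sd_step=p["patients"]["sd_step"],
            reorient_prob=p["patients"]["reorient_prob"],
        ),
        iat_params=IATParams(**p["iat"]),
        nurse_params=NurseParams(
            speed=p["nurses"]["speed"],
            guide_speed=p["nurses"]["guide_speed"],
            discovery_radius=p["nurses"]["discovery_radius"],
        ),
        policy=policy,
        n_patients=p["patients"]["count"],
        n_nurses=p["nurses"]["count"],
        horizon=p["run"]["horizon"],
        seed=p["run"]["seed"],
    )
    if overrides:
        from dataclasses import replace

        config = replace(config, **overrides)
    return config


def demo_policies() -> list[Policy]:
    return [parse_policy(s) for s in DEMO_POLICIES]


def write_demo_files(directory) -> dict[str, Path]:
    """Write ward.map, ward.json and demo.yaml into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    map_text, sidecar = build_demo_ward()
    paths = {
        "map": directory / "ward.map",
        "locations": directory / "ward.json",
        "config": directory / "demo.yaml",
    }
    paths["map"].write_text(map_text)
    paths["locations"].write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    doc = {
        "world": {"map": "ward.map", "locations": "ward.json"},
        "patients": DEMO_PARAMS["patients"],
        "nurses": DEMO_PARAMS["nurses"],
        "iat": DEMO_PARAMS["iat"],
        "policy": DEMO_PARAMS["policy"],
        "run": DEMO_PARAMS["run"],
    }
    import yaml

    paths["config"].write_text(yaml.safe_dump(doc, sort_keys=False))
    return paths
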