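"""Run protocols: the per-run record every value model is computed from.

A protocol holds the full seeded record of one simulation run: a header
(config digest, floor-plan digest, seed, horizon, agent roster), a per-tick
per-agent state table, and the ordered event list.  State and events are
stored redundantly — time-fraction scores read the state table, plausibility
checks read the events — and ``validate`` guards the redundancy.

On disk a protocol is a JSONL block: one header record, then
horizon x n_agents state records in tick-major order, then the events.
Several protocols may be appended to one file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agents import (
    DEST_REACHED,
    DISCOVERED,
    EVENT_KINDS,
    GUIDE_END,
    GUIDE_START,
    NURSE_ARRIVED,
    NURSE_CALLED,
)
from .errors import ProtocolInvariantError, ProtocolParseError

ORI_CODE = {"O": 0, "D": 1}
GUIDE_CODE = {"N": 0, "G": 1}
TASK_CODE = {"R": 0, "S": 1, "G": 2}
ORI_CHAR = {v: k for k, v in ORI_CODE.items()}
GUIDE_CHAR = {v: k for k, v in GUIDE_CODE.items()}
TASK_CHAR = {v: k for k, v in TASK_CODE.items()}


@dataclass(frozen=True)
class Event:
    tick: int
    agent_id: str
    kind: str
    payload: dict | None = None


@dataclass
class RunProtocol:
    """Complete record of one simulation run."""

    config_digest: str
    floorplan_digest: str
    seed: int
    horizon: int
    agents: list[dict]  # {"id", "kind": "patient"|"nurse", "start": ...}
    # state table: parallel arrays of length horizon * n_agents, tick-major
    states: dict[str, np.ndarray] = field(repr=False)
    events: list[Event] = field(repr=False)

    # -- roster -----------------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        return [a["id"] for a in self.agents if a["kind"] == "patient"]

    @property
    def nurse_ids(self) -> list[str]:
        return [a["id"] for a in self.agents if a["kind"] == "nurse"]

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def agent_index(self, agent_id: str) -> int:
        for i, a in enumerate(self.agents):
            if a["id"] == agent_id:
                return i
        raise KeyError(agent_id)

    def agent_mask(self, agent_id: str) -> np.ndarray:
        return self.states["agent"] == self.agent_index(agent_id)

    def events_for(self, agent_id: str, kinds: set[str] | None = None) -> list[Event]:
        return [
            e
            for e in self.events
            if e.agent_id == agent_id and (kinds is None or e.kind in kinds)
        ]

    def state_frame(self) -> pd.DataFrame:
        """State table as a tidy DataFrame (one row per tick per agent)."""
        ids = np.array([a["id"] for a in self.agents])
        df = pd.DataFrame(
            {
                "t": self.states["t"],
                "id": ids[self.states["agent"]],
                "x": self.states["x"],
                "y": self.states["y"],
                "ori": self.states["ori"],
                "guide": self.states["guide"],
                "task": self.states["task"],
            }
        )
        return df

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        """Raise ProtocolInvariantError on any structural-invariant breach."""
        n = self.horizon * self.n_agents
        if any(len(v) != n for v in self.states.values()):
            raise ProtocolInvariantError(
                f"state table must hold horizon x agents = {n} records"
            )
        ticks = [e.tick for e in self.events]
        if any(b < a for a, b in zip(ticks, ticks[1:])):
            raise ProtocolInvariantError("events must be sorted by tick")
        if any(not (0 <= t < self.horizon) for t in ticks):
            raise ProtocolInvariantError("event tick outside [0, horizon)")
        for pid in self.patient_ids:
            guiding = False
            called = False
            for e in self.events_for(
                pid, {GUIDE_START, GUIDE_END, NURSE_CALLED, DISCOVERED, NURSE_ARRIVED}
            ):
                if e.kind == GUIDE_START:
                    if guiding:
                        raise ProtocolInvariantError(
                            f"GUIDE_START/GUIDE_END must alternate for {pid}"
                        )
                    guiding = True
                elif e.kind == GUIDE_END:
                    if not guiding:
                        raise ProtocolInvariantError(
                            f"GUIDE_START/GUIDE_END must alternate for {pid}"
                        )
                    guiding = False
                elif e.kind in (NURSE_CALLED, DISCOVERED):
                    called = True
                elif e.kind == NURSE_ARRIVED and not called:
                    raise ProtocolInvariantError(
                        f"NURSE_ARRIVED without prior NURSE_CALLED/DISCOVERED for {pid}"
                    )

    # -- serialization ----------------------------------------------------

    def to_jsonl(self) -> str:
        header = {
            "kind": "header",
            "config_digest": self.config_digest,
            "floorplan_digest": self.floorplan_digest,
            "seed": self.seed,
            "horizon": self.horizon,
            "agents": self.agents,
        }
        lines = [json.dumps(header, separators=(",", ":"))]
        ids = [a["id"] for a in self.agents]
        kinds = [a["kind"] for a in self.agents]
        s = self.states
        for i in range(len(s["t"])):
            ai = int(s["agent"][i])
            rec: dict = {
                "t": int(s["t"][i]),
                "id": ids[ai],
                "pos": [float(s["x"][i]), float(s["y"][i])],
            }
            if kinds[ai] == "patient":
                rec["ori"] = ORI_CHAR[int(s["ori"][i])]
                rec["guide"] = GUIDE_CHAR[int(s["guide"][i])]
            else:
                rec["task"] = TASK_CHAR[int(s["task"][i])]
            lines.append(json.dumps(rec, separators=(",", ":")))
        for e in self.events:
            rec = {"t": e.tick, "id": e.agent_id, "ev": e.kind}
            if e.payload:
                rec["data"] = e.payload
            lines.append(json.dumps(rec, separators=(",", ":")))
        return "\n".join(lines) + "\n"


def write_protocol(protocol: RunProtocol, path, append: bool = False) -> None:
    """Write one protocol as a JSONL block; ``append`` adds to an existing file."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(protocol.to_jsonl())


def write_protocols(protocols: Iterable[RunProtocol], path) -> None:
    with open(path, "w") as fh:
        for p in protocols:
            fh.write(p.to_jsonl())


def _finish_block(header, states_rows, events, first_line) -> RunProtocol:
    agents = header["agents"]
    idx = {a["id"]: i for i, a in enumerate(agents)}
    n = len(states_rows)
    arr = {
        "t": np.empty(n, dtype=np.int32),
        "agent": np.empty(n, dtype=np.int16),
        "x": np.empty(n, dtype=np.float64),
        "y": np.empty(n, dtype=np.float64),
        "ori": np.full(n, -1, dtype=np.int8),
        "guide": np.full(n, -1, dtype=np.int8),
        "task": np.full(n, -1, dtype=np.int8),
    }
    for i, rec in enumerate(states_rows):
        arr["t"][i] = rec["t"]
        arr["agent"][i] = idx[rec["id"]]
        arr["x"][i], arr["y"][i] = rec["pos"]
        if "ori" in rec:
            arr["ori"][i] = ORI_CODE[rec["ori"]]
            arr["guide"][i] = GUIDE_CODE[rec["guide"]]
        if "task" in rec:
            arr["task"][i] = TASK_CODE[rec["task"]]
    proto = RunProtocol(
        config_digest=header["config_digest"],
        floorplan_digest=header["floorplan_digest"],
        seed=header["seed"],
        horizon=header["horizon"],
        agents=agents,
        states=arr,
        events=events,
    )
    expected = proto.horizon * proto.n_agents
    if n != expected:
        raise ProtocolParseError(
            f"state table holds {n} records, expected horizon x agents = {expected}",
            line=first_line,
        )
    try:
        proto.validate()
    except ProtocolInvariantError as exc:
        raise ProtocolParseError(str(exc), line=first_line) from exc
    return proto


def read_protocols(path) -> list[RunProtocol]:
    """Read every protocol block in a JSONL file, validating each."""
    protocols: list[RunProtocol] = []
    header = None
    states_rows: list[dict] = []
    events: list[Event] = []
    block_line = 1
    last_tick = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise ProtocolParseError("missing header record", line=1)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ProtocolParseError(f"invalid JSON: {exc.msg}", line=lineno) from exc
        if rec.get("kind") == "header":
            if header is not None:
                protocols.append(_finish_block(header, states_rows, events, block_line))
            missing = {"config_digest", "floorplan_digest", "seed", "horizon", "agents"} - set(rec)
            if missing:
                raise ProtocolParseError(
                    f"header missing fields {sorted(missing)}", line=lineno
                )
            header, states_rows, events = rec, [], []
            block_line, last_tick = lineno, None
        elif header is None:
            raise ProtocolParseError("missing header record", line=lineno)
        elif "ev" in rec:
            if rec["ev"] not in EVENT_KINDS:
                raise ProtocolParseError(f"unknown event kind {rec['ev']!r}", line=lineno)
            if last_tick is not None and rec["t"] < last_tick:
                raise ProtocolParseError(
                    "invariant violated: events sorted by tick", line=lineno
                )
            last_tick = rec["t"]
            events.append(Event(rec["t"], rec["id"], rec["ev"], rec.get("data")))
        elif "pos" in rec:
            if last_tick is not None:
                raise ProtocolParseError(
                    "state record after event records", line=lineno
                )
            states_rows.append(rec)
        else:
            raise ProtocolParseError("unrecognized record", line=lineno)
    if header is None:
        raise ProtocolParseError("missing header record", line=1)
    protocols.append(_finish_block(header, states_rows, events, block_line))
    return protocols


def read_protocol(path) -> RunProtocol:
    """Read a file expected to hold exactly one protocol."""
    protocols = read_protocols(path)
    if len(protocols) != 1:
        raise ProtocolParseError(
            f"expected exactly one protocol, found {len(protocols)}", line=1
        )
    return protocols[0]
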