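"""Geometry of the simulated ward.

The world is a rectangular grid of unit cells ('#' wall, '.' walkable) with a
JSON sidecar naming destination cells (residents' rooms, lounge, dining) and
nurse-station cells.  Agent positions are continuous, in cell units, origin at
the top-left corner, x rightward, y downward; the cell containing position
(x, y) is (row, col) = (floor(y), floor(x)) and its center is
(col + 0.5, row + 0.5).  Routing is breadth-first search over the 4-connected
walkable grid, with BFS trees cached per root cell so that repeated queries
against a moving target (a nurse pursuing a wandering patient) are cheap.
"""

from __future__ import annotations

import hashlib
import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .errors import (
    FloorPlanError,
    LocationOnWallError,
    NonRectangularMapError,
    RoutingError,
    UnreachableDestinationError,
)

Cell = tuple[int, int]  # (row, col)


class Position(NamedTuple):
    """Continuous location in cell units (x rightward, y downward)."""

    x: float
    y: float

    @property
    def cell(self) -> Cell:
        return (int(self.y), int(self.x))


def cell_center(cell: Cell) -> Position:
    """Center of a grid cell as a continuous position."""
    row, col = cell
    return Position(col + 0.5, row + 0.5)


def straight_line_distance(a: Position, b: Position) -> float:
    """Euclidean distance between two positions, in cell units."""
    return math.hypot(a[0] - b[0], a[1] - b[1])


def path_length(traj: Iterable[Position]) -> float:
    """Total length of a polyline; fewer than two points yields 0."""
    traj = list(traj)
    if len(traj) < 2:
        return 0.0
    return sum(straight_line_distance(a, b) for a, b in zip(traj, traj[1:]))


@dataclass(frozen=True)
class Route:
    """An ordered chain of adjacent cell centers with its total length."""

    waypoints: tuple[Position, ...]
    total_length: float

    def __len__(self) -> int:
        return len(self.waypoints)


EMPTY_ROUTE = Route(waypoints=(), total_length=0.0)


@dataclass
class FloorPlan:
    """Walkable-cell grid with named destinations and nurse stations."""

    width: int
    height: int
    cell_size: float
    walkable: np.ndarray  # bool, shape (height, width)
    destinations: dict[str, Cell]
    nurse_stations: list[Cell]
    _bfs_cache: dict[Cell, tuple[dict[Cell, int], dict[Cell, Cell]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    # -- queries ----------------------------------------------------------

    def in_bounds(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.height and 0 <= c < self.width

    def is_walkable_cell(self, cell: Cell) -> bool:
        return self.in_bounds(cell) and bool(self.walkable[cell])

    def is_walkable_position(self, pos: Position) -> bool:
        if not (0 <= pos[0] < self.width and 0 <= pos[1] < self.height):
            return False
        return bool(self.walkable[int(pos[1]), int(pos[0])])

    def neighbors(self, cell: Cell):
        r, c = cell
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if self.is_walkable_cell(nb):
                yield nb

    # -- routing ----------------------------------------------------------

    def bfs_tree(self, root: Cell) -> tuple[dict[Cell, int], dict[Cell, Cell]]:
        """Distances and step-toward-root parents for every cell reaching root.

        parent[cell] is the 4-neighbor one step closer to ``root``; following
        parents from any reachable cell walks a shortest path to the root.
        Cached per root for the lifetime of the plan.
        """
        cached = self._bfs_cache.get(root)
        if cached is not None:
            return cached
        if not self.is_walkable_cell(root):
            raise RoutingError(f"BFS root {root} is not a walkable cell")
        dist: dict[Cell, int] = {root: 0}
        parent: dict[Cell, Cell] = {}
        queue = deque([root])
        while queue:
            cur = queue.popleft()
            for nb in self.neighbors(cur):
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    parent[nb] = cur
                    queue.append(nb)
        self._bfs_cache[root] = (dist, parent)
        return dist, parent

    def grid_distance(self, a: Cell, b: Cell) -> int:
        """Length in hops of a shortest 4-connected walkable path a -> b."""
        dist, _ = self.bfs_tree(b)
        if a not in dist:
            raise RoutingError(f"no walkable route from {a} to {b}")
        return dist[a]

    def next_cell_toward(self, a: Cell, b: Cell) -> Cell:
        """The neighbor of ``a`` on a shortest path to ``b`` (``b`` if a == b)."""
        if a == b:
            return b
        dist, parent = self.bfs_tree(b)
        if a not in dist:
            raise RoutingError(f"no walkable route from {a} to {b}")
        return parent[a]

    # -- identity ---------------------------------------------------------

    def serialize(self) -> tuple[str, str]:
        """Canonical (map text, sidecar JSON) pair; inverse of load_floorplan."""
        rows = [
            "".join("." if self.walkable[r, c] else "#" for c in range(self.width))
            for r in range(self.height)
        ]
        map_text = "\n".join(rows) + "\n"
        sidecar = {
            "cell_size_m": self.cell_size,
            "destinations": {k: list(v) for k, v in sorted(self.destinations.items())},
            "nurse_stations": [list(c) for c in self.nurse_stations],
        }
        return map_text, json.dumps(sidecar, indent=2, sort_keys=True) + "\n"

    def digest(self) -> str:
        """Content hash identifying this geometry."""
        map_text, sidecar_text = self.serialize()
        return hashlib.sha256((map_text + sidecar_text).encode()).hexdigest()


def load_floorplan(map_text: str, sidecar: str | dict) -> FloorPlan:
    """Parse and validate a floor plan from ASCII map text plus its sidecar.

    The sidecar may be a JSON string or an already-decoded mapping with keys
    ``destinations`` (name -> [row, col]), ``nurse_stations`` ([[row, col]...])
    and ``cell_size_m``.  Raises a named ``FloorPlanError`` subclass when the
    map is non-rectangular, a named location sits on a wall, or the named
    locations are not mutually reachable.
    """
    if isinstance(sidecar, str):
        sidecar = json.loads(sidecar)
    rows = [line for line in map_text.splitlines() if line]
    if not rows:
        raise FloorPlanError("empty map")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise NonRectangularMapError("map rows have unequal lengths")
    height = len(rows)
    if width < 2 or height < 2:
        raise FloorPlanError(f"map must be at least 2x2, got {height}x{width}")
    bad = {ch for r in rows for ch in r} - {"#", "."}
    if bad:
        raise FloorPlanError(f"unknown map characters: {sorted(bad)}")
    walkable = np.array([[ch == "." for ch in r] for r in rows], dtype=bool)

    destinations = {
        str(name): (int(rc[0]), int(rc[1]))
        for name, rc in dict(sidecar.get("destinations", {})).items()
    }
    stations = [(int(rc[0]), int(rc[1])) for rc in sidecar.get("nurse_stations", [])]
    if len(destinations) < 2:
        raise FloorPlanError("a floor plan needs at least 2 named destinations")

    plan = FloorPlan(
        width=width,
        height=height,
        cell_size=float(sidecar.get("cell_size_m", 1.0)),
        walkable=walkable,
        destinations=destinations,
        nurse_stations=stations,
    )
    for name, cell in destinations.items():
        if not plan.is_walkable_cell(cell):
            raise LocationOnWallError(f"destination {name!r} at {cell} is not walkable")
    for cell in stations:
        if not plan.is_walkable_cell(cell):
            raise LocationOnWallError(f"nurse station at {cell} is not walkable")

    cells = list(destinations.values())
    reachable, _ = plan.bfs_tree(cells[0])
    unreachable = [n for n, c in destinations.items() if c not in reachable]
    if unreachable:
        raise UnreachableDestinationError(
            f"unreachable destination(s): {sorted(unreachable)}"
        )
    return plan


def shortest_route(plan: FloorPlan, frm: Position, to: Position) -> Route:
    """Minimum-length route between two walkable positions (4-connected).

    Waypoints are the cell centers of a shortest cell path from the cell of
    ``frm`` to the cell of ``to``; identical positions yield the empty route.
    """
    frm = Position(*frm)
    to = Position(*to)
    for p in (frm, to):
        if not plan.is_walkable_position(p):
            raise RoutingError(f"position {tuple(p)} is not walkable")
    if frm == to:
        return EMPTY_ROUTE
    start, goal = frm.cell, to.cell
    dist, parent = plan.bfs_tree(goal)
    if start not in dist:
        raise RoutingError(f"no walkable route from {start} to {goal}")
    cells = [start]
    while cells[-1] != goal:
        cells.append(parent[cells[-1]])
    waypoints = tuple(cell_center(c) for c in cells)
    return Route(waypoints=waypoints, total_length=float(len(cells) - 1))
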