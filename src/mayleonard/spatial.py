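"""Periodic geometry of the square arena and a uniform cell-list index.

Distances use the minimum-image convention, which equals the minimum over
the nine periodic images whenever the queried radius is below half the box.
The cell list guarantees complete radius queries as long as the query
radius does not exceed the cell size, because then the 3x3 block of cells
around the centre covers the whole disk.  ``brute_force_neighbors`` is the
O(N) oracle used in tests and as an alternative engine backend.
"""

from __future__ import annotations

import math

import numpy as np


def wrap(x: float, y: float, box_length: float) -> tuple[float, float]:
    """Map a point into [0, box_length) per coordinate (periodic boundaries)."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite coordinates ({x}, {y})")
    return x % box_length, y % box_length


def torus_distance(ax: float, ay: float, bx: float, by: float, box_length: float) -> float:
    """Euclidean distance on the torus (minimum-image convention)."""
    dx = ax - bx
    dy = ay - by
    dx -= box_length * round(dx / box_length)
    dy -= box_length * round(dy / box_length)
    return math.hypot(dx, dy)


def torus_distance_9image(ax, ay, bx, by, box_length) -> float:
    """Exhaustive minimum over the 9 periodic images; oracle for torus_distance."""
    best = math.inf
    for sx in (-box_length, 0.0, box_length):
        for sy in (-box_length, 0.0, box_length):
            best = min(best, math.hypot(ax - bx + sx, ay - by + sy))
    return best


def brute_force_neighbors(xs, ys, cx, cy, radius, box_length):
    """All indices i with torus_distance((xs[i],ys[i]), centre) <= radius.

    Returns a list of (index, distance) pairs in index order.  Vectorised
    over all points; this is the reference against which the cell grid is
    checked.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    dx = xs - cx
    dy = ys - cy
    dx -= box_length * np.round(dx / box_length)
    dy -= box_length * np.round(dy / box_length)
    d = np.hypot(dx, dy)
    idx = np.flatnonzero(d <= radius)
    return [(int(i), float(d[i])) for i in idx]


class CellGrid:
    """Uniform periodic cell list over the square arena.

    ``cells_per_side = max(1, floor(box_length / cell_size_request))`` and
    the effective cell size is ``box_length / cells_per_side``, so cells
    tile the box exactly and the effective size never falls below the
    request.  Membership is id -> cell; queries walk the 3x3 block of cells
    around the centre (deduplicated when the grid is narrower than 3 cells).
    """

    def __init__(self, cell_size: float, box_length: float):
        if cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {cell_size}")
        if cell_size > box_length:
            raise ValueError(f"cell_size={cell_size} exceeds box_length={box_length}")
        self.box_length = float(box_length)
        self.cells_per_side = max(1, int(math.floor(box_length / cell_size)))
        self.cell_size = box_length / self.cells_per_side
        self._members: list[set[int]] = [set() for _ in range(self.cells_per_side ** 2)]
        self._cell_of: dict[int, int] = {}

    # -- membership -------------------------------------------------------
    def cell_index(self, x: float, y: float) -> int:
        n = self.cells_per_side
        ix = min(int(x / self.box_length * n), n - 1)
        iy = min(int(y / self.box_length * n), n - 1)
        return iy * n + ix

    def insert(self, ident: int, x: float, y: float) -> None:
        if ident in self._cell_of:
            raise KeyError(f"id {ident} already present")
        c = self.cell_index(x, y)
        self._members[c].add(ident)
        self._cell_of[ident] = c

    def remove(self, ident: int) -> None:
        c = self._cell_of.pop(ident)
        self._members[c].discard(ident)

    def move(self, ident: int, x: float, y: float) -> None:
        c_new = self.cell_index(x, y)
        c_old = self._cell_of[ident]
        if c_new != c_old:
            self._members[c_old].discard(ident)
            self._members[c_new].add(ident)
            self._cell_of[ident] = c_new

    def __len__(self) -> int:
        return len(self._cell_of)

    def members(self) -> set[int]:
        return set(self._cell_of)

    def cell_of(self, ident: int) -> int:
        return self._cell_of[ident]

    # -- queries ----------------------------------------------------------
    def _block_cells(self, cx: float, cy: float):
        n = self.cells_per_side
        c = self.cell_index(cx, cy)
        iy0, ix0 = divmod(c, n)
        cells = {((iy0 + dy) % n) * n + (ix0 + dx) % n
                 for dy in (-1, 0, 1) for dx in (-1, 0, 1)}
        return cells

    def candidates(self, cx: float, cy: float):
        """Ids in the 3x3 block of cells around (cx, cy)."""
        out: list[int] = []
        for c in self._block_cells(cx, cy):
            out.extend(self._members[c])
        return out


def build_grid(positions, cell_size: float, box_length: float) -> CellGrid:
    """Build a CellGrid from ``positions``, a mapping id -> (x, y) or a sequence."""
    grid = CellGrid(cell_size, box_length)
    items = positions.items() if hasattr(positions, "items") else enumerate(positions)
    for ident, (x, y) in items:
        grid.insert(ident, x, y)
    return grid


def neighbors_within(grid: CellGrid, cx: float, cy: float, radius: float, positions):
    """All (id, distance) with torus distance to the centre <= radius (closed disk).

    ``positions`` maps id -> (x, y).  Raises if the radius exceeds the cell
    size, because the 3x3 block would then no longer cover the query disk.
    """
    if radius > grid.cell_size + 1e-15:
        raise ValueError(
            f"radius {radius} exceeds cell size {grid.cell_size}; query would be incomplete"
        )
    L = grid.box_length
    out = []
    for ident in grid.candidates(cx, cy):
        x, y = positions[ident]
        d = torus_distance(x, y, cx, cy, L)
        if d <= radius:
            out.append((ident, d))
    out.sort(key=lambda t: t[0])
    return out


def closest_of_species(grid: CellGrid, cx: float, cy: float, radius: float,
                       species_label, state, exclude_id: int | None = None):
    """Id of the nearest individual of ``species_label`` within ``radius``.

    ``state`` must expose ``position_of(id)`` and ``species_of(id)``.  The
    individual ``exclude_id`` (the actor itself) is skipped by id, not by
    coordinates, so a prey sitting exactly on the predator is still fair
    game.  Distance ties break toward the smallest id (exact ties have
    probability zero in continuous space).  Returns None if no candidate.
    """
    if radius > grid.cell_size + 1e-15:
        raise ValueError(
            f"radius {radius} exceeds cell size {grid.cell_size}; query would be incomplete"
        )
    L = grid.box_length
    best_id, best_d = None, math.inf
    for ident in grid.candidates(cx, cy):
        if ident == exclude_id or state.species_of(ident) != species_label:
            continue
        x, y = state.position_of(ident)
        d = torus_distance(x, y, cx, cy, L)
        if d <= radius and (d < best_d or (d == best_d and (best_id is None or ident < best_id))):
            best_id, best_d = ident, d
    return best_id
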