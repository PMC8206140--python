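"""May-Leonard population dynamics: state, microscopic processes, MC stepping.

Two interchangeable execution paths share one random-number stream and one
draw order, so they produce bit-identical trajectories from the same seed:

* a pure-Python reference layer (:class:`PopulationState` plus the
  ``attempt_*`` / ``elementary_step`` / ``mc_step`` functions), written for
  clarity and used in unit tests, and
* the compiled engine in :mod:`mayleonard._kernel`, used by :func:`run`.

Individuals live in slots ``0..n-1`` of flat arrays; a death moves the last
slot into the vacated one, so the slot index doubles as the individual id
and uniform selection among the living is O(1).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, spatial
from .params import SimParams, validate

SPECIES_LABELS = ("A", "B", "C")
_LABEL_TO_INDEX = {s: i for i, s in enumerate(SPECIES_LABELS)}

TWO_PI = 2.0 * math.pi


class Action(enum.Enum):
    MOVE = "move"
    PREDATE = "predate"
    REPRODUCE = "reproduce"


def prey_species(label: str) -> str:
    """Cyclic dominance: A preys on B, B on C, C on A."""
    try:
        i = _LABEL_TO_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown species label {label!r}") from None
    return SPECIES_LABELS[(i + 1) % 3]


# ---------------------------------------------------------------------------
# Counts series
# ---------------------------------------------------------------------------

@dataclass
class CountsSeries:
    """Per-MC-step record of species counts.

    ``t`` counts full MC steps since measurement started (1-based).
    ``extinction_step[s]`` is the first MC step at whose end species ``s``
    had zero individuals, measured on the same axis (values <= 0 mean the
    extinction happened during relaxation); None if the species survived.
    """

    t: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    n_c: np.ndarray
    extinction_step: dict = field(default_factory=dict)

    @property
    def n_total(self) -> np.ndarray:
        return self.n_a + self.n_b + self.n_c

    def counts_of(self, label: str) -> np.ndarray:
        return (self.n_a, self.n_b, self.n_c)[_LABEL_TO_INDEX[label]]

    @property
    def symmetry_broken(self) -> bool:
        return any(v is not None for v in self.extinction_step.values())

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "nA": self.n_a, "nB": self.n_b, "nC": self.n_c,
             "N": self.n_total}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountsSeries":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(), n_a=df["nA"].to_numpy(),
                   n_b=df["nB"].to_numpy(), n_c=df["nC"].to_numpy())


# ---------------------------------------------------------------------------
# Reference population state (pure Python)
# ---------------------------------------------------------------------------

class PopulationState:
    """Positions, species labels and counts of all living individuals.

    ``use_grid=False`` switches every neighbourhood query to the O(N)
    brute-force scan; trajectories are identical because ties in the
    nearest-prey search have probability zero.
    """

    def __init__(self, box_length: float, cell_size: float, capacity_hint: int = 256,
                 use_grid: bool = True):
        self.box_length = float(box_length)
        self._cap = max(16, capacity_hint)
        self.x = np.zeros(self._cap)
        self.y = np.zeros(self._cap)
        self.sp = np.zeros(self._cap, dtype=np.int64)
        self.n = 0
        self.counts = np.zeros(3, dtype=np.int64)
        self.use_grid = use_grid and cell_size * 3 <= box_length
        self.grid = spatial.CellGrid(cell_size, box_length) if self.use_grid else None

    # -- protocol used by spatial.closest_of_species ----------------------
    def position_of(self, ident: int):
        return self.x[ident], self.y[ident]

    def species_of(self, ident: int) -> int:
        return int(self.sp[ident])

    def species_label_of(self, ident: int) -> str:
        return SPECIES_LABELS[int(self.sp[ident])]

    # -- structural edits --------------------------------------------------
    def _grow(self):
        self._cap *= 2
        for name in ("x", "y", "sp"):
            arr = getattr(self, name)
            new = np.zeros(self._cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def add(self, species, x: float, y: float) -> int:
        if self.n == self._cap:
            self._grow()
        idx = _LABEL_TO_INDEX[species] if isinstance(species, str) else int(species)
        i = self.n
        x, y = spatial.wrap(x, y, self.box_length)
        self.x[i] = x
        self.y[i] = y
        self.sp[i] = idx
        self.counts[idx] += 1
        if self.grid is not None:
            self.grid.insert(i, x, y)
        self.n += 1
        return i

    def remove(self, ident: int) -> None:
        """Swap-with-last removal; the last individual inherits slot ``ident``."""
        self.counts[self.sp[ident]] -= 1
        if self.grid is not None:
            self.grid.remove(ident)
        last = self.n - 1
        if ident != last:
            if self.grid is not None:
                self.grid.remove(last)
            self.x[ident] = self.x[last]
            self.y[ident] = self.y[last]
            self.sp[ident] = self.sp[last]
            if self.grid is not None:
                self.grid.insert(ident, self.x[ident], self.y[ident])
        self.n = last

    def displace(self, ident: int, x: float, y: float) -> None:
        x, y = spatial.wrap(x, y, self.box_length)
        self.x[ident] = x
        self.y[ident] = y
        if self.grid is not None:
            self.grid.move(ident, x, y)

    # -- queries ------------------------------------------------------------
    def neighbors_within(self, cx: float, cy: float, radius: float):
        if self.grid is not None:
            pos = {i: (self.x[i], self.y[i]) for i in self.grid.candidates(cx, cy)}
            return spatial.neighbors_within(self.grid, cx, cy, radius, pos)
        return spatial.brute_force_neighbors(
            self.x[: self.n], self.y[: self.n], cx, cy, radius, self.box_length)

    def closest_prey(self, actor: int, radius: float):
        prey_idx = (int(self.sp[actor]) + 1) % 3
        cx, cy = self.x[actor], self.y[actor]
        if self.grid is not None:
            return spatial.closest_of_species(
                self.grid, cx, cy, radius, prey_idx, self, exclude_id=actor)
        best, best_d = None, math.inf
        for j in range(self.n):
            if j == actor or self.sp[j] != prey_idx:
                continue
            d = spatial.torus_distance(self.x[j], self.y[j], cx, cy, self.box_length)
            if d <= radius and d < best_d:
                best, best_d = j, d
        return best

    def tally(self) -> np.ndarray:
        """Recount species from labels (consistency check against ``counts``)."""
        return np.bincount(self.sp[: self.n], minlength=3).astype(np.int64)


def init_positions(params: SimParams, rng: np.random.Generator):
    """Draw the initial uniform configuration; shared by both engine paths.

    Returns (x, y, species) arrays of length ``3 * init_per_species`` with
    species in blocks A, B, C.
    """
    k = params.init_per_species
    pos = rng.random((3 * k, 2)) * params.box_length
    sp = np.repeat(np.arange(3, dtype=np.int64), k)
    return pos[:, 0].copy(), pos[:, 1].copy(), sp


def init_population(params: SimParams, rng: np.random.Generator,
                    use_grid: bool = True) -> PopulationState:
    """Uniformly random initial population with equal species counts."""
    x, y, sp = init_positions(params, rng)
    cell = max(params.pred_radius, params.repro_radius)
    state = PopulationState(params.box_length, cell,
                            capacity_hint=4 * len(x), use_grid=use_grid)
    for i in range(len(x)):
        state.add(int(sp[i]), x[i], y[i])
    return state


# ---------------------------------------------------------------------------
# Microscopic processes (reference implementations)
# ---------------------------------------------------------------------------

def attempt_predation(state: PopulationState, actor: int, params: SimParams) -> bool:
    """Kill the closest prey within ``pred_radius`` of the actor, if any.

    Returns True on a kill.  Consumes no random numbers.
    """
    victim = state.closest_prey(actor, params.pred_radius)
    if victim is None:
        return False
    state.remove(victim)
    return True


def attempt_reproduction(state: PopulationState, actor: int, params: SimParams,
                         rng: np.random.Generator) -> bool:
    """Capacity-gated birth.

    Counts every individual (the actor included) within ``repro_radius`` of
    the actor; if the count is strictly below ``capacity`` a newborn of the
    actor's species appears uniformly in the disk of ``offspring_radius``
    around the actor.  With capacity M=1 the actor alone saturates the
    neighbourhood, so no birth is ever possible.  Draws two uniforms
    (radius, angle) only on success.
    """
    cx, cy = state.x[actor], state.y[actor]
    count = len(state.neighbors_within(cx, cy, params.repro_radius))
    if count >= params.capacity:
        return False
    u1 = rng.random()
    u2 = rng.random()
    rad = params.offspring_radius * math.sqrt(u1)
    th = TWO_PI * u2
    state.add(int(state.sp[actor]), cx + rad * math.cos(th), cy + rad * math.sin(th))
    return True


def move(state: PopulationState, actor: int, params: SimParams,
         rng: np.random.Generator) -> None:
    """Displace the actor by exactly ``move_length`` in a uniform direction."""
    theta = TWO_PI * rng.random()
    state.displace(actor,
                   state.x[actor] + params.move_length * math.cos(theta),
                   state.y[actor] + params.move_length * math.sin(theta))


def elementary_step(state: PopulationState, params: SimParams,
                    rng: np.random.Generator) -> Action:
    """One elementary MC step: random living actor, one action drawn with (m, p, r)."""
    if state.n == 0:
        raise RuntimeError("elementary step on an empty population")
    actor = int(rng.integers(0, state.n))
    u = rng.random()
    if u < params.prob_move:
        move(state, actor, params, rng)
        return Action.MOVE
    if u < params.prob_move + params.prob_predate:
        attempt_predation(state, actor, params)
        return Action.PREDATE
    attempt_reproduction(state, actor, params, rng)
    return Action.REPRODUCE


def mc_step(state: PopulationState, params: SimParams,
            rng: np.random.Generator) -> None:
    """One full MC step: N0 elementary steps, N0 frozen at the step's start."""
    n0 = state.n
    for _ in range(n0):
        if state.n == 0:
            break
        elementary_step(state, params, rng)


# ---------------------------------------------------------------------------
# Production run
# ---------------------------------------------------------------------------

def _extinction_dict(ext_out: np.ndarray, relax_steps: int) -> dict:
    out = {}
    for s, label in enumerate(SPECIES_LABELS):
        out[label] = None if ext_out[s] < 0 else int(ext_out[s]) - relax_steps
    return out


def run(params: SimParams, *, backend: str = "cell", return_state: bool = False):
    """Full simulation: seeded init, relaxation, measured trajectory.

    Parameters
    ----------
    params:
        Validated model parameters; ``params.seed`` fully determines the run.
    backend:
        ``"cell"`` (compiled engine with the cell-list index, default),
        ``"brute"`` (compiled engine, O(N) neighbour scans; identical
        trajectory, for cross-checks) or ``"reference"`` (pure-Python layer,
        slow, identical trajectory).
    return_state:
        If True also return the final configuration as a
        ``(x, y, species_index)`` tuple of arrays.

    Returns
    -------
    CountsSeries, optionally followed by the final snapshot arrays.
    """
    validate(params)
    if backend == "reference":
        return _run_reference(params, return_state)
    if backend not in ("cell", "brute"):
        raise ValueError(f"unknown backend {backend!r}")

    L = params.box_length
    cell = max(params.pred_radius, params.repro_radius)
    n_side = max(1, int(math.floor(L / cell)))
    use_grid = backend == "cell" and n_side >= 3

    density_cap = params.capacity / (math.pi * params.repro_radius ** 2)
    scale = 1
    for _attempt in range(4):
        rng = np.random.default_rng(params.seed)
        x0, y0, sp0 = init_positions(params, rng)
        max_n = int(3 * params.init_per_species
                    + scale * (1.5 * density_cap * L * L + 4096))
        x = np.zeros(max_n)
        y = np.zeros(max_n)
        sp = np.zeros(max_n, dtype=np.int64)
        n0 = len(x0)
        x[:n0], y[:n0], sp[:n0] = x0 % L, y0 % L, sp0
        counts = np.bincount(sp0, minlength=3).astype(np.int64)

        if use_grid:
            cell_eff = L / n_side
            per_cell = params.capacity * cell_eff ** 2 / (math.pi * params.repro_radius ** 2)
            cell_cap = scale * (max(64, int(8 * per_cell) + 16))
            cell_count = np.zeros(n_side * n_side, dtype=np.int64)
            cell_items = np.zeros((n_side * n_side, cell_cap), dtype=np.int64)
        else:
            cell_cap = 1
            cell_count = np.zeros(1, dtype=np.int64)
            cell_items = np.zeros((1, 1), dtype=np.int64)
        cell_of = np.zeros(max_n, dtype=np.int64)
        slot_of = np.zeros(max_n, dtype=np.int64)

        counts_out = np.zeros((params.measure_steps, 3), dtype=np.int64)
        ext_out = np.full(3, -1, dtype=np.int64)

        status = _kernel.simulate(
            x, y, sp, n0, counts, L,
            params.pred_radius, params.repro_radius, params.offspring_radius,
            params.move_length, params.capacity,
            params.prob_move, params.prob_predate,
            n_side if use_grid else 1, cell_cap, cell_count, cell_items,
            cell_of, slot_of,
            params.relax_steps, params.measure_steps, counts_out, ext_out,
            rng, use_grid)
        if status == _kernel.STATUS_OK:
            break
        scale *= 4
    else:
        raise RuntimeError("engine buffers overflowed repeatedly; parameters "
                           "imply an unexpectedly dense population")

    series = CountsSeries(
        t=np.arange(1, params.measure_steps + 1),
        n_a=counts_out[:, 0], n_b=counts_out[:, 1], n_c=counts_out[:, 2],
        extinction_step=_extinction_dict(ext_out, params.relax_steps))
    if return_state:
        n_final = int(counts.sum())
        return series, (x[:n_final].copy(), y[:n_final].copy(), sp[:n_final].copy())
    return series


def _run_reference(params: SimParams, return_state: bool):
    rng = np.random.default_rng(params.seed)
    state = init_population(params, rng)
    ext = {label: None for label in SPECIES_LABELS}
    rows = np.zeros((params.measure_steps, 3), dtype=np.int64)
    for t in range(params.relax_steps + params.measure_steps):
        mc_step(state, params, rng)
        for s, label in enumerate(SPECIES_LABELS):
            if state.counts[s] == 0 and ext[label] is None:
                ext[label] = t + 1 - params.relax_steps
        if t >= params.relax_steps:
            rows[t - params.relax_steps] = state.counts
    series = CountsSeries(t=np.arange(1, params.measure_steps + 1),
                          n_a=rows[:, 0], n_b=rows[:, 1], n_c=rows[:, 2],
                          extinction_step=ext)
    if return_state:
        return series, (state.x[: state.n].copy(), state.y[: state.n].copy(),
                        state.sp[: state.n].copy())
    return series
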