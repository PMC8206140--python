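"""Model parameters: definition, validation, and flat key-value config I/O.

All lengths are fractions of the periodic square box (side ``box_length``),
so the model is dimensionless.  The three action probabilities ``prob_move``,
``prob_predate`` and ``prob_reproduce`` must sum to one: each elementary
Monte Carlo step draws exactly one of the three actions for the chosen
individual.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path


class ParamError(ValueError):
    """A parameter set violates a model invariant, or a config file is malformed."""


_INT_FIELDS = {"capacity", "init_per_species", "relax_steps", "measure_steps", "seed"}


@dataclass(frozen=True)
class SimParams:
    """Full parameter set of the off-lattice May-Leonard model.

    Attributes
    ----------
    box_length:
        Side of the periodic square arena (L).
    pred_radius:
        Predation range: the closest prey within this distance of a predator
        is killed.
    repro_radius:
        Reproduction range: a birth succeeds only if the number of
        individuals (any species, the parent included) within this distance
        of the parent is smaller than ``capacity``.
    move_length:
        Step length of a single movement action; the direction is uniform.
    offspring_radius:
        Radius of the disk, centred on the parent, in which a newborn is
        placed uniformly.  Kept as an independent knob; defaults to
        ``move_length``.
    capacity:
        Local carrying capacity M.  Low M models a harsh environment, high M
        a benign one.
    prob_move, prob_predate, prob_reproduce:
        Probabilities (m, p, r) of the three actions; must sum to 1.
    init_per_species:
        Initial number of individuals of each of the three species.
    relax_steps:
        Monte Carlo steps discarded before measurement begins.
    measure_steps:
        Monte Carlo steps recorded.
    seed:
        Seed of the single pseudo-random stream driving the whole run.
    """

    box_length: float = 1.0
    pred_radius: float = 0.02
    repro_radius: float = 0.02
    move_length: float = 0.01
    offspring_radius: float = 0.01
    capacity: int = 30
    prob_move: float = 0.5
    prob_predate: float = 0.25
    prob_reproduce: float = 0.25
    init_per_species: int = 10_000
    relax_steps: int = 2_000
    measure_steps: int = 10_000
    seed: int = 0

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_params() -> SimParams:
    """The reference parameter set: L=1, l_p=l_r=0.02, l_m=0.01, m=0.5, p=r=0.25.

    ``relax_steps``/``measure_steps`` default to desk-scale values (2000 /
    10000); spectral runs conventionally use 1000 relaxation steps.
    """
    return SimParams()


def validate(params: SimParams) -> SimParams:
    """Return ``params`` unchanged if every invariant holds, else raise ParamError.

    The first violated invariant is named in the error message.
    """
    p = params
    if not (p.box_length > 0 and math.isfinite(p.box_length)):
        raise ParamError(f"box_length must be positive and finite, got {p.box_length}")
    for name in ("pred_radius", "repro_radius", "offspring_radius"):
        v = getattr(p, name)
        if not (0 < v < p.box_length):
            raise ParamError(
                f"{name}={v}: radius must lie strictly between 0 and "
                f"box_length={p.box_length} (radius exceeds box)"
            )
    # move_length only needs to be positive: a long step simply wraps around
    # the torus (the well-mixed limit), whereas interaction radii must stay
    # below the box for minimum-image distances to be meaningful.
    if not (p.move_length > 0 and math.isfinite(p.move_length)):
        raise ParamError(f"move_length must be positive and finite, got {p.move_length}")
    probs = (p.prob_move, p.prob_predate, p.prob_reproduce)
    for name, v in zip(("prob_move", "prob_predate", "prob_reproduce"), probs):
        if not (0.0 <= v <= 1.0):
            raise ParamError(f"{name}={v}: probability outside [0, 1]")
    if abs(sum(probs) - 1.0) > 1e-12:
        raise ParamError(
            f"probabilities sum != 1: m+p+r = {sum(probs)!r} (must equal 1 within 1e-12)"
        )
    if p.capacity < 1:
        raise ParamError(f"capacity={p.capacity}: must be >= 1")
    if p.init_per_species < 1:
        raise ParamError(f"init_per_species={p.init_per_species}: must be >= 1")
    if p.relax_steps < 0:
        raise ParamError(f"relax_steps={p.relax_steps}: must be >= 0")
    if p.measure_steps < 1:
        raise ParamError(f"measure_steps={p.measure_steps}: must be >= 1")
    return params


def write_config(params: SimParams, path) -> None:
    """Write a flat ``key = value`` config file, one field per line."""
    lines = [f"{f.name} = {getattr(params, f.name)!r}" if False else
             f"{f.name} = {getattr(params, f.name)}"
             for f in dataclasses.fields(SimParams)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> SimParams:
    """Read a flat key-value config file written by :func:`write_config`.

    Accepts ``key = value`` or ``key: value`` lines; ``#`` starts a comment.
    Every field must be present exactly once; unknown keys are an error.
    The resulting parameter set is validated.
    """
    field_names = {f.name for f in dataclasses.fields(SimParams)}
    seen: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        elif ":" in line:
            key, _, val = line.partition(":")
        else:
            raise ParamError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = key.strip(), val.strip()
        if key not in field_names:
            raise ParamError(f"line {lineno}: unknown key {key!r}")
        if key in seen:
            raise ParamError(f"line {lineno}: duplicate key {key!r}")
        try:
            seen[key] = int(val) if key in _INT_FIELDS else float(val)
        except ValueError as exc:
            raise ParamError(f"line {lineno}: unparsable value for {key!r}: {val!r}") from exc
    missing = field_names - seen.keys()
    if missing:
        raise ParamError(f"missing key(s): {', '.join(sorted(missing))}")
    return validate(SimParams(**seen))
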