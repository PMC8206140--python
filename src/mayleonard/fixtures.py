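"""Deterministic fixtures for testing the analysis layer without the engine.

``make_sinusoid_fixture`` plants a known tone in a noisy fraction series so
the spectral pipeline's peak recovery can be validated against ground
truth; ``make_planted_configuration`` builds a population with hand-placed
individuals for microscopic tests of predation and reproduction.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .dynamics import PopulationState, _LABEL_TO_INDEX
from .spectral import FractionSeries


def make_sinusoid_fixture(k: int, n_components: int = 10_000,
                          amplitude: float = 0.1, noise_sd: float = 0.0,
                          seed: int = 0) -> FractionSeries:
    """Fraction series 1/3 + A*cos(2*pi*k*t/N_G) + Gaussian noise, clipped to [0,1].

    ``k`` is the planted cycle count per window and must satisfy
    1 <= k < N_G/2.  Amplitudes above 1/3 are allowed but warned about,
    since clipping then distorts the tone.
    """
    if not 1 <= k < n_components / 2:
        raise ValueError(f"k={k} outside [1, N_G/2) for N_G={n_components}")
    if amplitude > 1 / 3:
        warnings.warn(f"amplitude {amplitude} > 1/3: clipping will distort the tone",
                      stacklevel=2)
    t = np.arange(n_components)
    values = 1 / 3 + amplitude * np.cos(2 * math.pi * k * t / n_components)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, n_components)
    return FractionSeries(values=np.clip(values, 0.0, 1.0))


def make_planted_configuration(individuals, box_length: float = 1.0,
                               cell_size: float = 0.02,
                               use_grid: bool = True) -> PopulationState:
    """PopulationState holding exactly the given (species, x, y) individuals.

    Species may be labels ("A"/"B"/"C") or indices; ids are assigned in
    input order.  Duplicate positions are allowed — ids keep individuals
    distinct.
    """
    state = PopulationState(box_length, cell_size,
                            capacity_hint=4 * max(4, len(individuals)),
                            use_grid=use_grid)
    for species, x, y in individuals:
        if isinstance(species, str) and species not in _LABEL_TO_INDEX:
            raise ValueError(f"unknown species label {species!r}")
        if not (0 <= x < box_length and 0 <= y < box_length):
            raise ValueError(f"position ({x}, {y}) outside [0, {box_length})^2")
        state.add(species, x, y)
    return state
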