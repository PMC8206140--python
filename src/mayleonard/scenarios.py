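"""Scripted desk-scale experiments.

The reference studies run in the unit box with 3x10^4 initial individuals
and up to 10^8 relaxation steps; that budget is out of reach for a
workstation check.  The scenarios here shrink the *box* (radii unchanged)
and scale the initial population by the area ratio.  Local densities,
rates and hence the per-step oscillation frequency are preserved — only
the large-scale pattern imagery is lost, which these scenarios do not
attempt to reproduce quantitatively.  Every scenario can write a manifest
sufficient to re-run it exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import io
from .dynamics import run
from .observables import LinearFit, fit_mean_vs_capacity, sweep_capacity
from .params import SimParams, default_params, validate
from .spectral import (PeakScaling, Spectrum, ensemble_power_spectrum,
                       fit_log_scaling, fraction_series, peak_frequency)

BASE_DENSITY_PER_SPECIES = 10_000  # initial individuals per species in the unit box


@dataclass
class ScenarioSpec:
    """A named, re-runnable experiment: parameter overrides plus seeds."""

    name: str
    overrides: dict = field(default_factory=dict)
    replicates: int = 1
    seeds: list = field(default_factory=list)
    outputs: tuple = ("series",)

    def __post_init__(self):
        if len(self.seeds) < self.replicates:
            raise ValueError(
                f"scenario {self.name!r}: {len(self.seeds)} seeds for "
                f"{self.replicates} replicates")


def scaled_init(box_length: float, per_unit_area: int = BASE_DENSITY_PER_SPECIES) -> int:
    """Initial individuals per species for a shrunken box, at the reference density."""
    return max(1, round(per_unit_area * box_length ** 2))


def desk_params(box_length: float = 0.5, **overrides) -> SimParams:
    """Reference parameters rescaled to a smaller box at constant density."""
    p = default_params().replace(box_length=box_length,
                                 init_per_species=scaled_init(box_length))
    return validate(p.replace(**overrides))


def _manifest_entries(name: str, params: SimParams, seeds, elapsed: float,
                      extra: dict | None = None) -> dict:
    from . import __version__
    entries = {"scenario": name, "package_version": __version__}
    entries.update(params.as_dict())
    entries["seeds"] = ",".join(str(s) for s in seeds)
    entries["wall_time_s"] = f"{elapsed:.2f}"
    if extra:
        entries.update(extra)
    return entries


# ---------------------------------------------------------------------------
# Oscillation spectra vs carrying capacity
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSweepResult:
    spectra: dict  # M -> Spectrum
    peaks: dict  # M -> f_peak (cycles per N_G-step window)
    peak_powers: dict  # M -> power at the peak
    scaling: PeakScaling | None
    n_components: int
    box_length: float
    discarded: dict = field(default_factory=dict)  # M -> symmetry-broken runs skipped


def spectrum_sweep(m_values, n_components: int = 10_000, replicates: int = 5,
                   box_length: float = 0.5, relax_steps: int = 1_000,
                   base_seed: int = 0, species: str = "A",
                   smoothing_window: int = 1, max_attempt_factor: int = 6,
                   out_dir=None) -> SpectrumSweepResult:
    """Ensemble power spectra and peak frequencies across carrying capacities.

    For each M, ``replicates`` independent runs are relaxed for
    ``relax_steps`` MC steps and recorded for ``n_components`` steps; the
    species-fraction series are transformed and their power averaged.  The
    peak frequencies across M are then fitted as f_peak = a + b*ln(M)
    (when at least three M values are given).

    The spectrum characterises the oscillation of the *coexisting* state,
    so replicates in which a species dies out (possible in small desk-scale
    boxes at low M, where the oscillation is nearly box-coherent) are
    discarded and replaced by further runs from the same deterministic seed
    sequence, up to ``max_attempt_factor * replicates`` attempts per M.
    The number discarded per M is reported in the result and manifest.
    """
    t0 = time.perf_counter()
    m_values = sorted(int(m) for m in m_values)
    spectra: dict[int, Spectrum] = {}
    peaks: dict[int, int] = {}
    peak_powers: dict[int, float] = {}
    discarded: dict[int, int] = {}
    all_seeds = []
    for mi, m in enumerate(m_values):
        fracs = []
        discarded[m] = 0
        for attempt in range(max_attempt_factor * replicates):
            if len(fracs) == replicates:
                break
            seed = int(base_seed + 101 * mi + 10_007 * attempt + 1)
            all_seeds.append(seed)
            p = desk_params(box_length, capacity=m, relax_steps=relax_steps,
                            measure_steps=n_components, seed=seed)
            series = run(p)
            if series.symmetry_broken:
                discarded[m] += 1
                continue
            fracs.append(fraction_series(series, species=species))
        if not fracs:
            raise RuntimeError(
                f"M={m}: every attempted run lost a species; no coexisting "
                f"trajectory to analyse at box_length={box_length}")
        spec = ensemble_power_spectrum(fracs)
        spec.smoothing_window = smoothing_window
        spectra[m] = spec
        peaks[m] = peak_frequency(spec, smoothing_window=smoothing_window)
        peak_powers[m] = float(spec.power[peaks[m]])
    scaling = (fit_log_scaling(sorted(peaks.items()))
               if len(m_values) >= 3 else None)
    result = SpectrumSweepResult(spectra=spectra, peaks=peaks,
                                 peak_powers=peak_powers, scaling=scaling,
                                 n_components=n_components,
                                 box_length=box_length, discarded=discarded)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for m, spec in spectra.items():
            io.write_spectrum(out_dir / f"spectrum_M{m}.csv", spec)
        pd.DataFrame({"M": list(peaks), "f_peak": list(peaks.values()),
                      "peak_power": [peak_powers[m] for m in peaks]}
                     ).to_csv(out_dir / "peaks.csv", index=False)
        params0 = desk_params(box_length, capacity=m_values[0],
                              relax_steps=relax_steps,
                              measure_steps=n_components, seed=base_seed)
        extra = {"m_values": ",".join(map(str, m_values)),
                 "replicates": replicates, "species": species,
                 "smoothing_window": smoothing_window,
                 "discarded_broken_runs": ",".join(
                     f"{m}:{discarded[m]}" for m in m_values)}
        if scaling is not None:
            extra.update(scaling_intercept=scaling.intercept,
                         scaling_slope=scaling.slope,
                         scaling_r2=scaling.r_squared)
        io.write_manifest(out_dir / "manifest.txt",
                          _manifest_entries("spectrum_sweep", params0, all_seeds,
                                            time.perf_counter() - t0, extra))
    return result


# ---------------------------------------------------------------------------
# Mean population vs carrying capacity
# ---------------------------------------------------------------------------

@dataclass
class CapacitySweepResult:
    table: pd.DataFrame
    fit: LinearFit
    box_length: float
    move_length: float


def capacity_scenario(m_values=(5, 10, 15, 20, 25), box_length: float = 0.25,
                      relax_steps: int = 2_000, measure_steps: int = 4_000,
                      replicates: int = 3, move_length: float = 0.01,
                      base_seed: int = 0, out_dir=None) -> CapacitySweepResult:
    """Stationary <N> against M with a weighted linear fit.

    The mean grows linearly in M; the slope is robust to the movement
    length, which this scenario exposes via ``move_length`` so two sweeps
    can be compared.
    """
    t0 = time.perf_counter()
    base = desk_params(box_length, relax_steps=relax_steps,
                       measure_steps=measure_steps, move_length=move_length)
    seeds = [int(base_seed + 131 * k + 7) for k in range(replicates)]
    table = sweep_capacity(base, m_values, replicates=replicates, seeds=seeds)
    fit = fit_mean_vs_capacity(table)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_sweep(out_dir / "sweep.csv", table)
        io.write_manifest(out_dir / "manifest.txt", _manifest_entries(
            "capacity_sweep", base, seeds, time.perf_counter() - t0,
            {"m_values": ",".join(str(m) for m in m_values),
             "replicates": replicates, "fit_slope": fit.slope,
             "fit_intercept": fit.intercept, "fit_r2": fit.r_squared}))
    return CapacitySweepResult(table=table, fit=fit, box_length=box_length,
                               move_length=move_length)


# ---------------------------------------------------------------------------
# Well-mixed extinction
# ---------------------------------------------------------------------------

def extinction_scenario(move_length: float, n_seeds: int = 20,
                        box_length: float = 0.25, capacity: int = 10,
                        n_steps: int = 2_000, base_seed: int = 0) -> float:
    """Fraction of independent runs in which at least one species dies out.

    When the movement length is comparable to the box the system is
    effectively well mixed and demographic fluctuations drive one species
    extinct in most runs; at the reference movement length spatial
    structure protects coexistence.
    """
    broken = 0
    for k in range(n_seeds):
        p = desk_params(box_length, capacity=capacity, move_length=move_length,
                        relax_steps=0, measure_steps=n_steps,
                        seed=int(base_seed + 17 * k + 3))
        series = run(p)
        if series.symmetry_broken:
            broken += 1
    return broken / n_seeds


# ---------------------------------------------------------------------------
# Large interaction ranges (empty space as an extra "species")
# ---------------------------------------------------------------------------

def empty_space_fraction(x, y, box_length: float, radius: float,
                         probes_per_side: int = 200) -> float:
    """Share of box area farther than ``radius`` from every individual.

    Estimated on a regular probes_per_side^2 grid with periodic distances.
    """
    x = np.asarray(x)
    if len(x) == 0:
        return 1.0
    pts = np.column_stack([x % box_length, np.asarray(y) % box_length])
    tree = cKDTree(pts, boxsize=box_length)
    g = (np.arange(probes_per_side) + 0.5) * (box_length / probes_per_side)
    gx, gy = np.meshgrid(g, g)
    probes = np.column_stack([gx.ravel(), gy.ravel()])
    d, _ = tree.query(probes, k=1)
    return float(np.mean(d > radius))


@dataclass
class LargeRangeResult:
    snapshots: dict  # M -> (x, y, sp)
    mean_n: dict  # M -> stationary mean N
    empty_fraction: dict  # M -> empty-space share at range repro_radius


def large_range_scenario(m_values=(30, 120, 240), box_length: float = 1.0,
                         interaction_radius: float = 0.1,
                         relax_steps: int = 2_000, measure_steps: int = 500,
                         base_seed: int = 0, out_dir=None) -> LargeRangeResult:
    """Runs with predation/reproduction ranges comparable to the box.

    Even large M then supports only a sparse population, and deserted
    areas occupy a significant share of the arena; raising M restores the
    spiral-forming regime.  Snapshots and the probe-grid empty-space
    fraction at range ``interaction_radius`` quantify this.
    """
    t0 = time.perf_counter()
    snapshots, mean_n, empty = {}, {}, {}
    seeds = []
    for mi, m in enumerate(m_values):
        seed = int(base_seed + 211 * mi + 5)
        seeds.append(seed)
        p = desk_params(box_length, capacity=int(m),
                        pred_radius=interaction_radius,
                        repro_radius=interaction_radius,
                        relax_steps=relax_steps, measure_steps=measure_steps,
                        seed=seed)
        series, snap = run(p, return_state=True)
        snapshots[int(m)] = snap
        mean_n[int(m)] = float(np.mean(series.n_total))
        empty[int(m)] = empty_space_fraction(snap[0], snap[1], box_length,
                                             interaction_radius)
    result = LargeRangeResult(snapshots=snapshots, mean_n=mean_n,
                              empty_fraction=empty)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for m, (sx, sy, ssp) in snapshots.items():
            io.write_snapshot(out_dir / f"snapshot_M{m}.csv", sx, sy, ssp)
        pd.DataFrame({"M": list(mean_n), "mean_N": list(mean_n.values()),
                      "empty_fraction": [empty[m] for m in mean_n]}
                     ).to_csv(out_dir / "summary.csv", index=False)
        params0 = desk_params(box_length, capacity=int(m_values[0]),
                              pred_radius=interaction_radius,
                              repro_radius=interaction_radius,
                              relax_steps=relax_steps,
                              measure_steps=measure_steps, seed=base_seed)
        io.write_manifest(out_dir / "manifest.txt", _manifest_entries(
            "large_ranges", params0, seeds, time.perf_counter() - t0,
            {"m_values": ",".join(str(m) for m in m_values)}))
    return result
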