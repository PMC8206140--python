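"""Fourier analysis of species-fraction time series.

The oscillation of a species' population share rho(t) = n_s(t)/N(t) is
characterised by the discrete Fourier transform

    rho(f) = (1/N_G) * sum_{t=0}^{N_G-1} rho(t) * exp(-2*pi*i*f*t),

with the 1/N_G prefactor, so rho(0) is the time mean of the series.  The
ensemble power spectrum <|rho(f)|^2> is the per-frequency mean of the
squared magnitude over independent runs, folded to non-negative
frequencies.  Its peak over f > 0, on the axis "cycles per N_G-step
window" (integer bin index k), defines the characteristic oscillation
frequency; the peak location grows logarithmically with the local carrying
capacity M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .dynamics import CountsSeries


@dataclass
class FractionSeries:
    """A species' population share per MC step over an N_G-step window."""

    values: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.values)


@dataclass
class Spectrum:
    """One-sided ensemble power spectrum.

    ``frequencies[k]`` is the integer cycle count per N_G-step window;
    ``power[k]`` is the across-run mean of |rho(k)|^2.  The DC bin (k=0)
    is retained but excluded from peak searches.
    """

    frequencies: np.ndarray
    power: np.ndarray
    replicates: int
    n_components: int
    smoothing_window: int = 1


@dataclass
class PeakScaling:
    """Fit of f_peak = a + b*ln(M) over several carrying capacities."""

    points: list  # (M, f_peak) pairs
    intercept: float
    slope: float
    r_squared: float


def fraction_series(series: CountsSeries, species: str = "A", start: int = 0,
                    n_components: int | None = None) -> FractionSeries:
    """rho(t) = n_s(t)/N(t) over ``n_components`` steps from ``start``."""
    n_s = np.asarray(series.counts_of(species), dtype=float)
    n_tot = np.asarray(series.n_total, dtype=float)
    if n_components is None:
        n_components = len(n_s) - start
    stop = start + n_components
    if stop > len(n_s):
        raise ValueError(f"window [{start}, {stop}) exceeds series length {len(n_s)}")
    window_tot = n_tot[start:stop]
    if np.any(window_tot == 0):
        raise ValueError("population is empty somewhere in the window; "
                         "fractions are undefined")
    return FractionSeries(values=n_s[start:stop] / window_tot)


def dft(series: FractionSeries | np.ndarray) -> np.ndarray:
    """Normalised DFT with the 1/N_G prefactor; bin 0 is the time mean."""
    values = series.values if isinstance(series, FractionSeries) else np.asarray(series)
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    return np.fft.fft(values) / len(values)


def power_spectrum(series: FractionSeries | np.ndarray) -> np.ndarray:
    """One-sided |rho(f)|^2 for f = 0 .. floor(N_G/2)."""
    coeff = dft(series)
    n = len(coeff)
    return np.abs(coeff[: n // 2 + 1]) ** 2


def ensemble_power_spectrum(runs) -> Spectrum:
    """Per-frequency mean of |rho(f)|^2 across independent runs."""
    runs = list(runs)
    if not runs:
        raise ValueError("need at least one run")
    lengths = {r.n_components if isinstance(r, FractionSeries) else len(r) for r in runs}
    if len(lengths) != 1:
        raise ValueError(f"mismatched series lengths: {sorted(lengths)}")
    (n_g,) = lengths
    acc = np.zeros(n_g // 2 + 1)
    for r in runs:
        acc += power_spectrum(r)
    return Spectrum(frequencies=np.arange(n_g // 2 + 1), power=acc / len(runs),
                    replicates=len(runs), n_components=n_g)


def peak_frequency(spec: Spectrum, smoothing_window: int = 1) -> int:
    """Location of the non-DC power maximum, in cycles per N_G-step window.

    An odd ``smoothing_window`` > 1 applies a centred moving average to the
    non-DC power before the argmax; the default applies none.  Invariant to
    any overall rescaling of the power.
    """
    body = np.asarray(spec.power[1:], dtype=float)
    if len(body) < 3:
        raise ValueError("spectrum needs at least 3 non-DC bins")
    if not np.any(body > 0):
        raise ValueError("all-zero spectrum has no peak")
    if smoothing_window > 1:
        if smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        kern = np.ones(smoothing_window) / smoothing_window
        body = np.convolve(body, kern, mode="same")
    return int(spec.frequencies[1:][np.argmax(body)])


def fit_log_scaling(points) -> PeakScaling:
    """Least-squares fit f_peak = a + b*ln(M) over >= 3 distinct capacities."""
    pts = [(float(m), float(f)) for m, f in points]
    ms = np.array([p[0] for p in pts])
    fs = np.array([p[1] for p in pts])
    if np.any(ms <= 0):
        raise ValueError("carrying capacities must be positive for a log fit")
    if len(np.unique(ms)) < 3:
        raise ValueError("need at least 3 distinct M values")
    with np.errstate(divide="ignore", invalid="ignore"):  # exact fits: ssr=0
        res = sm.OLS(fs, sm.add_constant(np.log(ms))).fit()
    return PeakScaling(points=pts, intercept=float(res.params[0]),
                       slope=float(res.params[1]), r_squared=float(res.rsquared))


def naive_dft(values: np.ndarray) -> np.ndarray:
    """Direct O(N^2) evaluation of the normalised transform; test oracle."""
    values = np.asarray(values, dtype=complex)
    n = len(values)
    out = np.empty(n, dtype=complex)
    for f in range(n):
        acc = 0.0 + 0.0j
        for t in range(n):
            acc += values[t] * np.exp(-2j * math.pi * f * t / n)
        out[f] = acc / n
    return out
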