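"""Stationary-state observables: time averages, histograms, capacity sweeps.

The headline observable is the stationary mean population size <N> as a
function of the local carrying capacity M, which grows linearly with M with
a slope that is insensitive to microscopic details such as the movement
length.  Successive MC steps are strongly autocorrelated, so standard
errors use block averaging rather than the naive iid formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dynamics import CountsSeries, run
from .params import SimParams

DEFAULT_BLOCK = 100  # MC steps per block for the stderr estimate


@dataclass
class PopulationSummary:
    """Stationary summary of total population size over a measurement window."""

    mean_n: float
    stderr_n: float
    histogram: dict  # N value (or bin left edge) -> occurrence count
    window: tuple  # (start, end) indices into the series, end exclusive
    block_length: int


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float


def block_stderr(values: np.ndarray, block_length: int) -> float:
    """Standard error of the mean from non-overlapping block means.

    Falls back to the iid estimate when fewer than two full blocks exist.
    """
    values = np.asarray(values, dtype=float)
    n_blocks = len(values) // block_length
    if n_blocks >= 2:
        blocks = values[: n_blocks * block_length].reshape(n_blocks, block_length).mean(axis=1)
        return float(blocks.std(ddof=1) / math.sqrt(n_blocks))
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def summarize(series: CountsSeries, burn_in: int = 0,
              block_length: int = DEFAULT_BLOCK,
              max_bins: int = 1000) -> PopulationSummary:
    """Mean, block-averaged stderr and histogram of N after ``burn_in`` steps.

    N is integer-valued, so the histogram uses unit bins unless the range
    would exceed ``max_bins``, in which case equal-width bins are used and
    keys are the left bin edges.
    """
    n_tot = np.asarray(series.n_total)
    if burn_in >= len(n_tot):
        raise ValueError(f"burn_in={burn_in} leaves an empty window "
                         f"(series length {len(n_tot)})")
    window = n_tot[burn_in:]
    mean_n = float(window.mean())
    stderr = block_stderr(window, block_length)
    lo, hi = int(window.min()), int(window.max())
    if hi - lo + 1 <= max_bins:
        vals, counts = np.unique(window, return_counts=True)
        hist = {int(v): int(c) for v, c in zip(vals, counts)}
    else:
        counts, edges = np.histogram(window, bins=max_bins)
        hist = {float(e): int(c) for e, c in zip(edges[:-1], counts)}
    return PopulationSummary(mean_n=mean_n, stderr_n=stderr, histogram=hist,
                             window=(burn_in, len(n_tot)),
                             block_length=block_length)


def linear_fit(points) -> LinearFit:
    """Weighted least-squares line through (x, y[, weight]) points.

    ``points`` is an iterable of 2- or 3-tuples; omitted weights default
    to 1.  Requires at least two distinct x values.
    """
    rows = [tuple(p) for p in points]
    x = np.array([r[0] for r in rows], dtype=float)
    y = np.array([r[1] for r in rows], dtype=float)
    w = np.array([r[2] if len(r) > 2 else 1.0 for r in rows], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("linear fit needs at least two distinct x values")
    with np.errstate(divide="ignore", invalid="ignore"):  # exact fits: ssr=0
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return LinearFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                     r_squared=float(res.rsquared),
                     slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]))


def sweep_capacity(params_base: SimParams, m_values, replicates: int = 3,
                   seeds=None, burn_in: int = 0,
                   block_length: int = DEFAULT_BLOCK) -> pd.DataFrame:
    """Stationary <N> for each carrying capacity M, pooled over replicates.

    Each replicate is an independent full run (its own seed).  The pooled
    mean is the average of replicate means; the pooled standard error
    combines the per-replicate block-averaged errors as independent
    measurements: se = sqrt(sum se_i^2) / R.

    Returns a DataFrame with columns M, mean_N, stderr_N, replicates.
    """
    m_values = list(m_values)
    if seeds is None:
        seeds = [params_base.seed + 1000 * k for k in range(replicates)]
    seeds = list(seeds)
    if len(seeds) < replicates:
        raise ValueError("need at least one seed per replicate")
    rows = []
    for m in m_values:
        means, ses = [], []
        for k in range(replicates):
            p = params_base.replace(capacity=int(m), seed=int(seeds[k]))
            summary = summarize(run(p), burn_in=burn_in, block_length=block_length)
            means.append(summary.mean_n)
            ses.append(summary.stderr_n)
        pooled_se = math.sqrt(sum(s * s for s in ses)) / replicates
        rows.append({"M": int(m), "mean_N": float(np.mean(means)),
                     "stderr_N": pooled_se, "replicates": replicates})
    return pd.DataFrame(rows)


def fit_mean_vs_capacity(sweep: pd.DataFrame) -> LinearFit:
    """Weighted line <N> = a + b*M through a sweep table (weights 1/se^2)."""
    se = sweep["stderr_N"].to_numpy(dtype=float)
    se = np.where(se > 0, se, np.nanmin(np.where(se > 0, se, np.nan)) if (se > 0).any() else 1.0)
    pts = list(zip(sweep["M"], sweep["mean_N"], 1.0 / se ** 2))
    return linear_fit(pts)


def slopes_agree(fit_a: LinearFit, fit_b: LinearFit, n_se: float = 2.0) -> bool:
    """True when two fitted slopes differ by less than n_se joint standard errors."""
    joint = math.hypot(fit_a.slope_se, fit_b.slope_se)
    return abs(fit_a.slope - fit_b.slope) <= n_se * joint
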