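"""Binomial colonization-bottleneck model and survival-probability inference.

Seeding of the tumor niche is modeled as an independent Bernoulli trial per
injected cell with success probability q: a barcode carried by n_i = N*f_i
inoculum cells leaves x founder cells with probability Binom(n_i, q)(x).
Consequences used throughout:

* observation probability of a barcode: 1 - (1-q)^(N*f)
* expected surviving barcode count:     Bbar(q) = sum_i [1 - (1-q)^(N*f_i)]

Bbar is strictly increasing in q, so q is inferred from an observed barcode
count by bisection. A simulation-based calibration maps q to the day-1
survivor count B of the full stochastic dynamics via a power law B = a*q^b
and inverts it, mirroring how an experimental B is translated into a q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seeding import stream

__all__ = [
    "founder_pmf",
    "apply_bottleneck",
    "observation_probability",
    "expected_surviving",
    "infer_q",
    "InfeasibleInferenceError",
    "aggregate_observation_curve",
    "binned_observation_curve",
    "CalibrationFit",
    "calibrate_q_vs_B",
    "founder_counts",
]


class InfeasibleInferenceError(ValueError):
    """Observed barcode count outside the attainable range of the model."""


def founder_counts(frequencies: Sequence[float] | np.ndarray, total_cells: float) -> np.ndarray:
    """Integer inoculum cell counts round(N*f_i) per barcode."""
    f = np.asarray(frequencies, dtype=float)
    return np.rint(f * total_cells).astype(np.int64)


def founder_pmf(n_founders: int, q: float, x) -> float | np.ndarray:
    """P(x cells survive | n_founders inoculum cells, per-cell survival q).

    Plain binomial pmf, evaluated in log space by scipy so it is stable for
    n_founders up to 1e7 and beyond.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    n = int(n_founders)
    x_arr = np.asarray(x)
    if np.any(x_arr < 0) or np.any(x_arr > n):
        raise ValueError(f"x must lie in [0, {n}]")
    out = stats.binom.pmf(x_arr, n, q)
    return float(out) if out.shape == () else out


def apply_bottleneck(
    founder_counts: Sequence[int] | np.ndarray,
    q: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Independent binomial thinning of each barcode's inoculum cells."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    n = np.asarray(founder_counts)
    if n.ndim != 1 or np.any(n < 0):
        raise ValueError("founder counts must be a 1-D array of non-negative integers")
    if not np.issubdtype(n.dtype, np.integer):
        if not np.allclose(n, np.rint(n)):
            raise ValueError("founder counts must be integers")
        n = np.rint(n).astype(np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "bottleneck")
    return rng.binomial(n, q)


def observation_probability(f, N: float, q: float):
    """P(barcode detected at all) = 1 - (1-q)^(N*f); increasing in f, N, q."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f must be in [0, 1]")
    if q == 1:
        # every inoculum cell survives: observed iff the barcode has cells
        out = np.where(f * N > 0, 1.0, 0.0)
    else:
        out = -np.expm1(f * N * math.log1p(-q))
    return float(out) if out.shape == () else out


def expected_surviving(frequencies, N: float, q: float) -> float:
    """Expected number of barcodes with >= 1 surviving cell (Bbar)."""
    f = np.asarray(frequencies, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    return float(np.sum(observation_probability(f, N, q)))


def infer_q(
    frequencies,
    N: float,
    observed_B: float,
    rtol: float = 1e-8,
    q_min: float = 1e-12,
) -> float:
    """Invert Bbar(q) = observed_B for q by bisection.

    Bbar is strictly increasing on [0, 1] with Bbar(0) = 0 and
    Bbar(1) = #{i : N*f_i >= 1 cell}, so the root is unique whenever
    observed_B lies strictly inside that range. Bisection is used because
    the bracket is guaranteed.
    """
    f = np.asarray(frequencies, dtype=float)
    b_max = expected_surviving(f, N, 1.0)
    if not 0 < observed_B < b_max:
        raise InfeasibleInferenceError(
            f"observed_B={observed_B} outside the attainable range (0, {b_max:g}) "
            f"for this inoculum (N={N:g})"
        )
    lo, hi = q_min, 1.0
    if expected_surviving(f, N, lo) > observed_B:
        lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_surviving(f, N, mid) < observed_B:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rtol * hi:
            break
    return 0.5 * (lo + hi)


def aggregate_observation_curve(
    inoc_frequencies,
    presence_flags,
    group_size_schedule: Sequence[int],
    N: float,
    q: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Random-aggregation observation curve.

    For each group size in the schedule, barcodes are partitioned at random
    into disjoint groups of that size. A group's inoculum frequency is the
    sum of its members' frequencies and it counts as observed if any member
    was observed; the model predicts observation with probability
    1-(1-q)^(N*f_group). Aggregation populates the high-frequency end of the
    curve that individual barcodes cannot reach.

    Returns a DataFrame with columns ``group_size``, ``frequency``,
    ``observed`` (0/1) and ``predicted``.
    """
    f = np.asarray(inoc_frequencies, dtype=float)
    obs = np.asarray(presence_flags, dtype=bool)
    if f.shape != obs.shape:
        raise ValueError("presence flags must align with frequencies")
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "aggregate")
    rows = []
    n = f.size
    for size in group_size_schedule:
        size = int(size)
        if size < 1 or size > n:
            raise ValueError(f"group size {size} exceeds library size {n}")
        perm = rng.permutation(n)
        n_groups = n // size
        for gi in range(n_groups):
            members = perm[gi * size : (gi + 1) * size]
            fg = float(f[members].sum())
            rows.append(
                {
                    "group_size": size,
                    "frequency": fg,
                    "observed": int(obs[members].any()),
                    "predicted": float(observation_probability(fg, N, q)),
                }
            )
    return pd.DataFrame(rows)


def binned_observation_curve(curve: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Log-spaced frequency binning of an aggregation curve.

    Returns per-bin mean frequency, empirical observed fraction, mean
    predicted probability and group count.
    """
    f = curve["frequency"].to_numpy()
    edges = np.geomspace(f.min() * 0.999, f.max() * 1.001, n_bins + 1)
    idx = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        sub = curve[sel]
        out.append(
            {
                "frequency": float(sub["frequency"].mean()),
                "observed_fraction": float(sub["observed"].mean()),
                "predicted": float(sub["predicted"].mean()),
                "n_groups": int(sel.sum()),
            }
        )
    return pd.DataFrame(out)


@dataclass
class CalibrationFit:
    """Power-law map B = a * q^b between bottleneck size and day-1 survivors."""

    a: float
    b: float
    q_grid: np.ndarray
    B_values: np.ndarray
    residual: float  # RMS residual of log B

    def predict(self, q) -> np.ndarray | float:
        out = self.a * np.asarray(q, dtype=float) ** self.b
        return float(out) if out.shape == () else out

    def invert(self, B) -> float | np.ndarray:
        """q(B) = (B/a)^(1/b)."""
        out = (np.asarray(B, dtype=float) / self.a) ** (1.0 / self.b)
        return float(out) if out.shape == () else out


def fit_power_law_map(q_values, B_values) -> CalibrationFit:
    """Least-squares fit of log B on log q."""
    q = np.asarray(q_values, dtype=float)
    B = np.asarray(B_values, dtype=float)
    good = (q > 0) & (B > 0)
    q, B = q[good], B[good]
    if len(np.unique(B)) < 2 or q.size < 3:
        raise ValueError("degenerate calibration grid: need >= 3 points with distinct B")
    b, loga = np.polyfit(np.log(q), np.log(B), 1)
    resid = float(np.sqrt(np.mean((np.log(B) - (loga + b * np.log(q))) ** 2)))
    return CalibrationFit(a=float(np.exp(loga)), b=float(b), q_grid=q, B_values=B, residual=resid)


def calibrate_q_vs_B(
    sim_params,
    q_grid: Sequence[float],
    n_reps: int,
    seed: int,
    library=None,
    day_hours: float = 24.0,
    depth: int = 1_000_000,
) -> CalibrationFit:
    """Simulate day-1 survivor counts over a q grid and fit B = a*q^b.

    Each grid point runs ``n_reps`` full in-silico tumors (bottleneck +
    stochastic dynamics) and records the mean number of barcodes above one
    cell at ``day_hours``. The fitted map's :meth:`CalibrationFit.invert`
    translates an observed B back into a q.
    """
    from .synthetic import generate_inoculum, simulate_experiment  # local: avoid cycle

    q_grid = np.asarray(list(q_grid), dtype=float)
    if q_grid.size < 3:
        raise ValueError("q_grid must contain >= 3 values")
    if library is None:
        library = generate_inoculum(
            n_barcodes=2000, fold_range=6.0, central_mass=0.99,
            total_cells=250_000, seed=stream(seed, "calibration-library"),
        )
    B_means = []
    for qi, q in enumerate(q_grid):
        bundle = simulate_experiment(
            library, sim_params, q=float(q), n_tumors=n_reps,
            sample_days=[day_hours], depth=depth,
            seed=stream(seed, "calibration", qi),
        )
        Bs = [int(np.count_nonzero(tr.final_abundances >= 1.0)) for tr in bundle.trajectories]
        B_means.append(float(np.mean(Bs)))
    return fit_power_law_map(q_grid, np.asarray(B_means))
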