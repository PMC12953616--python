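"""Descriptive clone-abundance statistics for barcode count tables.

Covers the processing steps applied to barcode-sequencing data: RPM
normalization, the master-list replicate filter that removes sequencing
artifacts, replicate averaging, rank-frequency tables and power-law
(Zipf) fits f = beta * r^(-alpha), Shannon diversity, set-overlap and
rank-correlation tests, and back-of-envelope lineage arithmetic
(doublings, generation time, probability of a mutation-free expansion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tables import CountTable, RPM_SCALE

__all__ = [
    "RankAbundance",
    "PowerLawFit",
    "rpm_normalize",
    "build_master_list",
    "collapse_replicates",
    "rank_frequency",
    "fit_power_law",
    "shannon_entropy",
    "overlap_fisher",
    "spearman_corr",
    "bonferroni_adjust",
    "mutation_free_probability",
    "doublings",
    "generation_time",
]


# ---------------------------------------------------------------------------
# count-table processing
# ---------------------------------------------------------------------------

def rpm_normalize(table: CountTable) -> CountTable:
    """Scale every sample column to a depth of one million reads."""
    return table.to_rpm()


def build_master_list(
    t0_table: CountTable,
    min_rpm: float = 10.0,
    min_replicates: int = 2,
) -> set[str]:
    """Barcodes present above ``min_rpm`` (strictly) in >= ``min_replicates``
    technical replicates of the inoculum (T0) sequencing.

    This filter defines the qualified barcode set; barcodes seen only in
    tumor samples are sequencing/PCR artifacts and are excluded downstream.
    """
    if t0_table.units != "rpm":
        warnings.warn("master-list input not RPM-normalized; normalizing", stacklevel=2)
        t0_table = t0_table.to_rpm()
    if t0_table.data.shape[1] < min_replicates:
        raise ValueError(
            f"need >= {min_replicates} replicate columns, got {t0_table.data.shape[1]}"
        )
    hits = (t0_table.data > min_rpm).sum(axis=1)
    return set(t0_table.data.index[hits >= min_replicates])


def collapse_replicates(table: CountTable, master_set: Iterable[str]) -> CountTable:
    """Average technical replicates per sample and drop non-master barcodes."""
    if table.units != "rpm":
        raise ValueError("collapse_replicates expects an RPM table")
    groups = table.replicate_groups()
    n_reps = {name: len(cols) for name, cols in groups.items()}
    expected = max(n_reps.values())
    short = [name for name, n in n_reps.items() if n != expected]
    if short and len(set(n_reps.values())) > 1:
        raise ValueError(f"samples with missing replicates: {short}")
    master = set(master_set)
    keep = [b for b in table.data.index if b in master]
    collapsed = pd.DataFrame(
        {name: table.data.loc[keep, cols].mean(axis=1) for name, cols in groups.items()}
    )
    return CountTable(collapsed, units="rpm")


# ---------------------------------------------------------------------------
# rank-frequency and power-law fits
# ---------------------------------------------------------------------------

@dataclass
class RankAbundance:
    """Descending relative clone frequencies with their 1-based ranks."""

    ranks: np.ndarray
    frequencies: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) > 0):
            raise ValueError("frequencies must be non-increasing")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def __len__(self) -> int:
        return len(self.frequencies)


def rank_frequency(abundances, ids: Sequence[str] | None = None) -> RankAbundance:
    """Rank clones by abundance (descending), renormalizing to frequencies.

    Zeros are dropped; ties are broken deterministically by barcode id (or
    by input position when no ids are given).
    """
    a = np.asarray(abundances, dtype=float)
    if ids is None:
        ids = [f"_{i}" for i in range(a.size)]
    ids = list(ids)
    if len(ids) != a.size:
        raise ValueError("ids must align with abundances")
    pos = a > 0
    if not pos.any():
        raise ValueError("all abundances are zero")
    pairs = sorted(
        ((float(a[i]), ids[i]) for i in np.flatnonzero(pos)),
        key=lambda t: (-t[0], t[1]),
    )
    values = np.array([v for v, _ in pairs])
    total = values.sum()
    return RankAbundance(
        ranks=np.arange(1, values.size + 1),
        frequencies=values / total,
        ids=[b for _, b in pairs],
    )


@dataclass
class PowerLawFit:
    """Fitted rank-frequency power law f = beta * r^(-alpha)."""

    alpha: float
    beta: float
    method: str
    residual: float  # RMS residual in the fitted space

    def predict(self, r):
        return self.beta * np.asarray(r, dtype=float) ** (-self.alpha)


def fit_power_law(
    ra: RankAbundance,
    method: str = "nls",
    rank_range: tuple[int, int] | None = None,
) -> PowerLawFit:
    """Fit f = beta * r^(-alpha) to a rank-abundance table.

    ``method="nls"`` performs nonlinear least squares on the untransformed
    (r, f) pairs, which weights the high-frequency head; ``method="loglog"``
    is ordinary least squares of log10(f) on log10(r), the slope-reading of
    a Zipf plot. ``rank_range`` restricts the fit to ranks [lo, hi]
    (inclusive); default is the full detected range.
    """
    r = np.asarray(ra.ranks, dtype=float)
    f = np.asarray(ra.frequencies, dtype=float)
    if rank_range is not None:
        lo, hi = rank_range
        sel = (r >= lo) & (r <= hi)
        r, f = r[sel], f[sel]
    if r.size < 3:
        raise ValueError("need >= 3 points to fit")
    if np.any(f <= 0):
        raise ValueError("non-positive frequencies in fit range")
    if method == "loglog":
        slope, intercept = np.polyfit(np.log10(r), np.log10(f), 1)
        pred = intercept + slope * np.log10(r)
        resid = float(np.sqrt(np.mean((np.log10(f) - pred) ** 2)))
        return PowerLawFit(alpha=float(-slope), beta=float(10**intercept), method="loglog", residual=resid)
    if method == "nls":
        # log-log solution as starting point; bounds keep beta positive
        s0, i0 = np.polyfit(np.log10(r), np.log10(f), 1)
        popt, _ = optimize.curve_fit(
            lambda rr, alpha, beta: beta * rr ** (-alpha),
            r, f, p0=[-s0, 10**i0], maxfev=10_000,
        )
        alpha, beta = popt
        resid = float(np.sqrt(np.mean((f - beta * r ** (-alpha)) ** 2)))
        return PowerLawFit(alpha=float(alpha), beta=float(beta), method="nls", residual=resid)
    raise ValueError("method must be 'nls' or 'loglog'")


# ---------------------------------------------------------------------------
# diversity and association tests
# ---------------------------------------------------------------------------

def shannon_entropy(frequencies, log_base: float | None = None) -> float:
    """H = -sum f*log(f), with 0*log(0) := 0. Natural log by default."""
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    pos = f[f > 0]
    h = float(-np.sum(pos * np.log(pos)))
    if log_base is not None:
        h /= math.log(log_base)
    return h


def overlap_fisher(set_a: Iterable, set_b: Iterable, universe_size: int) -> float:
    """Two-sided Fisher exact p-value for overlap of two barcode sets.

    The 2x2 table is (in both / only A / only B / in neither) over a universe
    of ``universe_size`` barcodes; two-sidedness follows the standard
    minimum-likelihood rule.
    """
    A, B = set(set_a), set(set_b)
    union = len(A | B)
    if universe_size < union:
        raise ValueError(f"universe ({universe_size}) smaller than |A u B| ({union})")
    a = len(A & B)
    table = [[a, len(A) - a], [len(B) - a, universe_size - union]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation and its t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Family-wise correction: p_adj = min(1, m*p)."""
    m = len(p_values)
    return [min(1.0, m * float(p)) for p in p_values]


# ---------------------------------------------------------------------------
# lineage arithmetic
# ---------------------------------------------------------------------------

def doublings(final_size: float) -> float:
    """Number of cell doublings to grow a single cell to ``final_size``."""
    if final_size < 1:
        raise ValueError("final_size must be >= 1")
    return math.log2(final_size)


def generation_time(final_size: float, elapsed_hours: float) -> float:
    """Average minutes per division for a clone reaching ``final_size``."""
    if elapsed_hours <= 0:
        raise ValueError("elapsed_hours must be > 0")
    return 60.0 * elapsed_hours / doublings(final_size)


def mutation_free_probability(mu: float, final_size: float) -> float:
    """P(no mutation anywhere on a lineage expanding to ``final_size``).

    With a genome-wide mutation rate ``mu`` per genome per generation and
    log2(final_size) generations, the founding lineage stays mutation-free
    with probability (1-mu)^generations.
    """
    if not 0 <= mu < 1:
        raise ValueError("mu must be in [0, 1)")
    return (1.0 - mu) ** doublings(final_size)
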