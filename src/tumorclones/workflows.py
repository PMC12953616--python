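"""End-to-end study workflows at desk scale.

These functions chain the package's stages the way the full study does —
inoculum generation, binomial bottleneck, stochastic growth, multinomial
sequencing, and the downstream statistics — at problem sizes a single CPU
handles in minutes. They back the ``tumorclones reproduce`` subcommand and
the analysis scripts.
"""

from __future__ import annotations

import numpy as np

from .bottleneck import apply_bottleneck, expected_surviving, founder_pmf, infer_q
from .clonestats import (
    doublings,
    fit_power_law,
    generation_time,
    mutation_free_probability,
    rank_frequency,
    shannon_entropy,
)
from .dynamics import SimulationParams
from .seeding import stream
from .synthetic import generate_inoculum, simulate_experiment

__all__ = [
    "founder_statistics",
    "lineage_estimates",
    "intratumor_zipf",
    "bottleneck_recovery",
    "full_report",
]

#: Per-cell survival probabilities inferred for the two injection routes.
Q_INTRATUMOR = 2.6e-3
Q_INTRAVENOUS = 5.0e-5

#: Mean inoculum cells per barcode in the study (5e6 cells / ~40,000 barcodes).
MEAN_CELLS_PER_BARCODE = 125


def founder_statistics(n_cells: int = 100, q: float = Q_INTRATUMOR) -> dict:
    """Founder-size pmf of a typical barcode (n_cells inoculum cells).

    Returns the probabilities of 0, 1 and 2 surviving founder cells, as
    percentages.
    """
    p0, p1, p2 = (founder_pmf(n_cells, q, x) for x in (0, 1, 2))
    return {
        "pct_zero_founders": 100.0 * p0,
        "pct_one_founder": 100.0 * p1,
        "pct_two_founders": 100.0 * p2,
    }


def lineage_estimates(
    mu: float = 0.001,
    mutation_population: float = 2e9,
    leading_clone_size: float = 2.5e8,
    elapsed_hours: float = 24.0,
) -> dict:
    """Back-of-envelope estimates for a dominant single-cell-founded clone:
    doublings to its observed size, implied generation time, and the
    probability its expansion acquired no mutation."""
    return {
        "mutation_free_probability": mutation_free_probability(mu, mutation_population),
        "doublings": doublings(leading_clone_size),
        "generation_time_min": generation_time(leading_clone_size, elapsed_hours),
    }


def intratumor_zipf(
    seed: int,
    n_barcodes: int = 10_000,
    fold_range: float = 6.0,
    central_mass: float = 0.99,
    cells_per_barcode: float = MEAN_CELLS_PER_BARCODE,
    q: float = Q_INTRATUMOR,
    depth: int = 1_000_000,
    day_hours: float = 24.0,
    n_tumors: int = 3,
    params: SimulationParams | None = None,
) -> dict:
    """Direct-injection scenario: bottleneck, growth, sequencing, Zipf fit.

    Generates a narrow six-fold inoculum (total cells scaled so the mean
    barcode keeps the study's ~125 cells), applies the intratumor bottleneck
    q=2.6e-3, integrates the local-growth-limitation model with the study
    parameters to the sampled day, sequences the tumor, and fits the
    log10(frequency)-vs-log10(rank) slope by ordinary least squares over
    ranks 1..max(100, B/10) — at least two decades. The window is the
    small-rank regime r <= B/10 where the model's rank-frequency law
    f = -n*/(N ln(1-r/B)) is itself a pure power law to within ~5%; at
    larger r the law (and the data) bend down as -ln(1-r/B) leaves its
    linear regime, which is a property of the curve, not of the fit.

    The reported slope is the median over ``n_tumors`` independent tumors,
    matching how the study summarizes the exponent across tumors.
    """
    if params is None:
        params = SimulationParams()  # intratumor defaults
    library = generate_inoculum(
        n_barcodes=n_barcodes,
        fold_range=fold_range,
        central_mass=central_mass,
        total_cells=cells_per_barcode * n_barcodes,
        seed=stream(seed, "zipf-library"),
    )
    bundle = simulate_experiment(
        library, params, q=q, n_tumors=n_tumors, sample_days=[day_hours],
        depth=depth, seed=seed,
    )
    table = bundle.count_tables[day_hours]
    groups = table.replicate_groups()
    slopes, betas, detected, rank_his, entropies = [], [], [], [], []
    for cols in groups.values():
        counts = table.data[cols].mean(axis=1)  # mean of technical replicates
        ra = rank_frequency(counts.to_numpy(), ids=list(counts.index))
        rank_hi = max(100, len(ra) // 10)
        fit = fit_power_law(ra, method="loglog", rank_range=(1, rank_hi))
        slopes.append(-fit.alpha)
        betas.append(fit.beta)
        detected.append(len(ra))
        rank_his.append(rank_hi)
        entropies.append(shannon_entropy(ra.frequencies))
    slope = float(np.median(slopes))
    return {
        "slope": slope,
        "alpha": -slope,
        "per_tumor_slopes": slopes,
        "beta": float(np.median(betas)),
        "n_founder_barcodes": int(np.count_nonzero(bundle.founders, axis=1).min()),
        "n_detected": int(np.median(detected)),
        "fit_rank_max": int(np.median(rank_his)),
        "rank_decades": float(np.log10(min(rank_his))),
        "entropy_nats": float(np.median(entropies)),
        "total_cfu": float(np.median([tr.total_cfu[-1] for tr in bundle.trajectories])),
    }


def bottleneck_recovery(
    seed: int,
    q_true: float,
    n_trials: int = 20,
    n_barcodes: int = 40_000,
    total_cells: float = 5e6,
) -> dict:
    """Parameter-recovery exercise for the survival probability.

    Simulates presence/absence data by binomial thinning of a study-scale
    inoculum and re-infers q from the observed barcode count; reports the
    mean inferred q and the worst relative error across trials.
    """
    library = generate_inoculum(
        n_barcodes=n_barcodes, total_cells=total_cells,
        seed=stream(seed, "recovery-library", int(1e6 * q_true)),
    )
    cells = library.cell_counts()
    q_hats, b_obs = [], []
    for trial in range(n_trials):
        surv = apply_bottleneck(cells, q_true, stream(seed, "recovery", int(1e6 * q_true), trial))
        B = int(np.count_nonzero(surv))
        q_hats.append(infer_q(library.frequencies, total_cells, B))
        b_obs.append(B)
    q_hats = np.asarray(q_hats)
    rel_err = np.abs(q_hats - q_true) / q_true
    return {
        "q_true": q_true,
        "q_hat_mean": float(q_hats.mean()),
        "rel_error_max": float(rel_err.max()),
        "rel_error_mean": float(rel_err.mean()),
        "observed_B_mean": float(np.mean(b_obs)),
        "expected_B": expected_surviving(library.frequencies, total_cells, q_true),
    }


def full_report(seed: int, zipf_kwargs: dict | None = None) -> dict:
    """Run the synthetic intratumor and intravenous scenarios and collect
    the study's headline numbers into one dictionary."""
    report = {
        "founder_pmf_pct": founder_statistics(),
        "lineage": lineage_estimates(),
        "zipf_intratumor": intratumor_zipf(seed, **(zipf_kwargs or {})),
        "bottleneck_intratumor": bottleneck_recovery(seed, Q_INTRATUMOR, n_trials=5),
        "bottleneck_intravenous": bottleneck_recovery(seed, Q_INTRAVENOUS, n_trials=5),
    }
    report["survivor_ratio_it_vs_iv"] = (
        report["bottleneck_intratumor"]["expected_B"]
        / report["bottleneck_intravenous"]["expected_B"]
    )
    return report
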