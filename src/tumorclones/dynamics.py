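"""Stochastic consumer-resource dynamics of barcoded clones.

The model describes B barcoded clones competing for a single shared resource
s inside a tumor. Each clone grows at a Monod rate g*s/(s+k) or, under local
growth limitation (Contois kinetics), at g*s/(s+k*N_i), with multiplicative
environmental noise of strength sigma. The resource is depleted by growth
(inverse yield gamma) and replenished from the surrounding tissue at rate D
toward a background concentration s0:

    dN_i/dt = mu(N_i, s) * N_i + sigma * eta_i * N_i          (environmental)
    ds/dt   = -gamma * sum_i mu(N_i, s) * N_i + D*(s0 - s)

where mu is the per-capita growth rate and eta_i are independent unit white
noises. An in vitro variant replaces the environmental noise with demographic
noise eta_i*sqrt(mu*N_i). Only the ratios s0/gamma and k/gamma affect the
cell-count dynamics, so the integrator works internally in resource-per-gamma
units and trajectories are bit-identical under
(s0, k, gamma) -> (c*s0, c*k, c*gamma).

In the fluctuation-dominated regime (k*N_i >> s) the Contois model reduces
to a one-dimensional Langevin equation with constant drift
c = g*D*s0/(D*k + B*g*gamma) and multiplicative noise, whose stationary
clone-size distribution is p(n) = (n*/n^2) * exp(-n*/n) with characteristic
abundance n* = 2c/sigma^2. That law implies the rank-frequency curve
f(r) = -n* / (N * ln(1 - r/B)), i.e. Zipf's law f ~ 1/r for r << B. The
closed forms live here next to the simulator they describe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seeding import stream

__all__ = [
    "SimulationParams",
    "PopulationState",
    "Trajectory",
    "StationaryLaw",
    "growth_rate",
    "resource_update",
    "simulate",
    "simulate_reduced",
    "run_ensemble",
    "EnsembleBands",
    "compute_n_star",
    "stationary_pdf",
    "stationary_ccdf",
    "predicted_rank_frequency",
    "generations",
    "NumericalError",
]

MODES = ("monod", "contois", "demographic")

#: Abundance Euler step above which the integrator refuses to run unless
#: explicitly overridden (the resource is handled separately, see below).
MAX_STABLE_DT = 1e-3


class NumericalError(RuntimeError):
    """Raised when the integration produces NaN/Inf or a solver fails."""


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the consumer-resource model.

    Defaults are the intratumor condition: maximal growth rate g = 2/hr,
    noise sigma = sqrt(g), replenishment D = 1/s = 3600/hr, s0/gamma = 5e4
    and k/gamma = 1 (the intravenous condition uses k/gamma = 0.01).
    """

    g: float = 2.0                     # maximal per-capita growth rate (1/hr)
    k: float = 1.0                     # half-saturation (resource units; per cell in contois mode)
    gamma: float = 1.0                 # inverse yield (resource units per cell)
    D: float = 3600.0                  # resource replenishment rate (1/hr)
    s0: float = 5.0e4                  # background resource concentration
    sigma: float = math.sqrt(2.0)      # environmental noise strength (hr^-1/2)
    dt: float = 1e-3                   # Euler step for abundances (hr)
    horizon: float = 24.0              # total simulated time (hr)
    extinction_threshold: float | None = None  # clone removed when N_i drops below; None disables
    mode: str = "contois"
    resource_policy: str = "qss"       # "qss" (quasi-steady-state root) | "substep" (explicit Euler)
    geometric_update: bool = False     # exact log-normal update for the linear part
    allow_large_dt: bool = False

    def __post_init__(self) -> None:
        for name in ("g", "D", "s0", "gamma", "dt", "horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k < 0 or self.sigma < 0:
            raise ValueError("k and sigma must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.resource_policy not in ("qss", "substep"):
            raise ValueError("resource_policy must be 'qss' or 'substep'")
        if self.dt > MAX_STABLE_DT and not self.allow_large_dt:
            raise ValueError(
                f"dt={self.dt} exceeds the stability policy ({MAX_STABLE_DT} hr); "
                "set allow_large_dt=True to override"
            )

    # internal, scale-invariant quantities (resource measured per gamma)
    @property
    def s0_hat(self) -> float:
        return self.s0 / self.gamma

    @property
    def k_hat(self) -> float:
        return self.k / self.gamma

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


@dataclass
class PopulationState:
    """Instantaneous state: clone abundances, resource, survivor count."""

    abundances: np.ndarray
    resource: float
    extinction_threshold: float | None = None

    @property
    def survivors(self) -> int:
        thr = self.extinction_threshold
        if thr is None:
            return int(np.count_nonzero(self.abundances > 0))
        return int(np.count_nonzero(self.abundances >= thr))


@dataclass
class Trajectory:
    """Recorded time series of a single stochastic run."""

    times: np.ndarray            # hr, strictly increasing
    abundances: np.ndarray       # (n_times, n_clones)
    resource: np.ndarray         # (n_times,)
    survivors: np.ndarray        # (n_times,) integer counts

    @property
    def total_cfu(self) -> np.ndarray:
        return self.abundances.sum(axis=1)

    @property
    def final_abundances(self) -> np.ndarray:
        return self.abundances[-1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_hr": self.times,
                "total_cfu": self.total_cfu,
                "survivors": self.survivors,
                "resource": self.resource,
            }
        )


@dataclass(frozen=True)
class StationaryLaw:
    """The analytic stationary clone-size law p(n) = (n*/n^2) exp(-n*/n)."""

    n_star: float
    B: int
    N_total: float

    def pdf(self, n):
        return stationary_pdf(n, self.n_star)

    def ccdf(self, n):
        return stationary_ccdf(n, self.n_star)

    def rank_frequency(self, r):
        return predicted_rank_frequency(r, self.B, self.n_star, self.N_total)


# ---------------------------------------------------------------------------
# growth and resource kinetics
# ---------------------------------------------------------------------------

def growth_rate(N_i, s, params: SimulationParams):
    """Per-capita growth rate mu (1/hr).

    Monod/demographic: g*s/(s+k). Contois: g*s/(s + k*N_i), the local
    growth-limitation form where each clone's half-saturation scales with its
    own size. The degenerate 0/0 point is defined as 0.
    """
    N_i = np.asarray(N_i, dtype=float)
    s = float(s)
    k_hat = params.k_hat
    # gamma cancels: g*s/(s+k) == g*shat/(shat+khat); callers pass s in the
    # same units as params.s0, so rescale here.
    s_hat = s / params.gamma
    if params.mode == "contois":
        denom = s_hat + k_hat * N_i
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(denom > 0, params.g * s_hat / np.where(denom > 0, denom, 1.0), 0.0)
        return mu if mu.shape else float(mu)
    denom = s_hat + k_hat
    if denom <= 0:
        return np.zeros_like(N_i) if N_i.shape else 0.0
    mu = params.g * s_hat / denom
    return np.full_like(N_i, mu) if N_i.shape else float(mu)


def _consumption_hat(s_hat: float, N: np.ndarray, params: SimulationParams) -> float:
    """Total resource consumption rate in per-gamma units."""
    if params.mode == "contois":
        denom = s_hat + params.k_hat * N
        good = denom > 0
        return float(params.g * s_hat * np.sum(N[good] / denom[good]))
    denom = s_hat + params.k_hat
    if denom <= 0:
        return 0.0
    return float(params.g * s_hat * N.sum() / denom)


def _qss_resource_hat(N: np.ndarray, params: SimulationParams, s_guess: float) -> float:
    """Quasi-steady-state resource: root of D*(s0-s) = consumption(s).

    The balance h(s) = D*(s0-s) - C(s) is strictly decreasing on [0, s0]
    (replenishment falls, consumption grows with s), with h(0) > 0, so the
    root is unique. Newton iterations from the previous value, safeguarded by
    bisection on [0, s0].
    """
    s0h, kh, g, D = params.s0_hat, params.k_hat, params.g, params.D
    if N.size == 0 or N.sum() == 0:
        return s0h
    if params.mode != "contois":
        # Monod consumption gives a quadratic: D(s0-s)(s+k) = g*s*Ntot
        Nt = float(N.sum())
        b = kh - s0h + g * Nt / D
        c = -s0h * kh
        disc = b * b - 4 * c
        s = (-b + math.sqrt(disc)) / 2.0
        return min(max(s, 0.0), s0h)

    lo, hi = 0.0, s0h
    s = min(max(s_guess, 1e-300), s0h)
    for _ in range(100):
        denom = s + kh * N
        frac = N / denom
        h = D * (s0h - s) - g * s * float(frac.sum())
        if h > 0:
            lo = s
        else:
            hi = s
        # dh/ds = -D - g * sum(k*N_i^2/denom^2)  (d/ds of s*N/(s+kN) = kN^2/denom^2)
        dh = -D - g * float(np.sum(kh * N * N / (denom * denom)))
        step = h / dh
        s_new = s - step
        if not (lo < s_new < hi):
            s_new = 0.5 * (lo + hi)
        if abs(s_new - s) <= 1e-12 * max(s, 1e-30):
            s = s_new
            break
        s = s_new
    else:
        if hi - lo > 1e-8 * s0h:
            raise NumericalError("quasi-steady-state resource root did not converge")
    return min(max(s, 0.0), s0h)


def resource_update(s, abundances, params: SimulationParams, dt: float):
    """Advance the resource by one abundance step of length dt.

    Policy "qss": return the quasi-steady-state balance (the resource relaxes
    on the 1/D ~ 1 s timescale, far faster than the cells). Policy "substep":
    explicit Euler sub-steps of length <= 1/(2D). Result is clamped to
    [0, max(s, s0)].
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    N = np.asarray(abundances, dtype=float)
    s_hat = s / params.gamma
    if params.resource_policy == "qss":
        out = _qss_resource_hat(N, params, s_hat)
    else:
        n_sub = max(1, math.ceil(dt * 2.0 * params.D))
        h = dt / n_sub
        for _ in range(n_sub):
            ds = -_consumption_hat(s_hat, N, params) + params.D * (params.s0_hat - s_hat)
            s_hat = max(s_hat + h * ds, 0.0)
        out = s_hat
    out = min(out, max(s / params.gamma, params.s0_hat))
    return out * params.gamma


# ---------------------------------------------------------------------------
# Euler-Maruyama integration
# ---------------------------------------------------------------------------

def simulate(
    params: SimulationParams,
    init_abundances: Sequence[float] | np.ndarray,
    seed: int | np.random.Generator,
    record_stride: int | None = None,
    record_matrix: bool = True,
) -> Trajectory:
    """Integrate the model by Euler-Maruyama from the given initial clones.

    Noise increments per clone per step are independent N(0, dt) (Ito
    interpretation). Abundances crossing zero are clamped to 0 (absorbing);
    with an extinction threshold set, clones falling below it are removed
    (set to 0 permanently). The resource starts at s0 and follows
    :func:`resource_update` each step.

    Parameters
    ----------
    record_stride
        Record every ``record_stride``-th step (plus the initial and final
        states). Default records ~500 points.
    record_matrix
        If False, per-clone abundances are recorded only at the final time
        (summary series are always full); saves memory on long runs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "dynamics")
    N = np.asarray(init_abundances, dtype=float).copy()
    if N.ndim != 1:
        raise ValueError("init_abundances must be 1-D")
    if (N < 0).any():
        raise ValueError("initial abundances must be >= 0")

    n_steps = max(1, int(round(params.horizon / params.dt)))
    if record_stride is None:
        record_stride = max(1, n_steps // 500)
    thr = params.extinction_threshold
    sigma, dt = params.sigma, params.dt
    sqrt_dt = math.sqrt(dt)
    s_hat = params.s0_hat
    work = params.with_(gamma=1.0, s0=params.s0_hat, k=params.k_hat)  # per-gamma units

    rec_t, rec_s, rec_B, rec_N = [0.0], [s_hat * params.gamma], [], []
    alive_count = _survivors(N, thr)
    rec_B.append(alive_count)
    if record_matrix:
        rec_N.append(N.copy())

    # only track currently-alive clones; dead ones stay 0
    for step in range(1, n_steps + 1):
        active = N > 0
        Na = N[active]
        if Na.size:
            if work.mode == "contois":
                denom = s_hat + work.k_hat * Na
                mu = work.g * s_hat / denom
            else:
                mu = np.full_like(Na, work.g * s_hat / (s_hat + work.k_hat))
            eta = rng.standard_normal(Na.size)
            if work.mode == "demographic":
                Na = Na + mu * Na * dt + np.sqrt(np.maximum(mu * Na, 0.0)) * sqrt_dt * eta
            elif params.geometric_update:
                Na = Na * np.exp((mu - 0.5 * sigma * sigma) * dt + sigma * sqrt_dt * eta)
            else:
                Na = Na + mu * Na * dt + sigma * Na * sqrt_dt * eta
            np.maximum(Na, 0.0, out=Na)
            if thr is not None:
                Na[Na < thr] = 0.0
            N[active] = Na
            s_hat = _advance_resource_hat(s_hat, N[N > 0], work)
        else:
            s_hat = _advance_resource_hat(s_hat, Na, work)

        if step % record_stride == 0 or step == n_steps:
            if not np.isfinite(N).all() or not math.isfinite(s_hat):
                raise NumericalError(
                    f"non-finite state at t={step * dt:.4f} hr "
                    f"(max N={np.nanmax(N):.3g}, s={s_hat:.3g}); reduce dt or sigma"
                )
            rec_t.append(step * dt)
            rec_s.append(s_hat * params.gamma)
            rec_B.append(_survivors(N, thr))
            if record_matrix:
                rec_N.append(N.copy())

    if not record_matrix:
        rec_N = [np.zeros_like(N)] * (len(rec_t) - 1) + [N.copy()]
    return Trajectory(
        times=np.asarray(rec_t),
        abundances=np.vstack(rec_N),
        resource=np.asarray(rec_s),
        survivors=np.asarray(rec_B, dtype=int),
    )


def _survivors(N: np.ndarray, thr: float | None) -> int:
    if thr is None:
        return int(np.count_nonzero(N > 0))
    return int(np.count_nonzero(N >= thr))


def _advance_resource_hat(s_hat: float, N_alive: np.ndarray, work: SimulationParams) -> float:
    if work.resource_policy == "qss":
        return _qss_resource_hat(N_alive, work, s_hat)
    n_sub = max(1, math.ceil(work.dt * 2.0 * work.D))
    h = work.dt / n_sub
    for _ in range(n_sub):
        ds = -_consumption_hat(s_hat, N_alive, work) + work.D * (work.s0_hat - s_hat)
        s_hat = max(s_hat + h * ds, 0.0)
    return min(s_hat, work.s0_hat) if s_hat > work.s0_hat else s_hat


def simulate_reduced(
    drift: float,
    sigma: float,
    n0: float,
    n_traj: int,
    horizon: float,
    dt: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Euler-Maruyama ensemble of the reduced Langevin dn = c dt + sigma*n dW.

    This is the fluctuation-dominated limit of the Contois model, with the
    resource already eliminated at quasi-steady state: constant drift
    c = g*D*s0/(D*k+B*g*gamma) and multiplicative noise. Its stationary
    density is p(n) = (n*/n^2) exp(-n*/n) with n* = 2c/sigma^2. Returns the
    final abundances of ``n_traj`` independent trajectories.
    """
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "langevin")
    n = np.full(int(n_traj), float(n0))
    steps = int(round(horizon / dt))
    sqrt_dt = math.sqrt(dt)
    for _ in range(steps):
        n += drift * dt + sigma * n * sqrt_dt * rng.standard_normal(n.size)
        np.maximum(n, 0.0, out=n)
    return n


@dataclass
class EnsembleBands:
    """Pointwise median and quartile bands across stochastic runs."""

    times: np.ndarray
    total_cfu_median: np.ndarray
    total_cfu_q1: np.ndarray
    total_cfu_q3: np.ndarray
    survivors_median: np.ndarray
    survivors_q1: np.ndarray
    survivors_q3: np.ndarray
    final_abundances: list[np.ndarray] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_hr": self.times,
                "total_cfu_median": self.total_cfu_median,
                "total_cfu_q1": self.total_cfu_q1,
                "total_cfu_q3": self.total_cfu_q3,
                "survivors_median": self.survivors_median,
                "survivors_q1": self.survivors_q1,
                "survivors_q3": self.survivors_q3,
            }
        )


def run_ensemble(
    params: SimulationParams,
    init_abundances: Sequence[float] | np.ndarray,
    n_runs: int,
    seed: int,
    record_stride: int | None = None,
) -> EnsembleBands:
    """Run independent trajectories and summarize N(t) and B(t) bands."""
    if n_runs < 3:
        raise ValueError("n_runs must be >= 3")
    totals, survivors, finals = [], [], []
    times = None
    for i in range(n_runs):
        traj = simulate(
            params, init_abundances, stream(seed, "ensemble", i),
            record_stride=record_stride, record_matrix=False,
        )
        times = traj.times
        totals.append(traj.total_cfu)
        survivors.append(traj.survivors)
        finals.append(traj.final_abundances)
    T = np.vstack(totals)
    S = np.vstack(survivors)
    return EnsembleBands(
        times=times,
        total_cfu_median=np.median(T, axis=0),
        total_cfu_q1=np.percentile(T, 25, axis=0),
        total_cfu_q3=np.percentile(T, 75, axis=0),
        survivors_median=np.median(S, axis=0),
        survivors_q1=np.percentile(S, 25, axis=0),
        survivors_q3=np.percentile(S, 75, axis=0),
        final_abundances=finals,
    )


# ---------------------------------------------------------------------------
# analytic stationary law
# ---------------------------------------------------------------------------

def compute_n_star(params: SimulationParams, B: int) -> float:
    """Characteristic abundance n* = 2*g*D*s0 / ((D*k + B*g*gamma) * sigma^2).

    Invariant under joint rescaling of (s0, k, gamma); diverges as sigma -> 0
    (the law is undefined without noise, hence an error).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if params.sigma == 0:
        raise ValueError("n* is undefined for sigma = 0")
    num = 2.0 * params.g * params.D * params.s0
    den = (params.D * params.k + B * params.g * params.gamma) * params.sigma**2
    return num / den


def stationary_pdf(n, n_star: float):
    """Stationary clone-size density p(n) = (n*/n^2) * exp(-n*/n), n > 0."""
    _check_positive(n, n_star)
    n = np.asarray(n, dtype=float)
    out = (n_star / n**2) * np.exp(-n_star / n)
    return out if out.shape else float(out)


def stationary_ccdf(n, n_star: float):
    """P(size > n) = 1 - exp(-n*/n); decreases from 1 (n->0) to 0 (n->inf)."""
    _check_positive(n, n_star)
    n = np.asarray(n, dtype=float)
    out = -np.expm1(-n_star / n)
    return out if out.shape else float(out)


def _check_positive(n, n_star):
    if n_star <= 0:
        raise ValueError("n_star must be > 0")
    if np.any(np.asarray(n) <= 0):
        raise ValueError("n must be > 0")


def predicted_rank_frequency(r, B: int, n_star: float, N_total: float):
    """Model rank-frequency curve f(r) = -n* / (N_total * ln(1 - r/B)).

    For r << B this is f ~ n*B/(N_total*r), i.e. Zipf's law with exponent 1.
    Defined for 1 <= r < B; the log diverges at r = B.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 1) or np.any(r >= B):
        raise ValueError("ranks must satisfy 1 <= r < B")
    out = -n_star / (N_total * np.log1p(-r / B))
    return out if out.shape else float(out)


def generations(t_hours, g: float) -> np.ndarray | float:
    """Convert elapsed hours to doublings at the maximal rate: g*t/ln 2."""
    return np.asarray(t_hours, dtype=float) * g / math.log(2.0)
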