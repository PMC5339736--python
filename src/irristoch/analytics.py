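"""Stationary-distribution oracles, collapse detection, and experiment protocols.

For a one-dimensional birth-death chain the invariant distribution has a
product form, mass(N) proportional to prod_{n=1..N} b(n-1)/d(n).  The
forced-move ("jump") chain carries an extra factor (b+d)(N)/(b+d)(0)
because its embedded clock ticks faster where total rates are higher.
These closed forms are the analytic oracle against which Monte Carlo
runs are checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .drivers import DriverSpec, constant_driver
from .payoff_model import (
    ModelParams,
    Thresholds,
    compute_thresholds,
    entry_exit_rates,
    per_capita_payoff,
)
from .simulator import SimConfig, Trajectory, run_trajectory, spawn_seeds

__all__ = [
    "StationaryDistribution",
    "CollapseReport",
    "TrapResult",
    "TailMassError",
    "product_form_from_rates",
    "stationary_product_form",
    "empirical_distribution",
    "summarize_population",
    "total_variation",
    "detect_collapse",
    "drift_profile",
    "all_drift_negative",
    "all_drift_positive",
    "asymmetry_search",
    "collapse_fractions",
    "collapse_trap_protocol",
]

DEFAULT_N_MAX = 12_000


class TailMassError(ValueError):
    """The truncation bound N_max carries non-negligible probability mass."""


@dataclass
class StationaryDistribution:
    """Probability mass over integer populations 0..N_max.

    ``logp`` is kept alongside ``p`` because the two basins of the model
    are separated by hundreds of log-units: linear masses underflow where
    the log-scale structure (modes, barrier depth) is still meaningful.
    """

    p: np.ndarray
    logp: np.ndarray
    scheme: str
    W: Optional[float] = None
    T: Optional[float] = None

    @property
    def n_max(self) -> int:
        return len(self.p) - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.p))

    def local_modes(self) -> List[int]:
        """States whose log-mass strictly exceeds both neighbours (boundaries count)."""
        lp = self.logp
        modes = []
        for i in range(len(lp)):
            left = lp[i - 1] if i > 0 else -np.inf
            right = lp[i + 1] if i < len(lp) - 1 else -np.inf
            if lp[i] > left and lp[i] > right:
                modes.append(i)
        return modes

    def restricted(self, lo: int, hi: int) -> "StationaryDistribution":
        """Renormalised restriction to the states lo..hi inclusive."""
        p = np.zeros_like(self.p)
        seg = self.p[lo : hi + 1]
        if seg.sum() <= 0:
            raise ValueError("restriction carries no mass")
        p[lo : hi + 1] = seg / seg.sum()
        with np.errstate(divide="ignore"):
            logp = np.where(p > 0, np.log(np.maximum(p, 1e-320)), -np.inf)
        return StationaryDistribution(p, logp, self.scheme, self.W, self.T)


@dataclass(frozen=True)
class CollapseReport:
    """Outcome of first-passage analysis below the maintenance threshold."""

    collapsed: bool
    first_passage_year: Optional[int]
    min_N: int
    final_N: int

    def to_dict(self) -> dict:
        return {
            "collapsed": self.collapsed,
            "first_passage_year": self.first_passage_year,
            "min_N": self.min_N,
            "final_N": self.final_N,
        }


def product_form_from_rates(
    b: np.ndarray, d: np.ndarray, scheme: str = "bernoulli"
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalised (p, logp) of the birth-death chain with rate arrays b, d.

    ``b[n]``/``d[n]`` are the rates in state n; ``d[0]`` is ignored (the
    chain cannot leave 0 downward).  For the jump scheme the embedded
    forced-move chain's invariant measure gains a total-rate factor.
    """
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    if b.shape != d.shape or b.ndim != 1 or b.size < 2:
        raise ValueError("b and d must be equal-length 1-d arrays, length >= 2")
    if np.any(b[:-1] <= 0) or np.any(d[1:] <= 0):
        raise ValueError("interior rates must be positive for the product form")
    log_ratio = np.log(b[:-1]) - np.log(d[1:])
    logm = np.concatenate([[0.0], np.cumsum(log_ratio)])
    if scheme == "jump":
        total = b + d
        logm = logm + np.log(total) - np.log(total[0])
    elif scheme != "bernoulli":
        raise ValueError(f"unknown scheme {scheme!r}")
    logp = logm - logsumexp(logm)
    return np.exp(logp), logp


def stationary_product_form(
    params: ModelParams,
    W: Optional[float] = None,
    T: Optional[float] = None,
    N_max: int = DEFAULT_N_MAX,
    tail_tol: float = 1e-10,
) -> StationaryDistribution:
    """Exact stationary distribution of the chain at fixed drivers (W, T).

    Raises :class:`TailMassError` if the state ``N_max`` holds more than
    ``tail_tol`` probability, i.e. the truncation is too tight.
    """
    W = params.W_bar if W is None else float(W)
    T = params.T_bar if T is None else float(T)
    grid = np.arange(N_max + 1)
    b, d = entry_exit_rates(grid, W, T, params)
    p, logp = product_form_from_rates(b, d, params.scheme)
    if logp[-1] > math.log(tail_tol):
        raise TailMassError(
            f"mass {math.exp(logp[-1]):.3g} at N_max = {N_max} exceeds "
            f"{tail_tol:g}; increase N_max"
        )
    return StationaryDistribution(p, logp, params.scheme, W, T)


def empirical_distribution(
    traj: Trajectory, burn_in_years: float, N_max: Optional[int] = None
) -> StationaryDistribution:
    """Normalised histogram of recorded states after a burn-in period."""
    if burn_in_years >= traj.n_years:
        raise ValueError(
            f"burn_in_years = {burn_in_years} must be < n_years = {traj.n_years}"
        )
    keep = traj.N[traj.time > burn_in_years]
    if keep.size == 0:
        raise ValueError("no recorded samples after burn-in")
    top = int(keep.max()) if N_max is None else int(N_max)
    if keep.max() > top:
        raise ValueError("trajectory exceeds requested N_max")
    counts = np.bincount(keep, minlength=top + 1).astype(float)
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.maximum(p, 1e-320)), -np.inf)
    return StationaryDistribution(
        p, logp, traj.scheme,
        W=float(traj.W_years[0]), T=float(traj.T_years[0]),
    )


def summarize_population(dist: StationaryDistribution) -> Tuple[float, float, float]:
    """(mean, sd, cv) of the integer-valued distribution."""
    n = dist.support
    mean = float((n * dist.p).sum())
    sd = float(np.sqrt(((n - mean) ** 2 * dist.p).sum()))
    if mean == 0:
        raise ValueError("cv undefined: distribution has zero mean")
    return mean, sd, sd / mean


def total_variation(d1: StationaryDistribution, d2: StationaryDistribution) -> float:
    """Total variation distance, with supports zero-padded to a common length."""
    size = max(len(d1.p), len(d2.p))
    p1 = np.zeros(size)
    p2 = np.zeros(size)
    p1[: len(d1.p)] = d1.p
    p2[: len(d2.p)] = d2.p
    return 0.5 * float(np.abs(p1 - p2).sum())


def detect_collapse(traj: Trajectory, n_tilde: int) -> CollapseReport:
    """First passage strictly below the maintenance threshold ``n_tilde``.

    Uses the exact per-year minima, so dips between recorded samples count.
    """
    below = np.nonzero(traj.year_min < n_tilde)[0]
    collapsed = below.size > 0
    return CollapseReport(
        collapsed=collapsed,
        first_passage_year=int(below[0]) + 1 if collapsed else None,
        min_N=traj.min_N,
        final_N=traj.final_N,
    )


def drift_profile(
    params: ModelParams, W: float, T: float, N_range: Sequence[int]
) -> np.ndarray:
    """Two-column array of (N, b - d) over the requested states."""
    grid = np.asarray(N_range, dtype=np.int64)
    b, d = entry_exit_rates(grid, W, T, params)
    return np.column_stack([grid.astype(float), b - d])


def _scan_top(params: ModelParams, W: float) -> int:
    """Upper end of the drift scan: past W/a the payoff is pinned at zero."""
    return int(math.floor(max(W, params.W_bar) / params.a)) + 2


def all_drift_negative(params: ModelParams, W: float, T: float) -> bool:
    """True iff b(N) < d(N) for every N >= 1 at fixed (W, T)."""
    grid = np.arange(1, _scan_top(params, W))
    pi = per_capita_payoff(grid, W, T, params)
    # beyond the scan top pi = 0 < pi_o, so the tail is negative automatically
    return bool(np.all(pi < params.pi_o))


def all_drift_positive(params: ModelParams, W: float, T: float) -> bool:
    """True iff b(N) > d(N) for every N >= 1; impossible whenever pi_o > 0."""
    grid = np.arange(1, _scan_top(params, W))
    pi = per_capita_payoff(grid, W, T, params)
    return bool(np.all(pi > params.pi_o))


def asymmetry_search(
    params: ModelParams, W_grid: Sequence[float], T_grid: Sequence[float]
) -> Dict[str, list]:
    """Classify driver pairs by their drift sign pattern.

    Returns the (W, T) pairs with all-N negative drift and with all-N
    positive drift.  The latter list is provably empty: payoff vanishes
    for N >= W/a while the outside payoff stays positive, so exits
    dominate somewhere regardless of the drivers.
    """
    all_neg, all_pos = [], []
    for w in W_grid:
        for t in T_grid:
            if all_drift_negative(params, w, t):
                all_neg.append((w, t))
            if all_drift_positive(params, w, t):
                all_pos.append((w, t))
    return {"all_negative": all_neg, "all_positive": all_pos}


def collapse_fractions(
    params: ModelParams,
    driver: str,
    cv_levels: Sequence[float],
    n_reps: int = 20,
    n_years: int = 30,
    base_seed: int = 0,
    N0: Optional[int] = None,
    record_stride: int = 200,
) -> Dict[float, float]:
    """Fraction of replicates collapsing, per CV level of one driver.

    ``driver`` is ``"W"`` (lognormal water varied, tax held constant) or
    ``"T"`` (beta tax varied, water held constant).  A replicate counts
    as collapsed when its population first passes below n_tilde.
    """
    from .drivers import beta_from_mean_cv, lognormal_from_mean_cv

    thr = compute_thresholds(params)
    if not thr.viable:
        raise ValueError("baseline parameters are nonviable; no reference basin")
    n0 = thr.n_star if N0 is None else int(N0)
    out: Dict[float, float] = {}
    for lvl, cv in enumerate(cv_levels):
        if driver == "W":
            w_spec = lognormal_from_mean_cv(params.W_bar, cv)
            t_spec = constant_driver("beta", params.T_bar)
        elif driver == "T":
            w_spec = constant_driver("lognormal", params.W_bar)
            t_spec = beta_from_mean_cv(params.T_bar, cv)
        else:
            raise ValueError(f"driver must be 'W' or 'T', got {driver!r}")
        cfg = SimConfig(
            params=params, w_spec=w_spec, t_spec=t_spec,
            n_years=n_years, N0=n0, seed=0, record_stride=record_stride,
        )
        collapsed = 0
        for seed in spawn_seeds(base_seed + lvl, n_reps):
            traj = run_trajectory(replace(cfg, seed=seed))
            if detect_collapse(traj, thr.n_tilde).collapsed:
                collapsed += 1
        out[float(cv)] = collapsed / n_reps
    return out


@dataclass
class TrapResult:
    """Outcome of the three-phase calm/storm/calm protocol."""

    phases: Tuple[Trajectory, Trajectory, Trajectory]
    report: CollapseReport
    collapsed_in_storm: bool
    recovered: bool
    thresholds: Thresholds

    @property
    def phase_years(self) -> Tuple[int, int, int]:
        return tuple(t.n_years for t in self.phases)  # type: ignore[return-value]


def collapse_trap_protocol(
    params: ModelParams,
    calm_specs: Tuple[DriverSpec, DriverSpec],
    storm_specs: Tuple[DriverSpec, DriverSpec],
    years: Tuple[int, int, int],
    seed: int,
    N0: Optional[int] = None,
    record_stride: int = 50,
) -> TrapResult:
    """Calm / storm / calm protocol probing the one-way collapse transition.

    Starts at the break-even population, runs ``years = (n_A, n_B, n_C)``
    with the storm driver specs in the middle phase, and reports whether
    the population dropped below the maintenance threshold during the
    storm and whether it re-entered the upper basin (exceeded n_low)
    during the calm aftermath.  A run that never collapses counts as
    (vacuously) recovered.
    """
    thr = compute_thresholds(params)
    if not thr.viable:
        raise ValueError("baseline parameters are nonviable")
    n0 = thr.n_star if N0 is None else int(N0)
    seeds = spawn_seeds(seed, 3)
    phase_specs = (calm_specs, storm_specs, calm_specs)
    trajs: List[Trajectory] = []
    n = n0
    for (w_spec, t_spec), n_years, phase_seed in zip(phase_specs, years, seeds):
        cfg = SimConfig(
            params=params, w_spec=w_spec, t_spec=t_spec,
            n_years=n_years, N0=n, seed=phase_seed, record_stride=record_stride,
        )
        traj = run_trajectory(cfg)
        trajs.append(traj)
        n = traj.final_N

    year_min = np.concatenate([t.year_min for t in trajs])
    below = np.nonzero(year_min < thr.n_tilde)[0]
    collapsed = below.size > 0
    report = CollapseReport(
        collapsed=collapsed,
        first_passage_year=int(below[0]) + 1 if collapsed else None,
        min_N=int(year_min.min()),
        final_N=trajs[-1].final_N,
    )
    collapsed_in_storm = bool(np.any(trajs[1].year_min < thr.n_tilde))
    if not collapsed:
        recovered = True
    else:
        recovered = bool(np.any(trajs[2].year_max > thr.n_low))
    return TrapResult(tuple(trajs), report, collapsed_in_storm, recovered, thr)
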