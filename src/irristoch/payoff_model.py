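"""Deterministic core of the irrigated-commons model.

Per-capita payoff inside the system is

    pi(N; W, T) = (1 - T) * h * W(N) * g(x(N; W, T))

with available water ``W(N) = max(0, W - a*N)``, funding index
``x = T * N * h * W(N)`` and infrastructure performance
``g(x) = z / (z + kappa)`` where ``z = max(0, x - x0)``.  The three
functional-form constants ``x0``, ``kappa``, ``pi_o`` are not free knobs:
they are pinned by :func:`calibrate` to three integer population landmarks
(maintenance threshold, payoff maximiser, inside/outside break-even).

Entry and exit rates are payoff-driven around a demographic noise floor
``m``; see :func:`entry_exit_rates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ModelParams",
    "Thresholds",
    "CalibrationError",
    "DEFAULT_ANCHORS",
    "available_water",
    "funding_index",
    "infrastructure_performance",
    "per_capita_payoff",
    "entry_exit_rates",
    "compute_thresholds",
    "calibrate",
    "payoff_surface",
    "default_params",
]

#: Population landmarks used to pin (x0, kappa, pi_o) at baseline drivers:
#: (maintenance threshold, payoff maximiser, break-even population).
DEFAULT_ANCHORS: Tuple[int, int, int] = (727, 3333, 7015)

_SCHEMES = ("jump", "bernoulli")


class CalibrationError(ValueError):
    """Anchors are inconsistent with the payoff functional family."""


@dataclass(frozen=True)
class ModelParams:
    """All constants of the payoff and demographic process.

    ``x0``, ``kappa`` and ``pi_o`` may be left ``None`` while building a
    base parameter set for :func:`calibrate`; every evaluation routine
    requires them to be set.
    """

    m: float = 1.0          # baseline entry/exit rate (events / year)
    h: float = 0.01         # income per person per unit available water
    r: float = 1.0          # responsiveness of flows to the payoff gap
    a: float = 1e-4         # per-capita water usage rate
    W_bar: float = 1.0      # mean water availability
    T_bar: float = 0.2      # mean tax fraction
    pi_o: Optional[float] = None    # outside per-capita payoff
    x0: Optional[float] = None      # maintenance threshold on funding index
    kappa: Optional[float] = None   # half-saturation of infrastructure perf.
    dt: float = 5e-5        # time-step length (years)
    scheme: str = "jump"    # transition scheme: jump | bernoulli

    def __post_init__(self) -> None:
        for name in ("m", "h", "r", "a", "W_bar", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not 0 < self.T_bar < 1:
            raise ValueError(f"T_bar must lie in (0, 1), got {self.T_bar!r}")
        if self.pi_o is not None and not self.pi_o > 0:
            raise ValueError(f"pi_o must be > 0, got {self.pi_o!r}")
        if self.x0 is not None and not self.x0 >= 0:
            raise ValueError(f"x0 must be >= 0, got {self.x0!r}")
        if self.kappa is not None and not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa!r}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")

    @property
    def calibrated(self) -> bool:
        return None not in (self.x0, self.kappa, self.pi_o)

    @property
    def n_cap(self) -> int:
        """Largest population with positive available water at mean W."""
        return int(math.floor(self.W_bar / self.a))

    def with_scheme(self, scheme: str) -> "ModelParams":
        return replace(self, scheme=scheme)

    def _require_calibrated(self) -> None:
        if not self.calibrated:
            raise ValueError(
                "ModelParams has unset x0/kappa/pi_o; run calibrate() first "
                "or use default_params()"
            )


@dataclass(frozen=True)
class Thresholds:
    """Population landmarks of the payoff curve at a given (W, T).

    ``n_low``/``n_star`` are ``None`` when the system is nonviable at
    those drivers (max payoff below the outside payoff): population then
    shrinks at every size and the system heads to collapse.
    """

    n_tilde: int
    n_low: Optional[int]
    n_m: int
    n_star: Optional[int]
    pi_max: float
    W: float
    T: float

    @property
    def viable(self) -> bool:
        return self.n_low is not None

    def to_dict(self) -> dict:
        return {
            "n_tilde": self.n_tilde,
            "n_low": self.n_low,
            "n_m": self.n_m,
            "n_star": self.n_star,
            "pi_max": self.pi_max,
            "viable": self.viable,
            "W": self.W,
            "T": self.T,
        }


def _as_array(x, name: str, lower=0.0):
    arr = np.asarray(x, dtype=float)
    if lower is not None and np.any(arr < lower):
        raise ValueError(f"{name} must be >= {lower}")
    return arr


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def available_water(N, W, params: ModelParams):
    """Water left after extraction: ``max(0, W - a*N)``."""
    scalar = np.isscalar(N) and np.isscalar(W)
    n = _as_array(N, "N")
    w = _as_array(W, "W")
    return _maybe_scalar(np.maximum(0.0, w - params.a * n), scalar)


def _check_tax(T) -> np.ndarray:
    t = np.asarray(T, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("T must lie in [0, 1]")
    return t


def funding_index(N, W, T, params: ModelParams):
    """Tax revenue proxy feeding maintenance: ``x = T * N * h * max(0, W - a*N)``."""
    scalar = np.isscalar(N) and np.isscalar(W) and np.isscalar(T)
    n = _as_array(N, "N")
    t = _check_tax(T)
    x = t * n * params.h * available_water(n, W, params)
    return _maybe_scalar(x, scalar)


def infrastructure_performance(N, W, T, params: ModelParams):
    """Saturating performance ``g(x) = z/(z + kappa)``, ``z = max(0, x - x0)``.

    Exactly zero while the funding index stays at or below the maintenance
    threshold ``x0``; approaches (but never reaches) 1 as funding grows.
    """
    params._require_calibrated()
    scalar = np.isscalar(N) and np.isscalar(W) and np.isscalar(T)
    x = funding_index(N, W, T, params)
    z = np.maximum(0.0, np.asarray(x) - params.x0)
    return _maybe_scalar(z / (z + params.kappa), scalar)


def per_capita_payoff(N, W, T, params: ModelParams):
    """After-tax income per person: ``(1 - T) * h * available_water * g(x)``."""
    scalar = np.isscalar(N) and np.isscalar(W) and np.isscalar(T)
    t = _check_tax(T)
    pi = (
        (1.0 - t)
        * params.h
        * available_water(N, W, params)
        * infrastructure_performance(N, W, T, params)
    )
    return _maybe_scalar(pi, scalar)


def entry_exit_rates(N, W, T, params: ModelParams):
    """Per-year entry and exit rates ``(b, d)`` at population N.

    For N >= 1 the rate on the favoured side is ``m + r*N*|pi - pi_o|``
    and the other side stays at the demographic floor ``m``.  At the
    boundary ``b(0) = m`` and ``d(0) = 0``: an empty system can only gain
    its first member.
    """
    params._require_calibrated()
    scalar = np.isscalar(N) and np.isscalar(W) and np.isscalar(T)
    n = _as_array(N, "N")
    delta = np.asarray(per_capita_payoff(n, W, T, params)) - params.pi_o
    gain = params.r * n * delta
    b = params.m + np.maximum(gain, 0.0)
    d = params.m + np.maximum(-gain, 0.0)
    at_zero = n == 0
    b = np.where(at_zero, params.m, b)
    d = np.where(at_zero, 0.0, d)
    return _maybe_scalar(b, scalar), _maybe_scalar(d, scalar)


def _first_crossing(values: np.ndarray, level: float) -> Optional[int]:
    """Index of the last element before ``values`` first exceeds ``level``."""
    above = np.nonzero(values > level)[0]
    if above.size == 0:
        return None
    return int(above[0]) - 1


def _bisect_boundary(pi_of, lo: int, hi: int, pi_o: float, want_low: bool) -> int:
    """Integer bisection for the pi = pi_o crossing on a monotone branch.

    ``want_low``: invariant pi(lo) < pi_o <= pi(hi), returns smallest N with
    pi >= pi_o; otherwise pi(lo) >= pi_o > pi(hi), returns largest such N.
    """
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if (pi_of(mid) >= pi_o) == want_low:
            hi = mid
        else:
            lo = mid
    return hi if want_low else lo


def compute_thresholds(
    params: ModelParams, W: Optional[float] = None, T: Optional[float] = None
) -> Thresholds:
    """Locate the payoff-curve landmarks at drivers (W, T).

    ``n_tilde`` by scan for the first funding-index crossing of ``x0``;
    ``n_m`` by exhaustive integer scan (ties to the smaller N); the two
    ``pi = pi_o`` crossings by integer bisection bracketed against
    ``n_m``.  If even the peak payoff falls short of the outside payoff
    the record is flagged nonviable.
    """
    params._require_calibrated()
    W = params.W_bar if W is None else float(W)
    T = params.T_bar if T is None else float(T)
    if W <= 0:
        raise ValueError("W must be > 0")
    n_cap = int(math.floor(W / params.a))
    grid = np.arange(0, n_cap + 1)
    x = funding_index(grid, W, T, params)
    pi = per_capita_payoff(grid, W, T, params)

    crossing = _first_crossing(x, params.x0)
    n_tilde = n_cap if crossing is None else crossing

    n_m = int(np.argmax(pi))  # argmax takes the first = smallest maximiser
    pi_max = float(pi[n_m])
    if pi_max < params.pi_o or crossing is None:
        return Thresholds(n_tilde, None, n_m, None, pi_max, W, T)

    def pi_of(n: int) -> float:
        return per_capita_payoff(n, W, T, params)

    if pi_of(n_tilde) >= params.pi_o:  # degenerate bracket; cannot occur: pi(n_tilde)=0
        n_low = n_tilde
    else:
        n_low = _bisect_boundary(pi_of, n_tilde, n_m, params.pi_o, want_low=True)
    if pi_of(n_cap) >= params.pi_o:
        n_star = n_cap
    else:
        n_star = _bisect_boundary(pi_of, n_m, n_cap, params.pi_o, want_low=False)
    return Thresholds(n_tilde, n_low, n_m, n_star, pi_max, W, T)


def calibrate(
    anchors: Sequence[int], base: ModelParams
) -> Tuple[float, float, float]:
    """Pin (x0, kappa, pi_o) so the landmarks at baseline drivers equal ``anchors``.

    ``x0`` is the funding index at the maintenance anchor.  ``kappa``
    solves the first-order condition for the payoff maximum at ``n_m``,

        a * z_M * (z_M + kappa) = (W - a*n_m) * kappa * x'(n_m),

    which is linear in kappa.  ``pi_o`` is then set to the payoff at
    ``n_star`` exactly, so the >= comparison in threshold finding recovers
    the anchor without tolerance.
    """
    n_tilde, n_m, n_star = (int(v) for v in anchors)
    W, T = base.W_bar, base.T_bar
    if not (0 < n_tilde < n_m < n_star < W / base.a):
        raise CalibrationError(
            f"anchors must satisfy 0 < n_tilde < n_m < n_star < W_bar/a, "
            f"got {(n_tilde, n_m, n_star)} with W_bar/a = {W / base.a:g}"
        )
    x0 = funding_index(n_tilde, W, T, base)
    z_m = funding_index(n_m, W, T, base) - x0
    if z_m <= 0:
        raise CalibrationError("funding index not increasing between n_tilde and n_m")
    x_prime = T * base.h * (W - 2.0 * base.a * n_m)
    denom = (W - base.a * n_m) * x_prime - base.a * z_m
    if denom <= 0:
        raise CalibrationError(
            "first-order condition has no positive root for kappa; "
            "n_m is inconsistent with the saturating-performance family"
        )
    kappa = base.a * z_m * z_m / denom
    trial = replace(base, x0=x0, kappa=kappa, pi_o=1.0)
    pi_o = per_capita_payoff(n_star, W, T, trial)
    if not pi_o > 0:
        raise CalibrationError("payoff at n_star is not positive")
    if per_capita_payoff(n_m, W, T, trial) <= pi_o:
        raise CalibrationError("anchors leave no interior basin (pi(n_m) <= pi_o)")
    return float(x0), float(kappa), float(pi_o)


def calibrated_params(
    anchors: Sequence[int] = DEFAULT_ANCHORS, base: Optional[ModelParams] = None
) -> ModelParams:
    """Return ``base`` completed with constants calibrated to ``anchors``."""
    if base is None:
        base = ModelParams()
    x0, kappa, pi_o = calibrate(anchors, base)
    return replace(base, x0=x0, kappa=kappa, pi_o=pi_o)


@lru_cache(maxsize=1)
def default_params() -> ModelParams:
    """Paper-default parameters with constants calibrated to the default anchors."""
    return calibrated_params()


def payoff_surface(N_grid, T_grid, W, params: ModelParams) -> np.ndarray:
    """Payoff matrix with element [i, j] = pi(N_i; W, T_j)."""
    n = _as_array(N_grid, "N_grid")
    t = _check_tax(np.asarray(T_grid, dtype=float))
    if n.size == 0 or t.size == 0:
        raise ValueError("grids must be nonempty")
    return np.asarray(
        per_capita_payoff(n[:, None], W, t[None, :], params), dtype=float
    )
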