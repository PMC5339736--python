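"""Moment-matched annual drivers: lognormal water, beta tax.

Both drivers are parameterised by (mean, cv) and converted to natural
parameters in closed form, so the mean stays fixed while the coefficient
of variation is dialled.  ``cv = 0`` denotes an exactly constant driver
(same code path, degenerate draw).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "DriverSpec",
    "lognormal_from_mean_cv",
    "beta_from_mean_cv",
    "constant_driver",
    "draw_annual_series",
    "implied_mean_cv",
]


@dataclass(frozen=True)
class DriverSpec:
    """A stochastic annual driver defined by mean and CV.

    ``natural_params`` is ``(mu, sigma)`` for a lognormal and
    ``(alpha, beta)`` for a beta; for a degenerate beta both diverge and
    are stored as ``inf``.
    """

    kind: str  # "lognormal" | "beta"
    mean: float
    cv: float
    natural_params: Tuple[float, float]

    @property
    def degenerate(self) -> bool:
        return self.cv == 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` i.i.d. annual values."""
        if self.degenerate:
            return np.full(n, self.mean)
        p, q = self.natural_params
        if self.kind == "lognormal":
            return rng.lognormal(mean=p, sigma=q, size=n)
        return rng.beta(p, q, size=n)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mean": self.mean, "cv": self.cv}


def lognormal_from_mean_cv(mean: float, cv: float) -> DriverSpec:
    """Lognormal spec with the given mean and CV.

    Moment matching: ``sigma^2 = ln(1 + cv^2)``, ``mu = ln(mean) - sigma^2/2``.
    """
    if not mean > 0:
        raise ValueError(f"lognormal mean must be > 0, got {mean!r}")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv!r}")
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return DriverSpec("lognormal", float(mean), float(cv), (mu, math.sqrt(sigma2)))


def beta_from_mean_cv(mean: float, cv: float) -> DriverSpec:
    """Beta spec with the given mean and CV.

    With ``var = (cv*mean)^2`` and ``nu = mean*(1-mean)/var - 1``:
    ``alpha = mean*nu``, ``beta = (1-mean)*nu``.  Feasibility on (0, 1)
    requires ``cv^2 < (1 - mean)/mean``.
    """
    if not 0 < mean < 1:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean!r}")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv!r}")
    if cv == 0:
        return DriverSpec("beta", float(mean), 0.0, (math.inf, math.inf))
    bound = (1.0 - mean) / mean
    if cv * cv >= bound:
        raise ValueError(
            f"infeasible beta cv: need cv^2 < (1 - mean)/mean = {bound:g}, "
            f"got cv^2 = {cv * cv:g}"
        )
    var = (cv * mean) ** 2
    nu = mean * (1.0 - mean) / var - 1.0
    return DriverSpec("beta", float(mean), float(cv), (mean * nu, (1.0 - mean) * nu))


def constant_driver(kind: str, mean: float) -> DriverSpec:
    """Degenerate driver pinned at its mean (cv = 0)."""
    if kind == "lognormal":
        return lognormal_from_mean_cv(mean, 0.0)
    if kind == "beta":
        return beta_from_mean_cv(mean, 0.0)
    raise ValueError(f"unknown driver kind {kind!r}")


def implied_mean_cv(spec: DriverSpec) -> Tuple[float, float]:
    """Mean and CV implied by the natural parameters (round-trip check)."""
    if spec.degenerate:
        return spec.mean, 0.0
    p, q = spec.natural_params
    if spec.kind == "lognormal":
        mean = math.exp(p + 0.5 * q * q)
        cv = math.sqrt(math.expm1(q * q))
    else:
        mean = p / (p + q)
        cv = math.sqrt(q / (p * (p + q + 1.0)))
    return mean, cv


def draw_annual_series(
    w_spec: DriverSpec, t_spec: DriverSpec, n_years: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Independent annual (W_t, T_t) series, reproducible from ``seed``.

    The water series is drawn first, then the tax series, from a single
    PCG64 generator.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    return w_spec.sample(rng, n_years), t_spec.sample(rng, n_years)
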