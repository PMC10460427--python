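"""Closed-form mathematics of the activity model.

In the large-``tau``, large-``k`` limit the distribution of a randomly chosen
alter's activity ``a`` solves the master equation

    d_t p_a = [(a - 1 + alpha) p_{a-1} - (a + alpha) p_a] / (t + alpha),

with ``p_a(a0) = delta_{a,a0}``, and has the explicit solution (in relative
activity ``a_r = a - a0``)

    p_a = p0 * a_r^{-1} / B(a_r, alpha_r) * (1 + 1/beta)^{-a_r},
    p0  = (1 + beta)^{-alpha_r},

a negative binomial with shape ``alpha_r`` and mean ``t_r = beta * alpha_r``,
shifted by ``a0``.  Its mean is ``t``, its variance ``t_r (1 + beta)``, and
the dispersion index is ``d = beta / (2 + beta)``: ``beta`` alone controls
the shape, crossing from homogeneous (Poisson-like, ``beta < 1``) to
heterogeneous (gamma-like, ``beta > 1``) signatures at ``beta = 1``
(``d = 1/3``).

All pmf evaluation is done in log space through ``gammaln``; the Euler beta
function is never called directly (it overflows already for moderate
relative activities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gammaln

from .params import ModelParams

__all__ = [
    "ActivityDistribution",
    "connection_probability",
    "activity_pmf",
    "activity_logpmf",
    "model_moments",
    "classify_regime",
    "dispersion_from_beta",
    "beta_from_dispersion",
    "pgf",
    "integrate_master_equation",
    "MasterEquationSolution",
]

#: |beta - 1| below which :func:`classify_regime` reports the crossover.
CROSSOVER_TOL = 1e-9

#: beta below which the distribution is treated as the degenerate point mass.
_BETA_DEGENERATE = 1e-14


def connection_probability(a: float, tau: float, params: ModelParams) -> float:
    """Probability that an alter with activity ``a`` receives event ``tau + 1``.

    ``pi_a = (a + alpha) / (tau + k * alpha)``; in reduced variables this is
    ``(a_r + alpha_r) / (tau_r + k * alpha_r)``.
    """
    if a < params.a0:
        raise ValueError(f"activity a={a} below minimum a0={params.a0}")
    if tau < params.k * params.a0:
        raise ValueError(f"event time tau={tau} below initial time {params.k * params.a0}")
    denom = tau + params.k * params.alpha
    if denom <= 0:
        raise ValueError("non-positive kernel denominator tau + k*alpha")
    return (a + params.alpha) / denom


def _logpmf_relative(a_r: np.ndarray, alpha_r: float, beta: float) -> np.ndarray:
    """log p at relative activities ``a_r >= 0`` (negative-binomial form)."""
    a_r = np.asarray(a_r, dtype=float)
    with np.errstate(divide="ignore"):
        out = (
            gammaln(a_r + alpha_r)
            - gammaln(alpha_r)
            - gammaln(a_r + 1.0)
            + a_r * (np.log(beta) - np.log1p(beta))
            - alpha_r * np.log1p(beta)
        )
    return out


def activity_logpmf(a: np.ndarray, params: ModelParams, t: float | None = None) -> np.ndarray:
    """Log-pmf of the closed-form activity distribution at activities ``a``.

    Activities below ``a0`` get ``-inf``.  Safe for arbitrarily large
    activities (log-space evaluation).
    """
    p = params if t is None else params.with_t(t)
    a = np.asarray(a, dtype=float)
    a_r = a - p.a0
    beta = p.beta
    if beta < _BETA_DEGENERATE:
        out = np.where(a_r == 0, 0.0, -np.inf)
        return out
    out = _logpmf_relative(np.clip(a_r, 0, None), p.alpha_r, beta)
    return np.where(a_r < 0, -np.inf, out)


@dataclass
class ActivityDistribution:
    """Truncated closed-form activity distribution on ``[a0, a_max]``.

    ``pmf[i]`` is the probability of activity ``support[i]``; the truncation
    point ``a_max`` is the smallest activity whose tail mass is below
    ``truncation_tol``.  ``leaked_mass`` reports ``1 - sum(pmf)``.
    """

    params: ModelParams
    support: np.ndarray
    pmf: np.ndarray
    truncation_tol: float
    leaked_mass: float
    _cdf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._cdf = np.cumsum(self.pmf)

    @property
    def a0(self) -> int:
        return self.params.a0

    @property
    def a_max(self) -> int:
        return int(self.support[-1])

    @property
    def p0(self) -> float:
        """Probability of the minimum activity, ``(1 + beta)^{-alpha_r}``."""
        return float(self.pmf[0])

    @property
    def mean(self) -> float:
        return float(self.support @ self.pmf)

    @property
    def variance(self) -> float:
        m = self.mean
        return float(((self.support - m) ** 2) @ self.pmf)

    @property
    def dispersion(self) -> float:
        """Dispersion index ``d = (var - t_r) / (var + t_r)`` with ``t_r = mean - a0``."""
        t_r = self.mean - self.a0
        var = self.variance
        if var + t_r == 0:
            return 0.0
        return (var - t_r) / (var + t_r)

    def cdf(self, a: np.ndarray) -> np.ndarray:
        """Model CDF ``P[a' <= a]`` at integer activities ``a``."""
        a = np.asarray(a)
        idx = np.clip(a - self.a0, -1, len(self.support) - 1).astype(int)
        out = np.where(idx >= 0, self._cdf[np.clip(idx, 0, None)], 0.0)
        return out

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        """Sample activities by inverse CDF on the truncated support."""
        u = rng.random(size)
        idx = np.searchsorted(self._cdf, u * self._cdf[-1], side="left")
        idx = np.clip(idx, 0, len(self.support) - 1)
        return self.support[idx]


def activity_pmf(
    params: ModelParams,
    t: float | None = None,
    truncation_tol: float = 1e-12,
    a_max: int | None = None,
    max_support: int = 50_000_000,
) -> ActivityDistribution:
    """Closed-form activity distribution, truncated to tail mass below tolerance.

    Degenerate cases (``t = a0``, i.e. ``beta = 0``) return an explicit point
    mass at ``a0``.  An explicit ``a_max`` forces truncation at that activity
    regardless of the tail mass (useful when only CDF values up to ``a_max``
    are needed; the distribution then must not be sampled from).
    """
    p = params if t is None else params.with_t(t)
    if p.beta < 0:
        raise ValueError("beta must be non-negative")
    a0 = p.a0
    beta = p.beta
    if beta < _BETA_DEGENERATE or p.t_r == 0:
        return ActivityDistribution(
            params=p,
            support=np.array([a0]),
            pmf=np.array([1.0]),
            truncation_tol=truncation_tol,
            leaked_mass=0.0,
        )
    if a_max is not None:
        cut = n = max(int(a_max) - a0, 0)
        pmf = np.exp(_logpmf_relative(np.arange(n + 1), p.alpha_r, beta))
    else:
        sigma = np.sqrt(p.t_r * (1.0 + beta))
        n = min(int(p.t_r + 20 * sigma) + 64, max_support)
        while True:
            a_r = np.arange(n + 1)
            pmf = np.exp(_logpmf_relative(a_r, p.alpha_r, beta))
            cum = np.cumsum(pmf)
            cut = int(np.searchsorted(cum, 1.0 - truncation_tol, side="left"))
            if cut < n or n >= max_support:
                break
            n = min(n * 4, max_support)
    cut = min(cut, n)
    pmf = pmf[: cut + 1]
    return ActivityDistribution(
        params=p,
        support=a0 + np.arange(cut + 1),
        pmf=pmf,
        truncation_tol=truncation_tol,
        leaked_mass=float(1.0 - pmf.sum()),
    )


def model_moments(params: ModelParams, t: float | None = None) -> tuple[float, float, float]:
    """Mean ``t``, variance ``t_r (1 + beta)`` and dispersion ``beta / (2 + beta)``."""
    p = params if t is None else params.with_t(t)
    beta = p.beta
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return float(p.t), float(p.t_r * (1.0 + beta)), float(beta / (2.0 + beta))


def dispersion_from_beta(beta: float) -> float:
    """Dispersion index ``d = beta / (2 + beta)`` of the closed-form model."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return beta / (2.0 + beta)


def beta_from_dispersion(d: float) -> float:
    """Invert ``d = beta / (2 + beta)``: ``beta = 2 d / (1 - d)``."""
    if not 0 <= d < 1:
        raise ValueError("dispersion must lie in [0, 1)")
    return 2.0 * d / (1.0 - d)


def classify_regime(beta: float, tol: float = CROSSOVER_TOL) -> str:
    """Label ``beta``: "heterogeneous" (>1), "homogeneous" (<1) or "crossover"."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if abs(beta - 1.0) <= tol:
        return "crossover"
    return "heterogeneous" if beta > 1.0 else "homogeneous"


def pgf(z: float, t: float, params: ModelParams) -> float:
    """Probability generating function ``g(z,t) = z^{a0} [z + (1-z)(1+beta)]^{-alpha_r}``."""
    if not 0.0 <= z <= 1.0:
        raise ValueError("pgf defined on z in [0, 1]")
    p = params.with_t(t)
    base = z + (1.0 - z) * (1.0 + p.beta)
    return z**p.a0 * base ** (-p.alpha_r)


@dataclass
class MasterEquationSolution:
    """Numerically integrated pmf trajectory ``p_a(t)`` on a truncated support."""

    params: ModelParams
    t_grid: np.ndarray
    support: np.ndarray
    trajectory: np.ndarray  # shape (len(t_grid), len(support))
    tol: float

    @property
    def leaked_mass(self) -> np.ndarray:
        return 1.0 - self.trajectory.sum(axis=1)

    def check_mass(self) -> None:
        leak = np.abs(self.leaked_mass).max()
        if leak > self.tol:
            raise RuntimeError(
                f"truncation-mass violation: leaked {leak:.3e} > tolerance {self.tol:.3e}; "
                "enlarge the support"
            )

    def final_pmf(self) -> np.ndarray:
        return self.trajectory[-1]


def integrate_master_equation(
    params: ModelParams,
    t_grid,
    a_max: int | None = None,
    tol: float = 1e-8,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> MasterEquationSolution:
    """Integrate the activity master equation from the point mass at ``a0``.

    Serves as an independent numerical oracle for :func:`activity_pmf`: the
    ODE system is integrated directly in ``t`` on a truncated support, and
    the leaked probability mass is reported (``check_mass`` raises if it
    exceeds ``tol``).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != params.a0:
        raise ValueError("t_grid must start at a0 (initial condition is a point mass there)")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    a0, alpha = params.a0, params.alpha
    if a_max is None:
        # size the support from the closed form at the final time
        dist = activity_pmf(params, t=float(t_grid[-1]), truncation_tol=min(tol, 1e-12) * 1e-2)
        a_max = dist.a_max + 10
    support = np.arange(a0, a_max + 1)
    coeff = support + alpha  # (a + alpha), >= alpha_r > 0

    def rhs(t: float, p: np.ndarray) -> np.ndarray:
        flux = coeff * p  # flux out of each state
        dp = -flux
        dp[1:] += flux[:-1]
        return dp / (t + alpha)

    p_init = np.zeros(len(support))
    p_init[0] = 1.0
    if len(t_grid) == 1:
        traj = p_init[None, :]
    else:
        sol = solve_ivp(
            rhs,
            (t_grid[0], t_grid[-1]),
            p_init,
            t_eval=t_grid,
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"master-equation integration failed: {sol.message}")
        traj = sol.y.T
    return MasterEquationSolution(
        params=params, t_grid=t_grid, support=support, trajectory=traj, tol=tol
    )
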