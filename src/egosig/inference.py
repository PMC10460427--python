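"""Per-ego maximum-likelihood estimation and parametric-bootstrap goodness of fit.

With ``k``, ``a0`` and the mean activity ``t`` fixed by an observed sample
``{a_i}``, the closed-form activity distribution has a single free parameter
``alpha_r`` (equivalently ``beta = t_r / alpha_r``).  The profile score is

    d ln L / d alpha  propto  F_alpha - ln(1 + beta),

where ``F_alpha = mean_i [psi(a_r,i + alpha_r) - psi(alpha_r)]`` averages the
digamma function over observed relative activities.  The maximizer solves
``alpha_r = t_r / (exp(F_alpha) - 1)``, i.e. ``beta_hat = exp(F_alpha) - 1``,
found here by bracketed root search on the score in log-``alpha_r``.

The fitted model is then tested by parametric bootstrap: simulate ``n_sim``
samples of size ``k`` from the fitted pmf, re-fit each, recompute the test
statistic, and report the fraction at least as large as the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma

from .distribution import ActivityDistribution, activity_pmf, _logpmf_relative
from .params import ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "ActivitySample",
    "FitResult",
    "digamma_average",
    "score",
    "log_likelihood",
    "solve_mle",
    "ks_statistic",
    "cvm_family_statistics",
    "bootstrap_gof",
    "fit_ego",
    "BRACKET",
]

#: default root-search bracket for alpha_r
BRACKET = (1e-6, 1e6)

STATUS_CONVERGED = "converged"
STATUS_CONSTANT = "degenerate-constant"
STATUS_UNDERDISPERSED = "degenerate-underdispersed"
STATUS_SKIPPED = "skipped"


@dataclass(frozen=True)
class ActivitySample:
    """An ego's alter activities ``{a_i}`` with derived summaries.

    ``a0`` defaults to the sample minimum (how the data pipeline determines
    it) but may be forced lower, e.g. when re-fitting bootstrap replicates
    against the original minimum.
    """

    activities: np.ndarray
    a0: int = None  # type: ignore[assignment]
    # unique relative values and their multiplicities (cached for fast fits)
    _unique: np.ndarray = field(init=False, repr=False, compare=False)
    _counts: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        acts = np.asarray(self.activities, dtype=np.int64)
        if acts.size < 1:
            raise ValueError("empty activity sample")
        object.__setattr__(self, "activities", acts)
        a0 = int(acts.min()) if self.a0 is None else int(self.a0)
        if a0 > acts.min():
            raise ValueError(f"a0={a0} exceeds the sample minimum {acts.min()}")
        object.__setattr__(self, "a0", a0)
        u, c = np.unique(acts - a0, return_counts=True)
        object.__setattr__(self, "_unique", u)
        object.__setattr__(self, "_counts", c)

    @property
    def k(self) -> int:
        return int(self.activities.size)

    @property
    def a_m(self) -> int:
        return int(self.activities.max())

    @property
    def tau(self) -> int:
        return int(self.activities.sum())

    @property
    def t(self) -> float:
        return self.tau / self.k

    @property
    def t_r(self) -> float:
        return self.t - self.a0

    @property
    def variance(self) -> float:
        """Population (divide-by-k) variance of the activities."""
        return float(np.var(self.activities))

    def empirical_cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer grid ``[a0, a_m]`` and empirical CDF on it."""
        grid = np.arange(self.a0, self.a_m + 1)
        counts = np.zeros(grid.size, dtype=np.int64)
        counts[self._unique] = self._counts
        return grid, np.cumsum(counts) / self.k


@dataclass
class FitResult:
    """Per-ego estimation and goodness-of-fit record."""

    ego: str | None
    k: int
    a0: int
    a_m: int
    tau: int
    t: float
    alpha_r: float = np.nan
    beta: float = np.nan
    F_alpha: float = np.nan
    log_likelihood: float = np.nan
    dispersion: float = np.nan
    D: float = np.nan
    cvm_stats: dict = field(default_factory=dict)
    p_value: float = np.nan
    accepted: bool | None = None
    n_sim: int = 0
    n_failed: int = 0
    status: str = STATUS_CONVERGED
    reason: str = ""

    @property
    def regime(self) -> str:
        from .distribution import classify_regime

        return classify_regime(self.beta) if np.isfinite(self.beta) else "undefined"


def digamma_average(sample: ActivitySample, alpha_r) -> float | np.ndarray:
    """``F_alpha = (1/k) sum_i [psi(a_r,i + alpha_r) - psi(alpha_r)]``.

    Vectorized over ``alpha_r``; uses unique relative activities with
    multiplicities, so cost scales with the number of distinct values.
    """
    alpha_arr = np.atleast_1d(np.asarray(alpha_r, dtype=float))
    if np.any(alpha_arr <= 0):
        raise ValueError("alpha_r must be positive")
    u = sample._unique[:, None]
    F = (sample._counts @ digamma(u + alpha_arr[None, :])) / sample.k - digamma(alpha_arr)
    return float(F[0]) if np.ndim(alpha_r) == 0 else F


def score(sample: ActivitySample, alpha_r) -> float | np.ndarray:
    """Profile score ``F_alpha - ln(1 + t_r / alpha_r)`` (zero at the MLE)."""
    alpha_r = np.asarray(alpha_r, dtype=float)
    return digamma_average(sample, alpha_r) - np.log1p(sample.t_r / alpha_r)


def log_likelihood(sample: ActivitySample, alpha_r: float) -> float:
    """Exact log-likelihood of the sample under the closed-form pmf at ``alpha_r``
    (with ``t`` profiled out at the sample mean)."""
    t_r = sample.t_r
    if t_r == 0:
        return 0.0
    beta = t_r / alpha_r
    lp = _logpmf_relative(sample._unique.astype(float), alpha_r, beta)
    return float(sample._counts @ lp)


def solve_mle(
    sample: ActivitySample,
    bracket: tuple[float, float] = BRACKET,
    rtol: float = 1e-10,
    n_grid: int = 49,
    ego: str | None = None,
) -> FitResult:
    """Maximum-likelihood estimate of ``alpha_r`` (hence ``beta``) for one ego.

    The score changes sign exactly once on the bracket for over-dispersed
    samples; a coarse log-spaced grid locates the sign change and `brentq`
    polishes it.  Degenerate cases:

    * constant sample (``t_r = 0``): ``beta_hat = 0`` (Poisson/point limit),
      status "degenerate-constant";
    * under-dispersed sample (variance < ``t_r``): the score has no interior
      zero; ``alpha_r`` is clamped at the bracket cap (``beta_hat`` at the
      implied minimum), status "degenerate-underdispersed".
    """
    res = FitResult(
        ego=ego, k=sample.k, a0=sample.a0, a_m=sample.a_m, tau=sample.tau, t=sample.t
    )
    t_r = sample.t_r
    if t_r == 0:
        res.alpha_r = np.inf
        res.beta = 0.0
        res.F_alpha = 0.0
        res.log_likelihood = 0.0
        res.status = STATUS_CONSTANT
        return res
    lo, hi = bracket
    x = np.linspace(np.log(lo), np.log(hi), n_grid)
    s = score(sample, np.exp(x))
    neg = np.nonzero(s <= 0)[0]
    if neg.size == 0:
        # no interior zero: under-dispersed, clamp at the cap
        res.alpha_r = hi
        res.beta = t_r / hi
        res.F_alpha = digamma_average(sample, hi)
        res.log_likelihood = log_likelihood(sample, hi)
        res.status = STATUS_UNDERDISPERSED
        return res
    i = int(neg[0])
    if i == 0:
        root_x = x[0]  # extreme over-dispersion beyond the bracket floor
    else:
        root_x = brentq(
            lambda y: score(sample, np.exp(y)), x[i - 1], x[i], xtol=1e-13, rtol=8.9e-16
        )
    alpha_hat = float(np.exp(root_x))
    # enforce the implicit-equation form beta = exp(F) - 1 at the optimum
    res.F_alpha = digamma_average(sample, alpha_hat)
    res.alpha_r = alpha_hat
    res.beta = t_r / alpha_hat
    res.log_likelihood = log_likelihood(sample, alpha_hat)
    res.status = STATUS_CONVERGED
    return res


def _fitted_distribution(
    sample: ActivitySample,
    alpha_r: float,
    truncation_tol: float = 1e-12,
    a_max: int | None = None,
) -> ActivityDistribution:
    """Closed-form distribution at the fitted ``alpha_r`` with ``t`` from the sample."""
    if np.isinf(alpha_r) or sample.t_r == 0:
        params = ModelParams.from_reduced(k=sample.k, a0=sample.a0, alpha_r=1.0, t_r=0.0)
    else:
        params = ModelParams.from_reduced(
            k=sample.k, a0=sample.a0, alpha_r=alpha_r, t_r=sample.t_r
        )
    return activity_pmf(params, truncation_tol=truncation_tol, a_max=a_max)


def ks_statistic(sample: ActivitySample, fitted: ActivityDistribution) -> float:
    """Kolmogorov-Smirnov statistic ``D = max_{a0<=a<=a_m} |ecdf(a) - cdf(a)|``."""
    if fitted.a0 != sample.a0:
        raise ValueError(f"support mismatch: sample a0={sample.a0}, fitted a0={fitted.a0}")
    grid, ecdf = sample.empirical_cdf()
    return float(np.abs(ecdf - fitted.cdf(grid)).max())


def cvm_family_statistics(sample: ActivitySample, fitted: ActivityDistribution) -> dict:
    """Discrete Cramer-von Mises family statistics ``W2``, ``A2`` (Anderson-
    Darling) and ``U2`` (Watson).

    Computed from CDF differences on the integer window ``[a0, a_m]`` with
    model-pmf weights and sample-size factor ``k``; the Anderson-Darling sum
    drops cells with ``H(1-H) = 0``, and the Watson centering uses
    window-normalized weights.
    """
    if fitted.a0 != sample.a0:
        raise ValueError(f"support mismatch: sample a0={sample.a0}, fitted a0={fitted.a0}")
    grid, ecdf = sample.empirical_cdf()
    H = fitted.cdf(grid)
    dP = ecdf - H
    w = np.zeros(grid.size)
    n_avail = min(grid.size, len(fitted.pmf))
    w[:n_avail] = fitted.pmf[:n_avail]
    k = sample.k
    w2 = k * float((dP**2) @ w)
    hh = H * (1.0 - H)
    ok = hh > 0
    a2 = k * float(((dP[ok] ** 2) * w[ok] / hh[ok]).sum())
    wsum = w.sum()
    zbar = float((dP @ w) / wsum) if wsum > 0 else 0.0
    u2 = k * float(((dP - zbar) ** 2) @ w)
    return {"W2": w2, "A2": a2, "U2": u2}


def _statistic(sample: ActivitySample, fitted: ActivityDistribution, which: str) -> float:
    if which == "ks":
        return ks_statistic(sample, fitted)
    stats = cvm_family_statistics(sample, fitted)
    try:
        return stats[{"w2": "W2", "a2": "A2", "u2": "U2"}[which.lower()]]
    except KeyError:
        raise ValueError(f"unknown statistic {which!r}; use ks, w2, a2 or u2") from None


@dataclass
class BootstrapResult:
    observed: float
    p_value: float
    accepted: bool
    n_sim: int
    n_failed: int
    statistic: str


def bootstrap_gof(
    sample: ActivitySample,
    fit: FitResult | None = None,
    n_sim: int = 2500,
    statistic: str = "ks",
    rng: np.random.Generator | None = None,
    threshold: float = 0.1,
    refit_a0: str = "replicate",
    truncation_tol: float = 1e-12,
) -> BootstrapResult:
    """Parametric-bootstrap goodness of fit for the fitted activity model.

    Draws ``n_sim`` samples of size ``k`` from the fitted pmf, re-fits each
    replicate (against its own minimum activity by default, or the data's
    ``a0`` with ``refit_a0="data"``), recomputes the chosen statistic, and
    returns the fraction of simulated statistics >= the observed one (ties
    count as extreme).  Acceptance means ``p > threshold``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if fit is None:
        fit = solve_mle(sample)
    fitted = _fitted_distribution(sample, fit.alpha_r, truncation_tol)
    observed = _statistic(sample, fitted, statistic)
    draws = fitted.rvs((n_sim, sample.k), rng)
    sims = np.empty(n_sim)
    n_failed = 0
    for j in range(n_sim):
        row = draws[j]
        try:
            a0_rep = None if refit_a0 == "replicate" else sample.a0
            rep = ActivitySample(row, a0=a0_rep)
            rep_fit = solve_mle(rep)
            # only CDF values up to the replicate's maximum are needed
            rep_dist = _fitted_distribution(rep, rep_fit.alpha_r, truncation_tol, a_max=rep.a_m)
            sims[j] = _statistic(rep, rep_dist, statistic)
        except Exception as exc:  # noqa: BLE001 - record, exclude, continue
            sims[j] = np.nan
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", j, exc)
    if n_failed:
        logger.info("bootstrap: excluded %d/%d failed replicates", n_failed, n_sim)
    valid = sims[np.isfinite(sims)]
    if valid.size == 0:
        raise RuntimeError("all bootstrap replicates failed")
    p = float(np.count_nonzero(valid >= observed) / valid.size)
    return BootstrapResult(
        observed=observed,
        p_value=p,
        accepted=p > threshold,
        n_sim=int(valid.size),
        n_failed=n_failed,
        statistic=statistic,
    )


def fit_ego(
    aggregate,
    config=None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Full per-ego pipeline: filters, MLE, GoF statistics, bootstrap p-value.

    ``aggregate`` is an :class:`~egosig.empirics.EgoAggregate` (or anything
    with ``to_sample()``, ``n_events`` and ``ego``).  Egos failing the
    configured filters (default: more than 10 events, ``k >= 2``) get an
    explicit "skipped" record.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    sample = aggregate.to_sample() if hasattr(aggregate, "to_sample") else aggregate
    ego = getattr(aggregate, "ego", None)
    n_events = getattr(aggregate, "n_events", sample.tau)
    if n_events <= cfg.min_events or sample.k < cfg.min_k:
        res = FitResult(
            ego=ego, k=sample.k, a0=sample.a0, a_m=sample.a_m, tau=sample.tau, t=sample.t
        )
        res.status = STATUS_SKIPPED
        res.reason = (
            f"events={n_events} (need > {cfg.min_events}), k={sample.k} (need >= {cfg.min_k})"
        )
        return res
    res = solve_mle(sample, ego=ego)
    if sample.k >= 2:
        mean_r = sample.t_r
        var = sample.variance
        if var + mean_r > 0:
            res.dispersion = (var - mean_r) / (var + mean_r)
    fitted = _fitted_distribution(sample, res.alpha_r, cfg.truncation_tol)
    res.D = ks_statistic(sample, fitted)
    res.cvm_stats = cvm_family_statistics(sample, fitted)
    if cfg.n_sim > 0:
        boot = bootstrap_gof(
            sample,
            fit=res,
            n_sim=cfg.n_sim,
            statistic=cfg.statistic,
            rng=rng,
            threshold=cfg.p_threshold,
            refit_a0=cfg.bootstrap_a0,
            truncation_tol=cfg.truncation_tol,
        )
        res.p_value = boot.p_value
        res.accepted = boot.accepted
        res.n_sim = boot.n_sim
        res.n_failed = boot.n_failed
        if cfg.statistic != "ks":
            res.D = ks_statistic(sample, fitted)  # D always reported on the KS scale
    return res
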