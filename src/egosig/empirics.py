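"""Data-side statistics on communication event logs.

Per-ego aggregation, the dispersion index of alter activities, pooled CCDFs
with dispersion-quartile or regime grouping, the empirical connection kernel
``pi_a`` against its random-choice baseline ``<1/k>``, and the two-interval
persistence analysis (alter turnover ``J`` vs preferentiality change
``dbeta / beta``).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import ActivitySample, FitResult, solve_mle
from .io import EventLog

logger = logging.getLogger(__name__)

__all__ = [
    "EgoAggregate",
    "KernelEstimate",
    "PersistenceResult",
    "DegenerateEgoError",
    "aggregate_events",
    "dispersion_index",
    "activity_ccdf",
    "dispersion_quartile_groups",
    "estimate_connection_kernel",
    "split_equal_events",
    "jaccard_turnover",
    "persistence_analysis",
]


class DegenerateEgoError(ValueError):
    """An ego-level statistic is undefined for this input (explicit, with reason)."""


@dataclass
class EgoAggregate:
    """One ego's alter -> activity mapping with derived summaries."""

    ego: str
    activities: dict  # alter id -> activity count
    n_events: int

    @property
    def k(self) -> int:
        return len(self.activities)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(sorted(self.activities.values()), dtype=np.int64)

    @property
    def a0(self) -> int:
        return int(min(self.activities.values()))

    @property
    def a_m(self) -> int:
        return int(max(self.activities.values()))

    @property
    def tau(self) -> int:
        return int(sum(self.activities.values()))

    @property
    def t(self) -> float:
        return self.tau / self.k

    @property
    def t_r(self) -> float:
        return self.t - self.a0

    def to_sample(self) -> ActivitySample:
        return ActivitySample(self.values)


def aggregate_events(log: EventLog, directed: bool = False) -> dict[str, EgoAggregate]:
    """Count events per (ego, alter) tie.

    By default any event on the edge counts toward the alter's activity; with
    ``directed=True`` and a ``direction`` column, only rows marked ``out``
    (ego-initiated) count.  Empty logs give an empty collection.
    """
    df = log.sorted().frame
    if directed:
        if "direction" not in df.columns:
            raise ValueError("directed aggregation requested but no 'direction' column present")
        df = df[df["direction"] == "out"]
    out: dict[str, EgoAggregate] = {}
    if len(df) == 0:
        return out
    grouped = df.groupby("ego", sort=True)
    for ego, sub in grouped:
        counts = sub.groupby("alter").size().to_dict()
        out[str(ego)] = EgoAggregate(ego=str(ego), activities=counts, n_events=len(sub))
    return out


def dispersion_index(aggregate) -> float:
    """Dispersion index ``d = (var - t_r) / (var + t_r)`` of an ego's activities.

    ``var`` is the population (divide-by-``k``) variance and ``t_r`` the mean
    activity relative to the minimum.  Undefined (raises
    :class:`DegenerateEgoError`) for ``k < 2`` or when ``var + t_r = 0``.
    """
    values = aggregate.values if hasattr(aggregate, "values") else np.asarray(aggregate)
    values = np.asarray(values, dtype=float)
    k = values.size
    if k < 2:
        raise DegenerateEgoError(f"dispersion undefined for k={k} < 2")
    t_r = values.mean() - values.min()
    var = values.var()
    if var + t_r == 0:
        raise DegenerateEgoError("dispersion undefined: zero variance and zero relative mean")
    return float((var - t_r) / (var + t_r))


def _quartile_label(q: int) -> str:
    return f"d-quartile-{q + 1}"


def dispersion_quartile_groups(
    aggregates: dict[str, EgoAggregate],
    min_k: int = 10,
    min_events: int = 10,
) -> dict[str, set]:
    """Partition filtered egos (``k >= min_k``, events > ``min_events``) into
    quartile ranges of the dispersion distribution ``p_d``."""
    ids, ds = [], []
    for ego, agg in aggregates.items():
        if agg.k < min_k or agg.n_events <= min_events:
            continue
        try:
            ds.append(dispersion_index(agg))
        except DegenerateEgoError:
            continue
        ids.append(ego)
    groups: dict[str, set] = {_quartile_label(q): set() for q in range(4)}
    if not ids:
        return groups
    ds_arr = np.asarray(ds)
    edges = np.quantile(ds_arr, [0.25, 0.5, 0.75])
    which = np.searchsorted(edges, ds_arr, side="right")
    for ego, q in zip(ids, which):
        groups[_quartile_label(int(q))].add(ego)
    return groups


def activity_ccdf(
    aggregates: dict[str, EgoAggregate],
    grouping: str = "none",
    fits: dict[str, FitResult] | None = None,
    min_k: int = 10,
    min_events: int = 10,
) -> dict[str, pd.DataFrame]:
    """Pooled CCDF ``P[a' >= a]`` of alter activities per ego group.

    ``grouping``: "none" (all egos pooled), "dispersion-quartiles"
    (quartile ranges of ``p_d`` over egos with ``k >= min_k``), or "regime"
    (heterogeneous ``beta > 1`` vs homogeneous ``beta < 1``, needing
    ``fits``).  Each table carries the group's ego count; empty groups give
    empty tables and a log entry.
    """
    if grouping == "none":
        groups = {"all": set(aggregates)}
    elif grouping == "dispersion-quartiles":
        groups = dispersion_quartile_groups(aggregates, min_k=min_k, min_events=min_events)
    elif grouping == "regime":
        if fits is None:
            raise ValueError("regime grouping needs per-ego fits")
        groups = {"heterogeneous": set(), "homogeneous": set()}
        for ego, f in fits.items():
            if ego not in aggregates or not np.isfinite(f.beta):
                continue
            if f.beta > 1:
                groups["heterogeneous"].add(ego)
            elif f.beta < 1:
                groups["homogeneous"].add(ego)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    out = {}
    for label, egos in groups.items():
        pooled = np.concatenate(
            [aggregates[e].values for e in sorted(egos)] or [np.empty(0, dtype=np.int64)]
        )
        if pooled.size == 0:
            logger.info("ccdf group %r is empty", label)
            out[label] = pd.DataFrame(columns=["a", "ccdf", "n_alters", "n_egos"])
            continue
        grid = np.unique(pooled)
        # P[a' >= a]: fraction of alters with activity >= a
        ge = pooled.size - np.searchsorted(np.sort(pooled), grid, side="left")
        out[label] = pd.DataFrame(
            {"a": grid, "ccdf": ge / pooled.size, "n_alters": pooled.size, "n_egos": len(egos)}
        )
    return out


# ---------------------------------------------------------------------------
# connection kernel
# ---------------------------------------------------------------------------


@dataclass
class KernelEstimate:
    """Binned estimate of the connection kernel ``pi_a`` with its baseline.

    ``table`` columns: ``bin`` (raw activity, or normalized-bin lower edge),
    ``pi`` (successes / opportunities), ``opportunities``, ``successes``,
    ``n_egos`` and ``relative`` (``pi - <1/k>``).  Bins backed by fewer than
    the minimum number of egos are not emitted.
    """

    table: pd.DataFrame
    baseline: float
    normalized: bool
    min_egos: int
    n_egos_used: int


def _ego_kernel_counts(
    seq: list,
    alters: list,
    initial_activity: int,
    skip: int,
):
    """Per-ego opportunity/success counts by pre-event activity level.

    Opportunities at level ``a`` accumulate lazily: each level's running
    integral is settled whenever its alter count changes (O(1) per event).
    The first ``skip`` events update activities without being scored.
    """
    n_at: dict[int, int] = defaultdict(int)
    n_at[initial_activity] = len(alters)
    acts = {alter: initial_activity for alter in alters}
    integral: dict[int, int] = defaultdict(int)
    succ: dict[int, int] = defaultdict(int)
    last: dict[int, int] = defaultdict(int)
    n_scored = 0
    for i, alter in enumerate(seq):
        a = acts[alter]
        if i >= skip:
            step = i - skip
            succ[a] += 1
            for lvl in (a, a + 1):
                integral[lvl] += n_at[lvl] * (step + 1 - last[lvl])
                last[lvl] = step + 1
            n_scored += 1
        acts[alter] = a + 1
        n_at[a] -= 1
        n_at[a + 1] += 1
    for lvl, cnt in n_at.items():
        if cnt > 0:
            integral[lvl] += cnt * (n_scored - last[lvl])
    return integral, succ, n_scored


def estimate_connection_kernel(
    log: EventLog,
    normalized: bool = False,
    n_bins: int = 20,
    min_egos: int = 30,
    min_k: int = 2,
    initial_activity: int = 0,
    baseline_events: int | str = 0,
    egos: set | None = None,
) -> KernelEstimate:
    """Empirical connection kernel ``pi_a`` pooled over egos.

    For every scored event, the risk set is each of the ego's alters (every
    alter the ego contacts over the whole window) at its pre-event activity;
    ``pi_a`` is pooled successes over pooled opportunities at activity ``a``,
    and the random-choice baseline ``<1/k>`` is the opportunity-weighted mean
    of ``1/k`` over the same events.

    ``initial_activity`` sets the activity alters hold before their first
    recorded event.  ``baseline_events="auto"`` skips each ego's leading
    ``k * a0`` records (the simulator's baseline block); an integer skips
    that many records per ego.  ``normalized`` bins the activity axis as
    ``a / a_m`` with ``n_bins`` fixed-width bins for cross-ego pooling.
    Egos with ``k < min_k`` are excluded (no alter choice exists); bins
    backed by fewer than ``min_egos`` egos are dropped.
    """
    df = log.sorted().frame
    opp: dict = defaultdict(float)
    suc: dict = defaultdict(float)
    ego_sets: dict = defaultdict(set)
    total_opportunities = 0.0
    weighted_invk = 0.0
    n_used = 0
    for ego, sub in df.groupby("ego", sort=True):
        if egos is not None and ego not in egos:
            continue
        alters = sub["alter"].unique().tolist()
        k = len(alters)
        if k < min_k:
            continue
        seq = sub["alter"].tolist()
        if baseline_events == "auto":
            counts = sub.groupby("alter").size()
            skip = k * int(counts.min())
        else:
            skip = int(baseline_events)
        if len(seq) <= skip:
            continue
        integral, succ, n_scored = _ego_kernel_counts(seq, alters, initial_activity, skip)
        if n_scored == 0:
            continue
        n_used += 1
        if normalized:
            counts = sub.groupby("alter").size()
            a_m = float(initial_activity + counts.max())
            def key(a):  # noqa: B023 - a_m rebound per ego on purpose
                return min(int(n_bins * a / a_m), n_bins - 1)
        else:
            def key(a):
                return int(a)
        for a, n in integral.items():
            if n <= 0:
                continue
            opp[key(a)] += n
            ego_sets[key(a)].add(ego)
            total_opportunities += n
            weighted_invk += n / k
        for a, n in succ.items():
            suc[key(a)] += n
    if total_opportunities == 0:
        logger.warning("kernel estimation: no usable egos")
        empty = pd.DataFrame(
            columns=["bin", "pi", "opportunities", "successes", "n_egos", "relative"]
        )
        return KernelEstimate(empty, np.nan, normalized, min_egos, 0)
    baseline = weighted_invk / total_opportunities
    rows = []
    for b in sorted(opp):
        n_egos_bin = len(ego_sets[b])
        if n_egos_bin < min_egos:
            continue
        pi = suc.get(b, 0.0) / opp[b]
        rows.append(
            {
                "bin": b if not normalized else b / n_bins,
                "pi": pi,
                "opportunities": opp[b],
                "successes": suc.get(b, 0.0),
                "n_egos": n_egos_bin,
                "relative": pi - baseline,
            }
        )
    return KernelEstimate(pd.DataFrame(rows), float(baseline), normalized, min_egos, n_used)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def split_equal_events(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one ego's ordered events into consecutive halves ``(I1, I2)``.

    The first ``floor(n/2)`` events form ``I1``; for odd ``n`` the extra
    event goes to ``I2``.  Requires at least two events.
    """
    n = len(events)
    if n < 2:
        raise ValueError(f"cannot split {n} event(s) into two intervals")
    half = n // 2
    return events.iloc[:half], events.iloc[half:]


def jaccard_turnover(alters_i1: set, alters_i2: set) -> float:
    """Jaccard similarity ``|I1 ∩ I2| / |I1 ∪ I2|`` between interval alter sets."""
    union = set(alters_i1) | set(alters_i2)
    if not union:
        raise DegenerateEgoError("Jaccard undefined for two empty alter sets")
    return len(set(alters_i1) & set(alters_i2)) / len(union)


@dataclass
class PersistenceResult:
    """Whole-period vs two-interval preferentiality comparison for one ego."""

    ego: str
    k: int
    beta: float
    beta_i1: float
    beta_i2: float
    jaccard: float
    status: str = "ok"

    @property
    def dbeta(self) -> float:
        return self.beta_i2 - self.beta_i1

    @property
    def rel_dbeta(self) -> float:
        """``dbeta`` relative to the whole-period estimate."""
        return self.dbeta / self.beta if self.beta else np.nan


def _sample_of(events: pd.DataFrame) -> ActivitySample:
    counts = events.groupby("alter").size().to_numpy()
    return ActivitySample(counts)


def persistence_analysis(
    log: EventLog,
    min_events: int = 10,
    min_k: int = 2,
) -> tuple[list[PersistenceResult], pd.DataFrame]:
    """Fit ``beta`` on each ego's whole period and on its two equal-event halves.

    Egos must pass the filters (events > ``min_events`` and ``k >= min_k``)
    on the whole period and on both intervals; failures are recorded with a
    status instead of being silently dropped.  Returns the per-ego records
    plus a tidy frame (one row per ego) for the joint ``(J, dbeta/beta)``
    histogramming.
    """
    results: list[PersistenceResult] = []
    df = log.sorted().frame
    for ego, sub in df.groupby("ego", sort=True):
        ego = str(ego)
        if len(sub) < 2:
            results.append(PersistenceResult(ego, 0, np.nan, np.nan, np.nan, np.nan, "too-few-events"))
            continue
        i1, i2 = split_equal_events(sub)
        alters1, alters2 = set(i1["alter"]), set(i2["alter"])
        J = jaccard_turnover(alters1, alters2)
        samples = {"whole": _sample_of(sub), "I1": _sample_of(i1), "I2": _sample_of(i2)}
        events = {"whole": len(sub), "I1": len(i1), "I2": len(i2)}
        bad = [
            name
            for name, s in samples.items()
            if events[name] <= min_events or s.k < min_k
        ]
        if bad:
            results.append(
                PersistenceResult(
                    ego, samples["whole"].k, np.nan, np.nan, np.nan, J,
                    "filtered:" + ",".join(bad),
                )
            )
            continue
        fits = {name: solve_mle(s) for name, s in samples.items()}
        results.append(
            PersistenceResult(
                ego=ego,
                k=samples["whole"].k,
                beta=fits["whole"].beta,
                beta_i1=fits["I1"].beta,
                beta_i2=fits["I2"].beta,
                jaccard=J,
            )
        )
    frame = pd.DataFrame(
        {
            "ego": [r.ego for r in results],
            "k": [r.k for r in results],
            "beta": [r.beta for r in results],
            "beta_i1": [r.beta_i1 for r in results],
            "beta_i2": [r.beta_i2 for r in results],
            "dbeta": [r.dbeta for r in results],
            "rel_dbeta": [r.rel_dbeta for r in results],
            "jaccard": [r.jaccard for r in results],
            "status": [r.status for r in results],
        }
    )
    return results, frame
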