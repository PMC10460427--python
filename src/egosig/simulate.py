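"""Exact simulation of the urn dynamics and synthetic event-log generation.

The event-level process is a Polya urn: each of the ``k`` alters starts with
weight ``alpha_r`` and the weight of the receiving alter grows by one per
event.  Two exact samplers are provided:

* ``method="urn"`` draws events sequentially with the literal kernel
  ``pi propto a_r + alpha_r`` (cumulative-weight inversion);
* ``method="dirichlet"`` uses exchangeability: the Polya sequence is, in
  law, an iid categorical sequence with Dirichlet(alpha_r, ..., alpha_r)
  mixing weights, so a single Dirichlet draw followed by iid alter choices
  reproduces the exact sequence law at O(tau_r) cost independent of k per
  event.

The terminal activity composition is Dirichlet-multinomial, which
``simulate_final_activities`` samples directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .io import EventLog
from .params import ModelParams

__all__ = [
    "SimulatedEgo",
    "simulate_ego_events",
    "simulate_final_activities",
    "simulate_population",
    "LogUniformParamSampler",
]


@dataclass
class SimulatedEgo:
    """One simulated ego: full event sequence plus terminal activities."""

    params: ModelParams
    tau_r: int
    event_sequence: np.ndarray  # alter indices, length tau_r
    final_activities: np.ndarray  # length k, >= a0, sums to k*a0 + tau_r

    def __post_init__(self) -> None:
        assert len(self.event_sequence) == self.tau_r
        assert self.final_activities.sum() == self.params.k * self.params.a0 + self.tau_r


def _urn_sequence(k: int, alpha_r: float, tau_r: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.full(k, alpha_r)
    seq = np.empty(tau_r, dtype=np.int64)
    total = k * alpha_r
    for step in range(tau_r):
        u = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(weights), u, side="right"))
        idx = min(idx, k - 1)
        seq[step] = idx
        weights[idx] += 1.0
        total += 1.0
    return seq


def _dirichlet_weights(k: int, alpha_r: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.gamma(alpha_r, size=k)
    s = w.sum()
    if s == 0.0 or not np.isfinite(s):  # only possible at extremely small alpha_r
        w = np.zeros(k)
        w[rng.integers(k)] = 1.0
        return w
    return w / s


def simulate_ego_events(
    params: ModelParams,
    tau_r: int,
    rng: np.random.Generator,
    method: str = "urn",
) -> SimulatedEgo:
    """Simulate ``tau_r`` events for one ego, recording the full sequence.

    Both methods sample from the exact sequence law; "dirichlet" is the fast
    path for large ``tau_r``.
    """
    if tau_r < 0:
        raise ValueError("tau_r must be non-negative")
    k, a0 = params.k, params.a0
    if method == "urn":
        seq = _urn_sequence(k, params.alpha_r, tau_r, rng)
    elif method == "dirichlet":
        w = _dirichlet_weights(k, params.alpha_r, rng)
        seq = rng.choice(k, size=tau_r, p=w)
    else:
        raise ValueError(f"unknown method {method!r}")
    final = a0 + np.bincount(seq, minlength=k)
    return SimulatedEgo(params=params, tau_r=tau_r, event_sequence=seq, final_activities=final)


def simulate_final_activities(
    params: ModelParams, tau_r: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample terminal activities from the Dirichlet-multinomial urn law.

    Equivalent in law to ``simulate_ego_events(...).final_activities`` but
    without materializing the event sequence.
    """
    if tau_r < 0:
        raise ValueError("tau_r must be non-negative")
    w = _dirichlet_weights(params.k, params.alpha_r, rng)
    counts = rng.multinomial(tau_r, w)
    return params.a0 + counts


class LogUniformParamSampler:
    """Per-ego parameter sampler with independent log-uniform marginals.

    Emulates a population whose degrees, offsets and activity levels are
    broadly (log-uniformly) distributed; every range is configurable.
    Yields dicts with keys ``k, a0, alpha_r, tau_r``.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (10, 100),
        a0: int = 1,
        alpha_r_range: tuple[float, float] = (0.1, 10.0),
        t_r_range: tuple[float, float] = (5.0, 50.0),
    ):
        self.k_range = k_range
        self.a0 = a0
        self.alpha_r_range = alpha_r_range
        self.t_r_range = t_r_range

    @staticmethod
    def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def __call__(self, rng: np.random.Generator) -> dict:
        k = int(round(self._log_uniform(rng, *self.k_range)))
        alpha_r = self._log_uniform(rng, *self.alpha_r_range)
        t_r = self._log_uniform(rng, *self.t_r_range)
        return {
            "k": max(k, 2),
            "a0": self.a0,
            "alpha_r": alpha_r,
            "tau_r": max(int(round(k * t_r)), 1),
        }


def simulate_population(
    param_sampler: Callable[[np.random.Generator], dict] | None,
    n_egos: int,
    rng: np.random.Generator,
    method: str = "dirichlet",
    emit_baseline: bool = True,
    timestamp_jitter: float = 0.0,
) -> EventLog:
    """Generate a synthetic event log for ``n_egos`` independent egos.

    Each ego gets its own counter-based RNG substream (spawned from ``rng``),
    so the log is reproducible and independent of generation order.
    Timestamps are consecutive integers per ego preserving event order;
    ``timestamp_jitter`` adds uniform integer offsets (I/O testing only).

    With ``emit_baseline`` (default) each alter's ``a0`` initial events are
    written at the start of the ego's record (round-robin), so aggregating
    the log recovers the simulated final activities exactly and the minimum
    aggregated activity equals ``a0``.  ``emit_baseline=False`` yields an
    "empirical-style" log containing only the dynamic events, in which an
    alter is visible only from its first contact on.
    """
    if n_egos <= 0:
        raise ValueError("n_egos must be positive")
    sampler = param_sampler if param_sampler is not None else LogUniformParamSampler()
    streams = rng.spawn(n_egos)
    frames = []
    meta = {}
    for i, sub in enumerate(streams):
        p = sampler(sub)
        params = ModelParams.from_reduced(k=p["k"], a0=p["a0"], alpha_r=p["alpha_r"])
        ego = simulate_ego_events(params, p["tau_r"], sub, method=method)
        ego_id = f"ego{i:06d}"
        if emit_baseline and params.a0 > 0:
            baseline = np.tile(np.arange(params.k), params.a0)
            seq = np.concatenate([baseline, ego.event_sequence])
        else:
            seq = ego.event_sequence
        ts = np.arange(len(seq), dtype=np.int64)
        if timestamp_jitter > 0:
            ts = ts + sub.integers(0, int(timestamp_jitter) + 1, size=len(seq)).cumsum()
        frames.append(
            pd.DataFrame(
                {
                    "ego": ego_id,
                    "alter": [f"{ego_id}.a{j}" for j in seq],
                    "timestamp": ts,
                }
            )
        )
        meta[ego_id] = params
    df = pd.concat(frames, ignore_index=True)
    return EventLog(frame=df, params=meta)
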