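"""Run configuration: filters, goodness-of-fit and kernel settings.

Defaults follow the reference analysis: egos need more than 10 events to be
fitted, the bootstrap uses 2500 replicates of the KS statistic, fits are
retained when ``p > 0.1``, and kernel bins are reported only when backed by
at least 30 egos.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # ego filters
    min_events: int = 10  # egos must have MORE events than this
    min_k: int = 2
    ccdf_min_k: int = 10  # degree filter for CCDF/quartile plots
    # goodness of fit
    n_sim: int = 2500
    statistic: str = "ks"  # ks | w2 | a2 | u2
    p_threshold: float = 0.1
    bootstrap_a0: str = "replicate"  # replicate | data
    truncation_tol: float = 1e-12
    # connection kernel
    kernel_normalized: bool = False
    kernel_bins: int = 20
    kernel_min_egos: int = 30
    kernel_initial_activity: int = 0
    kernel_baseline_events: str | int = 0  # "auto" skips each ego's k*a0 baseline block
    # event handling
    directed: bool = False
    # reproducibility
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_events < 0 or self.min_k < 1:
            raise ValueError("filters must be positive")
        if self.n_sim < 0:
            raise ValueError("n_sim must be non-negative")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.statistic not in ("ks", "w2", "a2", "u2"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.bootstrap_a0 not in ("replicate", "data"):
            raise ValueError("bootstrap_a0 must be 'replicate' or 'data'")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    def with_options(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @property
    def hash(self) -> str:
        """Short stable digest of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
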