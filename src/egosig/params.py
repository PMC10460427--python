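"""Parameters of the egocentric-network activity model.

An ego with ``k`` alters accumulates communication events one at a time.
Every alter starts at activity ``a0``; the alter receiving the next event is
drawn with probability proportional to ``a + alpha``, where ``a`` is its
current activity and ``alpha`` tunes the balance between cumulative
advantage (``alpha -> -a0``) and uniformly random choice (``alpha -> inf``).

The natural reduced coordinates are ``alpha_r = alpha + a0`` (random-choice
offset), ``t = tau / k`` (mean alter activity, playing the role of time),
``t_r = t - a0`` and the preferentiality parameter ``beta = t_r / alpha_r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """Immutable parameter set ``(k, a0, alpha)`` with optional mean activity ``t``.

    Parameters
    ----------
    k : int
        Ego-network degree (number of alters), ``k >= 1``.
    a0 : int
        Initial (minimum) alter activity, ``a0 >= 0``.
    alpha : float
        Preferentiality offset; must satisfy ``alpha > -a0`` so that
        ``alpha_r = alpha + a0 > 0``.
    t : float, optional
        Mean alter activity (``t = tau / k``). Required by quantities that
        depend on elapsed events (``beta``, ``tau``, the activity pmf);
        must satisfy ``t >= a0``.
    """

    k: int
    a0: int
    alpha: float
    t: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.a0 < 0 or int(self.a0) != self.a0:
            raise ValueError(f"a0 must be a non-negative integer, got {self.a0}")
        if not self.alpha > -self.a0:
            raise ValueError(
                f"alpha must exceed -a0 (alpha_r > 0); got alpha={self.alpha}, a0={self.a0}"
            )
        if self.t is not None and self.t < self.a0:
            raise ValueError(f"mean activity t must be >= a0; got t={self.t}, a0={self.a0}")

    # -- reduced coordinates -------------------------------------------------

    @property
    def alpha_r(self) -> float:
        """Random-choice offset ``alpha + a0 > 0``."""
        return self.alpha + self.a0

    @property
    def t_r(self) -> float:
        """Relative mean activity ``t - a0 >= 0``."""
        self._require_t()
        return self.t - self.a0  # type: ignore[operator]

    @property
    def beta(self) -> float:
        """Preferentiality parameter ``t_r / alpha_r``."""
        return self.t_r / self.alpha_r

    @property
    def tau(self) -> float:
        """Total event time ``k * t``."""
        self._require_t()
        return self.k * self.t  # type: ignore[operator]

    @property
    def tau0(self) -> float:
        """Initial event time ``k * a0``."""
        return self.k * self.a0

    @property
    def tau_r(self) -> float:
        """Relative event time ``tau - tau0``."""
        return self.tau - self.tau0

    def with_t(self, t: float) -> "ModelParams":
        """Return a copy with mean activity ``t`` set."""
        return ModelParams(self.k, self.a0, self.alpha, t)

    @classmethod
    def from_reduced(
        cls, k: int, a0: int, alpha_r: float, t_r: float | None = None
    ) -> "ModelParams":
        """Build from reduced coordinates ``(alpha_r, t_r)`` instead of ``(alpha, t)``."""
        t = None if t_r is None else a0 + t_r
        return cls(k=k, a0=a0, alpha=alpha_r - a0, t=t)

    def _require_t(self) -> None:
        if self.t is None:
            raise ValueError("this quantity needs the mean activity t; use with_t(t)")
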