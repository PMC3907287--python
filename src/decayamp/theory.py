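"""Closed-form envelopes and tuning bounds for the decay-amplify mechanism.

During maintenance the chain is linear, so a deep (persistent) cell follows
the envelope ``x0 * exp((g - 1) t)``.  With feedback of strength ``c``
switched on at the executive-input time ``t_s``, the envelope becomes
piecewise exponential: decay at rate ``d = 1 - g`` before ``t_s``,
amplification at rate ``a = g + c - 1`` after.  Requiring the end-of-delay
level to sit inside the resolution band ``x0 * [1 - eps, 1 + eps]`` yields

* a minimal coupling for a plain line attractor,
  ``g >= 1 + ln(1 - eps) / T``;
* an admissible window for the executive-input time,
  ``t_s in [(a T - ln(1 + eps)) / (a + d), (a T - ln(1 - eps)) / (a + d)]``,
  of length ``ln((1 + eps) / (1 - eps)) / (a + d) ~ 2 eps / (a + d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import ConfigurationError, DegenerateRegimeError, DomainError

__all__ = [
    "RateParams",
    "TimingInterval",
    "persistent_envelope",
    "decay_amplify_envelope",
    "line_attractor_min_coupling",
    "timing_interval",
    "interval_length_approx",
    "chain_solution",
]


@dataclass(frozen=True)
class RateParams:
    """Rates and tolerances entering the timing analysis.

    ``d = 1 - g`` is the decay rate during maintenance, ``a = g + c - 1``
    the amplification rate once feedback of strength ``c`` is active, and
    ``eps`` the relative resolution of the network (success band
    ``x0 * [1 - eps, 1 + eps]`` at the end of the delay period ``T``).
    """

    g: float
    c: float
    eps: float
    T: float
    x0: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.eps < 1:
            raise ConfigurationError(f"eps must lie in (0, 1), got {self.eps}")
        if self.T <= 0:
            raise ConfigurationError(f"delay length T must be > 0, got {self.T}")
        if self.x0 <= 0:
            raise ConfigurationError(f"loaded level x0 must be > 0, got {self.x0}")
        if self.g < 0 or self.c < 0:
            raise ConfigurationError("couplings g, c must be >= 0")

    @classmethod
    def from_rates(
        cls, d: float, a: float, eps: float, T: float, x0: float = 1.0
    ) -> "RateParams":
        """Build from decay/amplification rates (``g = 1 - d``, ``c = a + d``)."""
        return cls(g=1.0 - d, c=a + d, eps=eps, T=T, x0=x0)

    @property
    def d(self) -> float:
        """Decay rate during maintenance (positive when g < 1)."""
        return 1.0 - self.g

    @property
    def a(self) -> float:
        """Amplification rate with feedback on (positive when g + c > 1)."""
        return self.g + self.c - 1.0


@dataclass(frozen=True)
class TimingInterval:
    """Admissible executive-input window, clipped to the delay period.

    ``raw_lo``/``raw_hi`` are the unclipped algebraic bounds; ``lo``/``hi``
    their intersection with ``[0, T]``.
    """

    lo: float
    hi: float
    raw_lo: float
    raw_hi: float
    T: float

    @property
    def length(self) -> float:
        return self.hi - self.lo

    @property
    def raw_length(self) -> float:
        return self.raw_hi - self.raw_lo

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def __contains__(self, t_s: float) -> bool:
        return self.lo <= t_s <= self.hi


def persistent_envelope(t, g: float, x0: float):
    """Deep-cell activity envelope ``x0 * exp((g - 1) t)`` during maintenance."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    out = x0 * np.exp((g - 1.0) * t)
    return float(out) if out.ndim == 0 else out


def decay_amplify_envelope(t, t_s: float, params: RateParams):
    """Piecewise-exponential persistent-cell envelope.

    Decay at rate ``d`` until the executive input at ``t_s``, then
    amplification at rate ``a``; continuous at ``t_s``.
    """
    if not 0 <= t_s <= params.T:
        raise DomainError(f"t_s={t_s} outside the delay period [0, {params.T}]")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    d, a, x0 = params.d, params.a, params.x0
    out = np.where(
        t <= t_s,
        x0 * np.exp(-d * t),
        x0 * np.exp(-d * t_s) * np.exp(a * (t - t_s)),
    )
    return float(out) if out.ndim == 0 else out


def line_attractor_min_coupling(eps: float, T: float) -> float:
    """Smallest coupling g for which an uncorrected chain stays in band.

    Requires ``exp((g - 1) T) >= 1 - eps``, i.e. ``g = 1 + ln(1 - eps) / T``.
    """
    if not 0 < eps < 1:
        raise DomainError(f"eps must lie in (0, 1), got {eps}")
    if T <= 0:
        raise DomainError(f"T must be > 0, got {T}")
    return 1.0 + math.log1p(-eps) / T


def timing_interval(params: RateParams) -> TimingInterval:
    """Admissible window for the executive-input time ``t_s``.

    Solves ``|envelope(T; t_s) / x0 - 1| <= eps`` for ``t_s``; the algebraic
    bounds are clipped to the delay period ``[0, T]``.
    """
    d, a, eps, T = params.d, params.a, params.eps, params.T
    if a + d <= 0:
        raise DegenerateRegimeError(
            f"timing interval undefined for a + d = {a + d} <= 0"
        )
    raw_lo = (a * T - math.log1p(eps)) / (a + d)
    raw_hi = (a * T - math.log1p(-eps)) / (a + d)
    lo = min(max(raw_lo, 0.0), T)
    hi = min(max(raw_hi, 0.0), T)
    return TimingInterval(lo=lo, hi=hi, raw_lo=raw_lo, raw_hi=raw_hi, T=T)


def interval_length_approx(params: RateParams) -> float:
    """Small-eps approximation ``2 eps / (a + d)`` of the window length."""
    d, a = params.d, params.a
    if a + d <= 0:
        raise DegenerateRegimeError(
            f"timing interval undefined for a + d = {a + d} <= 0"
        )
    return 2.0 * params.eps / (a + d)


def chain_solution(profile, g: float, t) -> np.ndarray:
    """Exact noiseless maintenance solution of the linear feed-forward chain.

    Propagates an initial activity profile through ``dx/dt = (-I + g S) x``
    (S the sub-diagonal shift) using the matrix exponential. Returns an
    array of shape ``(len(t), n)`` (or ``(n,)`` for scalar ``t``).
    """
    x0 = np.asarray(profile, dtype=float)
    if x0.ndim != 1 or x0.size < 1:
        raise DomainError("profile must be a 1-D array")
    n = x0.size
    A = -np.eye(n) + g * np.eye(n, k=-1)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    out = np.empty((t_arr.size, n))
    for i, ti in enumerate(t_arr):
        out[i] = expm(A * ti) @ x0
    return out[0] if np.ndim(t) == 0 else out
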