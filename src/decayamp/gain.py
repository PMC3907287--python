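"""Response (gain) functions and the stimulus-to-activity map.

The response function ``F`` converts summed presynaptic input into
postsynaptic drive.  Four configurations are used, one per task phase:

``loading``
    rectified-linear with a saturation plateau; the stable fixed point of
    ``x = F(g x)`` sits at the stimulus-specific activity level.
``maintenance``
    rectified-linear, by default the identity on non-negative input, so a
    unit-coupled chain is a line attractor.
``comparison``
    rectified-linear with threshold and steep slope, creating an unstable
    fixed point (separatrix) at the level coding the second stimulus.
``quiescent``
    identically zero; the cell ignores all input.

All configurations are drawn from one rectified piecewise-linear family
with optional saturation: ``F(u) = clip(slope * (u - threshold), 0, M)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "GainMode",
    "GainSpec",
    "StimulusMap",
    "FixedPoint",
    "evaluate_gain",
    "classify_fixed_points",
    "comparison_spec",
]


class GainMode(str, Enum):
    """Task-phase configuration of the response function."""

    LOADING = "loading"
    MAINTENANCE = "maintenance"
    COMPARISON = "comparison"
    QUIESCENT = "quiescent"


@dataclass(frozen=True)
class GainSpec:
    """One configuration of the response function F.

    Parameters
    ----------
    mode
        Which task-phase configuration this is.
    threshold
        Input level below which the output is zero. Must be ``>= 0``.
    slope
        Gain above threshold. Must be ``> 0``.
    saturation
        Optional plateau level ``M > 0``; ``None`` means unbounded.
    """

    mode: GainMode
    threshold: float = 0.0
    slope: float = 1.0
    saturation: float | None = None

    def __post_init__(self) -> None:
        try:
            mode = GainMode(self.mode)
        except ValueError as exc:
            raise ConfigurationError(f"invalid gain mode: {self.mode!r}") from exc
        object.__setattr__(self, "mode", mode)
        if not np.isfinite(self.threshold) or self.threshold < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.threshold}")
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ConfigurationError(f"slope must be > 0, got {self.slope}")
        if self.saturation is not None and (
            not np.isfinite(self.saturation) or self.saturation <= 0
        ):
            raise ConfigurationError(
                f"saturation must be > 0 or None, got {self.saturation}"
            )

    # Convenience constructors ------------------------------------------------

    @classmethod
    def maintenance(cls, threshold: float = 0.0, slope: float = 1.0) -> "GainSpec":
        return cls(GainMode.MAINTENANCE, threshold=threshold, slope=slope)

    @classmethod
    def quiescent(cls) -> "GainSpec":
        return cls(GainMode.QUIESCENT)

    @classmethod
    def loading(
        cls, threshold: float = 0.0, slope: float = 2.0, saturation: float = 1.0
    ) -> "GainSpec":
        return cls(GainMode.LOADING, threshold=threshold, slope=slope, saturation=saturation)

    @classmethod
    def comparison(cls, threshold: float, slope: float) -> "GainSpec":
        return cls(GainMode.COMPARISON, threshold=threshold, slope=slope)

    def __call__(self, u):
        return evaluate_gain(self, u)


def evaluate_gain(spec: GainSpec, u):
    """Evaluate the response function F on input ``u`` (scalar or array).

    F is never negative and is zero below threshold; in quiescent mode it
    is identically zero. Accepts negative inputs (noise can drive the
    summed input below zero).
    """
    u = np.asarray(u, dtype=float)
    if spec.mode is GainMode.QUIESCENT:
        out = np.zeros_like(u)
    else:
        out = np.asarray(spec.slope * (u - spec.threshold))
        out = np.clip(
            out, 0.0, np.inf if spec.saturation is None else spec.saturation
        )
    return float(out) if out.ndim == 0 else out


def comparison_spec(separatrix: float, g: float, local_gain: float = 2.0) -> GainSpec:
    """Comparison-phase spec with an unstable fixed point at ``separatrix``.

    The fixed point of ``x = F(g x)`` is placed at ``separatrix`` with local
    slope ``local_gain`` (> 1 so the point repels): activity above the
    separatrix grows, activity below decays.
    """
    if separatrix <= 0:
        raise ConfigurationError("separatrix level must be > 0")
    if g <= 0:
        raise ConfigurationError("coupling g must be > 0 for a comparison spec")
    if local_gain <= 1:
        raise ConfigurationError("local_gain must exceed 1 for an unstable point")
    slope = local_gain / g
    threshold = separatrix * g * (local_gain - 1.0) / local_gain
    return GainSpec(GainMode.COMPARISON, threshold=threshold, slope=slope)


class FixedPoint(NamedTuple):
    """A non-negative solution of ``x = F(g x)`` with its stability."""

    level: float
    stability: str  # "stable" | "unstable" | "neutral-continuum"
    extent: tuple[float, float] | None = None  # set for the continuum case


def classify_fixed_points(spec: GainSpec, g: float) -> list[FixedPoint]:
    """All non-negative fixed points of the self-consistency map ``x = F(g x)``.

    Stability follows the local slope of ``x -> F(g x)``: below 1 stable,
    above 1 unstable, exactly 1 a neutral continuum (line attractor).
    """
    if g < 0:
        raise ConfigurationError(f"coupling must be >= 0, got {g}")
    pts: list[FixedPoint] = []
    if spec.mode is GainMode.QUIESCENT or g == 0:
        return [FixedPoint(0.0, "stable")]

    theta, s, M = spec.threshold, spec.slope, spec.saturation
    sg = s * g

    # Sub-threshold piece: F(g x) = 0 for x < theta / g.
    if theta > 0:
        pts.append(FixedPoint(0.0, "stable"))

    # Linear piece: x = s (g x - theta) while theta <= g x and F below M.
    if sg == 1.0:
        if theta == 0.0:
            hi = float("inf") if M is None else M
            pts.append(FixedPoint(0.0, "neutral-continuum", (0.0, hi)))
        # theta > 0 with unit local slope: the line x = x - s*theta has no
        # solution; nothing to add.
    else:
        x_star = s * theta / (sg - 1.0)
        if x_star >= 0 and g * x_star >= theta and (M is None or s * (g * x_star - theta) <= M):
            stability = "stable" if sg < 1 else "unstable"
            if not any(np.isclose(p.level, x_star) for p in pts):
                pts.append(FixedPoint(float(x_star), stability))

    # Saturated piece: x = M where s (g x - theta) >= M.
    if M is not None and s * (g * M - theta) >= M:
        if not any(p.extent is not None or np.isclose(p.level, M) for p in pts):
            pts.append(FixedPoint(float(M), "stable"))

    return sorted(pts, key=lambda p: p.level)


@dataclass(frozen=True)
class StimulusMap:
    """Strictly monotone map from stimulus value f to loaded activity level.

    Linear interpolation between ``(f_min, x_lo)`` and ``(f_max, x_hi)``;
    increasing encoders only (direction +1).
    """

    f_min: float = 10.0
    f_max: float = 34.0
    x_lo: float = 0.4
    x_hi: float = 1.2

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ConfigurationError("require f_min < f_max")
        if not 0 < self.x_lo < self.x_hi:
            raise ConfigurationError("require 0 < x_lo < x_hi")

    def load_level(self, f) -> float:
        """Activity level loaded by stimulus value ``f`` (must lie in range)."""
        f = np.asarray(f, dtype=float)
        if np.any(f < self.f_min) or np.any(f > self.f_max):
            raise DomainError(
                f"stimulus {f} outside [{self.f_min}, {self.f_max}]"
            )
        frac = (f - self.f_min) / (self.f_max - self.f_min)
        out = self.x_lo + frac * (self.x_hi - self.x_lo)
        return float(out) if out.ndim == 0 else out

    def inverse(self, x) -> float:
        """Stimulus value whose loaded level is ``x`` (bijection inverse)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x_lo) or np.any(x > self.x_hi):
            raise DomainError(f"level {x} outside [{self.x_lo}, {self.x_hi}]")
        frac = (x - self.x_lo) / (self.x_hi - self.x_lo)
        out = self.f_min + frac * (self.f_max - self.f_min)
        return float(out) if out.ndim == 0 else out

    @property
    def resolution_scale(self) -> float:
        """Activity range spanned by the stimulus interval."""
        return self.x_hi - self.x_lo
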