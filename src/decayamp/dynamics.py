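"""Stochastic rate-network simulation under a task schedule.

Two architectures are provided:

* a feed-forward nearest-neighbour chain (``simulate_chain``): cell ``i``
  receives ``g * x[i-1]``; a designated block of late cells is held
  quiescent until the executive input arrives, after which a single late
  cell feeds back with strength ``c`` onto every stimulated cell;
* a symmetric-kernel field (``simulate_kernel``): early/persistent cells
  coupled through a normalized Gaussian-shaped kernel (no boundary
  renormalization, so mass is lost at the edges), plus a separate late
  line driven divergently by the field and feeding back one-to-one.

Integration is Euler-Maruyama, ``dx = (-x + F(input)) dt / tau
+ sigma sqrt(dt) xi``; the state itself is never clipped, only the gain
is rectified.  Time 0 is stimulus offset; the membrane time constant
``tau`` defines the time unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, IntegrationError
from .gain import GainSpec, StimulusMap, evaluate_gain

__all__ = [
    "ChainConfig",
    "KernelConfig",
    "TaskSchedule",
    "GainPlan",
    "SimResult",
    "Phase",
    "build_chain_weights",
    "build_kernel",
    "simulate_chain",
    "simulate_chain_ensemble",
    "simulate_kernel",
    "phase_at",
    "derive_seed",
]

_CHUNK = 200  # integration steps per pre-generated noise block


def derive_seed(base_seed: int, *key: int) -> np.random.SeedSequence:
    """Counter-based seed splitting: one stream per (base, *indices) tuple.

    The entropy vector is ``[base_seed, *key]``; distinct key tuples give
    statistically independent, reproducible streams.
    """
    return np.random.SeedSequence([int(base_seed), *map(int, key)])


@dataclass(frozen=True)
class ChainConfig:
    """Feed-forward chain architecture parameters.

    ``n_stim`` cells (indices ``0 .. n_stim-1``) are initialized at the
    loaded level; the late block is ``n_stim .. n_cells-1``.
    ``feedback_source`` is the index of the single late cell whose
    activity, scaled by ``c``, is added to every stimulated cell's input
    once the gate is open (default: the first late cell).
    """

    n_cells: int = 150
    n_stim: int = 100
    g: float = 0.997
    c: float = 0.006
    sigma: float = 0.01
    dt: float = 0.01
    tau: float = 1.0
    feedback_source: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ConfigurationError(f"n_cells must be >= 2, got {self.n_cells}")
        if not 0 < self.n_stim < self.n_cells:
            raise ConfigurationError(
                f"require 0 < n_stim < n_cells, got n_stim={self.n_stim}"
            )
        if self.g < 0 or self.c < 0 or self.sigma < 0:
            raise ConfigurationError("g, c, sigma must be >= 0")
        if self.dt <= 0 or self.tau <= 0:
            raise ConfigurationError("dt and tau must be > 0")
        if self.feedback_source is None:
            object.__setattr__(self, "feedback_source", self.n_stim)
        if not self.n_stim <= self.feedback_source < self.n_cells:
            raise ConfigurationError(
                f"feedback_source {self.feedback_source} must index a late cell"
            )

    @property
    def d(self) -> float:
        return 1.0 - self.g

    @property
    def a(self) -> float:
        return self.g + self.c - 1.0


@dataclass(frozen=True)
class KernelConfig:
    """Symmetric-kernel field parameters.

    The kernel is Gaussian-shaped with scale ``kernel_sd`` (cell-index
    units), truncated at ``4 * kernel_sd`` and normalized to unit sum on
    the unbounded domain; ``gbar = 1`` then places interior cells exactly
    on the line-attractor balance of the discrete grid.
    """

    n_cells: int = 300
    kernel_sd: float = 5.0
    gbar: float = 1.0
    c: float = 0.0
    sigma: float = 0.0
    dt: float = 0.01
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ConfigurationError(f"n_cells must be >= 2, got {self.n_cells}")
        if self.kernel_sd <= 0:
            raise ConfigurationError("kernel_sd must be > 0")
        if self.gbar < 0 or self.c < 0 or self.sigma < 0:
            raise ConfigurationError("gbar, c, sigma must be >= 0")
        if self.dt <= 0 or self.tau <= 0:
            raise ConfigurationError("dt and tau must be > 0")


@dataclass(frozen=True)
class TaskSchedule:
    """Timeline of the task: delay period ``[0, T]``, executive input at
    ``t_exec``, optional comparison window of length ``t_cmp_len`` after
    ``T``.  ``f1``/``f2`` are the first/second stimulus values."""

    T: float = 50.0
    t_exec: float = 25.0
    t_cmp_len: float = 3.0
    f1: float = 22.0
    f2: float = 28.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ConfigurationError(f"delay length T must be > 0, got {self.T}")
        if not 0 <= self.t_exec <= self.T:
            raise ConfigurationError(
                f"t_exec={self.t_exec} must lie within the delay period [0, {self.T}]"
            )
        if self.t_cmp_len <= 0:
            raise ConfigurationError("t_cmp_len must be > 0")

    def with_exec(self, t_exec: float) -> "TaskSchedule":
        return dataclasses.replace(self, t_exec=t_exec)


class Phase(str, Enum):
    MAINTENANCE = "maintenance"
    COMPARISON = "comparison"


def phase_at(t: float, schedule: TaskSchedule) -> tuple[Phase, bool]:
    """Task phase and late-gate state at time ``t``.

    The gate opens at ``t_exec`` (closed-interval convention); the
    comparison phase begins strictly after ``T``.
    """
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    phase = Phase.COMPARISON if t > schedule.T else Phase.MAINTENANCE
    return phase, t >= schedule.t_exec


@dataclass(frozen=True)
class GainPlan:
    """Per-block response-function timeline.

    The stimulated block runs ``main`` during maintenance and switches to
    ``comparison`` (when provided) after the delay ends.  The late block
    runs ``late_closed`` until the executive input and ``late_open``
    afterwards; during the comparison phase late cells fall back to
    ``late_closed`` and feedback is switched off, isolating the
    separatrix dynamics of the readout.
    """

    main: GainSpec = field(default_factory=GainSpec.maintenance)
    late_closed: GainSpec = field(default_factory=GainSpec.quiescent)
    late_open: GainSpec = field(default_factory=GainSpec.maintenance)
    comparison: GainSpec | None = None


@dataclass
class SimResult:
    """A seeded trajectory of every cell on a uniform time grid.

    ``activity`` has shape ``(n_cells, len(times))``. For the kernel model
    ``late`` holds the parallel late-line trajectory. ``config`` is a
    plain-dict snapshot of everything that produced the run.
    """

    times: np.ndarray
    activity: np.ndarray
    seed: object
    config: dict
    late: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    def cell(self, index: int) -> np.ndarray:
        return self.activity[index]

    def at_time(self, t: float) -> np.ndarray:
        """State vector at the grid point nearest ``t``."""
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.activity[:, idx]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, cell_index (1-based), population, activity."""
        frames = [("main", self.activity)]
        if self.late is not None:
            frames.append(("late", self.late))
        parts = []
        for pop, arr in frames:
            n, m = arr.shape
            parts.append(
                pd.DataFrame(
                    {
                        "time": np.tile(self.times, n),
                        "cell_index": np.repeat(np.arange(1, n + 1), m),
                        "population": pop,
                        "activity": arr.ravel(),
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


def build_chain_weights(n_cells: int, g: float) -> np.ndarray:
    """Feed-forward nearest-neighbour connection matrix.

    Entry ``(i, i-1) = g`` for ``i = 1 .. n_cells-1``; the first cell
    receives no input.
    """
    if n_cells < 2:
        raise ConfigurationError(f"n_cells must be >= 2, got {n_cells}")
    if g < 0:
        raise ConfigurationError(f"coupling must be >= 0, got {g}")
    return g * np.eye(n_cells, k=-1)


def build_kernel(kernel_sd: float, n_sd: float = 4.0) -> np.ndarray:
    """Symmetric, non-negative coupling window of unit sum.

    Gaussian-shaped, truncated at ``n_sd * kernel_sd``; normalized so the
    full (unbounded-domain) window sums to one.
    """
    if kernel_sd <= 0:
        raise ConfigurationError("kernel_sd must be > 0")
    radius = int(round(n_sd * kernel_sd))
    offsets = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (offsets / kernel_sd) ** 2)
    return w / w.sum()


def _loaded_level(schedule: TaskSchedule, stim_map: StimulusMap | None, x0) -> float:
    if x0 is not None:
        return float(x0)
    return (stim_map or StimulusMap()).load_level(schedule.f1)


def _check_finite(x: np.ndarray, step: int, dt: float) -> None:
    if not np.all(np.isfinite(x)):
        bad = int(np.argmax(~np.isfinite(x).all(axis=tuple(range(x.ndim - 1)))))
        raise IntegrationError(
            f"non-finite state at step {step} (t={step * dt:.4f}), "
            f"first bad cell index {bad}"
        )


def _rep_noise(gens, m: int, n: int) -> np.ndarray:
    """Pre-generate a (reps, m, n) noise block, one stream per rep."""
    out = np.empty((len(gens), m, n))
    for r, gen in enumerate(gens):
        out[r] = gen.standard_normal((m, n))
    return out


def _integrate_chain(
    config: ChainConfig,
    schedule: TaskSchedule,
    plan: GainPlan,
    x_init: np.ndarray,  # (reps, n_cells)
    gens: list,
    t_end: float,
    record_every: int | None,
):
    """Shared Euler-Maruyama core; returns (times, traj | None, final)."""
    n, ns = config.n_cells, config.n_stim
    g, c, sigma, dt, tau = config.g, config.c, config.sigma, config.dt, config.tau
    src = config.feedback_source
    steps = int(round(t_end / dt))
    x = np.array(x_init, dtype=float)
    reps = x.shape[0]
    sq = sigma * np.sqrt(dt)

    rec_idx = None
    traj = None
    if record_every is not None:
        rec_idx = np.arange(0, steps + 1, record_every)
        if rec_idx[-1] != steps:
            rec_idx = np.append(rec_idx, steps)
        traj = np.empty((reps, n, rec_idx.size))
        traj[:, :, 0] = x
        rec_pos = 1

    u = np.empty_like(x)
    drive = np.empty_like(x)
    with np.errstate(over="ignore", invalid="ignore"):
        for start in range(0, steps, _CHUNK):
            m = min(_CHUNK, steps - start)
            noise = _rep_noise(gens, m, n) if sigma > 0 else None
            for j in range(m):
                k = start + j
                t = k * dt
                gate = t >= schedule.t_exec
                in_cmp = plan.comparison is not None and t > schedule.T

                u[:, 0] = 0.0
                np.multiply(g, x[:, :-1], out=u[:, 1:])
                if gate and not in_cmp and c > 0.0:
                    u[:, :ns] += c * x[:, src, None]

                if in_cmp:
                    drive[:, :ns] = evaluate_gain(plan.comparison, u[:, :ns])
                    drive[:, ns:] = evaluate_gain(plan.late_closed, u[:, ns:])
                else:
                    drive[:, :ns] = evaluate_gain(plan.main, u[:, :ns])
                    spec = plan.late_open if gate else plan.late_closed
                    drive[:, ns:] = evaluate_gain(spec, u[:, ns:])

                x += (drive - x) * (dt / tau)
                if noise is not None:
                    x += sq * noise[:, j]
                if rec_idx is not None and rec_pos < rec_idx.size and k + 1 == rec_idx[rec_pos]:
                    traj[:, :, rec_pos] = x
                    rec_pos += 1
            _check_finite(x, start + m, dt)

    times = (rec_idx * dt) if rec_idx is not None else None
    return times, traj, x


def simulate_chain(
    config: ChainConfig,
    schedule: TaskSchedule,
    plan: GainPlan | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    x0: float | None = None,
    stim_map: StimulusMap | None = None,
    record_every: int = 1,
) -> SimResult:
    """Simulate one trial of the feed-forward chain.

    The stimulated block starts at the loaded level (``x0`` explicitly, or
    ``stim_map.load_level(schedule.f1)``); the late block starts at zero
    and is quiescent until the executive input at ``schedule.t_exec``.
    The run covers ``[0, T]``, extended by the comparison window when
    ``plan.comparison`` is set.

    With ``sigma = 0`` the trajectory is independent of ``seed`` and
    bit-reproducible.
    """
    plan = plan or GainPlan()
    level = _loaded_level(schedule, stim_map, x0)
    x_init = np.zeros((1, config.n_cells))
    x_init[0, : config.n_stim] = level
    t_end = schedule.T + (schedule.t_cmp_len if plan.comparison is not None else 0.0)
    ss = seed if isinstance(seed, np.random.SeedSequence) else derive_seed(seed)
    gens = [np.random.default_rng(ss)]
    times, traj, _ = _integrate_chain(
        config, schedule, plan, x_init, gens, t_end, record_every
    )
    snapshot = {
        "model": "chain",
        "config": dataclasses.asdict(config),
        "schedule": dataclasses.asdict(schedule),
        "x0": level,
        "record_every": record_every,
    }
    return SimResult(
        times=times, activity=traj[0], seed=ss.entropy, config=snapshot
    )


def simulate_chain_ensemble(
    config: ChainConfig,
    schedule: TaskSchedule,
    n_reps: int,
    base_seed: int,
    plan: GainPlan | None = None,
    *,
    x0: float | None = None,
    stim_map: StimulusMap | None = None,
    seed_key: tuple[int, ...] = (),
) -> np.ndarray:
    """End-of-run state for ``n_reps`` independent trials, shape (reps, n).

    Rep ``r`` uses the stream ``derive_seed(base_seed, *seed_key, r)``, so
    every (sweep point, rep) pair is independently seeded yet the
    integration is vectorized across reps.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    plan = plan or GainPlan()
    level = _loaded_level(schedule, stim_map, x0)
    x_init = np.zeros((n_reps, config.n_cells))
    x_init[:, : config.n_stim] = level
    t_end = schedule.T + (schedule.t_cmp_len if plan.comparison is not None else 0.0)
    gens = [
        np.random.default_rng(derive_seed(base_seed, *seed_key, r))
        for r in range(n_reps)
    ]
    _, _, final = _integrate_chain(config, schedule, plan, x_init, gens, t_end, None)
    return final


def simulate_kernel(
    config: KernelConfig,
    schedule: TaskSchedule,
    seed: int | np.random.SeedSequence = 0,
    *,
    x0: float | None = None,
    stim_map: StimulusMap | None = None,
    plan: GainPlan | None = None,
    record_every: int = 1,
) -> SimResult:
    """Simulate the symmetric-kernel field with its late line.

    The field ``u`` starts uniformly at the loaded level; late line ``v``
    starts at zero and is quiescent before ``t_exec``.  Late cells receive
    divergent uniform-weight drive (the field mean); feedback adds
    ``c * v[i]`` to cell ``i``'s input once the gate is open.  No boundary
    renormalization is applied, so trailing fronts form at both edges.
    """
    plan = plan or GainPlan()
    level = _loaded_level(schedule, stim_map, x0)
    n = config.n_cells
    dt, tau, sigma = config.dt, config.tau, config.sigma
    w = build_kernel(config.kernel_sd)
    steps = int(round(schedule.T / dt))
    sq = sigma * np.sqrt(dt)

    u = np.full(n, level, dtype=float)
    v = np.zeros(n)
    ss = seed if isinstance(seed, np.random.SeedSequence) else derive_seed(seed)
    gen = np.random.default_rng(ss)

    rec_idx = np.arange(0, steps + 1, record_every)
    if rec_idx[-1] != steps:
        rec_idx = np.append(rec_idx, steps)
    traj_u = np.empty((n, rec_idx.size))
    traj_v = np.empty((n, rec_idx.size))
    traj_u[:, 0], traj_v[:, 0] = u, v
    rec_pos = 1

    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(steps):
            t = k * dt
            gate = t >= schedule.t_exec
            inp_u = config.gbar * np.convolve(u, w, mode="same")
            if gate and config.c > 0.0:
                inp_u = inp_u + config.c * v
            drive_u = evaluate_gain(plan.main, inp_u)
            if gate:
                drive_v = evaluate_gain(plan.late_open, np.full(n, u.mean()))
            else:
                drive_v = 0.0
            u += (drive_u - u) * (dt / tau)
            v += (drive_v - v) * (dt / tau)
            if sigma > 0:
                noise = gen.standard_normal(2 * n)
                u += sq * noise[:n]
                v += sq * noise[n:]
            if rec_pos < rec_idx.size and k + 1 == rec_idx[rec_pos]:
                traj_u[:, rec_pos], traj_v[:, rec_pos] = u, v
                rec_pos += 1
            if k % _CHUNK == 0:
                _check_finite(u, k, dt)
    _check_finite(u, steps, dt)

    snapshot = {
        "model": "kernel",
        "config": dataclasses.asdict(config),
        "schedule": dataclasses.asdict(schedule),
        "x0": level,
        "record_every": record_every,
    }
    return SimResult(
        times=rec_idx * dt,
        activity=traj_u,
        late=traj_v,
        seed=ss.entropy,
        config=snapshot,
    )
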