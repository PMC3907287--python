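"""Trial observables: encoding status, cell classes, wavefronts, decisions.

A cell *encodes* the stimulus at a given time when its trial-mean
activity is strictly increasing across a grid of first-stimulus values
and the spread of those means exceeds ``k_sd`` pooled within-stimulus
standard deviations.  Cells are then labelled early / persistent / late /
unresponsive from whether they encode in the opening and closing windows
of the delay period.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import ChainConfig, GainPlan, SimResult, TaskSchedule, derive_seed, simulate_chain
from .errors import ConfigurationError, DomainError, InputError
from .gain import StimulusMap

__all__ = [
    "EncodingCriterion",
    "EncodingEnsemble",
    "CellClassification",
    "FrontTrace",
    "TrialOutcome",
    "build_encoding_ensemble",
    "encoding_matrix",
    "is_encoding",
    "classify_cells",
    "encoding_count_curve",
    "track_front",
    "front_position",
    "success_band",
    "trial_success",
    "readout_decision",
    "readout_cells",
]


@dataclass(frozen=True)
class EncodingCriterion:
    """Operational definition of 'monotonically tuned'.

    ``f1_values`` must span the stimulus map with at least five points;
    ``reps`` noisy trials are run per stimulus; the mean range must exceed
    ``k_sd`` pooled within-stimulus standard deviations (and be strictly
    monotone when ``require_monotone`` is set).
    """

    f1_values: tuple[float, ...] = (10.0, 16.0, 22.0, 28.0, 34.0)
    reps: int = 20
    k_sd: float = 2.0
    require_monotone: bool = True

    def __post_init__(self) -> None:
        if len(self.f1_values) < 2:
            raise ConfigurationError("need at least 2 stimulus values")
        if list(self.f1_values) != sorted(self.f1_values):
            raise ConfigurationError("f1_values must be increasing")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if self.k_sd <= 0:
            raise ConfigurationError("k_sd must be > 0")


@dataclass
class EncodingEnsemble:
    """Seeded trials over a stimulus grid with otherwise identical configs.

    ``activity`` has shape ``(n_f1, reps, n_cells, n_times)``.
    """

    activity: np.ndarray
    times: np.ndarray
    f1_values: np.ndarray
    T: float
    t_exec: float
    config: dict

    @property
    def n_cells(self) -> int:
        return self.activity.shape[2]

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))


def build_encoding_ensemble(
    config: ChainConfig,
    schedule: TaskSchedule,
    criterion: EncodingCriterion,
    base_seed: int = 0,
    *,
    stim_map: StimulusMap | None = None,
    plan: GainPlan | None = None,
    record_every: int = 50,
) -> EncodingEnsemble:
    """Run ``reps`` seeded trials for each stimulus value in the criterion."""
    stim_map = stim_map or StimulusMap()
    n_f1, reps = len(criterion.f1_values), criterion.reps
    arrays = None
    for i, f1 in enumerate(criterion.f1_values):
        sched = dataclasses.replace(schedule, f1=f1)
        for r in range(reps):
            res = simulate_chain(
                config,
                sched,
                plan,
                derive_seed(base_seed, i, r),
                stim_map=stim_map,
                record_every=record_every,
            )
            if arrays is None:
                arrays = np.empty((n_f1, reps, *res.activity.shape))
                times = res.times
            arrays[i, r] = res.activity
    return EncodingEnsemble(
        activity=arrays,
        times=times,
        f1_values=np.asarray(criterion.f1_values, dtype=float),
        T=schedule.T,
        t_exec=schedule.t_exec,
        config={"chain": dataclasses.asdict(config), "base_seed": base_seed},
    )


def encoding_matrix(ensemble: EncodingEnsemble, criterion: EncodingCriterion) -> np.ndarray:
    """Boolean (n_cells, n_times) matrix: does each cell encode at each time?"""
    act = ensemble.activity
    if act.shape[0] != len(criterion.f1_values) or act.shape[1] != criterion.reps:
        raise InputError(
            "ensemble shape does not match criterion (f1 grid or reps differ)"
        )
    means = act.mean(axis=1)  # (n_f1, n_cells, n_times)
    spread = means[-1] - means[0]
    if criterion.reps > 1:
        pooled_sd = np.sqrt(act.var(axis=1, ddof=1).mean(axis=0))
    else:
        pooled_sd = np.zeros_like(spread)
    separated = np.where(pooled_sd > 0, spread > criterion.k_sd * pooled_sd, spread > 0)
    if criterion.require_monotone:
        mono = np.all(np.diff(means, axis=0) > 0, axis=0)
        return mono & separated
    return separated


def is_encoding(
    ensemble: EncodingEnsemble,
    cell: int,
    t: float,
    criterion: EncodingCriterion,
) -> bool:
    """Does ``cell`` encode the stimulus at time ``t`` (nearest grid point)?"""
    return bool(encoding_matrix(ensemble, criterion)[cell, ensemble.time_index(t)])


@dataclass
class CellClassification:
    """Exhaustive, exclusive per-cell labels plus the encoding-count curve."""

    labels: np.ndarray  # (n_cells,) of {"early","persistent","late","unresponsive"}
    times: np.ndarray
    counts: np.ndarray

    def cells(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_index": np.arange(1, self.labels.size + 1), "label": self.labels}
        )


def _window_mask(times: np.ndarray, T: float, window: tuple[float, float]) -> np.ndarray:
    a, b = window
    if not 0.0 <= a < b <= 1.0:
        raise ConfigurationError(f"window {window} must satisfy 0 <= a < b <= 1")
    mask = (times >= a * T) & (times <= b * T)
    if not mask.any():
        raise ConfigurationError(f"window {window} contains no sampled time points")
    return mask


def classify_cells(
    ensemble: EncodingEnsemble,
    criterion: EncodingCriterion,
    early_window: tuple[float, float] = (0.0, 0.1),
    late_window: tuple[float, float] = (0.9, 1.0),
) -> CellClassification:
    """Label cells early / persistent / late / unresponsive.

    A cell 'encodes in a window' when it encodes at any sampled time point
    inside that window (windows are fractions of the delay period).
    Early = opening window only, late = closing window only, persistent =
    both, unresponsive = neither.
    """
    enc = encoding_matrix(ensemble, criterion)
    early_mask = _window_mask(ensemble.times, ensemble.T, early_window)
    late_mask = _window_mask(ensemble.times, ensemble.T, late_window)
    in_early = enc[:, early_mask].any(axis=1)
    in_late = enc[:, late_mask].any(axis=1)
    labels = np.where(
        in_early & in_late,
        "persistent",
        np.where(in_early, "early", np.where(in_late, "late", "unresponsive")),
    )
    return CellClassification(
        labels=labels.astype(object), times=ensemble.times, counts=enc.sum(axis=0)
    )


def encoding_count_curve(
    ensemble: EncodingEnsemble, criterion: EncodingCriterion
) -> tuple[np.ndarray, np.ndarray]:
    """Number of encoding cells at each sampled time point."""
    enc = encoding_matrix(ensemble, criterion)
    return ensemble.times, enc.sum(axis=0)


@dataclass
class FrontTrace:
    """Per-cell threshold crossing times and a fitted front speed.

    ``crossing_times[i]`` is NaN when cell ``i`` never crosses; ``speed``
    (cells per time unit) is the least-squares slope of cell index against
    crossing time over ``fit_cells``.
    """

    crossing_times: np.ndarray
    level: float
    mode: str
    fit_cells: np.ndarray | None = None
    speed: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_index": np.arange(1, self.crossing_times.size + 1),
                "crossing_time": self.crossing_times,
            }
        )


def _first_upcross(times: np.ndarray, x: np.ndarray, thr: float) -> float:
    if x[0] >= thr:
        return float(times[0])
    above = x >= thr
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return float("nan")
    k = idx[0]
    frac = (thr - x[k]) / (x[k + 1] - x[k])
    return float(times[k] + frac * (times[k + 1] - times[k]))


def _last_downcross(times: np.ndarray, x: np.ndarray, thr: float) -> float:
    below = x < thr
    idx = np.flatnonzero(~below[:-1] & below[1:])
    if idx.size == 0:
        return float("nan")
    k = idx[-1]
    frac = (x[k] - thr) / (x[k] - x[k + 1])
    return float(times[k] + frac * (times[k + 1] - times[k]))


def track_front(
    result: SimResult,
    level: float = 0.5,
    *,
    x_ref: float | None = None,
    mode: str = "leading",
    fit_cells: np.ndarray | slice | None = None,
) -> FrontTrace:
    """Trace a wavefront through per-cell threshold crossings.

    ``level`` is a fraction of the reference activity ``x_ref`` (default:
    the loaded level recorded in the run config).  The leading front is
    the first up-crossing per cell, the trailing front the last
    down-crossing; crossings are linearly interpolated between time steps.
    """
    if not 0 < level < 1:
        raise DomainError(f"level must lie in (0, 1), got {level}")
    if mode not in ("leading", "trailing"):
        raise DomainError(f"mode must be 'leading' or 'trailing', got {mode!r}")
    ref = x_ref if x_ref is not None else result.config.get("x0")
    if ref is None or ref <= 0:
        raise InputError("no positive reference level available")
    thr = level * ref
    crosser = _first_upcross if mode == "leading" else _last_downcross
    crossings = np.array(
        [crosser(result.times, result.activity[i], thr) for i in range(result.n_cells)]
    )
    trace = FrontTrace(crossing_times=crossings, level=thr, mode=mode)
    if fit_cells is not None:
        cells = (
            np.arange(result.n_cells)[fit_cells]
            if isinstance(fit_cells, slice)
            else np.asarray(fit_cells)
        )
        tt = crossings[cells]
        ok = np.isfinite(tt)
        if ok.sum() >= 2 and np.ptp(tt[ok]) > 0:
            slope = np.polyfit(tt[ok], cells[ok].astype(float), 1)[0]
            trace = dataclasses.replace(trace, fit_cells=cells, speed=float(slope))
        else:
            trace = dataclasses.replace(trace, fit_cells=cells)
    return trace


def front_position(
    result: SimResult,
    level: float = 0.5,
    *,
    x_ref: float | None = None,
    which: str = "leading",
    cells: slice | None = None,
) -> np.ndarray:
    """Front position (cell index) over time.

    The leading-front position is the highest-index cell above threshold,
    the trailing-front position the lowest; NaN when no cell is above.
    """
    ref = x_ref if x_ref is not None else result.config.get("x0")
    if ref is None or ref <= 0:
        raise InputError("no positive reference level available")
    act = result.activity if cells is None else result.activity[cells]
    offset = 0 if cells is None else (cells.start or 0)
    above = act >= level * ref
    pos = np.full(result.times.size, np.nan)
    any_above = above.any(axis=0)
    idx = np.where(
        which == "leading",
        act.shape[0] - 1 - np.argmax(above[::-1], axis=0),
        np.argmax(above, axis=0),
    )
    pos[any_above] = idx[any_above] + offset
    return pos


def readout_cells(config: ChainConfig, n: int = 10) -> np.ndarray:
    """The last ``n`` stimulated (persistent) cells of the chain."""
    return np.arange(config.n_stim - n, config.n_stim)


def success_band(x0: float, eps: float) -> tuple[float, float]:
    """End-of-delay success band ``x0 * [1 - eps, 1 + eps]``."""
    if x0 <= 0 or not 0 < eps:
        raise DomainError("require x0 > 0 and eps > 0")
    return x0 * (1.0 - eps), x0 * (1.0 + eps)


@dataclass(frozen=True)
class TrialOutcome:
    """Comparison decision and end-of-delay success for one trial."""

    decision: str  # "f1_higher" | "f1_lower" | "undecided"
    success: bool
    readout_value: float


def _readout_indices(result: SimResult, readout) -> np.ndarray:
    if readout is not None:
        return np.asarray(readout)
    n_stim = result.config["config"]["n_stim"]
    return np.arange(n_stim - 10, n_stim)


def trial_success(
    result: SimResult,
    band: tuple[float, float],
    readout: np.ndarray | None = None,
) -> bool:
    """Mean readout activity at the end of the delay lies inside ``band``.

    Default readout: the last 10 persistent cells.
    """
    T = result.config["schedule"]["T"]
    value = float(result.at_time(T)[_readout_indices(result, readout)].mean())
    lo, hi = band
    return lo <= value <= hi


def readout_decision(
    result: SimResult,
    schedule: TaskSchedule,
    readout: np.ndarray | None = None,
    atol: float = 1e-6,
) -> str:
    """Comparison decision from the change of readout activity.

    Activity above the second-stimulus separatrix grows (report
    ``f1_higher``), below it decays (``f1_lower``); changes smaller than
    ``atol`` are ``undecided``.  Requires the run to include the
    comparison window.
    """
    if result.times[-1] < schedule.T + schedule.t_cmp_len - 1e-9:
        raise InputError("result does not include the comparison window")
    cells = _readout_indices(result, readout)
    start = float(result.at_time(schedule.T)[cells].mean())
    end = float(result.activity[cells, -1].mean())
    delta = end - start
    if delta > atol:
        return "f1_higher"
    if delta < -atol:
        return "f1_lower"
    return "undecided"


def evaluate_trial(
    result: SimResult,
    schedule: TaskSchedule,
    x0: float,
    eps: float,
    readout: np.ndarray | None = None,
) -> TrialOutcome:
    """Bundle decision, success flag, and readout value for one trial."""
    band = success_band(x0, eps)
    cells = _readout_indices(result, readout)
    value = float(result.at_time(schedule.T)[cells].mean())
    try:
        decision = readout_decision(result, schedule, readout)
    except InputError:
        decision = "undecided"
    return TrialOutcome(
        decision=decision,
        success=bool(band[0] <= value <= band[1]),
        readout_value=value,
    )
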