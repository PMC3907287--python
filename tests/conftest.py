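import numpy as np
import pytest

import decayamp as da

# Acceptance-regime constants: delay of 60 time units, 150 stimulated
# cells out of 170 so the trailing front never reaches the readout block,
# stimulus loaded at the top of the map (x0 = 1.2), 10% resolution band.
SWEEP_T = 60.0
SWEEP_X0 = 1.2
SWEEP_EPS = 0.1
SWEEP_GRID = tuple(np.arange(2.5, SWEEP_T, 2.5))
SWEEP_SIGMAS = (0.03, 0.045)
SWEEP_RATE_SETS = (0.002, 0.0025, 0.003)  # d = a per set
SWEEP_REPS = 200


def sweep_chain(d: float, sigma: float = 0.03) -> da.ChainConfig:
    """Matched-rate (a = d) chain used for the success sweeps."""
    return da.ChainConfig(
        n_cells=170, n_stim=150, g=1.0 - d, c=2.0 * d, sigma=sigma, dt=0.05
    )


@pytest.fixture(scope="session")
def small_chain() -> da.ChainConfig:
    return da.ChainConfig(n_cells=30, n_stim=20, g=0.95, c=0.0, sigma=0.0, dt=0.01)


@pytest.fixture(scope="session")
def default_schedule() -> da.TaskSchedule:
    return da.TaskSchedule()


@pytest.fixture(scope="session")
def sweep_reports():
    """Success sweeps for all rate sets plus the doubled set (shared by the
    timing-interval-recovery and interval-scaling acceptance tests)."""
    reports = {}
    for d in (*SWEEP_RATE_SETS, 2 * SWEEP_RATE_SETS[-1]):
        sigmas = SWEEP_SIGMAS if d in SWEEP_RATE_SETS else SWEEP_SIGMAS[:1]
        spec = da.SweepSpec(
            t_s_grid=SWEEP_GRID,
            sigma_grid=sigmas,
            reps=SWEEP_REPS,
            base_seed=1,
            chain=sweep_chain(d),
            schedule=da.TaskSchedule(T=SWEEP_T, t_exec=SWEEP_T / 2, f1=34.0),
            eps=SWEEP_EPS,
        )
        reports[d] = da.run_success_sweep(spec)
    return reports


def rate_crossings(t_s: np.ndarray, rate: np.ndarray, level: float = 0.5):
    """Interpolated level-crossing locations of a success-rate curve."""
    cross = []
    for i in range(len(rate) - 1):
        if (rate[i] - level) * (rate[i + 1] - level) < 0:
            frac = (level - rate[i]) / (rate[i + 1] - rate[i])
            cross.append(t_s[i] + frac * (t_s[i + 1] - t_s[i]))
    return np.asarray(cross)
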