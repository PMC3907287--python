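"""Structured text (YAML) run configuration with explicit validation.

Schema (every section optional; an empty file yields all defaults)::

    chain:     {n_cells, n_stim, g, c, sigma, dt, tau, feedback_source}
    kernel:    {n_cells, kernel_sd, gbar, c, sigma, dt, tau}
    schedule:  {T, t_exec, t_cmp_len, f1, f2}
    stimulus:  {f_min, f_max, x_lo, x_hi}
    criterion: {f1_values, reps, k_sd, require_monotone}
    eps:       <relative resolution, float in (0, 1)>
    sweep:     {t_s_grid, sigma_grid, reps, readout_n}

Unknown sections or keys raise :class:`ConfigurationError` naming the
offender; value ranges are validated by the underlying dataclasses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import EncodingCriterion
from .dynamics import ChainConfig, KernelConfig, TaskSchedule
from .errors import ConfigurationError
from .gain import StimulusMap

__all__ = ["RunConfig", "load_config", "dump_config"]

_SECTIONS = {
    "chain": ChainConfig,
    "kernel": KernelConfig,
    "schedule": TaskSchedule,
    "stimulus": StimulusMap,
    "criterion": EncodingCriterion,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of every configurable object."""

    chain: ChainConfig = field(default_factory=ChainConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    schedule: TaskSchedule = field(default_factory=TaskSchedule)
    stimulus: StimulusMap = field(default_factory=StimulusMap)
    criterion: EncodingCriterion = field(default_factory=EncodingCriterion)
    eps: float = 0.1
    sweep: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.eps < 1:
            raise ConfigurationError(f"eps must lie in (0, 1), got {self.eps}")

    def to_dict(self) -> dict:
        out = {
            name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS
        }
        out["criterion"]["f1_values"] = list(out["criterion"]["f1_values"])
        out["eps"] = self.eps
        if self.sweep:
            out["sweep"] = dict(self.sweep)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigurationError("config root must be a mapping")
        unknown = set(data) - set(_SECTIONS) - {"eps", "sweep"}
        if unknown:
            raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {}
        for name, klass in _SECTIONS.items():
            if name in data and data[name] is not None:
                kwargs[name] = _build(name, klass, data[name])
        if "eps" in data:
            kwargs["eps"] = float(data["eps"])
        if "sweep" in data and data["sweep"] is not None:
            kwargs["sweep"] = _check_sweep(data["sweep"])
        return cls(**kwargs)


def _build(section: str, klass, payload: dict):
    if not isinstance(payload, dict):
        raise ConfigurationError(f"section '{section}' must be a mapping")
    fields = {f.name for f in dataclasses.fields(klass)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}"
        )
    if section == "criterion" and "f1_values" in payload:
        payload = {**payload, "f1_values": tuple(payload["f1_values"])}
    try:
        return klass(**payload)
    except ConfigurationError as exc:
        raise ConfigurationError(f"section '{section}': {exc}") from exc


_SWEEP_KEYS = {"t_s_grid", "sigma_grid", "reps", "readout_n"}


def _check_sweep(payload: dict) -> dict:
    if not isinstance(payload, dict):
        raise ConfigurationError("section 'sweep' must be a mapping")
    unknown = set(payload) - _SWEEP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown key(s) in section 'sweep': {sorted(unknown)}")
    return dict(payload)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a YAML run config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back out; loading it reproduces ``config`` exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
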