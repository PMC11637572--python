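"""YAML run configuration: schema-checked loading with strict keys.

A run configuration collects the session knobs (block size, epoch cap,
target ladder, GP bounds), an optional simulated cohort definition, and the
seed.  Unknown keys are rejected so typos fail loudly, and every CLI command
writes back a fully resolved "config echo" next to its outputs.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
import yaml

from . import gp, policy, ptta
from .session import BLOCK_SIZE, EPOCH_CAP, STIMULUS_RATE_HZ, SessionConfig
from .simulate import SubjectProfile

_SESSION_KEYS = {
    "block_size",
    "stimulus_rate",
    "epoch_cap",
    "targets",
    "deltas",
    "max_level",
    "n_bootstrap",
    "search_ms",
    "max_sep_ms",
    "rejection_uv",
}
_COHORT_KEYS = {"n_subjects", "profiles"}
_TOP_KEYS = {"seed", "session", "cohort"}


class ConfigError(ValueError):
    """A configuration file violated the schema."""


def _check_keys(d: Mapping[str, Any], allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


def session_config_from_dict(d: Mapping[str, Any] | None) -> SessionConfig:
    """Build a :class:`SessionConfig` from a mapping, defaults filled in."""
    d = dict(d or {})
    _check_keys(d, _SESSION_KEYS, "session")
    schedule = policy.TargetSchedule(
        targets=tuple(d.pop("targets", policy.TARGETS_UV)),
        deltas=tuple(d.pop("deltas", policy.DELTAS_UV)),
        max_level=float(d.pop("max_level", policy.MAX_LEVEL_DB)),
    )
    try:
        return SessionConfig(
            block_size=int(d.get("block_size", BLOCK_SIZE)),
            stimulus_rate=float(d.get("stimulus_rate", STIMULUS_RATE_HZ)),
            epoch_cap=int(d.get("epoch_cap", EPOCH_CAP)),
            schedule=schedule,
            n_bootstrap=int(d.get("n_bootstrap", ptta.N_BOOTSTRAP)),
            search_ms=tuple(d.get("search_ms", ptta.SEARCH_WINDOW_MS)),
            max_sep_ms=float(d.get("max_sep_ms", ptta.MAX_SEPARATION_MS)),
            rejection_uv=float(d.get("rejection_uv", 20.0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_run_config(path) -> dict:
    """Load and validate a YAML run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(data, _TOP_KEYS, "run config")
    if "cohort" in data and data["cohort"] is not None:
        _check_keys(data["cohort"], _COHORT_KEYS, "cohort")
    # validate eagerly so errors surface at load time
    session_config_from_dict(data.get("session"))
    return data


def config_echo(config: SessionConfig, seed: int | None, extra: dict | None = None) -> dict:
    """A fully resolved, serialisable snapshot of the effective settings."""
    echo = {
        "seed": seed,
        "session": {
            "block_size": config.block_size,
            "stimulus_rate": config.stimulus_rate,
            "epoch_cap": config.epoch_cap,
            "targets": list(config.schedule.targets),
            "deltas": list(config.schedule.deltas),
            "max_level": config.schedule.max_level,
            "n_bootstrap": config.n_bootstrap,
            "search_ms": list(config.search_ms),
            "max_sep_ms": config.max_sep_ms,
            "rejection_uv": config.rejection_uv,
        },
        "gp": {
            "s_uv2": config.s,
            "theta_db_bounds": list(config.theta_db_bounds),
            "theta_hz_bounds": list(config.theta_hz_bounds),
            "n_theta_grid": config.n_theta_grid,
            "levels_db": [int(config.grid.levels.min()), int(config.grid.levels.max())],
            "frequencies_hz": [float(f) for f in config.grid.frequencies],
        },
    }
    if extra:
        echo.update(extra)
    return echo


def write_config_echo(path, config: SessionConfig, seed: int | None, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_echo(config, seed, extra), fh, sort_keys=False)
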