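"""Experiment configuration with printed-protocol defaults.

Every replicated protocol has a flat key-value configuration whose
unspecified fields resolve to the published defaults; unknown keys and
out-of-range values are rejected with the offending key named.  Each
resolved value carries provenance ("default" vs "user") so runs can log
exactly what they used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .learning import LearningParams

__all__ = ["ConfigurationError", "RunConfig", "DEFAULTS", "load_config", "save_config"]


class ConfigurationError(ValueError):
    """A configuration key is unknown or its value is out of range."""


_COMMON = {"seed": 0, "out": None}

#: Per-experiment defaults; every field printed in a protocol defaults to
#: the printed value.
DEFAULTS: dict[str, dict[str, Any]] = {
    "cone": dict(
        model="simple_state",
        n_train=50,
        n_replicates=5,
        r=0.5,
        alpha=0.1,
        epsilon=0.8,
        lam=0.01,
        v_update_variant="eq10_m_scaled",
        **_COMMON,
    ),
    "convergence": dict(
        model="gradient",
        motivation_condition="variable",
        r=1.0,
        n_trials=150,
        n_replicates=100,
        alpha=0.1,
        epsilon=0.8,
        lam=0.01,
        **_COMMON,
    ),
    "inductive_bias": dict(
        bins=[4, 10],
        alphas=[0.1, 0.3, 0.5],
        n_trials=400,
        n_replicates=50,
        r=1.0,
        q_utility_variant="second_order",
        **_COMMON,
    ),
    "salt_appetite": dict(
        model="gradient",
        n_train=50,
        n_test=50,
        n_replicates=5,
        r=0.5,
        noise_sd=0.1,
        alpha=0.1,
        epsilon=0.8,
        lam=0.01,
        **_COMMON,
    ),
    "state_valuation": dict(
        model="gradient",
        n_replicates=11,
        train_mean=65.0,
        train_sd=5.5,
        n_test=24,
        r=0.2,
        noise_sd=0.1,
        alpha=0.1,
        epsilon=0.8,
        lam=0.01,
        **_COMMON,
    ),
    "trajectories": dict(
        model="gradient",
        n_trials=1000,
        n_replicates=100,
        r=0.2,
        noise_sd=0.1,
        alpha=0.1,
        epsilon=0.8,
        lam=0.01,
        **_COMMON,
    ),
    "zhang": dict(
        R_depleted=1.0,
        R_balanced=-1.0,
        kappa_up=3.0,
        kappa_down=1.0 / 3.0,
        **_COMMON,
    ),
}

_MODEL_CHOICES = {
    "cone": ("classical_td", "simple_state", "gradient", "payoff_cost"),
    "convergence": ("gradient", "payoff_cost"),
    "salt_appetite": ("gradient", "payoff_cost"),
    "state_valuation": ("gradient", "payoff_cost"),
    "trajectories": ("gradient", "payoff_cost"),
}


def _check_value(experiment: str, key: str, value: Any) -> None:
    def bad(msg: str) -> None:
        raise ConfigurationError(f"{experiment}.{key}: {msg} (got {value!r})")

    positive_counts = {
        "n_train",
        "n_test",
        "n_trials",
        "n_replicates",
    }
    if key in positive_counts:
        if not isinstance(value, int) or isinstance(value, bool) or value < 1:
            bad("must be an integer >= 1")
    elif key == "alpha":
        if not isinstance(value, (int, float)) or not 0 < value <= 1:
            bad("must lie in (0, 1]")
    elif key == "epsilon":
        if not isinstance(value, (int, float)) or not 0 <= value <= 1:
            bad("must lie in [0, 1]")
    elif key == "lam":
        if not isinstance(value, (int, float)) or value < 0:
            bad("must be >= 0")
    elif key in ("r", "train_mean", "train_sd", "noise_sd"):
        if not isinstance(value, (int, float)) or not math.isfinite(value) or value < 0:
            bad("must be a finite number >= 0")
    elif key in ("kappa_up", "kappa_down"):
        if not isinstance(value, (int, float)) or value <= 0:
            bad("must be > 0")
    elif key == "model":
        choices = _MODEL_CHOICES.get(experiment, ())
        if value not in choices:
            bad(f"must be one of {choices}")
    elif key == "seed":
        if not isinstance(value, int) or isinstance(value, bool):
            bad("must be an integer")
    elif key == "bins":
        if not isinstance(value, (list, tuple)) or not all(
            isinstance(b, int) and b >= 1 for b in value
        ):
            bad("must be a list of integers >= 1")
    elif key == "alphas":
        if not isinstance(value, (list, tuple)) or not all(
            isinstance(a, (int, float)) and 0 < a <= 1 for a in value
        ):
            bad("must be a list of rates in (0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved experiment configuration with value provenance."""

    experiment: str
    values: dict[str, Any]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def learning_params(self) -> LearningParams:
        kw = {
            k: self.values[k]
            for k in ("alpha", "epsilon", "lam", "v_update_variant", "q_utility_variant")
            if k in self.values
        }
        return LearningParams(**kw)

    def to_dict(self) -> dict[str, Any]:
        return {"experiment": self.experiment, **self.values}


def load_config(
    experiment: str,
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Resolve a configuration from defaults, an optional file and overrides.

    Later sources win: defaults < config file (YAML / JSON-compatible
    key-value mapping) < explicit overrides.  Unknown keys raise
    :class:`ConfigurationError` naming the key.
    """
    if experiment not in DEFAULTS:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; expected one of {tuple(DEFAULTS)}"
        )
    values = dict(DEFAULTS[experiment])
    provenance = {k: "default" for k in values}

    sources: list[tuple[str, Mapping[str, Any]]] = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        sources.append(("user", loaded))
    if overrides:
        sources.append(("user", overrides))

    for label, mapping in sources:
        for key, value in mapping.items():
            if key == "experiment":
                if value != experiment:
                    raise ConfigurationError(
                        f"config file is for experiment {value!r}, not {experiment!r}"
                    )
                continue
            if key not in values:
                raise ConfigurationError(
                    f"unknown configuration key {key!r} for experiment {experiment!r}"
                )
            if key != "out":
                _check_value(experiment, key, value)
            values[key] = value
            provenance[key] = label
    return RunConfig(experiment=experiment, values=values, provenance=provenance)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as YAML; loading it back reproduces the config."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
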