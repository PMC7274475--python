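"""Trial-level machinery: noisy evaluation, action selection and updates.

A trial presents one or more actions, each with its own motivation (separate
appetitive systems, e.g. sodium vs fructose) and reinforcement magnitude.
The agent computes each available action's thalamic activity from its Go /
Nogo weights and the dopamine level implied by that action's motivation,
adds independent Gaussian exploration noise, and selects either by a
positivity threshold (go / no-go trials) or by picking the most active
option (choice trials).  When an action is taken, the utility of the
obtained reinforcement and the state-dependent prediction error are
computed from the *noise-free* activity — noise models exploration in
selection, not the teaching signal — and, in training phases only, the
chosen action's weights are updated.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .core import (
    PathwayWeights,
    PredictionError,
    bg_rpe,
    motivation_to_dopamine,
    thalamic_activity,
    utility,
)
from .learning import LearningParams, gradient_update, payoff_cost_update

__all__ = [
    "TrialSpec",
    "TrialOutcome",
    "RULES",
    "SELECTION_MODES",
    "evaluate_actions",
    "select_action",
    "run_trial",
]

RULES = ("gradient", "payoff_cost")
SELECTION_MODES = ("threshold", "argmax_positive")


@dataclass(frozen=True)
class TrialSpec:
    """One trial's configuration.

    ``motivation`` and ``reinforcement`` map action ids to that action's
    motivation and reinforcement magnitude; actions absent from
    ``available`` are presented with activity exactly zero and can never
    be chosen.
    """

    available: tuple[str, ...]
    motivation: Mapping[str, float]
    reinforcement: Mapping[str, float]
    phase: str = "training"
    noise_sd: float = 0.0
    selection: str = "threshold"

    def __post_init__(self) -> None:
        if self.phase not in ("training", "testing"):
            raise ValueError(f"phase must be 'training' or 'testing', got {self.phase!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.selection not in SELECTION_MODES:
            raise ValueError(
                f"selection must be one of {SELECTION_MODES}, got {self.selection!r}"
            )
        for a in self.available:
            if a not in self.motivation or a not in self.reinforcement:
                raise ValueError(f"action {a!r} lacks a motivation or reinforcement")
        object.__setattr__(self, "available", tuple(self.available))
        object.__setattr__(self, "motivation", MappingProxyType(dict(self.motivation)))
        object.__setattr__(
            self, "reinforcement", MappingProxyType(dict(self.reinforcement))
        )


@dataclass(frozen=True)
class TrialOutcome:
    """Record of one trial: choice, noisy activities, reinforcement, error."""

    chosen: str | None
    noisy_T: Mapping[str, float]
    r_obtained: float
    U: float | None = None
    delta: PredictionError | None = None

    def __post_init__(self) -> None:
        if self.chosen is None and self.r_obtained != 0.0:
            raise ValueError("no action taken implies zero reinforcement")


def evaluate_actions(
    weights: Mapping[str, PathwayWeights],
    spec: TrialSpec,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Noisy thalamic activity for every action known to the agent.

    Available actions get ``T = D*G - (1-D)*N + Normal(0, noise_sd)`` with
    ``D`` derived from that action's motivation and independent noise per
    action; unavailable actions get exactly zero.
    """
    out: dict[str, float] = {}
    for action, w in weights.items():
        if action not in spec.available:
            out[action] = 0.0
            continue
        D = motivation_to_dopamine(spec.motivation[action])
        T = thalamic_activity(w, D)
        if spec.noise_sd > 0:
            T += rng.normal(0.0, spec.noise_sd)
        out[action] = T
    return out


def select_action(
    noisy_T: Mapping[str, float],
    mode: str = "threshold",
    rng: np.random.Generator | None = None,
) -> str | None:
    """Select an action from noisy activities, or none.

    ``threshold``: act on strictly positive activity (single-action /
    go-no-go trials; with several candidates the most active positive one
    is taken).  ``argmax_positive``: choose the maximising action, or none
    if the maximum is <= 0.  Exact ties are broken uniformly at random.
    """
    if not noisy_T:
        raise ValueError("select_action requires at least one activity")
    if mode not in SELECTION_MODES:
        raise ValueError(f"mode must be one of {SELECTION_MODES}, got {mode!r}")
    best = max(noisy_T.values())
    if best <= 0.0:
        return None
    winners = [a for a, T in noisy_T.items() if T == best]
    if len(winners) == 1:
        return winners[0]
    if rng is None:
        raise ValueError("tie-breaking requires an rng")
    return winners[int(rng.integers(len(winners)))]


def run_trial(
    weights: Mapping[str, PathwayWeights],
    spec: TrialSpec,
    params: LearningParams,
    rule: str,
    rng: np.random.Generator,
) -> tuple[TrialOutcome, dict[str, PathwayWeights]]:
    """Run one trial and return its outcome plus the (possibly updated) weights.

    Only the chosen action's weights can change, and only in the training
    phase; testing-phase weights are frozen.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    noisy = evaluate_actions(weights, spec, rng)
    candidates = {a: noisy[a] for a in spec.available}
    chosen = select_action(candidates, spec.selection, rng) if candidates else None

    new_weights = dict(weights)
    if chosen is None:
        return TrialOutcome(None, noisy, 0.0), new_weights

    m = spec.motivation[chosen]
    r = spec.reinforcement[chosen]
    D = motivation_to_dopamine(m)
    U = utility(m, r)
    T_clean = thalamic_activity(weights[chosen], D)
    delta = bg_rpe(U, T_clean, D)

    if spec.phase == "training":
        if rule == "gradient":
            new_weights[chosen] = gradient_update(weights[chosen], delta, D, params.alpha)
        else:
            new_weights[chosen] = payoff_cost_update(weights[chosen], delta, params)

    return TrialOutcome(chosen, noisy, r, U=U, delta=delta), new_weights
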