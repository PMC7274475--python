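"""Weight and value update rules.

Four learners share the prediction errors defined in :mod:`bgmotiv.core`:

* a classical temporal-difference value learner (``td_update``),
* a state-dependent scalar value learner (``state_value_update``), with two
  variants of the update magnitude,
* the *gradient* model, which performs gradient ascent on ``-delta**2/2``
  with respect to the Go and Nogo weights (``gradient_update``),
* the *payoff-cost* model, a biologically motivated approximation with
  asymmetric error sensitivity and weight decay (``payoff_cost_update``),

plus a discretised Q-learning baseline over motivation bins (``QTable``,
``q_update``) used to demonstrate the inductive bias of the basal-ganglia
parameterisation.

Synaptic weights cannot be negative: any update that would drive ``G`` or
``N`` below zero clips it at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import PathwayWeights, PredictionError, simple_state_rpe

__all__ = [
    "LearningParams",
    "QTable",
    "V_UPDATE_VARIANTS",
    "Q_UTILITY_VARIANTS",
    "td_update",
    "state_value_update",
    "gradient_update",
    "payoff_cost_update",
    "bin_index",
    "q_update",
]

V_UPDATE_VARIANTS = ("eq10_m_scaled", "methods_plain")
Q_UTILITY_VARIANTS = ("second_order", "first_order")


@dataclass(frozen=True)
class LearningParams:
    """Learning-rule parameters.

    Parameters
    ----------
    alpha
        Learning rate, > 0 (0.1 in all replicated protocols).
    epsilon
        Attenuation of the weight change driven by prediction errors of the
        "wrong" sign in the payoff-cost model, in [0, 1] (default 0.8).
    lam
        Multiplicative weight decay of the payoff-cost model, >= 0
        (default 0.01).
    v_update_variant
        How the scalar value learner scales its update: ``eq10_m_scaled``
        uses ``dV = alpha * m * delta`` (the gradient of the objective),
        ``methods_plain`` uses ``dV = alpha * delta``.
    q_utility_variant
        Which utility the Q-learning baseline is trained on:
        ``second_order`` (``m*r - r**2/2``) or ``first_order`` (``m*r``).
    """

    alpha: float = 0.1
    epsilon: float = 0.8
    lam: float = 0.01
    v_update_variant: str = "eq10_m_scaled"
    q_utility_variant: str = "second_order"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (math.isfinite(self.epsilon) and 0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if not (math.isfinite(self.lam) and self.lam >= 0.0):
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.v_update_variant not in V_UPDATE_VARIANTS:
            raise ValueError(
                f"unknown v_update_variant {self.v_update_variant!r}; "
                f"expected one of {V_UPDATE_VARIANTS}"
            )
        if self.q_utility_variant not in Q_UTILITY_VARIANTS:
            raise ValueError(
                f"unknown q_utility_variant {self.q_utility_variant!r}; "
                f"expected one of {Q_UTILITY_VARIANTS}"
            )


def _as_delta(delta: PredictionError | float) -> float:
    return float(delta)


def td_update(V: float, r: float, alpha: float) -> float:
    """Classical value update ``V + alpha * (r - V)``."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    return V + alpha * (r - V)


def state_value_update(
    V: float,
    m: float,
    r: float,
    alpha: float,
    variant: str = "eq10_m_scaled",
) -> float:
    """State-dependent value update driven by ``delta = m*r - m*V``.

    ``eq10_m_scaled`` applies ``dV = alpha * m * delta`` (the gradient of
    ``-delta**2/2`` with respect to ``V``); ``methods_plain`` applies
    ``dV = alpha * delta``.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    delta = simple_state_rpe(m, r, V).delta
    if variant == "eq10_m_scaled":
        return V + alpha * m * delta
    if variant == "methods_plain":
        return V + alpha * delta
    raise ValueError(
        f"unknown variant {variant!r}; expected one of {V_UPDATE_VARIANTS}"
    )


def gradient_update(
    w: PathwayWeights,
    delta: PredictionError | float,
    D: float,
    alpha: float,
) -> PathwayWeights:
    """Gradient-ascent update of the Go / Nogo weights.

    ``dG = alpha * delta * D/(1-D)`` and ``dN = -alpha * delta``; the factor
    ``D/(1-D)`` equals the motivation ``m``, so only the Go term is scaled
    by motivational state.  Results are clipped at zero.
    """
    if not 0.0 <= D < 1.0:
        raise ValueError(f"dopamine level must lie in [0, 1), got D={D}")
    d = _as_delta(delta)
    G = w.G + alpha * d * D / (1.0 - D)
    N = w.N - alpha * d
    return PathwayWeights(max(G, 0.0), max(N, 0.0))


def payoff_cost_update(
    w: PathwayWeights,
    delta: PredictionError | float,
    params: LearningParams,
) -> PathwayWeights:
    """Payoff-cost update with asymmetric error sensitivity and decay.

    ``dG = alpha * f_eps(delta) - lam * G`` and
    ``dN = alpha * f_eps(-delta) - lam * N`` with
    ``f_eps(x) = x`` for ``x > 0`` and ``eps * x`` otherwise, so Go weights
    mostly track positive and Nogo weights negative prediction errors.
    Results are clipped at zero.
    """
    d = _as_delta(delta)

    def f_eps(x: float) -> float:
        return x if x > 0 else params.epsilon * x

    G = w.G + params.alpha * f_eps(d) - params.lam * w.G
    N = w.N + params.alpha * f_eps(-d) - params.lam * w.N
    return PathwayWeights(max(G, 0.0), max(N, 0.0))


# ---------------------------------------------------------------------------
# Discretised Q-learning baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTable:
    """Per-bin utility estimates over a bounded motivation range.

    The motivation axis is split into equal-width, left-closed bins; the top
    bin is closed on both sides so the upper boundary maps to the last bin.
    """

    edges: tuple[float, ...]
    values: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
        values = self.values or (0.0,) * (len(edges) - 1)
        if len(values) != len(edges) - 1:
            raise ValueError(
                f"expected {len(edges) - 1} values, got {len(values)}"
            )
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    @classmethod
    def uniform(cls, n_bins: int, lo: float = 0.0, hi: float = 2.0) -> "QTable":
        """Equal-width table of ``n_bins`` bins covering ``[lo, hi]``."""
        if n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {n_bins}")
        edges = tuple(np.linspace(lo, hi, n_bins + 1))
        return cls(edges=edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def bin_index(m: float, table: QTable) -> int:
    """Index of the half-open bin ``[lo, hi)`` containing ``m``.

    The top bin is closed, so ``m`` equal to the upper boundary maps to the
    last bin.  Values outside the table's range are rejected.
    """
    lo, hi = table.edges[0], table.edges[-1]
    if not lo <= m <= hi:
        raise ValueError(f"m={m} outside the table range [{lo}, {hi}]")
    if m == hi:
        return table.n_bins - 1
    return int(np.searchsorted(table.edges, m, side="right") - 1)


def q_update(table: QTable, m: float, U: float, alpha: float) -> QTable:
    """Update the estimate of the bin containing ``m`` by ``alpha*(U - Q_m)``."""
    i = bin_index(m, table)
    values = list(table.values)
    values[i] += alpha * (U - values[i])
    return replace(table, values=tuple(values))
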