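"""Scalar algebra of motivation-dependent utility and basal-ganglia output.

The framework models a single physiological resource (e.g. sodium reserve)
with current level ``S`` and a set point ``S*``.  The *motivation* for the
resource is the deficit ``m = S* - S``.  The desirability of a state is a
concave quadratic, ``Y(S) = -(S - S*)^2 / 2``, maximal at the set point, so
consuming a reinforcement of magnitude ``r`` (which moves the state from
``S`` to ``S + r``) changes desirability by the *utility*

    U = m*r - r**2 / 2.

The first term is the motivation-scaled payoff; the second is the overshoot
cost, independent of motivation.  A first-order approximation ``U ~ m*r`` is
also provided.

In the basal-ganglia implementation, per-action Go (direct pathway) and
Nogo (indirect pathway) cortico-striatal weights ``G`` and ``N`` estimate the
two terms (``G -> r``, ``N -> r**2/2``), a tonic dopaminergic activation
signal ``D = m / (1 + m)`` arbitrates between the pathways, and the thalamic
output ``T = D*G - (1 - D)*N`` equals ``(1 - D) * U`` once the weights are
fully learned.  Dividing by ``1 - D`` recovers the expected utility, which
enters the state-dependent reward prediction error ``delta = U - T/(1 - D)``
carried by the dopaminergic teaching signal.

All quantities are dimensionless scalars; no unit system is implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MotivationalState",
    "PathwayWeights",
    "PredictionError",
    "RPE_VARIANTS",
    "desirability",
    "motivation",
    "utility_first_order",
    "utility",
    "motivation_to_dopamine",
    "dopamine_to_motivation",
    "thalamic_activity",
    "expected_utility",
    "classical_rpe",
    "simple_state_rpe",
    "bg_rpe",
]

#: Recognised reward-prediction-error variants.
RPE_VARIANTS = ("classical_td", "simple_state", "basal_ganglia")


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotivationalState:
    """A physiological state and the motivation it induces.

    Parameters
    ----------
    m
        Motivation, the deficit ``S* - S``.  May be negative (overshoot),
        but the dopaminergic mapping is only defined for ``m >= 0``.
    S, S_star
        Optional underlying resource level and set point.  When both are
        given they must be consistent with ``m``.
    """

    m: float
    S: float | None = None
    S_star: float | None = None

    def __post_init__(self) -> None:
        _require_finite(m=self.m)
        if self.S is not None and self.S_star is not None:
            _require_finite(S=self.S, S_star=self.S_star)
            if not math.isclose(self.m, self.S_star - self.S, abs_tol=1e-12):
                raise ValueError(
                    f"inconsistent state: m={self.m} but S*-S="
                    f"{self.S_star - self.S}"
                )

    @classmethod
    def from_levels(cls, S: float, S_star: float) -> "MotivationalState":
        return cls(m=motivation(S, S_star), S=S, S_star=S_star)

    @classmethod
    def from_dopamine(cls, D: float) -> "MotivationalState":
        return cls(m=dopamine_to_motivation(D))

    @property
    def D(self) -> float:
        """Dopaminergic activation signal ``m / (1 + m)``; requires m >= 0."""
        return motivation_to_dopamine(self.m)


@dataclass(frozen=True)
class PathwayWeights:
    """Non-negative Go / Nogo cortico-striatal weights for one action."""

    G: float
    N: float

    def __post_init__(self) -> None:
        _require_finite(G=self.G, N=self.N)
        if self.G < 0 or self.N < 0:
            raise ValueError(f"pathway weights must be >= 0, got G={self.G}, N={self.N}")


@dataclass(frozen=True)
class PredictionError:
    """A signed prediction error together with the definition that produced it."""

    delta: float
    variant: str = field(default="basal_ganglia")

    def __post_init__(self) -> None:
        _require_finite(delta=self.delta)
        object.__setattr__(self, "delta", float(self.delta))
        if self.variant not in RPE_VARIANTS:
            raise ValueError(
                f"unknown prediction-error variant {self.variant!r}; "
                f"expected one of {RPE_VARIANTS}"
            )

    def __float__(self) -> float:
        return self.delta


# ---------------------------------------------------------------------------
# Desirability, motivation and utility
# ---------------------------------------------------------------------------


def desirability(S: float, S_star: float) -> float:
    """Desirability ``Y(S) = -(S - S*)**2 / 2`` of resource level ``S``.

    Maximal (zero) exactly at the set point; symmetric about it.
    """
    _require_finite(S=S, S_star=S_star)
    return -0.5 * (S - S_star) ** 2


def motivation(S: float, S_star: float) -> float:
    """Motivation ``m = S* - S``; negative when the set point is overshot."""
    _require_finite(S=S, S_star=S_star)
    return S_star - S


def utility_first_order(m: float, r: float) -> float:
    """First-order (linear) utility approximation ``U ~ m * r``.

    Accurate for small reinforcements; ignores the overshoot cost.
    """
    _require_finite(m=m, r=r)
    return m * r


def utility(m: float, r: float) -> float:
    """Exact utility ``U = m*r - r**2/2`` of consuming reinforcement ``r``.

    Equal to the change in quadratic desirability:
    ``Y(S + r) - Y(S)`` with ``m = S* - S``.  Zero when ``r = 2*m``
    (symmetric overshoot), negative beyond.
    """
    _require_finite(m=m, r=r)
    return m * r - 0.5 * r * r


# ---------------------------------------------------------------------------
# Dopamine <-> motivation mappings
# ---------------------------------------------------------------------------


def motivation_to_dopamine(m: float) -> float:
    """Dopaminergic activation signal ``D = m / (1 + m)`` for ``m >= 0``.

    Strictly increasing, mapping ``[0, inf)`` onto ``[0, 1)``: unbounded
    motivation is represented within the bounded firing range of
    dopaminergic neurons.
    """
    _require_finite(m=m)
    if m < 0:
        raise ValueError(f"dopamine mapping requires m >= 0, got m={m}")
    return m / (1.0 + m)


def dopamine_to_motivation(D: float) -> float:
    """Motivation ``m = D / (1 - D)`` encoded by activation signal ``D``."""
    _require_finite(D=D)
    if not 0.0 <= D < 1.0:
        raise ValueError(f"dopamine level must lie in [0, 1), got D={D}")
    return D / (1.0 - D)


# ---------------------------------------------------------------------------
# Basal-ganglia output
# ---------------------------------------------------------------------------


def thalamic_activity(w: PathwayWeights, D: float) -> float:
    """Thalamic (basal-ganglia output) activity ``T = D*G - (1 - D)*N``.

    Dopamine facilitates the Go pathway and suppresses the Nogo pathway;
    at the baseline level ``D = 0.5`` both contribute equally.
    Non-decreasing in ``D`` since ``dT/dD = G + N >= 0``.
    """
    _require_finite(D=D)
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"dopamine level must lie in [0, 1], got D={D}")
    return D * w.G - (1.0 - D) * w.N


def expected_utility(T: float, D: float) -> float:
    """Expected utility ``T / (1 - D)`` read out from thalamic activity.

    ``D = 1`` (unbounded motivation) is rejected rather than clamped.
    """
    _require_finite(T=T, D=D)
    if not 0.0 <= D < 1.0:
        raise ValueError(f"dopamine level must lie in [0, 1), got D={D}")
    return T / (1.0 - D)


# ---------------------------------------------------------------------------
# Reward prediction errors
# ---------------------------------------------------------------------------


def classical_rpe(r: float, V_next: float, V: float) -> PredictionError:
    """State-independent temporal-difference error ``r + V' - V``."""
    _require_finite(r=r, V_next=V_next, V=V)
    return PredictionError(r + V_next - V, variant="classical_td")


def simple_state_rpe(m: float, r: float, V: float) -> PredictionError:
    """State-dependent error ``m*r - m*V`` for a scalar value learner.

    The first-order utility of the obtained reinforcement minus the
    motivation-scaled expectation; reduces to the classical US-time error
    at ``m = 1``.
    """
    _require_finite(m=m, r=r, V=V)
    return PredictionError(m * r - m * V, variant="simple_state")


def bg_rpe(U: float, T: float, D: float) -> PredictionError:
    """State-dependent error ``U - T/(1 - D)`` of the basal-ganglia model.

    Utility of the obtained reinforcement minus the expected utility
    decoded from the thalamic output.  At baseline dopamine (``D = 0.5``)
    this reduces to ``U - (G - N)``.
    """
    _require_finite(U=U)
    return PredictionError(U - expected_utility(T, D), variant="basal_ganglia")
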