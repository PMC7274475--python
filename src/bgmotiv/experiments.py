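"""Turn-key replications of the framework's simulation experiments.

Each runner parameterises a published conditioning or choice protocol with
its printed defaults and returns a tidy long-format table with columns
``(experiment, condition, replicate, trial, phase, quantity, value)``.
Summary-level quantities (final weights, counts, proportions) use
``trial = -1`` and ``phase = "summary"``.

Experiments
-----------
``run_cone``
    CS / US dopaminergic teaching-signal readouts after training and
    testing in sodium-balanced vs -depleted states, for four model
    variants (the conditioning study the state-dependent error was built
    to explain).
``run_weight_convergence``
    Go / Nogo weight trajectories under variable or fixed motivation for
    a grid of reinforcement magnitudes.
``run_inductive_bias``
    Learning-speed comparison between the gradient model and discretised
    Q-learning over motivation bins.
``run_salt_appetite``
    Go / no-go responding to a sodium-paired (CS+) and fructose-paired
    (CS-) cue, tested salt-deprived vs balanced.
``run_state_dependent_valuation``
    Y-maze forced-choice training under hunger vs satiety, free-choice
    testing in both states.
``run_go_weight_trajectories``
    Long-run Go-weight growth at high vs low motivation.
``run_zhang``
    The additive incentive-salience model evaluated on the same four
    train/test conditions, for comparison.

Reproducibility: every source of randomness is a ``numpy`` generator
seeded as ``SeedSequence([seed, *subkeys])``, so any replicate can be
re-run in isolation and aggregates do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import TrialSpec, run_trial
from .core import (
    PathwayWeights,
    bg_rpe,
    expected_utility,
    motivation_to_dopamine,
    simple_state_rpe,
    thalamic_activity,
    utility,
    utility_first_order,
)
from .learning import (
    LearningParams,
    QTable,
    bin_index,
    gradient_update,
    payoff_cost_update,
    q_update,
    state_value_update,
    td_update,
)

__all__ = [
    "CONE_MODELS",
    "CSUSReadout",
    "replicate_rng",
    "run_cone_condition",
    "run_cone",
    "run_weight_convergence",
    "run_inductive_bias",
    "trials_to_criterion",
    "run_salt_appetite",
    "run_state_dependent_valuation",
    "run_go_weight_trajectories",
    "zhang_additive_utility",
    "zhang_multiplicative_utility",
    "run_zhang",
]

RESULT_COLUMNS = (
    "experiment",
    "condition",
    "replicate",
    "trial",
    "phase",
    "quantity",
    "value",
)

CONE_MODELS = ("classical_td", "simple_state", "gradient", "payoff_cost")

#: Motivation levels used throughout: near-balanced and depleted states.
M_BALANCED = 0.2
M_DEPLETED = 2.0

INIT_WEIGHT = 0.1


def replicate_rng(seed: int, *subkeys: int) -> np.random.Generator:
    """Independent generator for one replicate of one experiment.

    The stream is ``SeedSequence([seed, *subkeys])``; a replicate is
    reproducible in isolation from the root seed and its index.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, subkeys)]))


def _frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df["value"] = df["value"].astype(float)
    return df


# ---------------------------------------------------------------------------
# CS / US teaching-signal readouts (state-dependent conditioning)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CSUSReadout:
    """Teaching-signal values at CS and US time for one train/test condition."""

    cs_response: float
    us_response: float
    condition: tuple[str, str]


def _state_label(m: float) -> str:
    return "depleted" if m == M_DEPLETED else "balanced"


def run_cone_condition(
    model: str,
    m_train: float,
    m_test: float,
    *,
    n_train: int = 50,
    r: float = 0.5,
    params: LearningParams | None = None,
) -> CSUSReadout:
    """Train in one motivational state, test in another; read out CS and US.

    Value-based models learn a scalar ``V`` over ``n_train`` trials and
    report ``CS = m_test * V`` and ``US = m_test*r - m_test*V`` (the
    classical TD model uses ``m = 1`` throughout, making it
    state-independent).  Basal-ganglia models learn Go / Nogo weights on
    forced trials and report ``CS = T/(1-D_test)`` (the expected utility)
    and ``US = U(m_test, r) - T/(1-D_test)``.  Noise-free, hence
    deterministic.
    """
    if model not in CONE_MODELS:
        raise ValueError(f"model must be one of {CONE_MODELS}, got {model!r}")
    params = params or LearningParams()
    condition = (_state_label(m_train), _state_label(m_test))

    if model == "classical_td":
        V = 0.0
        for _ in range(n_train):
            V = td_update(V, r, params.alpha)
        return CSUSReadout(cs_response=V, us_response=r - V, condition=condition)

    if model == "simple_state":
        V = 0.0
        for _ in range(n_train):
            V = state_value_update(V, m_train, r, params.alpha, params.v_update_variant)
        return CSUSReadout(
            cs_response=m_test * V,
            us_response=simple_state_rpe(m_test, r, V).delta,
            condition=condition,
        )

    # basal-ganglia rules: forced single-action training, frozen test
    w = PathwayWeights(INIT_WEIGHT, INIT_WEIGHT)
    D_train = motivation_to_dopamine(m_train)
    U_train = utility(m_train, r)
    for _ in range(n_train):
        delta = bg_rpe(U_train, thalamic_activity(w, D_train), D_train)
        if model == "gradient":
            w = gradient_update(w, delta, D_train, params.alpha)
        else:
            w = payoff_cost_update(w, delta, params)
    D_test = motivation_to_dopamine(m_test)
    T_test = thalamic_activity(w, D_test)
    return CSUSReadout(
        cs_response=expected_utility(T_test, D_test),
        us_response=bg_rpe(utility(m_test, r), T_test, D_test).delta,
        condition=condition,
    )


def run_cone(
    model: str,
    seed: int = 0,
    *,
    n_train: int = 50,
    n_replicates: int = 5,
    r: float = 0.5,
    m_balanced: float = M_BALANCED,
    m_depleted: float = M_DEPLETED,
    params: LearningParams | None = None,
) -> pd.DataFrame:
    """All four train/test state combinations, per replicate.

    The protocol is noise-free, so replicates are identical by design
    (matching the published zero error bars); they are still emitted so
    the result schema is uniform across experiments.
    """
    rows = []
    for m_train in (m_balanced, m_depleted):
        for m_test in (m_balanced, m_depleted):
            out = run_cone_condition(
                model, m_train, m_test, n_train=n_train, r=r, params=params
            )
            cond = f"train_{out.condition[0]}_test_{out.condition[1]}"
            for rep in range(n_replicates):
                for quantity, value in (
                    ("cs_response", out.cs_response),
                    ("us_response", out.us_response),
                ):
                    rows.append(
                        dict(
                            experiment="cone",
                            condition=cond,
                            replicate=rep,
                            trial=-1,
                            phase="summary",
                            quantity=quantity,
                            value=value,
                        )
                    )
    return _frame(rows)


# ---------------------------------------------------------------------------
# Weight convergence under variable / fixed motivation
# ---------------------------------------------------------------------------

MOTIVATION_CONDITIONS = {
    "variable": None,  # drawn per trial from {0, 1, 2}
    "low": 0.0,
    "baseline": 1.0,
    "high": 2.0,
}


def run_weight_convergence(
    rule: str,
    motivation_condition: str = "variable",
    r: float = 1.0,
    seed: int = 0,
    *,
    n_trials: int = 150,
    n_replicates: int = 100,
    params: LearningParams | None = None,
) -> pd.DataFrame:
    """Forced-trial Go / Nogo learning for one reinforcement magnitude.

    Every trial the single action is taken (no selection step, no noise):
    the protocol isolates the plasticity rules.  Under variable motivation
    the gradient model's weights converge to ``(r, r**2/2)``; the
    payoff-cost model's decay leaves them strictly lower.
    """
    if motivation_condition not in MOTIVATION_CONDITIONS:
        raise ValueError(
            f"motivation_condition must be one of {tuple(MOTIVATION_CONDITIONS)}, "
            f"got {motivation_condition!r}"
        )
    params = params or LearningParams()
    fixed_m = MOTIVATION_CONDITIONS[motivation_condition]
    rows = []
    for rep in range(n_replicates):
        rng = replicate_rng(seed, 1, rep)
        w = PathwayWeights(INIT_WEIGHT, INIT_WEIGHT)
        for t in range(n_trials):
            m = fixed_m if fixed_m is not None else float(rng.integers(3))
            D = motivation_to_dopamine(m)
            delta = bg_rpe(utility(m, r), thalamic_activity(w, D), D)
            if rule == "gradient":
                w = gradient_update(w, delta, D, params.alpha)
            elif rule == "payoff_cost":
                w = payoff_cost_update(w, delta, params)
            else:
                raise ValueError(f"unknown rule {rule!r}")
            for quantity, value in (("G", w.G), ("N", w.N)):
                rows.append(
                    dict(
                        experiment="convergence",
                        condition=f"{rule}_{motivation_condition}_r{r}",
                        replicate=rep,
                        trial=t,
                        phase="training",
                        quantity=quantity,
                        value=value,
                    )
                )
    return _frame(rows)


# ---------------------------------------------------------------------------
# Inductive bias: gradient model vs discretised Q-learning
# ---------------------------------------------------------------------------


def run_inductive_bias(
    seed: int = 0,
    *,
    n_bins: tuple[int, ...] = (4, 10),
    alphas: tuple[float, ...] = (0.1, 0.3, 0.5),
    n_trials: int = 400,
    n_replicates: int = 50,
    r: float = 1.0,
    q_utility_variant: str = "second_order",
) -> pd.DataFrame:
    """Learning-speed comparison on a shared motivation stream.

    Per trial, motivation is uniform on (0, 2) and reinforcement ``r`` is
    received.  The gradient model exploits the known form of the utility;
    Q-learning estimates it per motivation bin and pays for discretisation
    both in speed (each bin is updated on a fraction of trials) and in an
    asymptotic error floor (within-bin spread of the utility).  All
    learners at all learning rates see identical motivation draws per
    replicate (common random numbers).

    Returns per-trial replicate means of the signed prediction error and
    its absolute value, one condition per ``(learner, alpha)``.
    """
    if q_utility_variant == "second_order":
        util = utility
    elif q_utility_variant == "first_order":
        util = utility_first_order
    else:
        raise ValueError(f"unknown q_utility_variant {q_utility_variant!r}")

    learners = ["gradient"] + [f"q{b}" for b in n_bins]
    sums: dict[tuple[str, float], np.ndarray] = {}
    abs_sums: dict[tuple[str, float], np.ndarray] = {}
    for learner in learners:
        for alpha in alphas:
            sums[(learner, alpha)] = np.zeros(n_trials)
            abs_sums[(learner, alpha)] = np.zeros(n_trials)

    for rep in range(n_replicates):
        rng = replicate_rng(seed, 2, rep)
        ms = rng.uniform(0.0, 2.0, size=n_trials)
        for alpha in alphas:
            w = PathwayWeights(INIT_WEIGHT, INIT_WEIGHT)
            for t, m in enumerate(ms):
                D = motivation_to_dopamine(m)
                delta = bg_rpe(util(m, r), thalamic_activity(w, D), D)
                sums[("gradient", alpha)][t] += delta.delta
                abs_sums[("gradient", alpha)][t] += abs(delta.delta)
                w = gradient_update(w, delta, D, alpha)
            for b in n_bins:
                table = QTable.uniform(b)
                for t, m in enumerate(ms):
                    U = util(m, r)
                    d = U - table.values[bin_index(m, table)]
                    sums[(f"q{b}", alpha)][t] += d
                    abs_sums[(f"q{b}", alpha)][t] += abs(d)
                    table = q_update(table, m, U, alpha)

    rows = []
    for (learner, alpha), s in sums.items():
        a = abs_sums[(learner, alpha)]
        for t in range(n_trials):
            cond = f"{learner}_alpha{alpha}"
            rows.append(
                dict(
                    experiment="inductive_bias",
                    condition=cond,
                    replicate=0,
                    trial=t,
                    phase="training",
                    quantity="mean_delta",
                    value=s[t] / n_replicates,
                )
            )
            rows.append(
                dict(
                    experiment="inductive_bias",
                    condition=cond,
                    replicate=0,
                    trial=t,
                    phase="training",
                    quantity="mean_abs_delta",
                    value=a[t] / n_replicates,
                )
            )
    return _frame(rows)


def trials_to_criterion(
    abs_delta_curve: np.ndarray,
    tol: float = 0.2,
    window: int = 20,
) -> int | None:
    """First trial whose trailing ``window``-mean of |delta| drops below ``tol``.

    Returns a 1-based trial count, or None if the criterion is never met.
    The tolerance sits above the discretisation floor of a 4-bin Q table
    at unit reinforcement (~0.125), so all learners can reach it.
    """
    curve = np.asarray(abs_delta_curve, dtype=float)
    for t in range(len(curve)):
        lo = max(0, t - window + 1)
        if curve[lo : t + 1].mean() < tol:
            return t + 1
    return None


# ---------------------------------------------------------------------------
# Salt appetite: go / no-go responding to CS+ and CS-
# ---------------------------------------------------------------------------


def run_salt_appetite(
    rule: str,
    seed: int = 0,
    *,
    n_train: int = 50,
    n_test: int = 50,
    n_replicates: int = 5,
    r: float = 0.5,
    noise_sd: float = 0.1,
    m_cs_plus_train: float = M_BALANCED,
    m_cs_minus: float = 0.1,
    m_depleted: float = M_DEPLETED,
    m_balanced: float = M_BALANCED,
    params: LearningParams | None = None,
) -> pd.DataFrame:
    """Salt-appetite protocol: train balanced, test balanced vs depleted.

    A sodium-paired cue (CS+) and a fructose-paired cue (CS-) are trained
    independently in the near-balanced state (CS+ at m=0.2, CS- at m=0.1,
    reflecting separate appetitive systems).  At test the weights are
    frozen; sodium depletion raises only the CS+ motivation to m=2 while
    the CS- motivation stays at 0.1 in both test states.  The readout is
    the number of test trials with positive noisy thalamic activity.
    """
    params = params or LearningParams()
    rows = []
    stimuli = {"cs_plus": m_cs_plus_train, "cs_minus": m_cs_minus}
    test_m = {
        ("cs_plus", "depleted"): m_depleted,
        ("cs_plus", "balanced"): m_balanced,
        ("cs_minus", "depleted"): m_cs_minus,
        ("cs_minus", "balanced"): m_cs_minus,
    }
    for rep in range(n_replicates):
        rng = replicate_rng(seed, 3, rep)
        learned: dict[str, PathwayWeights] = {}
        for stim, m_train in stimuli.items():
            weights = {stim: PathwayWeights(INIT_WEIGHT, INIT_WEIGHT)}
            spec = TrialSpec(
                available=(stim,),
                motivation={stim: m_train},
                reinforcement={stim: r},
                phase="training",
                noise_sd=noise_sd,
                selection="threshold",
            )
            for _ in range(n_train):
                _, weights = run_trial(weights, spec, params, rule, rng)
            learned[stim] = weights[stim]
            for quantity, value in (("G_final", weights[stim].G), ("N_final", weights[stim].N)):
                rows.append(
                    dict(
                        experiment="salt_appetite",
                        condition=stim,
                        replicate=rep,
                        trial=-1,
                        phase="summary",
                        quantity=quantity,
                        value=value,
                    )
                )
        for (stim, state), m in test_m.items():
            weights = {stim: learned[stim]}
            spec = TrialSpec(
                available=(stim,),
                motivation={stim: m},
                reinforcement={stim: r},
                phase="testing",
                noise_sd=noise_sd,
                selection="threshold",
            )
            count = 0
            for _ in range(n_test):
                outcome, weights = run_trial(weights, spec, params, rule, rng)
                count += outcome.chosen is not None
            rows.append(
                dict(
                    experiment="salt_appetite",
                    condition=f"{stim}_{state}",
                    replicate=rep,
                    trial=-1,
                    phase="summary",
                    quantity="action_count",
                    value=float(count),
                )
            )
    return _frame(rows)


# ---------------------------------------------------------------------------
# State-dependent valuation (Y-maze choice)
# ---------------------------------------------------------------------------


def _train_option(
    rule: str,
    m: float,
    n_trials: int,
    r: float,
    noise_sd: float,
    params: LearningParams,
    rng: np.random.Generator,
    record_G: list[float] | None = None,
    init: PathwayWeights = PathwayWeights(INIT_WEIGHT, 0.0),
) -> PathwayWeights:
    """Forced-choice training of one option at a fixed motivation."""
    weights = {"opt": init}
    spec = TrialSpec(
        available=("opt",),
        motivation={"opt": m},
        reinforcement={"opt": r},
        phase="training",
        noise_sd=noise_sd,
        selection="threshold",
    )
    for _ in range(n_trials):
        _, weights = run_trial(weights, spec, params, rule, rng)
        if record_G is not None:
            record_G.append(weights["opt"].G)
    return weights["opt"]


def run_state_dependent_valuation(
    rule: str,
    seed: int = 0,
    *,
    n_replicates: int = 11,
    train_mean: float = 65.0,
    train_sd: float = 5.5,
    n_test: int = 24,
    r: float = 0.2,
    noise_sd: float = 0.1,
    m_hungry: float = M_DEPLETED,
    m_sated: float = M_BALANCED,
    params: LearningParams | None = None,
    init: PathwayWeights = PathwayWeights(INIT_WEIGHT, 0.0),
) -> pd.DataFrame:
    """Preference for the option trained under hunger, tested in both states.

    Training is forced-choice: one option is reinforced while hungry
    (m=2), the other while sated (m=0.2); each replicate's training length
    is drawn from Normal(65, 5.5), rounded, floored at 1.  At test both
    options are evaluated at the current (shared) motivation with
    exploration noise and frozen weights.  Two readouts are reported per
    test state: the proportion of ``n_test`` trials on which the
    hunger-trained option wins the argmax, and the fraction of positive-
    activity events attributable to it.

    Go weights start at 0.1 and Nogo weights at 0 by default.  Gradient
    updates at fixed motivation conserve ``G + m*N``, so a non-zero
    initial Nogo weight is partially retained by the hunger-trained
    option and reverses the published sated-test preference; the zero
    Nogo start reproduces it.
    """
    params = params or LearningParams()
    rows = []
    for rep in range(n_replicates):
        rng = replicate_rng(seed, 4, rep)
        n_train = max(1, int(round(rng.normal(train_mean, train_sd))))
        w_hunger = _train_option(rule, m_hungry, n_train, r, noise_sd, params, rng, init=init)
        w_sated = _train_option(rule, m_sated, n_train, r, noise_sd, params, rng, init=init)
        for cond, w in (("hunger_trained", w_hunger), ("sated_trained", w_sated)):
            for quantity, value in (("G_final", w.G), ("N_final", w.N)):
                rows.append(
                    dict(
                        experiment="state_valuation",
                        condition=cond,
                        replicate=rep,
                        trial=-1,
                        phase="summary",
                        quantity=quantity,
                        value=value,
                    )
                )
        weights = {"hunger": w_hunger, "sated": w_sated}
        for state, m_test in (("hungry", m_hungry), ("sated", m_sated)):
            spec = TrialSpec(
                available=("hunger", "sated"),
                motivation={"hunger": m_test, "sated": m_test},
                reinforcement={"hunger": r, "sated": r},
                phase="testing",
                noise_sd=noise_sd,
                selection="argmax_positive",
            )
            chosen_hunger = 0
            n_chosen = 0
            pos = {"hunger": 0, "sated": 0}
            for _ in range(n_test):
                outcome, weights = run_trial(weights, spec, params, rule, rng)
                chosen_hunger += outcome.chosen == "hunger"
                n_chosen += outcome.chosen is not None
                for a in ("hunger", "sated"):
                    pos[a] += outcome.noisy_T[a] > 0
            n_pos = pos["hunger"] + pos["sated"]
            # proportions are over completed choices / positive events; a
            # trial with no action expresses no preference
            prop_argmax = chosen_hunger / n_chosen if n_chosen else 0.5
            prop_positive = pos["hunger"] / n_pos if n_pos else 0.5
            for quantity, value in (
                ("prop_hunger_argmax", prop_argmax),
                ("prop_hunger_positive", prop_positive),
            ):
                rows.append(
                    dict(
                        experiment="state_valuation",
                        condition=f"test_{state}",
                        replicate=rep,
                        trial=-1,
                        phase="summary",
                        quantity=quantity,
                        value=value,
                    )
                )
    return _frame(rows)


def run_go_weight_trajectories(
    rule: str,
    seed: int = 0,
    *,
    n_trials: int = 1000,
    n_replicates: int = 100,
    r: float = 0.2,
    noise_sd: float = 0.1,
    m_high: float = M_DEPLETED,
    m_low: float = M_BALANCED,
    params: LearningParams | None = None,
    init: PathwayWeights = PathwayWeights(INIT_WEIGHT, 0.0),
) -> pd.DataFrame:
    """Go-weight growth during training at high vs low motivation.

    Same per-trial mechanics as the valuation training phase, run long
    enough (1000 trials x 100 replicates by default) for the asymptotic
    difference between hunger- and satiety-trained Go weights to emerge.
    Go weights start at 0.1 exactly.
    """
    params = params or LearningParams()
    rows = []
    for cond, m in (("high_motivation", m_high), ("low_motivation", m_low)):
        for rep in range(n_replicates):
            rng = replicate_rng(seed, 5, rep, 0 if cond == "high_motivation" else 1)
            traj: list[float] = []
            _train_option(rule, m, n_trials, r, noise_sd, params, rng, record_G=traj, init=init)
            for t, G in enumerate(traj):
                rows.append(
                    dict(
                        experiment="trajectories",
                        condition=cond,
                        replicate=rep,
                        trial=t,
                        phase="training",
                        quantity="G",
                        value=G,
                    )
                )
    return _frame(rows)


# ---------------------------------------------------------------------------
# Additive / multiplicative incentive-salience comparison
# ---------------------------------------------------------------------------


def zhang_additive_utility(R: float, kappa: float, base: float = math.e) -> float:
    """Additive incentive-salience utility ``R + log(kappa)``.

    ``R`` is the learned reinforcement value and ``kappa > 0`` the gating
    parameter encoding the physiological shift between training and
    testing (``kappa > 1`` up-shift, ``< 1`` down-shift).  Natural
    logarithm by default.
    """
    if not (math.isfinite(R) and math.isfinite(kappa)):
        raise ValueError("R and kappa must be finite")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    return R + math.log(kappa) / math.log(base)


def zhang_multiplicative_utility(R: float, kappa: float) -> float:
    """Multiplicative incentive-salience utility ``R * kappa``."""
    if not (math.isfinite(R) and math.isfinite(kappa)):
        raise ValueError("R and kappa must be finite")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    return R * kappa


def run_zhang(
    *,
    R_depleted: float = 1.0,
    R_balanced: float = -1.0,
    kappa_up: float = 3.0,
    kappa_same: float = 1.0,
    kappa_down: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Additive-model CS utilities on the four train/test state conditions.

    ``R`` reflects the value learned in the training state (salt is
    aversive when balanced, appetitive when depleted); ``kappa`` encodes
    the state shift from training to testing.
    """
    grid = {
        ("depleted", "depleted"): (R_depleted, kappa_same),
        ("depleted", "balanced"): (R_depleted, kappa_down),
        ("balanced", "balanced"): (R_balanced, kappa_same),
        ("balanced", "depleted"): (R_balanced, kappa_up),
    }
    rows = []
    for (train, test), (R, kappa) in grid.items():
        rows.append(
            dict(
                experiment="zhang",
                condition=f"train_{train}_test_{test}",
                replicate=0,
                trial=-1,
                phase="summary",
                quantity="additive_utility",
                value=zhang_additive_utility(R, kappa),
            )
        )
        rows.append(
            dict(
                experiment="zhang",
                condition=f"train_{train}_test_{test}",
                replicate=0,
                trial=-1,
                phase="summary",
                quantity="multiplicative_utility",
                value=zhang_multiplicative_utility(R, kappa),
            )
        )
    return _frame(rows)
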