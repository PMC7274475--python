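"""Tests for the experiment runners (reduced problem sizes where stochastic)."""

import math

import numpy as np
import pytest
from scipy import stats

from bgmotiv import (
    run_cone,
    run_cone_condition,
    run_go_weight_trajectories,
    run_inductive_bias,
    run_salt_appetite,
    run_state_dependent_valuation,
    run_weight_convergence,
    run_zhang,
    trials_to_criterion,
    zhang_additive_utility,
    zhang_multiplicative_utility,
)

BAL, DEP = 0.2, 2.0


def summary_means(df, quantity):
    sub = df[df.quantity == quantity]
    return sub.groupby("condition").value.mean()


class TestConeReadouts:
    def test_classical_model_is_state_independent(self):
        outs = [
            run_cone_condition("classical_td", m_tr, m_te)
            for m_tr in (BAL, DEP)
            for m_te in (BAL, DEP)
        ]
        assert len({(round(o.cs_response, 12), round(o.us_response, 12)) for o in outs}) == 1
        # converged CS response equals the learned reinforcement estimate
        assert outs[0].cs_response == pytest.approx(0.5 * (1 - 0.9**50), abs=1e-12)

    def test_simple_state_trained_depleted_tested_balanced(self):
        out = run_cone_condition("simple_state", DEP, BAL)
        V50 = 0.5 * (1 - (1 - 0.1 * DEP**2) ** 50)  # geometric closed form
        assert out.cs_response == pytest.approx(BAL * V50, abs=1e-12)
        assert out.cs_response == pytest.approx(0.1, abs=1e-3)
        assert out.us_response == pytest.approx(0.0, abs=1e-3)

    def test_simple_state_trained_balanced_tested_depleted(self):
        out = run_cone_condition("simple_state", BAL, DEP)
        V50 = 0.5 * (1 - (1 - 0.1 * BAL**2) ** 50)
        assert out.cs_response == pytest.approx(DEP * V50, abs=1e-12)
        assert out.us_response == pytest.approx(DEP * (0.5 - V50), abs=1e-12)
        assert out.us_response > 3 * out.cs_response

    def test_methods_plain_variant_learns_faster_when_balanced(self):
        from bgmotiv import LearningParams

        plain = run_cone_condition(
            "simple_state", BAL, BAL, params=LearningParams(v_update_variant="methods_plain")
        )
        scaled = run_cone_condition("simple_state", BAL, BAL)
        assert plain.cs_response > scaled.cs_response

    @pytest.mark.parametrize("model", ["gradient", "payoff_cost"])
    def test_bg_models_transfer_learned_value_to_cs(self, model):
        dep_dep = run_cone_condition(model, DEP, DEP)
        assert dep_dep.cs_response > 3 * abs(dep_dep.us_response)
        bal_dep = run_cone_condition(model, BAL, DEP)
        assert bal_dep.us_response > 3 * abs(bal_dep.cs_response)

    def test_table_shape(self):
        df = run_cone("simple_state", seed=0)
        assert df.condition.nunique() == 4
        assert set(df.quantity) == {"cs_response", "us_response"}
        assert len(df) == 4 * 5 * 2

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            run_cone_condition("bogus", BAL, BAL)


class TestWeightConvergence:
    def test_gradient_high_motivation_hits_clipped_fixed_point(self):
        df = run_weight_convergence("gradient", "high", 1.0, seed=0, n_replicates=3)
        last = df[df.trial == 149].pivot_table(index="replicate", columns="quantity", values="value")
        assert last["G"].mean() == pytest.approx(0.75, abs=1e-6)
        assert last["N"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_low_motivation_facilitates_nogo_learning(self):
        df = run_weight_convergence("gradient", "low", 1.0, seed=0, n_replicates=3)
        last = df[df.trial == 149].pivot_table(index="replicate", columns="quantity", values="value")
        assert last["N"].mean() == pytest.approx(0.5, abs=1e-3)

    def test_replicates_reproducible_in_isolation(self):
        few = run_weight_convergence("gradient", "variable", 1.0, seed=3, n_replicates=2)
        more = run_weight_convergence("gradient", "variable", 1.0, seed=3, n_replicates=4)
        key = ["replicate", "trial", "quantity"]
        a = few.set_index(key).value
        b = more[more.replicate < 2].set_index(key).value
        assert (a == b).all()

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            run_weight_convergence("gradient", "bogus", 1.0)


@pytest.fixture(scope="module")
def curves():
    df = run_inductive_bias(seed=0, alphas=(0.1,), n_trials=300, n_replicates=20)
    out = {}
    for cond, sub in df[df.quantity == "mean_abs_delta"].groupby("condition"):
        out[cond] = sub.sort_values("trial").value.to_numpy()
    return out


class TestInductiveBias:
    def test_gradient_learns_before_q_learning(self, curves):
        t_grad = trials_to_criterion(curves["gradient_alpha0.1"])
        t_q4 = trials_to_criterion(curves["q4_alpha0.1"])
        assert t_grad < t_q4

    def test_finer_discretisation_learns_slower(self, curves):
        t_q4 = trials_to_criterion(curves["q4_alpha0.1"])
        t_q10 = trials_to_criterion(curves["q10_alpha0.1"])
        assert t_q4 < t_q10

    def test_errors_shrink_towards_zero(self, curves):
        # the gradient model's error vanishes; Q-learning keeps a
        # discretisation floor but falls far below its initial error
        assert curves["gradient_alpha0.1"][-20:].mean() < 0.01
        for cond in ("q4_alpha0.1", "q10_alpha0.1"):
            assert curves[cond][-20:].mean() < 0.3 * curves[cond][:10].mean()

    def test_signed_error_centres_on_zero(self):
        df = run_inductive_bias(seed=1, alphas=(0.3,), n_trials=300, n_replicates=20)
        sub = df[(df.quantity == "mean_delta") & (df.condition == "q4_alpha0.3")]
        tail = sub.sort_values("trial").value.to_numpy()[-50:]
        assert abs(tail.mean()) < 0.05


@pytest.fixture(scope="module", params=["gradient", "payoff_cost"])
def counts(request):
    df = run_salt_appetite(request.param, seed=0)
    sub = df[df.quantity == "action_count"]
    return sub.pivot_table(index="replicate", columns="condition", values="value")


class TestSaltAppetite:
    def test_salt_intake_increases_when_depleted(self, counts):
        assert counts["cs_plus_depleted"].mean() > counts["cs_plus_balanced"].mean()

    def test_irrelevant_cue_unaffected_by_sodium_state(self, counts):
        res = stats.ttest_rel(counts["cs_minus_depleted"], counts["cs_minus_balanced"])
        assert res.pvalue > 0.05

    def test_noise_free_balanced_test_yields_no_actions(self):
        df = run_salt_appetite("gradient", seed=0, noise_sd=0.0, n_replicates=2)
        sub = df[(df.quantity == "action_count") & (df.condition == "cs_plus_balanced")]
        assert (sub.value == 0).all()


@pytest.fixture(scope="module", params=["gradient", "payoff_cost"])
def valuation_table(request):
    return run_state_dependent_valuation(request.param, seed=0)


class TestStateDependentValuation:
    @pytest.mark.parametrize("state", ["test_hungry", "test_sated"])
    def test_hunger_trained_option_preferred(self, valuation_table, state):
        means = summary_means(valuation_table, "prop_hunger_argmax")
        assert means[state] > 0.5

    def test_positive_count_readout_agrees(self, valuation_table):
        means = summary_means(valuation_table, "prop_hunger_positive")
        assert (means > 0.5).all()

    def test_hunger_training_builds_larger_go_weight(self, valuation_table):
        G = summary_means(valuation_table, "G_final")
        assert G["hunger_trained"] > G["sated_trained"]


@pytest.fixture(scope="module")
def trajectory_table():
    return run_go_weight_trajectories("gradient", seed=0, n_trials=300, n_replicates=20)


class TestGoWeightTrajectories:
    def test_trajectories_start_at_initial_weight(self, trajectory_table):
        # first recorded trial may already include one update only if an
        # action was taken; the very first G values must still be near 0.1
        first = trajectory_table[trajectory_table.trial == 0]
        assert np.all(first.value >= 0.1 - 1e-12)
        assert np.all(first.value <= 0.1 + 0.1 * 0.5)

    def test_high_motivation_grows_larger_go_weight(self, trajectory_table):
        last = trajectory_table[trajectory_table.trial == trajectory_table.trial.max()]
        means = last.groupby("condition").value.mean()
        assert means["high_motivation"] > means["low_motivation"]

    def test_go_weights_never_negative(self, trajectory_table):
        assert (trajectory_table.value >= 0).all()


class TestZhangComparison:
    @pytest.mark.parametrize(
        "R, kappa, expected",
        [(1, 1, 1.0), (-1, 3, -1 + math.log(3)), (1, 1 / 3, 1 - math.log(3))],
    )
    def test_additive_values(self, R, kappa, expected):
        assert zhang_additive_utility(R, kappa) == pytest.approx(expected)

    def test_log_base_option(self):
        assert zhang_additive_utility(0, 8, base=2) == pytest.approx(3.0)

    def test_kappa_domain(self):
        with pytest.raises(ValueError):
            zhang_additive_utility(1, 0)
        with pytest.raises(ValueError):
            zhang_multiplicative_utility(1, -1)

    def test_multiplicative_cannot_flip_sign(self):
        assert zhang_multiplicative_utility(-1, 3) < 0 < zhang_multiplicative_utility(1, 3)

    def test_grid_sign_structure(self):
        means = summary_means(run_zhang(), "additive_utility")
        assert means["train_depleted_test_depleted"] == pytest.approx(1.0)
        assert means["train_depleted_test_balanced"] == pytest.approx(1 - math.log(3))
        assert means["train_balanced_test_balanced"] == pytest.approx(-1.0)
        assert means["train_balanced_test_depleted"] == pytest.approx(-1 + math.log(3))

    @pytest.mark.parametrize("R", [-1.0, 0.0, 1.0])
    def test_balanced_trained_offset_persists_for_any_R(self, R):
        """The additive model's failure mode: log-kappa offsets are added
        regardless of the learned value, so the two balanced-trained test
        conditions always sit log(3) apart (and the up/down-shifted
        conditions span 2*log(3))."""
        df = run_zhang(R_balanced=R, R_depleted=R)
        means = summary_means(df, "additive_utility")
        gap = means["train_balanced_test_depleted"] - means["train_balanced_test_balanced"]
        assert gap == pytest.approx(math.log(3))
        span = means["train_balanced_test_depleted"] - means["train_depleted_test_balanced"]
        assert span == pytest.approx(2 * math.log(3))
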