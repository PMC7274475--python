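# bgmotiv

Simulations of how physiological state shapes learning and action selection
in the basal ganglia.

## The problem

An animal's willingness to work for a reinforcer, and the dopaminergic
teaching signals recorded while it learns, both depend on its physiological
state: salt is appetitive when sodium-depleted and aversive when balanced,
and options learned while hungry remain preferred even when sated.  Classical
temporal-difference accounts, in which the reward prediction error is
`δ = r + V' − V`, are blind to such states.  `bgmotiv` implements a
state-dependent utility framework that brings incentive-salience ideas into a
direct/indirect-pathway model of the basal ganglia, for computational
neuroscientists who want to simulate, extend or test it.

## The model

A single resource has current level *S* and set point *S\**.  Motivation is
the deficit *m = S\** − *S*, desirability of a state is quadratic,
*Y(S) = −(S − S\*)²/2*, and the utility of consuming a reinforcement *r* is
the change in desirability:

    U = m·r − r²/2

The positive term scales with need; the overshoot cost does not.  In the
basal-ganglia implementation, per-action Go and Nogo cortico-striatal weights
learn the two terms (*G → r*, *N → r²/2*), a bounded dopaminergic activation
signal *D = m/(1 + m)* arbitrates the pathway competition, and the thalamic
output

    T = D·G − (1 − D)·N

equals *(1 − D)·U* once the weights are learned.  Dopaminergic teaching
signals carry the state-dependent prediction error `δ = U − T/(1 − D)`.
Two plasticity rules are provided: a normative **gradient** rule
(`ΔG = α·δ·D/(1−D)`, `ΔN = −α·δ`) and a biologically motivated
**payoff–cost** rule (`ΔG = α·f_ε(δ) − λG`, `ΔN = α·f_ε(−δ) − λN`, with
`f_ε(x) = x` for positive and `ε·x` for negative arguments).  Weights clip
at zero.  Scalar state-dependent value learning (`δ = m·r − m·V`), classical
TD learning, a motivation-binned Q-learning baseline, and the additive
incentive-salience model `U(CS) = R + log κ` are included for comparison.

## A worked example

```python
>>> from bgmotiv import run_weight_convergence
>>> df = run_weight_convergence("gradient", "variable", r=1.0, seed=0, n_replicates=50)
>>> last = df[df.trial == 149].pivot_table(index="replicate", columns="quantity", values="value")
>>> print(f"G = {last['G'].mean():.3f}  N = {last['N'].mean():.3f}")
G = 0.994  N = 0.492
```

After 150 trials in which motivation varies trial-to-trial over {0, 1, 2},
the Go weight has converged near the objective reinforcement (*r* = 1) and
the Nogo weight near the overshoot cost (*r²/2* = 0.5): the network has
learned the state-*independent* structure of the outcome, which it can then
evaluate flexibly in any motivational state.  The `examples/` directory
holds one short script per capability (utility algebra, conditioning
readouts, weight convergence, inductive bias, salt appetite, state-dependent
valuation, incentive-salience comparison); each prints its numbers with a
note on what they mean.

The same experiments are available from a shell:

```sh
bgmotiv -v cone --model simple_state --seed 1 --out cone.csv
bgmotiv salt-appetite --model payoff_cost --seed 1
```

Every runner emits a tidy long-format table
`(experiment, condition, replicate, trial, phase, quantity, value)` plus a
JSON summary of per-condition means and SDs and the resolved configuration.
All randomness flows from a single root seed through per-replicate
`SeedSequence([seed, experiment_key, replicate])` streams, so outputs are
byte-reproducible and any replicate can be re-run in isolation.

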