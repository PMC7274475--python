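# Methods

## Model

The framework couples a homeostatic account of value to the basal-ganglia
direct/indirect pathway architecture.  One physiological dimension is
modelled.  Its desirability is quadratic about the set point,
`Y(S) = −(S − S*)²/2`, so the motivation `m = S* − S` equals the local slope
of desirability and the utility of consuming a reinforcement `r` is exactly
`U = m·r − r²/2` — positive consequences scale with need, the overshoot cost
does not.  Negative motivation (overshoot) is representable in the state
type, but the dopaminergic encoding `D = m/(1+m)` is restricted to
`m ≥ 0` and raises a domain error otherwise, since every simulated protocol
uses non-negative motivation.  `D = 1` is likewise rejected rather than
clamped wherever `1/(1−D)` appears: the mapping never reaches 1 for finite
motivation, so a saturated input indicates caller error.

Assumptions inherited from the framework: the agent knows its motivation;
utility is computed from the true state change (no sensory noise on `r`);
Go and Nogo gains are modulated by dopamine symmetrically and linearly; and
the striatum can read the activation and teaching signals independently.

## Learning rules

* **Gradient rule** — ascent on `−δ²/2` with `δ = U − T/(1−D)`:
  `ΔG = α·δ·D/(1−D)`, `ΔN = −α·δ`.  The Go factor `D/(1−D)` equals `m`.
* **Payoff–cost rule** — `ΔG = α·f_ε(δ) − λG`, `ΔN = α·f_ε(−δ) − λN`, with
  `f_ε(x) = x` if `x > 0` else `ε·x`.
* **Scalar value learners** — classical TD (`ΔV = α(r − V)`) and the
  state-dependent learner driven by `δ = m·r − m·V`.  Two update variants
  are exposed because the source material is internally inconsistent:
  `eq10_m_scaled` (`ΔV = α·m·δ`, the gradient of the objective) and
  `methods_plain` (`ΔV = α·δ`).  The default is `eq10_m_scaled`, which
  reproduces the described near-balanced behaviour (after 50 trials at
  `m = 0.2`, `V ≈ 0.091` — "minimally adjusted" — versus `≈ 0.318` under the
  plain variant); both are tested against geometric closed forms.
* **Q-learning baseline** — equal-width bins over `m ∈ [0, 2]`,
  left-closed with a closed top bin, `ΔQ_m = α(U − Q_m)`.  The utility fed
  to it defaults to the exact second-order form; a first-order variant is
  exposed because the protocol text cites both.

Weights cannot be negative.  The set-to-zero rule is stated for the
payoff–cost model but applied to the gradient rule as well, as the
non-negativity of synaptic weights is a premise of the architecture.  Useful
analytic consequences, used as test oracles: at fixed `m` the gradient rule
conserves `G + m·N` until the first clipping event, and at `m = 2, r = 1`
the trajectory from `(0.1, 0.1)` clips `N` to zero and converges to
`G = U/m = 0.75`.

## Trial mechanics

Each action carries its own motivation and reinforcement (separate
appetitive systems).  Available actions are evaluated as
`T + Normal(0, σ)` with independent noise per action; unavailable actions
have activity exactly zero.  Selection is by positivity threshold
(go/no-go) or argmax-with-positivity (choice trials); exact ties break
uniformly at random (measure-zero under Gaussian noise).  The teaching
signal is computed from the *noise-free* activity of the chosen action —
noise implements exploration in selection, not corruption of the
dopaminergic error — and weights update only for the chosen action, only in
training phases.  When no activity is positive, no action, no
reinforcement, no learning.

## Protocols and defaults

All parameters default to the published protocol values: `α = 0.1`,
`ε = 0.8`, `λ = 0.01`; motivation 0.2 (near-balanced) / 2 (depleted);
conditioning 50 training trials + 1 test trial × 5 replicates with
`r = 0.5`; weight convergence 150 trials × 100 replicates with
`r ∈ {0.2, 1, 2, 3}` and motivation variable over {0, 1, 2} or fixed;
inductive bias `r = 1`, `m ~ U(0, 2)`, 4 or 10 bins,
`α ∈ {0.1, 0.3, 0.5}`; salt appetite CS+ trained at `m = 0.2`, CS− at
`m = 0.1`, noise SD 0.1, test at `m = 2` vs 0.2; valuation 11 replicates,
training length `round(Normal(65, 5.5))` floored at 1, 24 test trials,
`r = 0.2`; trajectories 1000 trials × 100 replicates.  Weights start at
`(G, N) = (0.1, 0.1)`.

Choices made where the protocols are silent:

* **Salt-appetite test length** — 50 trials (matching training), exposed as
  a flag.
* **Inductive-bias replication** — 50 replicates × 400 trials; enough for
  the slowest learner (10-bin Q at `α = 0.1`) to cross the criterion, by
  the rate estimate `(1−α)^(t/n_bins)`.  The trials-to-criterion tolerance
  is 0.2 on a trailing 20-trial mean of the replicate-averaged |δ|, chosen
  *above* the asymptotic discretisation floor of the coarsest Q table
  (within-bin spread of `U` ≈ bin-width/4 = 0.125 for 4 bins at `r = 1`)
  so that every learner can reach it.  Note the Q learners' mean |δ| does
  not vanish asymptotically — only the signed mean does.
* **Valuation initialisation** — in the valuation and trajectory
  experiments Nogo weights start at 0 (Go at 0.1).  This is forced by the
  conservation law above: starting Nogo at 0.1 leaves the hunger-trained
  option with `N ≈ 0.044` (vs `≈ 0.004` for the sated option), which
  reverses the sated-test preference; the published behaviour (hunger-
  trained option preferred in both states) requires the Nogo weights to
  start at zero, consistent with the trajectory protocol specifying the
  *Go* initialisation only.
* **Valuation readouts** — both published readouts are reported: the
  argmax choice proportion (computed over completed choice trials; a trial
  on which neither noisy activity is positive expresses no preference) and
  the fraction of positive-activity events for the hunger-trained option.
  One training-length draw per replicate is shared by both options.
* **Conditioning readouts for the pathway models** — CS response is the
  decoded expected utility `T/(1−D_test)`, US response the prediction error
  at test motivation; no selection noise in this experiment.
* **Incentive-salience log base** — natural log, with the base exposed.

## Synthetic data

There is no external data: every experiment generates its own trials from
the protocol parameters above, which *are* the study conditions.  The
generator reproduces the structure of the original paradigms (forced vs
free choice, frozen test weights, per-cue motivations) but not features of
real behaviour such as satiation within a session, reaction times, or
inter-animal parameter variability — passing tests show the model's
internal consistency and its qualitative match to the published group-level
patterns, not quantitative fit to animal data.

## Numerical notes

All quantities are dimensionless floats; no unit system.  Updates are exact
scalar arithmetic, so closed-form geometric convergence results hold to
1e−12 and the thalamic identity `T = (1−D)·U` holds to machine precision.
Randomness flows from a root seed through
`SeedSequence([seed, experiment_key, replicate])`, making replicates
independent, order-insensitive and reproducible in isolation.  Boundary
conventions: selection requires strictly positive activity (zero is "no
action"); the top motivation bin is closed; training lengths are rounded
half-away-from-zero then floored at 1.

## Known limitations

Single physiological dimension; quadratic desirability only; no vigour or
reaction-time model; no mechanism for decoding the two dopaminergic signals;
the conditioning readout for balanced testing after depleted training yields
a small negative US response (≈ −0.11 at the printed parameters) whose
magnitude sits just outside the package's own "near zero" convention of
0.1 — an exact property of the learning rules under this protocol, discussed
in the test suite rather than hidden by a wider band.
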