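"""Inductive bias: knowing the form of the utility speeds up learning.

Compares the gradient model against tabular Q-learning over 4 or 10
motivation bins on a common random stream of motivations (uniform on
(0, 2), r = 1), reporting trials to reach a mean |prediction error|
below 0.2.
"""

import numpy as np

from bgmotiv import run_inductive_bias, trials_to_criterion

df = run_inductive_bias(seed=0)
curves = {
    cond: sub.sort_values("trial").value.to_numpy()
    for cond, sub in df[df.quantity == "mean_abs_delta"].groupby("condition")
}

print(f"{'learner':>9} {'alpha':>6} {'trials-to-criterion':>20} {'final |delta|':>14}")
for alpha in (0.1, 0.3, 0.5):
    for learner in ("gradient", "q4", "q10"):
        curve = curves[f"{learner}_alpha{alpha}"]
        t = trials_to_criterion(curve)
        print(f"{learner:>9} {alpha:6.1f} {t:20d} {curve[-50:].mean():14.3f}")

print(
    "\nThe gradient model reaches the criterion first at every learning"
    " rate because its parameterisation already matches the utility's"
    " form; Q-learning is slower the finer its discretisation (each bin"
    " is updated on fewer trials) and keeps a residual error floor from"
    " the within-bin spread of the utility."
)
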