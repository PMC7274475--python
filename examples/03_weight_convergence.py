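"""Go / Nogo weight learning under variable vs fixed motivation.

The gradient rule recovers the objective reinforcement structure
(G -> r, N -> r^2/2) when motivation varies across trials; the
payoff-cost rule's weight decay biases both weights down.  At a fixed
high motivation only the zero-error combination m*G - N is identified
and the Nogo weight clips at zero.
"""

from bgmotiv import run_weight_convergence

r = 1.0
for rule in ("gradient", "payoff_cost"):
    for condition in ("variable", "high"):
        df = run_weight_convergence(rule, condition, r, seed=0, n_replicates=50)
        last = df[df.trial == 149].pivot_table(
            index="replicate", columns="quantity", values="value"
        )
        print(
            f"{rule:12s} {condition:9s} motivation: "
            f"G = {last['G'].mean():.3f}  N = {last['N'].mean():.3f}"
        )

print(
    f"\nTargets for r = {r}: G = {r}, N = {r**2 / 2}.  The gradient model"
    " under variable motivation comes within a few percent; at fixed m = 2"
    " it reaches the clipped fixed point (0.75, 0); the payoff-cost model"
    " converges to lower weights than desired."
)
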