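"""Conditioning across motivational states: CS and US teaching signals.

Replicates the four train/test state combinations of the sodium-depletion
conditioning protocol (50 training trials, r = 0.5) with the scalar
state-dependent value learner and with the classical state-independent
TD learner.
"""

from bgmotiv import run_cone, summarize

for model in ("classical_td", "simple_state"):
    table = summarize(run_cone(model, seed=0))
    print(f"\n{model}")
    for _, row in table.iterrows():
        print(f"  {row.condition:35s} {row.quantity:12s} {row['mean']:7.3f}")

print(
    "\nThe classical learner is identical in all conditions.  The"
    " state-dependent learner reproduces the observed pattern: a CS"
    " response only after training while depleted and testing while"
    " depleted, a US response when value was never learned (trained"
    " balanced) but the reinforcement is suddenly valuable (tested"
    " depleted), and near-zero responses whenever tested balanced."
)
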