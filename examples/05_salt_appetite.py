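"""Salt appetite: depletion selectively amplifies responding to the salt cue.

Trains a sodium-paired cue (CS+) and a fructose-paired cue (CS-) in the
near-balanced state, then counts go-responses with frozen weights when
tested balanced vs sodium-depleted.
"""

from bgmotiv import run_salt_appetite

for rule in ("gradient", "payoff_cost"):
    df = run_salt_appetite(rule, seed=0)
    counts = df[df.quantity == "action_count"].groupby("condition").value.mean()
    print(f"\n{rule}: mean actions out of 50 test trials")
    for cond in ("cs_plus_depleted", "cs_plus_balanced", "cs_minus_depleted", "cs_minus_balanced"):
        print(f"  {cond:18s} {counts[cond]:5.1f}")

print(
    "\nDepletion raises only the CS+ motivation (m: 0.2 -> 2), tilting"
    " the pathway competition toward Go and multiplying responding to"
    " the salt cue, while the fructose cue (its own appetitive system,"
    " m = 0.1 throughout) is unaffected - without any relearning."
)
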