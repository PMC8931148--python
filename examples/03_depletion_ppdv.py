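"""Recover a hidden PAM rule from a simulated depletion assay.

A randomized 6-mer PAM library is 'selected' by a nuclease that depletes
NNTA-prefixed constructs to 10% survival. PPDV (selected frequency /
control frequency) per PAM, the top-decile depletion logo and the PAM wheel
then recover the rule without being told it.
"""

from pamscape import (
    DepletionSimConfig,
    compute_ppdv,
    depletion_logo,
    pam_wheel,
    simulate_depletion,
    top_depleted,
)

control, selected, truth = simulate_depletion(
    DepletionSimConfig(k=6, rule="NNTA", retention=0.1, depth=1_000_000, seed=3)
)
table = compute_ppdv(selected, control)
decile = top_depleted(table, 0.1)

print(f"library: {len(control.counts)} PAMs, control depth {control.total}")
print(f"top decile: {len(decile)} PAMs; rule-matching PAMs inside it: "
      f"{len(truth.matching_pams & set(decile))}/{len(truth.matching_pams)}")

logo = depletion_logo(decile)
print("per-position log2FC over 0.25 (rows = PAM positions 1-6):")
for pos in range(6):
    cells = ", ".join(
        f"{b}:{logo.log2fc[pos, i]:+.2f}" for i, b in enumerate(logo.alphabet)
    )
    print(f"  pos {pos + 1}: {cells}")
# Positions 3 and 4 peak at T and A (the rule's literal core); the flanking
# N positions stay near zero, i.e. uniform.

wheel = pam_wheel(table, (2, 3, 4))
top3 = sorted(wheel.weights.items(), key=lambda kv: -kv[1])[:5]
print("PAM wheel (positions 2-4), heaviest trimers:",
      ", ".join(f"{k}={w:.3f}" for k, w in top3))
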