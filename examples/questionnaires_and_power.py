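"""Zung scale scoring, reliability, and the a-priori power computation.

SDS and SAS each have 20 four-point items with designated reverse-keyed
items (total = forward + (5 - reversed)).  The power routine finds the
smallest total N whose noncentral-F power for the 2x2 repeated-measures
within-between interaction reaches the target.
"""

from hyperdifc import (generate_scale_responses, interaction_power,
                       reliability, required_sample_size, score_table)
from hyperdifc.groupstats import recode_reversed

groups = [0] * 40 + [1] * 40
genders = (["male", "female"] * 40)[:80]
resp = generate_scale_responses(groups, genders, group_effect=0.6, seed=9)

for inst in ("SDS", "SAS"):
    totals = score_table(resp[inst], inst)
    recoded = recode_reversed(resp[inst], inst)
    alpha, omega = reliability(recoded.filter(like="item_").to_numpy())
    print(f"{inst}: mean total {totals.mean():.1f} (sd {totals.std():.1f}), "
          f"Cronbach alpha = {alpha:.3f}, McDonald omega = {omega:.3f}")

n = required_sample_size(f=0.20, alpha=0.05, power=0.95)
print(f"\nminimum total N for f=0.20, alpha=0.05, power=0.95 "
      f"(2x2 design, corr 0.5): {n}")
print(f"achieved power at that N: {interaction_power(n, 0.20):.3f}")
print("All-1 responses score 50 on the SDS (10 forward + 10 reverse items)"
      " and 35 on the SAS (15 forward + 5 reverse).")
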