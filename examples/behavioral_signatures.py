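"""Behavioral signatures of a momentum cohort.

Classifies every round of a simulated cohort (dominant vs max-progress vs
prospective/retrospective suit), then prints the aggregates the valuation
models are judged against: the retrospective pull as a function of progress
difference, its interaction with block disparity, and asymmetric switching.
"""

import goalmomentum as gm

spec = gm.CohortSpec("exp1", n_participants=8, model_id="momentum",
                     ranges=gm.HUMAN_PLAUSIBLE_RANGES, master_seed=31)
tab = gm.signature_table(gm.generate_cohort(spec))

print("P(choose max-progress over dominant) by progress-difference bin:")
for _, r in tab.maxprog_by_diff.iterrows():
    print(f"  diff ({r.bin_low:.2f}, {r.bin_high:.2f}] -> "
          f"{r.p_max_progress:.2f}")

print("\nDominant-suit share in conflict rounds, by block type:")
for _, r in tab.choice_shares.iterrows():
    print(f"  {r.block_type}: dominant {r.p_dominant:.2f}  "
          f"max-progress {r.p_max_progress:.2f}  third {r.p_third:.2f}")

sw = tab.switch_rates.groupby("suit_class")["p_switch"].mean()
print(f"\nMean switch-away rate: prospective suit {sw['prospective']:.2f}, "
      f"retrospective suit {sw['retrospective']:.2f}")
print("\nThe pull of accrued progress rises with the progress difference,")
print("is strongest in low-disparity blocks, and the cohort persists more")
print("with the retrospective suit than the prospective one.")
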