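"""Effect of variant categories on cross-strain binding strength.

Simulates ChIP-seq tag counts for two strains at regions carrying each
impact category, with a planted 4-fold binding loss at motif-mutation
regions and no effect of pure spacing alterations, then summarises per
category the |log2 fold change| and Cohen's d against variant-free
regions.
"""

from motifspacing.effects import strain_effect_table
from motifspacing.simulate import simulate_strain_tags
from motifspacing.variants import ImpactCategory

effect_map = {
    "motif_A_mutation": 0.25,   # 4-fold binding loss
    "motif_B_mutation": 0.25,
    "other_motif_mutation": 0.5,
    "spacing_alteration": 1.0,  # no effect of spacing change
    "no_effect": 1.0,
}
categories = [c.value for c in ImpactCategory for _ in range(500)]
tags = simulate_strain_tags(categories, effect_map=effect_map, seed=5)

table = strain_effect_table(
    tags["ref_tags"].to_numpy(), tags["strain_1"].to_numpy(), tags["category"]
)
print(table.to_string(index=False))
print("\nMotif mutations show large Cohen's d vs variant-free regions; "
      "spacing alterations are indistinguishable from no effect, matching "
      "the planted multipliers.")
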