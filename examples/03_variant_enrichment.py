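"""Frequency-class enrichment of variants between co-binding sites.

Plants gnomAD-style variants (singletons / rare / high-frequency) around
500 constrained co-binding regions with a two-fold singleton rate between
the motifs, then recovers the enrichment as class-vs-rest odds ratios of
between-motif counts against the 100-bp flanking background.
"""

from motifspacing.motifs import BindingSite
from motifspacing.simulate import simulate_genome, simulate_variants
from motifspacing.variants import (
    CoBindingRegion,
    class_enrichment_table,
    locate_and_classify,
)

genome = simulate_genome(260_000, seed=3)
regions = []
pos = 300
for _ in range(500):
    siteA = BindingSite("chr1", pos, pos + 10, "+", 10.0, "A")
    siteB = BindingSite("chr1", pos + 30, pos + 40, "+", 10.0, "B")
    regions.append(CoBindingRegion(siteA=siteA, siteB=siteB))
    pos += 500

variants, truth = simulate_variants(
    regions,
    genome,
    base_rates={"singleton": 0.05, "rare": 0.03, "high_frequency": 0.02},
    zone_multipliers={"between": {"singleton": 2.0}},  # planted 2x enrichment
    seed=4,
)
print(f"{len(variants)} variants placed; planted: 2x singleton rate between motifs\n")

located = locate_and_classify(regions, variants)
table = class_enrichment_table(located)
print(table[["category", "a", "b", "c", "d", "odds_ratio", "log2_odds_ratio"]]
      .to_string(index=False))
print("\nlog2 OR near 1 for singletons recovers the planted two-fold rate "
      "ratio; a depleted class would show a negative log2 OR.")
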