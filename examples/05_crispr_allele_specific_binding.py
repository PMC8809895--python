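"""Allele-specific TF binding across a CRISPR InDel spectrum.

Simulates paired input/ChIP amplicon reads over a Cas9 InDel spectrum with
a planted 10-fold binding loss for InDels that overlap a binding site and
no loss for pure spacing alterations, then quantifies per-InDel-group
log2 odds ratios of ChIP to input tags.
"""

import tempfile

import numpy as np

from motifspacing.crispr import TestRegion, quantify_region, read_sam
from motifspacing.motifs import BindingSite
from motifspacing.simulate import simulate_crispr_reads, simulate_genome

region = TestRegion(
    chrom="chr1", start=0, end=300,
    siteA=BindingSite("chr1", 100, 112, "+", 0.0, "PU1"),
    siteB=BindingSite("chr1", 150, 162, "+", 0.0, "CEBPB"),
    cut_site=131,
)
seq = simulate_genome(300, seed=6)

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate_crispr_reads(
        region, seq, depth=50_000,
        binding_loss_overlap=0.1, binding_loss_spacing=1.0,
        seed=7, out_dir=tmp,
    )
    chip_reads, _ = read_sam(sim["chip_sam"], region, "chip")
    input_reads, _ = read_sam(sim["input_sam"], region, "input")

table, stats = quantify_region(chip_reads, input_reads, region)
edited = table[table["net_size"] != 0]
overlap = edited.loc[edited["overlaps_site"], "log2_odds_ratio"]
spacing_only = edited.loc[~edited["overlaps_site"], "log2_odds_ratio"]

print(table.head(12).to_string(index=False))
print(f"\nretained reads: chip={stats['chip_retained']}, "
      f"input={stats['input_retained']}; groups kept: {stats['n_groups']}")
print(f"median log2 OR, site-overlapping InDels: {overlap.median():.2f} "
      f"(planted 10-fold loss -> log2(0.1) = {np.log2(0.1):.2f})")
print(f"median log2 OR, spacing-only InDels:     {spacing_only.median():.2f} "
      f"(planted no loss -> 0)")
print(f"Welch t-test, spacing vs overlapping groups: p = {stats['t_test_p']:.2e}")
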