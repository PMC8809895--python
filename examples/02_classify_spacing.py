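"""Classify a TF pair's motif-spacing relationship.

Plants co-binding sites for two synthetic motifs at a constrained spacing
of 7 bp (30% concentration), then runs the full classification: site
calling near peak centers, signed edge-to-edge spacings, the Monte-Carlo
spike test and the repeated KS test.
"""

from motifspacing.motifs import call_sites_in_peak, fpr_threshold, parse_jaspar, trim_pwm
from motifspacing.pipeline import DEMO_JASPAR
from motifspacing.simulate import SpacingModel, plant_cobinding, simulate_genome
from motifspacing.spacing import classify_pair, spike_null

pwmA, pwmB = (trim_pwm(p) for p in parse_jaspar(DEMO_JASPAR))
lomA, lomB = pwmA.log_odds(), pwmB.log_odds()
thrA, thrB = fpr_threshold(lomA), fpr_threshold(lomB)

model = SpacingModel(kind="constrained", s0=7, concentration=0.3)
genome = simulate_genome(200_000, seed=1)
seq, peaksA, peaksB, truth = plant_cobinding(
    genome, pwmA, pwmB, n_regions=300, model=model, seed=1,
    min_score_A=thrA, min_score_B=thrB,
)
genome_map = {"chr1": seq}

dists, results = classify_pair(
    peaksA,
    peaksB,
    lambda p: call_sites_in_peak(lomA, genome_map, p, thrA),
    lambda p: call_sites_in_peak(lomB, genome_map, p, thrB),
    tfA=pwmA.name,
    tfB=pwmB.name,
    null=spike_null(seed=0),
    seed=2,
)

print(f"planted model: constrained spacing at +{model.s0} bp, "
      f"{model.concentration:.0%} concentration\n")
for orientation, rel in results.items():
    spikes = ", ".join(f"{i:+d} bp (p={p:.1e})" for i, p in rel.spike_positions)
    print(f"orientation {orientation}: n={dists[orientation].total:4d}  "
          f"label={rel.label:11s}  spikes=[{spikes}]  ks_mean_p={rel.ks_mean_p:.3g}")
print("\nA 'constrained' label with a spike at +7 bp recovers the planted "
      "spacing; the KS statistic is reported alongside but a spike takes "
      "precedence.")
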