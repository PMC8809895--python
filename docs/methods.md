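# Methods

This note documents the statistical models, the defaults and the design
choices behind `motifspacing`, and what the synthetic-data generator does
and does not emulate.

## Motif model and site calling

Motifs are position probability matrices over (A, C, G, T). JASPAR count
matrices are converted column-wise with a pseudocount: each cell receives
`4 · pseudocount · background_b` added counts (a full pseudocount per cell
under the uniform background), the column then normalised. The default
pseudocount is 0.8; it only matters for sparse matrices and guarantees
finite log-odds. Scores are `log2(p / background)` summed over positions —
"bits" — with a uniform background of 0.25 per base. Bits are the unit in
which the two-bit motif-mutation rule is meaningful: a two-bit score
change is a 2² = 4-fold change in the likelihood ratio of binding.

Information content per position is `2 + Σ_b p_b log2 p_b` (0·log 0 ≡ 0),
i.e. 2 bits minus the Shannon entropy under a uniform background. Trimming
keeps the contiguous core from the first to the last position with IC
strictly above 0.3 bits, retaining interior low-IC positions; a motif with
no position above threshold is rejected as unusable (the corresponding TF
would be excluded from analysis).

The calling threshold is the smallest score t with `P(score ≥ t) ≤ fpr`
under i.i.d. uniform bases. The null score distribution is computed
exactly by per-position convolution with scores binned at 10⁻³ bits. The
binning makes the threshold accurate to about `L · 5·10⁻⁴` bits — far
below any score difference of interest — and the unit tests verify the
convolution against full 4^L k-mer enumeration for short motifs. Because
the distribution is discrete the achieved tail probability is ≤ fpr but
not exactly fpr; for the default 0.1% it stays within (fpr/4, fpr] for any
reasonably informative motif. Very short motifs for which even the top
score bin exceeds the requested fpr raise an explicit error.

Scanning reports every window on either strand scoring at least the
threshold, with 0-based half-open coordinates; reverse-strand windows are
scored on the reverse complement. Windows containing N are skipped rather
than scored against background, which would otherwise distort the
calibrated threshold. Sites are then restricted to those whose midpoint
lies within 50 bp (inclusive) of the ChIP-seq peak center; the midpoint
convention avoids strand asymmetry, and peaks are standardised to 200 bp.

## Spacing relationships

At overlapping peak pairs (≥ 1 shared base, half-open semantics), spacings
are computed edge-to-edge between every combination of non-overlapping
sites for the two TFs, signed relative to the reference TF's strand
(positive = partner 3′ of the reference site), and stratified by the
(strand_A, strand_B) orientation pair. Counts N_i over i ∈ [−100, 100]
form the per-orientation spacing distribution.

**Spike (constrained) test.** The statistic at position i is the average
of the single-step forward and backward slopes,
`S_i = (2 N_i − N_{i−1} − N_{i+1}) / 2`, which is zero for any locally
linear profile and large only at sharp peaks. The null pools slopes from
1000 replicates of 1000 uniform integer draws on [0, 100] histogrammed at
1-bp resolution (99 interior slopes per replicate, 99 000 pooled values).
Empirical upper-tail p-values use the add-one estimator
`(1 + #{null ≥ S_i}) / (1 + N)`, so the smallest attainable p is
≈ 1.01·10⁻⁵. The significance level is 0.05/200/4 = 6.25·10⁻⁵ — 0.05
corrected familywise for the ~200 slope positions and the four orientation
combinations. Any significant position calls the pair constrained.

Scale matching between the observed distribution and the fixed-size null
deserves care. Each observed distribution is split into its non-negative
half and its mirrored non-positive half so the support matches the null's
one-sided 0–100 range (101 bins; slopes exist only at interior bins, so
spikes at exactly 0 or ±100 bp are not callable). A half with **more**
spacings than the null's 1000 draws is rescaled down to total 1000 before
slope computation; this shrinks its counting noise relative to the null
and makes the test conservative for large samples. A half with **fewer**
spacings is instead tested against a fresh null built at its own total
(deterministic under the test's seed): rescaling a sparse histogram up
would inflate its noise and produce wholesale false spikes. The choice of
a fixed 1000-draw reference scale is configurable.

**Relaxed test.** The observed spacings are compared to size-matched
uniform draws on [−100, 100] with a two-sample KS test, repeated 100 times
with fresh draws, and the p-values averaged. Spacings are integers, so a
seeded ±0.5 uniform jitter is applied to both samples to avoid heavy-tie
artifacts in the KS statistic (switchable). A mean p below `alpha_relaxed`
labels the pair relaxed; the cutoff is not a quantity with a canonical
value and defaults to 10⁻³. Classification precedence is constrained >
relaxed > none, with both statistics always reported.

## Variant annotation

Frequency classes: singleton iff AC = 1 (taking precedence), otherwise
high-frequency iff AF > 0.01% (strict), otherwise rare.

Footprints: alleles are first normalised by stripping the shared VCF
anchor base. A deletion's footprint spans the deleted reference bases; an
insertion is a single inter-base point, so an insertion exactly at a site
boundary counts as between/flank rather than at-site. A variant is located
at_site, between_sites (wholly inside the inter-motif interval),
background (100-bp flanks outside the co-binding span), or outside; the
zones are mutually exclusive by construction.

Motif mutation: the ±L window around a site is rescanned on the alternate
haplotype (both strands) and Δ = best alternate score − reference site
score; |Δ| ≥ 2 bits (inclusive) is a mutation. Rescanning rather than
in-place scoring keeps an InDel that shifts but preserves a motif from
being miscalled as a mutation. Impact priority per region: motif A
mutation > motif B mutation > other-motif mutation (user-supplied motif
list) > spacing alteration (any between-sites InDel with no motif
mutation) > no effect > variant-free. For constrained pairs, co-binding
regions are pre-filtered to the identified constrained spacing ± 2 bp.

Enrichment is the odds ratio `(a/b)/(c/d)` of a frequency class versus all
other classes, between motifs versus background; the class-vs-rest
contrast (rather than class-vs-all-variants) is the default and
configurable. A +0.5 Haldane–Anscombe correction is applied to every cell
iff any cell is zero, and flagged.

## Effect sizes

Tag counts are normalised as `raw · 10⁷ / library size` and quantified in
half-open windows (default ±150 bp for TF ChIP/GRO-seq, ±500 bp for
H3K27ac). Fold changes use a pseudocount of 1 on normalised counts, so
zero-tag regions stay finite. Cohen's d uses the pooled-SD definition and
is computed on absolute fold changes, comparing each category's
distribution with the variant-free reference; the Mann–Whitney U test is
exact for combined n ≤ 20 without ties and a tie-corrected normal
approximation otherwise. Spearman correlations use average ranks.

## CRISPR InDel quantification

CIGAR I/D elements become events (reference position, signed size); a
read's group key is its **net** InDel size (events summed) together with a
flag for whether any event footprint overlaps either binding site. Keying
by net size is a choice: reads in these amplicons overwhelmingly carry a
single event, and net size is what determines the spacing change. Reads
with an event further than 10 bp (configurable) from the Cas9 cut site are
removed as mapping artifacts — deletions spanning the cut site are always
within distance zero. Groups below 0.05% of retained input reads (strict
less-than) are dropped. Odds-ratio denominators use the post-filtering
retained reads of each sample; a +0.5 correction applies to zero cells.
Spacing-only versus site-overlapping group classes are compared per region
with a Welch two-sample t-test; no cross-region multiple-testing
correction is applied.

## Synthetic data

The generator emulates, with planted truth:

* **Genomes** — i.i.d. bases at a requested GC fraction (default 0.41,
  mammalian-like).
* **Co-binding regions** — motif instances sampled base-wise from the PWM
  (optionally resampled until they clear the calling threshold, so planted
  sites are recoverable by construction), written at spacings drawn from a
  constrained (point mass s0 with optional jitter atop a uniform floor),
  relaxed (P(i) ∝ exp(−λ|i|)), or uniform model, across the four
  orientation combinations; 200-bp peaks centred on each planted site.
* **Variants** — per-zone, per-class Poisson rates with zone multipliers
  (e.g. a two-fold singleton rate between motifs); allele counts from a
  power-law (zeta-like) spectrum over a 75 000-genome diploid cohort, so
  AF = AC/150 000 and the class boundaries fall at AC 1 / 15 / 16; InDel
  sizes geometric with most under 5 bp. Deletions are kept inside their
  zone so planted zone labels remain exact.
* **Strain tags** — negative binomial counts (variance μ + μ²/k, default
  dispersion k = 10, depth 100) with per-category mean multipliers tying
  binding loss to motif mutation.
* **CRISPR read spectra** — a Cas9-like spectrum (deletions up to ~22 bp
  and a small mass of ~44–56 bp deletions centred on the cut site,
  insertions ≤ 5 bp at the cut point, ~45% of alleles unedited, with the
  site-overlapping mass kept to ~5% of reads so that unaffected groups'
  odds ratios are not materially displaced by depletion of the edited
  pool); ChIP reads are resampled from the input spectrum with probability
  proportional to each group's binding multiplier. SAM output carries
  consistent CIGARs and sequences.

All generators are bit-reproducible under a fixed seed. What the synthetic
data does **not** emulate: sequencing error, PCR duplicates, mappability
and repeat structure, chromatin context, linkage disequilibrium between
variants, and overlapping/composite motifs (the spacing analysis excludes
overlapping sites by design). Passing tests therefore demonstrate that the
statistical machinery recovers planted effects of realistic magnitude at
realistic sample sizes, not that real data are free of these confounders.

## Problem sizes and numerics

The test and acceptance runs use: 10⁶ bases for the empirical FPR check;
200 null datasets and 50 planted datasets of 5000 spacings for spike
type-I/power; 20 seeds for KS discrimination; 500 co-binding regions
(~12 000 variants) for enrichment recovery; 500 regions per category for
effect sizes; and 10⁵ reads per sample for the CRISPR recovery. These
sizes put Monte-Carlo error comfortably inside the assertion tolerances
while keeping a full run under a minute on one CPU.

Degenerate inputs are handled explicitly: empty spacing distributions
produce a warning and no spikes; the relaxed test requires ≥ 2 spacings;
Cohen's d with zero pooled SD errors unless the groups are identical;
odds ratios with an empty margin error rather than returning infinities.

## Known limitations

* The spike test cannot call constraints at spacing 0 or ±100 bp (no
  interior slope there), and its fixed-scale null makes it conservative
  for very large samples.
* `alpha_relaxed` has no principled default; the reported mean KS p-value
  should be examined rather than the label alone when a pair is near the
  cutoff.
* The two-bit mutation rule inherits the PWM's additivity assumption;
  cooperative or flanking-sequence effects are out of scope.
* Insertions at exact site boundaries are deliberately not counted as
  motif-disrupting; real boundary insertions may occasionally matter.
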