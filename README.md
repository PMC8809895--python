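# motifspacing

Tools for asking a precise regulatory-genomics question: **when two
transcription factors (TFs) co-bind a regulatory element, does the spacing
between their motifs matter?** Some TF pairs form ternary complexes on
composite elements and require a *constrained* spacing (a sharp preference
for one exact distance); most tolerate a *relaxed*, billboard-style
arrangement where co-binding frequency simply decays with distance. The
distinction predicts how damaging an insertion or deletion (InDel) between
the motifs will be.

The package implements the full analysis chain on ChIP-seq-derived inputs,
and ships a synthetic-data generator that plants known ground truth so
every stage can be validated end to end without external downloads. It is
aimed at computational biologists studying TF grammar, enhancer logic, and
the interpretation of non-coding variants.

## What it computes

**Binding-site calling** (`motifspacing.motifs`). JASPAR count matrices are
converted to position weight matrices (PWMs), trimmed to the core spanning
the first to last position with information content > 0.3 bits, and scored
in log2-odds units ("bits"). The calling threshold is calibrated by exact
convolution of the per-position score distribution so that the false
positive rate on uniform random sequence (25% A/C/G/T) is 0.1%. Sites are
kept when their midpoint lies within 50 bp of a ChIP-seq peak center.

**Spacing classification** (`motifspacing.spacing`). For a TF pair, signed
edge-to-edge spacings between non-overlapping sites at overlapping peaks
are histogrammed per motif-orientation combination over ±100 bp, as counts
N_i. The point-to-point slope

    S_i = (2 N_i − N_{i−1} − N_{i+1}) / 2

is compared against a Monte-Carlo null (1000 draws of 1000 uniform
integers on [0, 100], slopes pooled); an empirical p-value below
0.05/200/4 = 6.25e-05 (familywise correction over ~200 slope positions
and 4 orientations) calls a "spike" — a **constrained** spacing. Pairs
without spikes are tested with a two-sample Kolmogorov–Smirnov test
against size-matched uniform draws, repeated 100 times and averaged; a
small mean p labels the pair **relaxed**.

**Variant annotation** (`motifspacing.variants`). Variants are binned by
population frequency — singletons (AC = 1), rare (AF < 0.01%, AC > 1),
high-frequency (AF > 0.01%) — and by impact: a motif mutation is a PWM
score change of ≥ 2 bits (≈ 4-fold binding-likelihood change), assessed by
rescanning the alternate haplotype; an InDel between intact motifs is a
spacing alteration. Enrichment of a frequency class between the motifs
versus 100-bp flanking background is an odds ratio (Haldane–Anscombe
corrected when a cell is empty).

**Effect sizes** (`motifspacing.effects`). Binding change between strains
is the |log2 fold change| of library-size-normalised tag counts; per
impact category it is summarised by Cohen's d (on absolute values, pooled
SD) against variant-free regions with a Mann–Whitney U test.

**CRISPR allele-specific binding** (`motifspacing.crispr`). Amplicon reads
from paired input/ChIP samples are classified by net InDel size and
whether the InDel overlaps a binding site; reads with InDels away from the
Cas9 cut site are filtered, groups below 0.05% of input reads dropped, and
each group's binding is the log2 odds ratio

    OR = (ChIP tags in group / rest of ChIP tags) /
         (input tags in group / rest of input tags).

## Worked example

`examples/` contains one narrative script per capability. For instance,
classifying a planted constrained pair (`examples/02_classify_spacing.py`):

```
planted model: constrained spacing at +7 bp, 30% concentration

orientation ++: n=  98  label=constrained  spikes=[+7 bp (p=1.0e-05)]  ks_mean_p=0.0357
orientation +-: n= 126  label=constrained  spikes=[+7 bp (p=1.0e-05)]  ks_mean_p=0.0321
orientation -+: n= 104  label=constrained  spikes=[+7 bp (p=1.0e-05)]  ks_mean_p=0.0672
orientation --: n= 125  label=constrained  spikes=[+7 bp (p=1.0e-05)]  ks_mean_p=0.0393
```

Every orientation recovers the planted +7 bp constraint with an empirical
spike p-value at the resolution floor of the Monte-Carlo null, far below
the 6.25e-05 familywise threshold. And the CRISPR quantification
(`examples/05_crispr_allele_specific_binding.py`):

```
median log2 OR, site-overlapping InDels: -3.20 (planted 10-fold loss -> log2(0.1) = -3.32)
median log2 OR, spacing-only InDels:     0.07 (planted no loss -> 0)
Welch t-test, spacing vs overlapping groups: p = 1.90e-04
```

InDels that clip a binding site lose ~10-fold binding; pure spacing
alterations between the sites leave binding essentially unchanged.

A complete simulate→classify→annotate→quantify run is one call:

```bash
motifspacing full --out run/ --seed 1          # or: run_pipeline(RunConfig...)
```

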