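"""Variant annotation at TF co-binding regions.

Variants are binned by population frequency (singleton / rare /
high-frequency) and by functional impact: does the variant mutate one of
the two target motifs (a PWM-score change of at least two bits, i.e. about
a four-fold change in binding likelihood), mutate another user-supplied
functional motif, alter the spacing between the target motifs, or none of
these.  Enrichment of a frequency class in a region kind (between the
motifs vs. flanking background) is summarised as an odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motifs import BindingSite, LogOddsMatrix, scan_sites

DEFAULT_AF_HIGH = 1e-4  # AF > 0.01% is "high frequency"
MOTIF_MUTATION_BITS = 2.0


class VariantError(ValueError):
    pass


class ImpactCategory(str, Enum):
    MOTIF_A_MUTATION = "motif_A_mutation"
    MOTIF_B_MUTATION = "motif_B_mutation"
    OTHER_MOTIF_MUTATION = "other_motif_mutation"
    SPACING_ALTERATION = "spacing_alteration"
    NO_EFFECT = "no_effect"
    VARIANT_FREE = "variant_free"


@dataclass(frozen=True)
class VariantRecord:
    """A VCF-style variant with population allele frequency and count.

    ``pos`` is 0-based; ref/alt are left-anchored allele strings.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    AF: float | None = None
    AC: int | None = None

    @property
    def indel_size(self) -> int:
        """Signed size: inserted minus deleted bases (0 for a SNP/MNP)."""
        return len(self.alt) - len(self.ref)

    @property
    def is_indel(self) -> bool:
        return self.indel_size != 0

    def normalized(self) -> "VariantRecord":
        """Strip the shared left-anchor prefix common to ref and alt."""
        ref, alt, pos = self.ref, self.alt, self.pos
        while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        return VariantRecord(self.chrom, pos, ref, alt, self.AF, self.AC)

    def footprint(self) -> tuple[int, int]:
        """Affected reference interval, 0-based half-open after
        normalization.  Pure insertions have a zero-width footprint at the
        inter-base insertion point."""
        v = self.normalized()
        return v.pos, v.pos + len(v.ref)


@dataclass
class CoBindingRegion:
    """Two binding sites with their intermediate sequence and 100-bp
    flanking background intervals."""

    siteA: BindingSite
    siteB: BindingSite
    flank: int = 100

    def __post_init__(self) -> None:
        if self.siteA.chrom != self.siteB.chrom:
            raise VariantError("sites on different chromosomes")
        if self.siteA.overlaps(self.siteB):
            raise VariantError("co-binding sites must not overlap")

    @property
    def chrom(self) -> str:
        return self.siteA.chrom

    @property
    def between(self) -> tuple[int, int]:
        left = min(self.siteA.end, self.siteB.end)
        right = max(self.siteA.start, self.siteB.start)
        return left, right

    @property
    def spacing(self) -> int:
        left, right = self.between
        return right - left

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(self.siteA.start, self.siteB.start),
            max(self.siteA.end, self.siteB.end),
        )

    @property
    def flank_up(self) -> tuple[int, int]:
        s, _ = self.span
        return max(0, s - self.flank), s

    @property
    def flank_down(self) -> tuple[int, int]:
        _, e = self.span
        return e, e + self.flank


def af_category(v: VariantRecord, af_high: float = DEFAULT_AF_HIGH) -> str:
    """Assign singleton (AC == 1), high_frequency (AF > 0.01%) or rare.

    AC == 1 takes precedence over the AF comparison; the AF threshold is
    strict (>).  Returns None with a warning when AF or AC is missing.
    """
    if v.AC is None or v.AF is None:
        warnings.warn(f"variant {v.chrom}:{v.pos} missing AF/AC; skipped")
        return None
    if v.AC == 1:
        return "singleton"
    if v.AF > af_high:
        return "high_frequency"
    return "rare"


def select_constrained_windows(
    regions: Sequence[CoBindingRegion], constrained_spacing: int, tol: int = 2
) -> list[CoBindingRegion]:
    """Keep regions whose observed spacing is within ``tol`` bp of the
    identified constrained spacing."""
    return [r for r in regions if abs(r.spacing - constrained_spacing) <= tol]


def _intersects(fp: tuple[int, int], iv: tuple[int, int]) -> bool:
    s, e = fp
    if s == e:  # zero-width insertion point: strictly interior inter-base
        return iv[0] < s < iv[1]
    return s < iv[1] and iv[0] < e


def _within(fp: tuple[int, int], iv: tuple[int, int]) -> bool:
    s, e = fp
    if s == e:
        return iv[0] < s < iv[1]
    return iv[0] <= s and e <= iv[1]


def locate_variant(v: VariantRecord, region: CoBindingRegion) -> str:
    """Locate a variant's footprint relative to a co-binding region.

    Returns one of at_site, between_sites, background, outside.  A deletion
    footprint spans the deleted bases; an insertion is a single inter-base
    point, so an insertion at a site boundary counts as between/flank, not
    at_site.
    """
    if v.chrom != region.chrom:
        return "outside"
    fp = v.footprint()
    siteA = (region.siteA.start, region.siteA.end)
    siteB = (region.siteB.start, region.siteB.end)
    if _intersects(fp, siteA) or _intersects(fp, siteB):
        return "at_site"
    if _within(fp, region.between):
        return "between_sites"
    if _intersects(fp, region.flank_up) or _intersects(fp, region.flank_down):
        return "background"
    return "outside"


def apply_variant(seq: str, seq_start: int, v: VariantRecord) -> str:
    """Apply a variant to a sequence slice starting at genomic coordinate
    ``seq_start``.  The variant footprint must lie within the slice."""
    v = v.normalized()
    s, e = v.footprint()
    if s < seq_start or e > seq_start + len(seq):
        raise VariantError("variant outside sequence slice")
    i, j = s - seq_start, e - seq_start
    return seq[:i] + v.alt + seq[j:]


def delta_pwm_score(
    v: VariantRecord,
    site: BindingSite,
    genome,
    matrix: LogOddsMatrix,
) -> float:
    """PWM-score change caused by a variant at a binding site.

    A window extending one motif length on each side of the site is
    rescanned on the alternate haplotype (both strands) and the change is
    best alternate score minus the reference site score.  Rescanning, as
    opposed to in-place scoring, keeps InDels that merely shift an intact
    motif from being called mutations.  A variant whose footprint lies
    outside the rescanned window contributes 0.
    """
    L = len(matrix)
    w0, w1 = max(0, site.start - L), site.end + L
    fp = v.normalized().footprint()
    if not (w0 <= fp[0] and fp[1] <= w1):
        return 0.0
    ref_window = str(genome[site.chrom][w0:w1])
    alt_window = apply_variant(ref_window, w0, v)
    alt_sites = scan_sites(matrix, alt_window, threshold=-np.inf, chrom=site.chrom, offset=w0)
    best_alt = max((s.score for s in alt_sites), default=matrix.min_score)
    return float(best_alt - site.score)


def is_motif_mutation(
    v: VariantRecord,
    site: BindingSite,
    genome,
    matrix: LogOddsMatrix,
    min_bits: float = MOTIF_MUTATION_BITS,
) -> bool:
    """At least a ``min_bits`` (default two-bit, inclusive) PWM-score change."""
    return abs(delta_pwm_score(v, site, genome, matrix)) >= min_bits


def impact_category(
    region: CoBindingRegion,
    variants: Sequence[VariantRecord],
    genome,
    matrixA: LogOddsMatrix,
    matrixB: LogOddsMatrix,
    other_motifs: Sequence[tuple[LogOddsMatrix, Sequence[BindingSite]]] = (),
    min_bits: float = MOTIF_MUTATION_BITS,
) -> ImpactCategory:
    """Assign the region's single impact category for a set of variants.

    Motif mutation categories take priority over spacing alteration:
    motif_A > motif_B > other motif > spacing alteration (any between-sites
    InDel without a motif mutation) > no_effect > variant_free.  Variants
    in background flanks or outside the span are ignored.
    """
    relevant = [
        (v, locate_variant(v, region))
        for v in variants
    ]
    relevant = [(v, loc) for v, loc in relevant if loc in ("at_site", "between_sites")]
    if not relevant:
        return ImpactCategory.VARIANT_FREE
    for v, _loc in relevant:
        if is_motif_mutation(v, region.siteA, genome, matrixA, min_bits):
            return ImpactCategory.MOTIF_A_MUTATION
    for v, _loc in relevant:
        if is_motif_mutation(v, region.siteB, genome, matrixB, min_bits):
            return ImpactCategory.MOTIF_B_MUTATION
    for matrix, sites in other_motifs:
        for v, _loc in relevant:
            for s in sites:
                if s.chrom == region.chrom and is_motif_mutation(v, s, genome, matrix, min_bits):
                    return ImpactCategory.OTHER_MOTIF_MUTATION
    for v, loc in relevant:
        if v.is_indel and loc == "between_sites":
            return ImpactCategory.SPACING_ALTERATION
    return ImpactCategory.NO_EFFECT


@dataclass
class EnrichmentResult:
    category: str
    region_kind: str
    a: float
    b: float
    c: float
    d: float
    odds_ratio: float
    log2_odds_ratio: float
    corrected: bool


def enrichment_odds_ratio(
    n_cat_region: int,
    n_other_region: int,
    n_cat_bg: int,
    n_other_bg: int,
    category: str = "",
    region_kind: str = "",
) -> EnrichmentResult:
    """Odds ratio (a/b)/(c/d) for a variant category in a region versus
    background, with a Haldane-Anscombe +0.5 applied to every cell iff any
    cell is zero (flagged in the result)."""
    a, b, c, d = (float(x) for x in (n_cat_region, n_other_region, n_cat_bg, n_other_bg))
    if min(a, b, c, d) < 0:
        raise VariantError("negative counts")
    if (a + b == 0) or (c + d == 0):
        raise VariantError("odds ratio undefined: empty margin")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a / b) / (c / d)
    return EnrichmentResult(
        category=category,
        region_kind=region_kind,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=odds_ratio,
        log2_odds_ratio=float(np.log2(odds_ratio)),
        corrected=corrected,
    )


def locate_and_classify(
    regions: Sequence[CoBindingRegion],
    variants: Sequence[VariantRecord],
    af_high: float = DEFAULT_AF_HIGH,
) -> pd.DataFrame:
    """Tabulate every (variant, region) localisation with the variant's
    frequency class.  Variants falling outside a region are omitted."""
    rows = []
    for ri, region in enumerate(regions):
        for v in variants:
            loc = locate_variant(v, region)
            if loc == "outside":
                continue
            rows.append(
                {
                    "region": ri,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "indel_size": v.indel_size,
                    "zone": loc,
                    "af_class": af_category(v, af_high=af_high),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "chrom", "pos", "ref", "alt", "indel_size", "zone", "af_class",
        ],
    )


def class_enrichment_table(
    located: pd.DataFrame,
    region_zone: str = "between_sites",
    background_zone: str = "background",
) -> pd.DataFrame:
    """Class-vs-rest enrichment odds ratios of each frequency class in a
    region zone against the background zone."""
    results = []
    sub = located[located["zone"].isin([region_zone, background_zone])]
    for cls in sorted(sub["af_class"].dropna().unique()):
        in_zone = sub["zone"] == region_zone
        is_cls = sub["af_class"] == cls
        res = enrichment_odds_ratio(
            int((in_zone & is_cls).sum()),
            int((in_zone & ~is_cls).sum()),
            int((~in_zone & is_cls).sum()),
            int((~in_zone & ~is_cls).sum()),
            category=cls,
            region_kind=region_zone,
        )
        results.append(res.__dict__)
    return pd.DataFrame(results)


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF 4.x file (plain text or bgzipped) with AF and AC INFO keys."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for i, alt in enumerate(rec.alts or ()):
                af = rec.info.get("AF")
                ac = rec.info.get("AC")
                if isinstance(af, tuple):
                    af = af[i] if i < len(af) else None
                if isinstance(ac, tuple):
                    ac = ac[i] if i < len(ac) else None
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        AF=None if af is None else float(af),
                        AC=None if ac is None else int(ac),
                    )
                )
    return out
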