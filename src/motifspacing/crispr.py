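"""Allele-specific TF binding across CRISPR-induced InDel spectra.

Cas9 editing of a population of cells generates a spectrum of InDels around
the cut site.  Deep amplicon sequencing of an input DNA sample and of a TF
ChIP sample lets each read report simultaneously which InDel its allele
carries and whether the TF was bound.  Reads are classified by their net
InDel size and by whether the InDel overlaps either of the two TF binding
sites in the test region; per group, allele-specific binding is the odds
ratio of ChIP tags to input tags:

    OR = (chip_g / (chip_total - chip_g)) / (input_g / (input_total - input_g))

reported as log2, so 0 means binding proportional to allele abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import BindingSite

DEFAULT_CUT_TOLERANCE = 10
DEFAULT_MIN_FRAC = 0.0005  # drop groups below 0.05% of input reads


class CrisprError(ValueError):
    pass


@dataclass(frozen=True)
class TestRegion:
    """An amplicon with two TF binding sites and the Cas9 cut site."""

    chrom: str
    start: int
    end: int
    siteA: BindingSite
    siteB: BindingSite
    cut_site: int

    def __post_init__(self) -> None:
        if not (self.start <= self.cut_site < self.end):
            raise CrisprError("cut site outside amplicon")
        for s in (self.siteA, self.siteB):
            if s.start < self.start or s.end > self.end:
                raise CrisprError("binding site outside amplicon")


@dataclass
class ReadRecord:
    name: str
    aln_start: int
    aln_end: int
    events: list[tuple[int, int]]  # (reference position, signed size)
    sample: str = "input"

    @property
    def net_size(self) -> int:
        return sum(size for _, size in self.events)


_CIGAR_CONSUMES_REF = set("MDN=X")
_CIGAR_CONSUMES_QUERY = set("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise CrisprError(f"malformed CIGAR: {cigar}")
            out.append((int(num), ch))
            num = ""
    if num:
        raise CrisprError(f"malformed CIGAR: {cigar}")
    return out


def extract_indels(
    aln_start: int, cigar: str, name: str = "", sample: str = "input"
) -> ReadRecord:
    """Turn each I/D CIGAR element into an event at its reference position:
    +len for an insertion (an inter-base point), -len for a deletion
    (spanning the deleted reference bases)."""
    pos = aln_start
    events = []
    for length, op in parse_cigar(cigar):
        if op == "I":
            events.append((pos, length))
        elif op == "D":
            events.append((pos, -length))
        if op in _CIGAR_CONSUMES_REF:
            pos += length
    return ReadRecord(name=name, aln_start=aln_start, aln_end=pos, events=events, sample=sample)


def read_sam(path, region: TestRegion, sample: str) -> tuple[list[ReadRecord], int]:
    """Parse aligned amplicon reads from a SAM file.

    Returns (reads, n_skipped) where skipped reads are unmapped or aligned
    off the test region's chromosome.
    """
    import pysam

    reads, skipped = [], 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name != region.chrom:
                skipped += 1
                continue
            reads.append(
                extract_indels(
                    rec.reference_start, rec.cigarstring or "", rec.query_name, sample
                )
            )
    return reads, skipped


def _event_interval(event: tuple[int, int]) -> tuple[int, int]:
    pos, size = event
    return (pos, pos) if size > 0 else (pos, pos - size)


def filter_unexpected_gaps(
    reads: Iterable[ReadRecord],
    region: TestRegion,
    cut_tolerance: int = DEFAULT_CUT_TOLERANCE,
) -> tuple[list[ReadRecord], int]:
    """Remove reads with InDels at unexpected locations away from the Cas9
    cut site.

    A read is valid iff every event's interval comes within
    ``cut_tolerance`` bp of the cut site; deletions spanning the cut site
    are always within distance 0.  Event-free reads are always valid.
    """
    valid, removed = [], 0
    cut = region.cut_site
    for read in reads:
        ok = True
        for event in read.events:
            s, e = _event_interval(event)
            if not (s - cut_tolerance <= cut <= e + cut_tolerance):
                ok = False
                break
        if ok:
            valid.append(read)
        else:
            removed += 1
    return valid, removed


def _overlaps_site(event: tuple[int, int], site: BindingSite) -> bool:
    s, e = _event_interval(event)
    if s == e:  # insertion point: strictly inside the site
        return site.start < s < site.end
    return s < site.end and site.start < e


def group_reads(
    reads: Iterable[ReadRecord], region: TestRegion
) -> dict[tuple[int, bool], dict[str, int]]:
    """Group reads by (net InDel size, overlaps-a-binding-site flag) and
    count per sample.  The groups partition the input reads."""
    groups: dict[tuple[int, bool], dict[str, int]] = {}
    for read in reads:
        overlaps = any(
            _overlaps_site(ev, site)
            for ev in read.events
            for site in (region.siteA, region.siteB)
        )
        key = (read.net_size, overlaps)
        per_sample = groups.setdefault(key, {})
        per_sample[read.sample] = per_sample.get(read.sample, 0) + 1
    return groups


def filter_groups(
    groups: dict[tuple[int, bool], dict[str, int]],
    input_total: int,
    min_frac: float = DEFAULT_MIN_FRAC,
    input_sample: str = "input",
) -> dict[tuple[int, bool], dict[str, int]]:
    """Drop InDel groups taking up strictly less than ``min_frac`` of the
    input sample reads."""
    if input_total <= 0:
        raise CrisprError("input total must be positive")
    return {
        key: counts
        for key, counts in groups.items()
        if counts.get(input_sample, 0) / input_total >= min_frac
    }


@dataclass
class GroupOddsRatio:
    net_size: int
    overlaps_site: bool
    chip_tags: int
    input_tags: int
    odds_ratio: float
    log2_odds_ratio: float
    corrected: bool


def group_odds_ratio(
    chip_tags: int, input_tags: int, chip_total: int, input_total: int
) -> tuple[float, bool]:
    """Allele-specific binding odds ratio of one InDel group; +0.5 Haldane
    correction on every cell iff any cell is zero.  Returns (log2 OR,
    corrected flag)."""
    cells = [
        float(chip_tags),
        float(chip_total - chip_tags),
        float(input_tags),
        float(input_total - input_tags),
    ]
    if min(cells) < 0:
        raise CrisprError("group tags exceed totals")
    corrected = min(cells) == 0
    if corrected:
        cells = [c + 0.5 for c in cells]
    cg, crest, ig, irest = cells
    return float(np.log2((cg / crest) / (ig / irest))), corrected


def group_table(
    groups: dict[tuple[int, bool], dict[str, int]],
    chip_sample: str = "chip",
    input_sample: str = "input",
) -> pd.DataFrame:
    """Per-group log2 odds ratios.  Groups absent from the input sample are
    not computed (their odds are undefined)."""
    chip_total = sum(c.get(chip_sample, 0) for c in groups.values())
    input_total = sum(c.get(input_sample, 0) for c in groups.values())
    rows = []
    for (net, overlaps), counts in sorted(groups.items()):
        itags = counts.get(input_sample, 0)
        if itags == 0:
            continue
        ctags = counts.get(chip_sample, 0)
        log2_or, corrected = group_odds_ratio(ctags, itags, chip_total, input_total)
        rows.append(
            GroupOddsRatio(
                net_size=net,
                overlaps_site=overlaps,
                chip_tags=ctags,
                input_tags=itags,
                odds_ratio=float(2.0 ** log2_or),
                log2_odds_ratio=log2_or,
                corrected=corrected,
            ).__dict__
        )
    return pd.DataFrame(rows)


def compare_group_classes(spacing_only_log2or, site_overlap_log2or) -> float:
    """Welch two-sample t-test (two-sided) between log2 odds ratios of
    spacing-only and site-overlapping InDel groups."""
    x = np.asarray(spacing_only_log2or, dtype=float)
    y = np.asarray(site_overlap_log2or, dtype=float)
    if x.size < 2 or y.size < 2:
        raise CrisprError("each class needs at least 2 groups")
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def quantify_region(
    chip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    region: TestRegion,
    cut_tolerance: int = DEFAULT_CUT_TOLERANCE,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> tuple[pd.DataFrame, dict]:
    """Full per-region quantification.

    Filters unexpected gaps per sample, groups retained reads, drops rare
    groups, computes per-group log2 odds ratios (denominators use
    post-filtering retained reads of each sample) and the spacing-vs-site
    t-test.  Returns (group table, summary stats).
    """
    chip_valid, chip_removed = filter_unexpected_gaps(chip_reads, region, cut_tolerance)
    input_valid, input_removed = filter_unexpected_gaps(input_reads, region, cut_tolerance)
    groups = group_reads(chip_valid + input_valid, region)
    input_total = len(input_valid)
    kept = filter_groups(groups, input_total, min_frac=min_frac)
    table = group_table(kept)
    stats_out = {
        "chip_removed": chip_removed,
        "input_removed": input_removed,
        "chip_retained": len(chip_valid),
        "input_retained": len(input_valid),
        "n_groups": len(kept),
    }
    exclude_intact = table[table["net_size"] != 0]
    spacing_vals = exclude_intact.loc[~exclude_intact["overlaps_site"], "log2_odds_ratio"]
    overlap_vals = exclude_intact.loc[exclude_intact["overlaps_site"], "log2_odds_ratio"]
    if len(spacing_vals) >= 2 and len(overlap_vals) >= 2:
        stats_out["t_test_p"] = compare_group_classes(spacing_vals, overlap_vals)
    else:
        stats_out["t_test_p"] = float("nan")
    return table, stats_out
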