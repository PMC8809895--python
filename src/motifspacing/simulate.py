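"""Synthetic regulatory-genomics data with planted ground truth.

Every input the analysis consumes can be generated here: a random genome
with planted co-binding motif pairs under a chosen spacing model, gnomAD-
style variants with an allele-frequency spectrum, per-strain tag counts
with binding-loss effects tied to motif mutation, and CRISPR amplicon read
spectra for paired input/ChIP samples.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import (
    BASES,
    BindingSite,
    LogOddsMatrix,
    PWM,
    Peak,
    reverse_complement,
)
from .spacing import DEFAULT_WINDOW, ORIENTATIONS
from .variants import CoBindingRegion, ImpactCategory, VariantRecord

#: Diploid genomes behind the allele-frequency spectrum (gnomAD-scale
#: cohort of unrelated individuals).
DEFAULT_N_GENOMES = 75_000


class SimulationError(ValueError):
    pass


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome and spacing models


def simulate_genome(length: int, gc_fraction: float = 0.41, seed=0) -> str:
    """An i.i.d. random nucleotide sequence at the requested GC content."""
    if length < 1:
        raise SimulationError("length must be >= 1")
    rng = _rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(BASES[c] for c in codes)


@dataclass
class SpacingModel:
    """Generative model of signed edge-to-edge spacings for a TF pair.

    kind:
      constrained -- a fraction ``concentration`` of spacings at s0 with
        Gaussian jitter (sd ``jitter_sd``), the rest uniform;
      relaxed -- P(i) proportional to exp(-decay * |i|), emulating
        co-binding frequency that declines smoothly with distance;
      uniform -- no spacing preference.
    """

    kind: str = "uniform"
    s0: int = 7
    concentration: float = 0.3
    jitter_sd: float = 0.0
    decay: float = 0.03
    orientation_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.kind not in ("constrained", "relaxed", "uniform"):
            raise SimulationError(f"unknown spacing model kind {self.kind!r}")
        if not math.isclose(sum(self.orientation_probs), 1.0, abs_tol=1e-9):
            raise SimulationError("orientation probabilities must sum to 1")
        if self.kind == "relaxed" and self.decay <= 0:
            raise SimulationError("decay must be positive")
        if self.kind == "constrained" and not 0 < self.concentration <= 1:
            raise SimulationError("concentration must be in (0, 1]")


def sample_spacings(model: SpacingModel, n: int, seed=0) -> np.ndarray:
    """Draw n signed spacings on [-window, window] from the model."""
    rng = _rng(seed)
    w = model.window
    if model.kind == "uniform":
        return rng.integers(-w, w + 1, size=n)
    if model.kind == "relaxed":
        support = np.arange(-w, w + 1)
        p = np.exp(-model.decay * np.abs(support))
        return rng.choice(support, size=n, p=p / p.sum())
    spacings = rng.integers(-w, w + 1, size=n)
    at_spike = rng.random(n) < model.concentration
    jitter = (
        np.rint(rng.normal(0.0, model.jitter_sd, size=n)).astype(int)
        if model.jitter_sd > 0
        else np.zeros(n, dtype=int)
    )
    spacings[at_spike] = np.clip(model.s0 + jitter[at_spike], -w, w)
    return spacings


def sample_orientations(model: SpacingModel, n: int, seed=0) -> list[str]:
    rng = _rng(seed)
    return list(rng.choice(ORIENTATIONS, size=n, p=model.orientation_probs))


def sample_motif_instance(
    pwm: PWM, seed=0, min_score: float | None = None, max_tries: int = 100
) -> str:
    """Sample a motif instance base-by-base from the PWM columns; when
    ``min_score`` is given, resample until the instance scores at least
    that (falling back to the consensus after ``max_tries``)."""
    rng = _rng(seed)
    matrix = pwm.log_odds()
    for _ in range(max_tries):
        codes = [rng.choice(4, p=row) for row in pwm.probs]
        inst = "".join(BASES[c] for c in codes)
        if min_score is None or matrix.score(inst) >= min_score:
            return inst
    return matrix.consensus


def plant_cobinding(
    genome: str,
    pwmA: PWM,
    pwmB: PWM,
    n_regions: int,
    model: SpacingModel,
    seed=0,
    chrom: str = "chr1",
    peak_width: int = 200,
    stride: int = 600,
    min_score_A: float | None = None,
    min_score_B: float | None = None,
) -> tuple[str, list[Peak], list[Peak], pd.DataFrame]:
    """Write motif-instance pairs into a genome at sampled spacings.

    Regions are laid out every ``stride`` bp.  Each region gets an A
    instance and a B instance at the sampled signed spacing and
    orientation; a ``peak_width`` peak is centred on each planted site.
    Returns (modified sequence, peaksA, peaksB, truth table).
    """
    rng = _rng(seed)
    LA, LB = len(pwmA), len(pwmB)
    margin = peak_width + model.window + LA + LB
    needed = margin * 2 + (n_regions - 1) * stride
    if needed > len(genome):
        raise SimulationError(
            f"genome of length {len(genome)} too short for {n_regions} regions "
            f"(need {needed})"
        )
    spacings = sample_spacings(model, n_regions, rng)
    orientations = sample_orientations(model, n_regions, rng)
    seq = bytearray(genome.encode("ascii"))
    peaksA, peaksB, rows = [], [], []
    for k in range(n_regions):
        anchor = margin + k * stride
        s = int(spacings[k])
        strandA, strandB = orientations[k]
        instA = sample_motif_instance(pwmA, rng, min_score=min_score_A)
        instB = sample_motif_instance(pwmB, rng, min_score=min_score_B)
        a_start, a_end = anchor, anchor + LA
        # B downstream of A (3' relative to A's strand) for s >= 0
        b_right = (s >= 0) == (strandA == "+")
        gap = abs(s)
        if b_right:
            b_start = a_end + gap
        else:
            b_start = a_start - gap - LB
        b_end = b_start + LB
        seq[a_start:a_end] = (
            instA if strandA == "+" else reverse_complement(instA)
        ).encode("ascii")
        seq[b_start:b_end] = (
            instB if strandB == "+" else reverse_complement(instB)
        ).encode("ascii")
        mA, mB = (a_start + a_end) // 2, (b_start + b_end) // 2
        peaksA.append(Peak(chrom, mA - peak_width // 2, mA + peak_width // 2, pwmA.name))
        peaksB.append(Peak(chrom, mB - peak_width // 2, mB + peak_width // 2, pwmB.name))
        rows.append(
            {
                "region": k,
                "chrom": chrom,
                "startA": a_start,
                "endA": a_end,
                "strandA": strandA,
                "startB": b_start,
                "endB": b_end,
                "strandB": strandB,
                "spacing": s,
                "orientation": strandA + strandB,
                "instanceA": instA,
                "instanceB": instB,
            }
        )
    return seq.decode("ascii"), peaksA, peaksB, pd.DataFrame(rows)


def regions_from_truth(
    truth: pd.DataFrame, tfA: str = "A", tfB: str = "B", flank: int = 100
) -> list[CoBindingRegion]:
    """Build CoBindingRegion objects from a plant_cobinding truth table."""
    regions = []
    for row in truth.itertuples():
        siteA = BindingSite(row.chrom, row.startA, row.endA, row.strandA, 0.0, tfA)
        siteB = BindingSite(row.chrom, row.startB, row.endB, row.strandB, 0.0, tfB)
        if siteA.overlaps(siteB):
            continue
        regions.append(CoBindingRegion(siteA=siteA, siteB=siteB, flank=flank))
    return regions


# ---------------------------------------------------------------------------
# variants


_AF_CLASSES = ("singleton", "rare", "high_frequency")


def _sample_ac(cls: str, rng: np.random.Generator, n_genomes: int) -> int:
    """Allele count from a zeta-like (power-law) spectrum within the
    class's AC range; AF = AC / (2 * n_genomes)."""
    max_rare = int(1e-4 * 2 * n_genomes)  # AF <= 0.01% boundary
    if cls == "singleton":
        return 1
    if cls == "rare":
        support = np.arange(2, max_rare + 1)
    else:
        support = np.arange(max_rare + 1, max(10 * max_rare, max_rare + 2))
    w = support.astype(float) ** -1.6
    return int(rng.choice(support, p=w / w.sum()))


def simulate_variants(
    regions: Sequence[CoBindingRegion],
    genome: str,
    base_rates: Mapping[str, float] | None = None,
    zone_multipliers: Mapping[str, Mapping[str, float]] | None = None,
    p_indel: float = 0.5,
    indel_geom_p: float = 0.45,
    n_genomes: int = DEFAULT_N_GENOMES,
    seed=0,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Place SNPs and InDels in region zones with class-specific rates.

    ``base_rates`` gives the per-bp Poisson rate of each frequency class
    (singleton / rare / high_frequency); ``zone_multipliers`` scales a
    class's rate inside a zone ('site', 'between', 'flank'), e.g.
    ``{"between": {"singleton": 2.0}}`` plants a two-fold singleton
    enrichment between the motifs.  InDel sizes are geometric (most under
    5 bp), insertions and deletions equally likely; deletions are kept
    inside their zone so planted zone labels stay exact.
    """
    rng = _rng(seed)
    rates = dict(base_rates or {"singleton": 0.04, "rare": 0.03, "high_frequency": 0.01})
    zmult = {z: dict(m) for z, m in (zone_multipliers or {}).items()}
    variants, rows = [], []
    for ri, region in enumerate(regions):
        zones = {
            "site": [
                (region.siteA.start, region.siteA.end),
                (region.siteB.start, region.siteB.end),
            ],
            "between": [region.between],
            "flank": [region.flank_up, region.flank_down],
        }
        for zone, intervals in zones.items():
            intervals = [(s, e) for s, e in intervals if e > s]
            length = sum(e - s for s, e in intervals)
            if length == 0:
                continue
            for cls in _AF_CLASSES:
                mult = zmult.get(zone, {}).get(cls, 1.0)
                n = rng.poisson(rates[cls] * length * mult)
                for _ in range(n):
                    v = _place_variant(
                        intervals, genome, cls, zone, rng, p_indel, indel_geom_p, n_genomes
                    )
                    if v is None:
                        continue
                    variants.append(v)
                    rows.append(
                        {
                            "region": ri,
                            "zone": zone,
                            "af_class": cls,
                            "pos": v.pos,
                            "indel_size": v.indel_size,
                        }
                    )
    truth = pd.DataFrame(rows, columns=["region", "zone", "af_class", "pos", "indel_size"])
    return variants, truth


def _place_variant(
    intervals, genome, cls, zone, rng, p_indel, indel_geom_p, n_genomes
) -> VariantRecord | None:
    lens = np.array([e - s for s, e in intervals], dtype=float)
    s, e = intervals[rng.choice(len(intervals), p=lens / lens.sum())]
    ac = _sample_ac(cls, rng, n_genomes)
    af = ac / (2 * n_genomes)
    chrom = "chr1"
    if rng.random() >= p_indel:  # SNP
        pos = int(rng.integers(s, e))
        ref = genome[pos]
        alt = BASES[(rng.integers(1, 4) + BASES.index(ref)) % 4]
        return VariantRecord(chrom, pos, ref, alt, AF=af, AC=ac)
    size = int(rng.geometric(indel_geom_p))
    if rng.random() < 0.5:  # insertion at an inter-base point strictly inside
        if e - s < 3:
            return None
        p = int(rng.integers(s + 1, e))
        anchor = p - 1
        inserted = "".join(BASES[c] for c in rng.integers(0, 4, size=size))
        return VariantRecord(chrom, anchor, genome[anchor], genome[anchor] + inserted, AF=af, AC=ac)
    # deletion kept inside the zone interval
    size = min(size, e - s - 1) if e - s > 1 else 0
    if size < 1:
        return None
    start = int(rng.integers(s, e - size + 1))
    anchor = start - 1
    if anchor < 0:
        return None
    ref = genome[anchor : start + size]
    return VariantRecord(chrom, anchor, ref, genome[anchor], AF=af, AC=ac)


# ---------------------------------------------------------------------------
# strain tags


DEFAULT_EFFECT_MAP = {
    ImpactCategory.MOTIF_A_MUTATION.value: 0.25,
    ImpactCategory.MOTIF_B_MUTATION.value: 0.25,
    ImpactCategory.OTHER_MOTIF_MUTATION.value: 0.5,
    ImpactCategory.SPACING_ALTERATION.value: 1.0,
    ImpactCategory.NO_EFFECT.value: 1.0,
    ImpactCategory.VARIANT_FREE.value: 1.0,
}


def _negative_binomial(rng, mean, dispersion, size):
    """NB with var = mean + mean^2 / dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_strain_tags(
    categories: Sequence[str | ImpactCategory],
    n_strains: int = 2,
    depth: float = 100.0,
    dispersion: float = 10.0,
    effect_map: Mapping[str, float] | None = None,
    seed=0,
) -> pd.DataFrame:
    """Per-strain tag counts at regions aligned across strains.

    The reference strain draws NB(depth) at every region; each alternate
    strain draws NB(depth * multiplier(category)), modelling binding loss
    at regions whose variant mutates a motif.  Returns a table with one
    row per region: category, ref_tags, strain_1..(n_strains-1) columns.
    """
    rng = _rng(seed)
    effects = dict(DEFAULT_EFFECT_MAP)
    effects.update(effect_map or {})
    cats = [c.value if isinstance(c, ImpactCategory) else str(c) for c in categories]
    mult = np.array([effects[c] for c in cats])
    if np.any(mult <= 0):
        raise SimulationError("effect multipliers must be positive")
    n = len(cats)
    out = {"category": cats, "ref_tags": _negative_binomial(rng, depth, dispersion, n)}
    for k in range(1, n_strains):
        out[f"strain_{k}"] = _negative_binomial(rng, depth * mult, dispersion, n)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# CRISPR amplicon reads


@dataclass
class CrisprSpectrumEntry:
    size: int  # signed: negative deletion, positive insertion
    prob: float


def default_indel_spectrum(
    max_small_deletion: int = 22,
    max_insertion: int = 5,
    large_deletions: Sequence[int] = (44, 48, 52, 56),
) -> dict[int, float]:
    """A Cas9-like spectrum: mostly sub-30-bp deletions centred on the cut
    site, short insertions, and a small mass of long deletions reaching the
    flanking binding sites.  Remaining probability mass is unedited reads."""
    spectrum: dict[int, float] = {}
    for d in range(1, max_small_deletion + 1):
        spectrum[-d] = 0.018
    for i in range(1, max_insertion + 1):
        spectrum[i] = 0.02
    for d in large_deletions:
        spectrum[-d] = 0.0125
    total = sum(spectrum.values())
    if total > 1:
        raise SimulationError("spectrum exceeds probability 1")
    return spectrum


def _indel_placement(size: int, cut: int) -> tuple[int, int]:
    """Reference interval affected by an InDel of signed ``size`` placed at
    the cut site: deletions centred on the cut, insertions at the cut
    point (zero width)."""
    if size >= 0:
        return cut, cut
    d = -size
    start = cut - d // 2
    return start, start + d


def simulate_crispr_reads(
    region,
    region_seq: str,
    depth: int = 100_000,
    indel_spectrum: Mapping[int, float] | None = None,
    binding_loss_overlap: float = 0.1,
    binding_loss_spacing: float = 1.0,
    seed=0,
    out_dir=None,
    read_length: int | None = None,
) -> dict:
    """Paired input/ChIP amplicon read sets over a CRISPR InDel spectrum.

    Input reads are multinomial over the spectrum (the remainder of the
    probability mass is unedited reads); ChIP reads are resampled with
    probability proportional to the binding multiplier of each read's
    group: ``binding_loss_overlap`` for InDels overlapping a binding site,
    ``binding_loss_spacing`` for pure spacing alterations, 1.0 for
    unedited alleles.  When ``out_dir`` is given, SAM files with
    consistent CIGARs and sequences are written.

    Returns a dict with group truth table, per-group input/chip counts and
    SAM paths (if written).
    """
    rng = _rng(seed)
    spectrum = dict(indel_spectrum if indel_spectrum is not None else default_indel_spectrum())
    sizes = sorted(spectrum)
    probs = np.array([spectrum[s] for s in sizes])
    if probs.sum() > 1 + 1e-9:
        raise SimulationError("spectrum probabilities exceed 1")
    sizes = [0] + sizes
    probs = np.concatenate([[1.0 - probs.sum()], probs])

    cut = region.cut_site
    overlaps = []
    for size in sizes:
        s, e = _indel_placement(size, cut)
        hit = False
        if size != 0:
            for site in (region.siteA, region.siteB):
                if s == e:
                    hit = hit or site.start < s < site.end
                else:
                    hit = hit or (s < site.end and site.start < e)
        overlaps.append(hit)
    multipliers = np.array(
        [
            1.0 if size == 0 else (binding_loss_overlap if hit else binding_loss_spacing)
            for size, hit in zip(sizes, overlaps)
        ]
    )
    input_counts = rng.multinomial(depth, probs)
    chip_probs = probs * multipliers
    chip_probs = chip_probs / chip_probs.sum()
    chip_counts = rng.multinomial(depth, chip_probs)

    truth = pd.DataFrame(
        {
            "net_size": sizes,
            "overlaps_site": overlaps,
            "input_prob": probs,
            "binding_multiplier": multipliers,
            "input_count": input_counts,
            "chip_count": chip_counts,
        }
    )
    result = {"truth": truth, "region": region}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result["input_sam"] = _write_sam(
            out_dir / "input.sam", region, region_seq, sizes, input_counts, rng, "input"
        )
        result["chip_sam"] = _write_sam(
            out_dir / "chip.sam", region, region_seq, sizes, chip_counts, rng, "chip"
        )
    return result


def _write_sam(path, region, region_seq, sizes, counts, rng, sample) -> Path:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": region.chrom, "LN": max(region.end, len(region_seq))}],
    }
    amp_len = region.end - region.start
    seq0 = region_seq[region.start - 0 : region.end] if len(region_seq) >= region.end else region_seq
    cut_off = region.cut_site - region.start
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for size, count in zip(sizes, counts):
            if count == 0:
                continue
            s, e = _indel_placement(size, region.cut_site)
            if size == 0:
                cigar = f"{amp_len}M"
                qseq = seq0
            elif size < 0:
                pre = s - region.start
                post = amp_len - (e - region.start)
                cigar = f"{pre}M{-size}D{post}M"
                qseq = seq0[:pre] + seq0[pre + (-size) :]
            else:
                ins = "".join(BASES[c] for c in rng.integers(0, 4, size=size))
                cigar = f"{cut_off}M{size}I{amp_len - cut_off}M"
                qseq = seq0[:cut_off] + ins + seq0[cut_off:]
            for _ in range(int(count)):
                rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                rec.query_name = f"{sample}_{n}"
                rec.reference_id = 0
                rec.reference_start = region.start
                rec.mapping_quality = 60
                rec.cigarstring = cigar
                rec.query_sequence = qseq
                rec.flag = 0
                sam.write(rec)
                n += 1
    return Path(path)
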