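"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA, BED, VCF, and the TSV tables of sites, spacings and groups."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifs import BindingSite, Peak
from .spacing import SpacingDistribution
from .variants import VariantRecord


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def open_genome(path):
    """Indexed FASTA access via pyfaidx."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_peaks_bed(peaks: Sequence[Peak], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf}\n")
    return path


def read_peaks_bed(path, tf: str = "", width: int | None = 200) -> list[Peak]:
    """Read BED/narrowPeak intervals as peaks, optionally re-standardising
    each to a fixed width around its midpoint."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else tf
            if width is not None:
                center = (start + end) // 2
                start = max(0, center - width // 2)
                end = start + width
            peaks.append(Peak(chrom=chrom, start=start, end=end, tf=name or tf))
    return peaks


def write_sites_bed(sites: Sequence[BindingSite], path) -> Path:
    """BED6: name = TF, score = bits x 100 rounded, strand column."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.tf}\t{round(s.score * 100)}\t{s.strand}\n"
            )
    return path


def write_sites_tsv(sites: Sequence[BindingSite], path) -> Path:
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "score_bits": s.score,
                "tf": s.tf,
            }
            for s in sites
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_spacing_tsv(dist: SpacingDistribution, path) -> Path:
    df = pd.DataFrame({"spacing": dist.support, "count": dist.counts})
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_vcf(
    variants: Sequence[VariantRecord], path, contigs: Mapping[str, int]
) -> Path:
    """Write a minimal VCF 4.2 with AF and AC INFO fields (1-based POS)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = f"AF={v.AF:.6g};AC={v.AC}"
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")
    return path
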