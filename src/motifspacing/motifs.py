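"""Position weight matrices and binding-site calling.

Motifs are modelled as position probability matrices over (A, C, G, T) and
scored in log2-odds units ("bits") against a background base composition.
Binding sites are called with a score threshold calibrated to a target false
positive rate under an i.i.d. uniform-base null, and then restricted to the
neighbourhood of ChIP-seq peak centers.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as _bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


class MotifError(ValueError):
    """Base class for motif-model errors."""


class UntrimmableMotifError(MotifError):
    """No motif position exceeds the information-content threshold."""


class UnattainableFPRError(MotifError):
    """The requested FPR is below the smallest achievable tail probability."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position probability matrix for one transcription factor motif.

    probs[j, b] is the probability of base b (A,C,G,T order) at motif
    position j.  Rows sum to one; the pseudocount recorded here is the one
    used when the matrix was derived from counts.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise MotifError(f"{self.name}: probs must be an Lx4 matrix with L >= 1")
        if np.any(probs < 0) or np.any(probs > 1):
            raise MotifError(f"{self.name}: probabilities outside [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise MotifError(f"{self.name}: rows must sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise MotifError(f"{self.name}: background must sum to 1")
        if self.pseudocount < 0:
            raise MotifError(f"{self.name}: pseudocount must be nonnegative")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> "LogOddsMatrix":
        """log2(p/background) per position and base; finite for pseudocount > 0."""
        with np.errstate(divide="ignore"):
            matrix = np.log2(self.probs / self.background[None, :])
        return LogOddsMatrix(name=self.name, matrix=matrix)


@dataclass(frozen=True)
class LogOddsMatrix:
    """Log2-odds scoring matrix derived from a PWM; scores are in bits."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def reverse_complement(self) -> "LogOddsMatrix":
        return LogOddsMatrix(name=self.name, matrix=self.matrix[::-1, ::-1])

    def score(self, kmer: str) -> float:
        if len(kmer) != len(self):
            raise MotifError("k-mer length does not match motif length")
        codes = encode_sequence(kmer)
        if np.any(codes > 3):
            raise MotifError("cannot score a k-mer containing N")
        return float(self.matrix[np.arange(len(self)), codes].sum())


@dataclass(frozen=True)
class BindingSite:
    """One motif match: 0-based half-open interval, strand and score in bits."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    tf: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MotifError("binding site must have positive length")
        if self.strand not in "+-":
            raise MotifError("strand must be '+' or '-'")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "BindingSite") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak, standardised to a fixed width (200 bp by default)."""

    chrom: str
    start: int
    end: int
    tf: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MotifError("peak must have positive length")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and any other letter (N etc.) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def parse_jaspar(
    stream,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Parse JASPAR-format count matrices into probability PWMs.

    Counts are converted column-wise to probabilities after adding
    ``4 * pseudocount * background_b`` to each cell, i.e. a full pseudocount
    per cell under the uniform background, distributed proportionally for a
    non-uniform one.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    text = stream.read()
    if not text.strip():
        return []
    try:
        records = _bio_motifs.parse(io.StringIO(text), "jaspar")
        parsed = [(m.name or m.matrix_id, m.counts) for m in records]
    except Exception as exc:  # ragged rows, bad headers, ...
        raise MotifError(f"malformed JASPAR input: {exc}") from exc
    pwms = []
    for name, counts in parsed:
        mat = np.array([counts[b] for b in BASES], dtype=float).T  # L x 4
        if mat.shape[0] < 1:
            raise MotifError(f"{name}: empty count matrix")
        add = 4.0 * pseudocount * bg
        probs = (mat + add[None, :]) / (mat.sum(axis=1) + add.sum())[:, None]
        pwms.append(PWM(name=name, probs=probs, background=bg, pseudocount=pseudocount))
    return pwms


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits under a uniform background.

    IC_j = 2 + sum_b p_jb log2 p_jb, with 0*log2(0) taken as 0; ranges from
    0 (uninformative) to 2 bits (a fully determined base).
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + terms.sum(axis=1)


def trim_pwm(pwm: PWM, ic_threshold: float = 0.3) -> PWM:
    """Trim a PWM to its core: the span from the first to the last position
    with information content strictly greater than ``ic_threshold``.

    Interior low-IC positions are retained.  Raises
    :class:`UntrimmableMotifError` when no position passes, mirroring the
    exclusion of factors without a confident core motif.
    """
    ic = information_content(pwm)
    passing = np.flatnonzero(ic > ic_threshold)
    if passing.size == 0:
        raise UntrimmableMotifError(f"{pwm.name}: no position with IC > {ic_threshold}")
    first, last = passing[0], passing[-1]
    return PWM(
        name=pwm.name,
        probs=pwm.probs[first : last + 1],
        background=pwm.background,
        pseudocount=pwm.pseudocount,
    )


def score_distribution(
    matrix: LogOddsMatrix, precision: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Exact score distribution of the motif under i.i.d. uniform bases.

    Scores are binned at ``precision`` bits and the per-position
    distributions convolved.  Returns (scores, probabilities) with scores
    ascending; probabilities sum to 1.
    """
    scaled = np.rint(matrix.matrix / precision).astype(np.int64)  # L x 4
    offset = int(scaled.min(axis=1).sum())
    pmf = np.array([1.0])
    for row in scaled:
        shifted = row - row.min()
        new = np.zeros(len(pmf) + int(shifted.max()))
        for v in shifted:
            new[v : v + len(pmf)] += 0.25 * pmf
        pmf = new
    support = np.nonzero(pmf)[0]
    scores = (support + offset) * precision
    return scores, pmf[support]


def fpr_threshold(
    matrix: LogOddsMatrix,
    fpr: float = 0.001,
    precision: float = 1e-3,
) -> float:
    """Smallest score threshold t with P(score >= t) <= fpr under the
    uniform-base null (25% A, C, G, T).

    Raises :class:`UnattainableFPRError` when even the top score bin has
    tail probability above ``fpr`` (e.g. very short motifs).
    """
    if not 0.0 < fpr < 1.0:
        raise MotifError("fpr must be in (0, 1)")
    scores, probs = score_distribution(matrix, precision=precision)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[k] = P(score >= scores[k])
    passing = np.flatnonzero(tail <= fpr)
    if passing.size == 0:
        raise UnattainableFPRError(
            f"{matrix.name}: smallest achievable tail {tail[-1]:.3g} exceeds fpr {fpr:g}"
        )
    return float(scores[passing[0]])


def achieved_fpr(matrix: LogOddsMatrix, threshold: float, precision: float = 1e-3) -> float:
    """Exact tail probability P(score >= threshold) under the uniform null."""
    scores, probs = score_distribution(matrix, precision=precision)
    return float(probs[scores >= threshold - precision / 2].sum())


def scan_sites(
    matrix: LogOddsMatrix,
    seq: str,
    threshold: float,
    chrom: str = "seq",
    offset: int = 0,
) -> list[BindingSite]:
    """Report every window on either strand scoring at least ``threshold``.

    Coordinates are 0-based half-open on the forward strand; reverse-strand
    hits are scored on the reverse complement of the window.  Windows
    containing N are skipped.
    """
    L = len(matrix)
    codes = encode_sequence(seq)
    if codes.size < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~np.any(windows > 3, axis=1)
    idx = np.arange(L)
    sites: list[BindingSite] = []
    for strand, m in (("+", matrix.matrix), ("-", matrix.reverse_complement().matrix)):
        safe = np.where(windows > 3, 0, windows)
        scores = m[idx, safe].sum(axis=1)
        hits = np.flatnonzero(valid & (scores >= threshold))
        for i in hits:
            sites.append(
                BindingSite(
                    chrom=chrom,
                    start=offset + int(i),
                    end=offset + int(i) + L,
                    strand=strand,
                    score=float(scores[i]),
                    tf=matrix.name,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def sites_near_center(
    sites: Iterable[BindingSite], peak: Peak, max_dist: int = 50
) -> list[BindingSite]:
    """Keep sites whose midpoint lies within ``max_dist`` bp of the peak
    center (inclusive bound)."""
    return [
        s
        for s in sites
        if s.chrom == peak.chrom and abs(s.midpoint - peak.center) <= max_dist
    ]


def call_sites_in_peak(
    matrix: LogOddsMatrix,
    genome,
    peak: Peak,
    threshold: float,
    max_dist: int = 50,
    pad: int = 100,
) -> list[BindingSite]:
    """Scan a padded window around a peak and keep sites near its center.

    ``genome`` is any mapping chrom -> sequence supporting slicing
    (a pyfaidx.Fasta or a plain dict of strings).
    """
    start = max(0, peak.start - pad)
    seq = str(genome[peak.chrom][start : peak.end + pad])
    sites = scan_sites(matrix, seq, threshold, chrom=peak.chrom, offset=start)
    return sites_near_center(sites, peak, max_dist=max_dist)
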