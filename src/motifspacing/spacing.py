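"""Motif-spacing distributions and their classification.

For a pair of co-binding transcription factors the signed edge-to-edge
spacings between their motif matches are aggregated into per-orientation
histograms over [-100, +100] bp.  Two complementary tests classify each
distribution:

* a Monte-Carlo "spike" test on point-to-point slopes detects sharp
  over-representation at exact spacings (a *constrained* relationship), and
* a repeated two-sample Kolmogorov-Smirnov test against uniform spacings
  detects a smooth distance-dependent preference (a *relaxed* relationship).

A pair with a significant spike is constrained regardless of the KS result;
otherwise a small mean KS p-value labels it relaxed, and anything else is
left unclassified ("none").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .motifs import BindingSite, Peak

ORIENTATIONS = ("++", "+-", "-+", "--")

#: Familywise spike significance level: 0.05 corrected for ~200 slope
#: positions and the four motif-orientation combinations.
DEFAULT_ALPHA_SPIKE = 0.05 / 200 / 4

DEFAULT_ALPHA_RELAXED = 1e-3

DEFAULT_WINDOW = 100


class SpacingError(ValueError):
    pass


@dataclass
class CoBindingEvent:
    """A pair of overlapping peaks for two TFs, with their motif sites."""

    peakA: Peak
    peakB: Peak
    sitesA: list[BindingSite] = field(default_factory=list)
    sitesB: list[BindingSite] = field(default_factory=list)


@dataclass
class SpacingDistribution:
    """Integer spacing counts N_i for i in [-window, window] (201 bins)."""

    counts: np.ndarray
    orientation: str = "++"
    tfA: str = ""
    tfB: str = ""
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2 * self.window + 1,):
            raise SpacingError(
                f"counts must have length {2 * self.window + 1}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise SpacingError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def support(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def to_spacings(self) -> np.ndarray:
        """Expand the histogram back into a vector of spacing values."""
        return np.repeat(self.support, self.counts)


@dataclass
class SpacingRelationship:
    label: str  # constrained | relaxed | none
    spike_positions: list[tuple[int, float]]
    ks_mean_p: float
    alpha_spike: float = DEFAULT_ALPHA_SPIKE
    alpha_relaxed: float = DEFAULT_ALPHA_RELAXED
    orientation: str = ""
    tfA: str = ""
    tfB: str = ""


def cobinding_events(
    peaksA: Sequence[Peak], peaksB: Sequence[Peak]
) -> list[CoBindingEvent]:
    """One event per intersecting (A, B) peak pair.

    Intersection requires at least one shared base under 0-based half-open
    semantics, so peaks that merely touch do not co-bind.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaksB:
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: p.start)
    events = []
    for a in peaksA:
        blist = by_chrom.get(a.chrom, ())
        starts = [b.start for b in blist]
        # candidates: all B peaks with start < a.end; prune by end > a.start
        hi = np.searchsorted(starts, a.end)
        for b in blist[:hi]:
            if b.end > a.start:
                events.append(CoBindingEvent(peakA=a, peakB=b))
    return events


def _signed_spacing(a: BindingSite, b: BindingSite) -> int | None:
    """Edge-to-edge gap, signed relative to site A's strand; None if the
    sites overlap."""
    if a.start < b.end and b.start < a.end:
        return None
    if a.end <= b.start:
        gap = b.start - a.end
        b_is_downstream = a.strand == "+"
    else:
        gap = a.start - b.end
        b_is_downstream = a.strand == "-"
    return gap if b_is_downstream else -gap


def pairwise_spacings(
    event: CoBindingEvent, window: int = DEFAULT_WINDOW
) -> list[tuple[int, str]]:
    """All (spacing, orientation) pairs for one co-binding event.

    Every combination of a site for TF A with a site for TF B contributes
    one spacing; overlapping site pairs are excluded, as are gaps beyond
    ``window``.  Spacing is positive when the B site lies 3' of the A site
    relative to the A site's strand.  Orientation is the (strandA, strandB)
    pair.
    """
    out = []
    for a in event.sitesA:
        for b in event.sitesB:
            if a.chrom != b.chrom:
                continue
            s = _signed_spacing(a, b)
            if s is None or abs(s) > window:
                continue
            out.append((s, a.strand + b.strand))
    return out


def spacing_histogram(
    spacings: Iterable[tuple[int, str]],
    tfA: str = "",
    tfB: str = "",
    window: int = DEFAULT_WINDOW,
) -> dict[str, SpacingDistribution]:
    """Aggregate (spacing, orientation) pairs into one histogram per
    orientation combination."""
    counts = {o: np.zeros(2 * window + 1, dtype=np.int64) for o in ORIENTATIONS}
    for s, orient in spacings:
        if abs(s) > window:
            raise SpacingError(f"spacing {s} outside +/-{window}")
        counts[orient][s + window] += 1
    return {
        o: SpacingDistribution(counts=c, orientation=o, tfA=tfA, tfB=tfB, window=window)
        for o, c in counts.items()
    }


def slopes(dist: SpacingDistribution | np.ndarray) -> np.ndarray:
    """Average of single-step forward and backward slopes at each interior
    position: S_i = (2 N_i - N_{i-1} - N_{i+1}) / 2."""
    counts = dist.counts if isinstance(dist, SpacingDistribution) else np.asarray(dist)
    n = counts.astype(float)
    return (2.0 * n[1:-1] - n[:-2] - n[2:]) / 2.0


@dataclass
class SpikeNull:
    """Pooled Monte-Carlo null distribution of slope values.

    Each replicate draws ``n_values`` integers uniformly on ``value_range``,
    histograms them at 1-bp resolution and records all interior slopes; all
    replicates are pooled.
    """

    sorted_slopes: np.ndarray
    n_values: int
    value_range: tuple[int, int]
    n_reps: int = 1000

    @property
    def size(self) -> int:
        return self.sorted_slopes.size

    def upper_tail_p(self, values: np.ndarray) -> np.ndarray:
        """Add-one empirical upper-tail p: (1 + #{null >= v}) / (1 + N)."""
        values = np.asarray(values, dtype=float)
        n_below = np.searchsorted(self.sorted_slopes, values, side="left")
        exceed = self.size - n_below
        return (1.0 + exceed) / (1.0 + self.size)


def spike_null(
    n_values: int = 1000,
    n_reps: int = 1000,
    value_range: tuple[int, int] = (0, 100),
    seed: int | np.random.Generator = 0,
) -> SpikeNull:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = value_range
    n_bins = hi - lo + 1
    counts = rng.multinomial(n_values, np.full(n_bins, 1.0 / n_bins), size=n_reps)
    n = counts.astype(float)
    pooled = ((2.0 * n[:, 1:-1] - n[:, :-2] - n[:, 2:]) / 2.0).ravel()
    pooled.sort()
    return SpikeNull(
        sorted_slopes=pooled, n_values=n_values, value_range=(lo, hi), n_reps=n_reps
    )


def spike_test(
    dist: SpacingDistribution,
    null: SpikeNull,
    alpha: float = DEFAULT_ALPHA_SPIKE,
    match_scale: bool = True,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Monte-Carlo spike detection on a spacing distribution.

    The distribution is split into its non-negative half (i in [0, window])
    and the mirrored non-positive half so that each half matches the null's
    one-sided 0..100 support; each half is rescaled to the null's total draw
    count before slopes are computed, so observed and null slopes share
    units.  Down-scaling a large sample shrinks its counting noise relative
    to the null (a conservative comparison); up-scaling a sparse one would
    inflate it, so with ``match_scale`` (default) halves with fewer
    spacings than the null's draw count are instead tested against a fresh
    null built at their own total (deterministic under ``seed``).

    Returns the signed positions whose upper-tail empirical p-value is
    below ``alpha``, with their p-values.
    """
    if dist.total == 0:
        warnings.warn("all-zero spacing distribution: no spikes callable")
        return []
    w = dist.window
    halves = {
        +1: dist.counts[w:].astype(float),        # i = 0 .. w
        -1: dist.counts[: w + 1][::-1].astype(float),  # |i| = 0 .. w
    }
    spikes: list[tuple[int, float]] = []
    matched_nulls: dict[int, SpikeNull] = {}
    for sign, counts in halves.items():
        total = int(counts.sum())
        if total == 0:
            continue
        if match_scale and total < null.n_values:
            if total not in matched_nulls:
                matched_nulls[total] = spike_null(
                    n_values=total,
                    n_reps=null.n_reps,
                    value_range=null.value_range,
                    seed=np.random.default_rng([seed, total]),
                )
            half_null = matched_nulls[total]
            scaled = counts
        else:
            half_null = null
            scaled = counts * (null.n_values / total)
        s = (2.0 * scaled[1:-1] - scaled[:-2] - scaled[2:]) / 2.0
        p = half_null.upper_tail_p(s)
        for j in np.flatnonzero(p < alpha):
            pos = sign * (int(j) + 1)
            if pos == 0:
                continue
            spikes.append((pos, float(p[j])))
    # i = 0 belongs to both halves; dedupe is unnecessary since j starts at 1
    spikes.sort(key=lambda t: t[1])
    return spikes


def relaxed_test(
    dist: SpacingDistribution,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    jitter: bool = True,
) -> float:
    """Mean two-sample KS p-value of the observed spacings against repeated
    size-matched uniform draws on [-window, window].

    Spacings are integers, so by default a small seeded uniform jitter
    (+/- 0.5) is applied to both samples to avoid heavy-tie artifacts in the
    KS statistic.
    """
    if dist.total < 2:
        raise SpacingError("relaxed test undefined for fewer than 2 spacings")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = dist.to_spacings().astype(float)
    w = dist.window
    ps = np.empty(n_reps)
    for r in range(n_reps):
        ref = rng.integers(-w, w + 1, size=observed.size).astype(float)
        if jitter:
            obs = observed + rng.uniform(-0.5, 0.5, observed.size)
            ref = ref + rng.uniform(-0.5, 0.5, ref.size)
        else:
            obs = observed
        ps[r] = stats.ks_2samp(obs, ref).pvalue
    return float(ps.mean())


def classify_relationship(
    spikes: list[tuple[int, float]],
    ks_mean_p: float,
    alpha_spike: float = DEFAULT_ALPHA_SPIKE,
    alpha_relaxed: float = DEFAULT_ALPHA_RELAXED,
    **labels,
) -> SpacingRelationship:
    """Constrained if any spike is significant; else relaxed if the mean KS
    p-value is below ``alpha_relaxed``; else none.  Both statistics are
    always reported."""
    significant = [(i, p) for i, p in spikes if p < alpha_spike]
    if significant:
        label = "constrained"
    elif ks_mean_p < alpha_relaxed:
        label = "relaxed"
    else:
        label = "none"
    return SpacingRelationship(
        label=label,
        spike_positions=significant,
        ks_mean_p=ks_mean_p,
        alpha_spike=alpha_spike,
        alpha_relaxed=alpha_relaxed,
        **labels,
    )


def classify_distribution(
    dist: SpacingDistribution,
    null: SpikeNull | None = None,
    alpha_spike: float = DEFAULT_ALPHA_SPIKE,
    alpha_relaxed: float = DEFAULT_ALPHA_RELAXED,
    n_ks_reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> SpacingRelationship:
    """Run both tests on one distribution and classify it."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if null is None:
        null = spike_null(seed=rng)
    spikes = spike_test(dist, null, alpha=alpha_spike)
    if dist.total >= 2:
        ks_p = relaxed_test(dist, n_reps=n_ks_reps, seed=rng)
    else:
        ks_p = float("nan")
    return classify_relationship(
        spikes,
        ks_p,
        alpha_spike=alpha_spike,
        alpha_relaxed=alpha_relaxed,
        orientation=dist.orientation,
        tfA=dist.tfA,
        tfB=dist.tfB,
    )


def subset_peaks_by_regions(
    peaks: Sequence[Peak], regions: Sequence[tuple[str, int, int]]
) -> tuple[list[Peak], list[Peak]]:
    """Partition peaks by whether their center falls inside any region
    (0-based half-open).  Returns (inside, outside)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out: list[list[int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (np.array([s for s, _ in out]), np.array([e for _, e in out]))
    inside, outside = [], []
    for p in peaks:
        hit = False
        if p.chrom in merged:
            starts, ends = merged[p.chrom]
            k = np.searchsorted(starts, p.center, side="right") - 1
            hit = k >= 0 and p.center < ends[k]
        (inside if hit else outside).append(p)
    return inside, outside


def classify_pair(
    peaksA: Sequence[Peak],
    peaksB: Sequence[Peak],
    sites_for_peak_A,
    sites_for_peak_B,
    tfA: str = "A",
    tfB: str = "B",
    window: int = DEFAULT_WINDOW,
    null: SpikeNull | None = None,
    seed: int | np.random.Generator = 0,
    alpha_spike: float = DEFAULT_ALPHA_SPIKE,
    alpha_relaxed: float = DEFAULT_ALPHA_RELAXED,
) -> tuple[dict[str, SpacingDistribution], dict[str, SpacingRelationship]]:
    """End-to-end classification for one TF pair.

    ``sites_for_peak_A``/``B`` are callables mapping a Peak to its called
    binding sites (typically a closure over `motifs.call_sites_in_peak`).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if null is None:
        null = spike_null(seed=rng)
    all_spacings: list[tuple[int, str]] = []
    for event in cobinding_events(peaksA, peaksB):
        event.sitesA = sites_for_peak_A(event.peakA)
        event.sitesB = sites_for_peak_B(event.peakB)
        all_spacings.extend(pairwise_spacings(event, window=window))
    dists = spacing_histogram(all_spacings, tfA=tfA, tfB=tfB, window=window)
    results = {
        o: classify_distribution(
            d, null=null, alpha_spike=alpha_spike, alpha_relaxed=alpha_relaxed, seed=rng
        )
        for o, d in dists.items()
    }
    return dists, results
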