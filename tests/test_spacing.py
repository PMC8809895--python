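"""Tests for spacing distributions, the slope statistic, the Monte-Carlo
spike test and the relaxed (KS) test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifspacing.motifs import BindingSite, Peak
from motifspacing.simulate import SpacingModel, sample_spacings
from motifspacing.spacing import (
    DEFAULT_ALPHA_SPIKE,
    CoBindingEvent,
    SpacingDistribution,
    SpacingError,
    classify_distribution,
    classify_relationship,
    cobinding_events,
    pairwise_spacings,
    relaxed_test,
    slopes,
    spacing_histogram,
    spike_null,
    spike_test,
    subset_peaks_by_regions,
)


def _dist(counts):
    return SpacingDistribution(np.asarray(counts, dtype=np.int64))


def _uniform_dist(n, seed):
    sp = sample_spacings(SpacingModel(kind="uniform"), n, seed)
    return _dist(np.bincount(sp + 100, minlength=201))


class TestCobindingEvents:
    def test_one_base_overlap_counts(self):
        a, b = Peak("chr1", 0, 200), Peak("chr1", 199, 399)
        assert len(cobinding_events([a], [b])) == 1

    def test_half_open_touch_does_not(self):
        a, b = Peak("chr1", 0, 200), Peak("chr1", 200, 400)
        assert cobinding_events([a], [b]) == []

    def test_identical_lists(self):
        peaks = [Peak("chr1", i * 1000, i * 1000 + 200) for i in range(5)]
        assert len(cobinding_events(peaks, peaks)) >= 5

    def test_different_chromosomes(self):
        assert cobinding_events([Peak("chr1", 0, 200)], [Peak("chr2", 0, 200)]) == []


class TestPairwiseSpacings:
    def _event(self, siteA, siteB):
        return CoBindingEvent(
            peakA=Peak("chr1", 0, 200),
            peakB=Peak("chr1", 50, 250),
            sitesA=[siteA],
            sitesB=[siteB],
        )

    @pytest.mark.parametrize(
        "strandA, expected",
        [("+", 10), ("-", -10)],
    )
    def test_sign_follows_reference_strand(self, strandA, expected):
        a = BindingSite("chr1", 100, 110, strandA, 5.0, "A")
        b = BindingSite("chr1", 120, 130, "+", 5.0, "B")
        [(s, orient)] = pairwise_spacings(self._event(a, b))
        assert s == expected
        assert orient == strandA + "+"

    def test_overlapping_sites_excluded(self):
        a = BindingSite("chr1", 100, 110, "+", 5.0, "A")
        b = BindingSite("chr1", 105, 115, "+", 5.0, "B")
        assert pairwise_spacings(self._event(a, b)) == []

    def test_window_cutoff(self):
        a = BindingSite("chr1", 0, 10, "+", 5.0, "A")
        b = BindingSite("chr1", 111, 121, "+", 5.0, "B")
        assert pairwise_spacings(self._event(a, b)) == []
        b2 = BindingSite("chr1", 110, 120, "+", 5.0, "B")
        assert pairwise_spacings(self._event(a, b2)) == [(100, "++")]


class TestHistogram:
    def test_counts_and_conservation(self):
        pairs = [(10, "++"), (10, "++"), (-3, "++"), (5, "+-")]
        dists = spacing_histogram(pairs)
        assert dists["++"].counts[100 + 10] == 2
        assert dists["++"].counts[100 - 3] == 1
        total = sum(d.total for d in dists.values())
        assert total == len(pairs)

    def test_empty(self):
        dists = spacing_histogram([])
        assert all(d.total == 0 for d in dists.values())


class TestSlopes:
    def test_constant_is_flat(self):
        assert np.all(slopes(_dist([7] * 201)) == 0)

    def test_linear_ramp_is_flat(self):
        assert np.all(slopes(_dist(np.arange(201) + 100)) == 0)

    def test_delta(self):
        counts = np.zeros(201, dtype=int)
        counts[100 + 20] = 1000
        s = slopes(_dist(counts))
        # s is indexed by i in [-99, 99]
        assert s[99 + 20] == 1000
        assert s[99 + 19] == -500
        assert s[99 + 21] == -500

    def test_brute_force_oracle(self, rng):
        """slopes() equals independent (forward + backward)/2 averaging."""
        for _ in range(200):
            counts = rng.integers(0, 50, size=201)
            got = slopes(_dist(counts))
            for idx in rng.integers(0, 199, size=10):
                i = idx + 1  # position within the counts vector
                forward = counts[i] - counts[i + 1]
                backward = counts[i] - counts[i - 1]
                assert got[idx] == pytest.approx((forward + backward) / 2)


class TestSpikeNull:
    def test_deterministic(self):
        a = spike_null(seed=123)
        b = spike_null(seed=123)
        np.testing.assert_array_equal(a.sorted_slopes, b.sorted_slopes)

    def test_single_rep_size(self):
        null = spike_null(n_reps=1, seed=0)
        assert null.size == 99  # interior positions of a 101-bin histogram

    def test_mean_near_zero(self):
        null = spike_null(seed=5)
        # E[second difference of iid histogram counts] = 0
        assert abs(null.sorted_slopes.mean()) < 0.1


class TestSpikeTest:
    def test_default_alpha_is_familywise_correction(self):
        assert DEFAULT_ALPHA_SPIKE == pytest.approx(0.05 / 200 / 4)
        assert DEFAULT_ALPHA_SPIKE == pytest.approx(6.25e-05)

    def test_planted_spike_recovered(self):
        null = spike_null(seed=1)
        model = SpacingModel(kind="constrained", s0=7, concentration=0.3)
        sp = sample_spacings(model, 5000, seed=2)
        dist = _dist(np.bincount(sp + 100, minlength=201))
        spikes = spike_test(dist, null)
        assert spikes and spikes[0][0] == 7
        assert spikes[0][1] < DEFAULT_ALPHA_SPIKE

    def test_negative_spacing_spike(self):
        null = spike_null(seed=1)
        model = SpacingModel(kind="constrained", s0=-15, concentration=0.3)
        sp = sample_spacings(model, 5000, seed=3)
        dist = _dist(np.bincount(sp + 100, minlength=201))
        positions = [i for i, _ in spike_test(dist, null)]
        assert -15 in positions

    def test_all_zero_warns_and_returns_nothing(self):
        null = spike_null(seed=1)
        with pytest.warns(UserWarning):
            assert spike_test(_dist(np.zeros(201)), null) == []

    def test_uniform_rarely_spikes(self):
        null = spike_null(seed=1)
        hits = sum(
            bool(spike_test(_uniform_dist(5000, seed=100 + k), null)) for k in range(40)
        )
        assert hits <= 2


class TestRelaxedTest:
    def test_uniform_not_significant(self):
        p = relaxed_test(_uniform_dist(2000, seed=11), seed=1)
        assert p > 0.01

    def test_decay_highly_significant(self):
        sp = sample_spacings(SpacingModel(kind="relaxed", decay=0.03), 5000, seed=12)
        dist = _dist(np.bincount(sp + 100, minlength=201))
        assert relaxed_test(dist, seed=2) < 1e-6

    def test_single_rep_is_one_ks_p(self):
        dist = _uniform_dist(500, seed=13)
        p = relaxed_test(dist, n_reps=1, seed=3)
        assert 0 <= p <= 1

    def test_undefined_below_two(self):
        counts = np.zeros(201, dtype=int)
        counts[100] = 1
        with pytest.raises(SpacingError):
            relaxed_test(_dist(counts))


class TestClassify:
    def test_constrained_takes_precedence(self):
        r = classify_relationship([(7, 1e-6)], ks_mean_p=1e-9)
        assert r.label == "constrained"

    def test_relaxed(self):
        assert classify_relationship([], ks_mean_p=1e-7).label == "relaxed"

    def test_none(self):
        assert classify_relationship([], ks_mean_p=0.4).label == "none"

    def test_discrimination_across_seeds(self):
        """Planted relaxed datasets classify relaxed; planted uniform as
        none, in at least 90% of seeds."""
        null = spike_null(seed=0)
        ok_relaxed = ok_none = 0
        n_seeds = 10
        for k in range(n_seeds):
            sp = sample_spacings(SpacingModel(kind="relaxed", decay=0.03), 5000, seed=200 + k)
            d = _dist(np.bincount(sp + 100, minlength=201))
            ok_relaxed += classify_distribution(d, null=null, seed=300 + k).label == "relaxed"
            ok_none += classify_distribution(_uniform_dist(5000, 400 + k), null=null, seed=500 + k).label == "none"
        assert ok_relaxed >= 0.9 * n_seeds
        assert ok_none >= 0.9 * n_seeds


class TestSubsetPeaks:
    def test_boundaries_and_partition(self):
        peaks = [Peak("chr1", x, x + 200) for x in (0, 100, 300, 900)]
        # centers: 100, 200, 400, 1000
        regions = [("chr1", 100, 401)]
        inside, outside = subset_peaks_by_regions(peaks, regions)
        assert [p.center for p in inside] == [100, 200, 400]
        assert [p.center for p in outside] == [1000]
        assert len(inside) + len(outside) == len(peaks)

    def test_empty_regions(self):
        peaks = [Peak("chr1", 0, 200)]
        inside, outside = subset_peaks_by_regions(peaks, [])
        assert inside == [] and outside == peaks


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_orientation_bookkeeping(seed):
    """Total spacings across the four orientation histograms equals the
    number emitted."""
    r = np.random.default_rng(seed)
    pairs = [
        (int(r.integers(-100, 101)), "+-"[r.integers(0, 2)] + "+-"[r.integers(0, 2)])
        for _ in range(r.integers(0, 200))
    ]
    dists = spacing_histogram(pairs)
    assert sum(d.total for d in dists.values()) == len(pairs)
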