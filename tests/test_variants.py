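"""Tests for frequency classification, variant localisation, PWM-score
deltas, impact categories and enrichment odds ratios."""

import numpy as np
import pytest

from motifspacing.motifs import PWM, BindingSite, scan_sites
from motifspacing.variants import (
    CoBindingRegion,
    ImpactCategory,
    VariantError,
    VariantRecord,
    af_category,
    delta_pwm_score,
    enrichment_odds_ratio,
    impact_category,
    is_motif_mutation,
    locate_variant,
    select_constrained_windows,
)


class TestAfCategory:
    @pytest.mark.parametrize(
        "af, ac, expected",
        [
            (0.5, 1, "singleton"),          # AC == 1 wins regardless of AF
            (0.0002, 12, "high_frequency"),  # 0.02% > 0.01%
            (0.00005, 3, "rare"),
            (1e-4, 5, "rare"),               # strict >: exactly 0.01% is rare
            (1.00001e-4, 5, "high_frequency"),
        ],
    )
    def test_classes(self, af, ac, expected):
        assert af_category(VariantRecord("chr1", 0, "A", "G", AF=af, AC=ac)) == expected

    def test_missing_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert af_category(VariantRecord("chr1", 0, "A", "G")) is None

    def test_partition(self, rng):
        vs = [
            VariantRecord("chr1", i, "A", "G",
                          AF=float(rng.uniform(1e-6, 1e-3)), AC=int(rng.integers(1, 50)))
            for i in range(200)
        ]
        cats = [af_category(v) for v in vs]
        assert all(c in ("singleton", "rare", "high_frequency") for c in cats)


@pytest.fixture
def region():
    siteA = BindingSite("chr1", 100, 110, "+", 8.0, "A")
    siteB = BindingSite("chr1", 140, 150, "+", 8.0, "B")
    return CoBindingRegion(siteA=siteA, siteB=siteB)


class TestSelectConstrainedWindows:
    def _regions(self, spacings):
        out = []
        for s in spacings:
            a = BindingSite("chr1", 100, 110, "+", 8.0, "A")
            b = BindingSite("chr1", 110 + s, 120 + s, "+", 8.0, "B")
            out.append(CoBindingRegion(siteA=a, siteB=b))
        return out

    def test_tolerance_boundaries(self):
        regions = self._regions([27, 29, 31, 32])
        kept = select_constrained_windows(regions, 29, tol=2)
        assert [r.spacing for r in kept] == [27, 29, 31]

    def test_exact_match_with_zero_tol(self):
        regions = self._regions([28, 29, 30])
        assert [r.spacing for r in select_constrained_windows(regions, 29, tol=0)] == [29]


class TestLocateVariant:
    def test_deletion_straddling_site_edge(self, region):
        # deletes bases 109 and 110: clips siteA's last base
        v = VariantRecord("chr1", 108, "ACT", "A")
        assert locate_variant(v, region) == "at_site"

    def test_insertion_between_sites(self, region):
        v = VariantRecord("chr1", 120, "A", "ATT")
        assert locate_variant(v, region) == "between_sites"

    def test_snp_in_upstream_flank(self, region):
        v = VariantRecord("chr1", 40, "A", "G")  # 60 bp upstream of span
        assert locate_variant(v, region) == "background"

    def test_outside(self, region):
        assert locate_variant(VariantRecord("chr1", 400, "A", "G"), region) == "outside"
        assert locate_variant(VariantRecord("chr2", 120, "A", "G"), region) == "outside"

    def test_footprint_never_both_between_and_at_site(self, region, rng):
        """Each variant gets exactly one zone."""
        for _ in range(300):
            pos = int(rng.integers(0, 260))
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                v = VariantRecord("chr1", pos, "A" * (size + 1), "A")
            else:
                v = VariantRecord("chr1", pos, "A", "A" * (size + 1))
            assert locate_variant(v, region) in (
                "at_site", "between_sites", "background", "outside",
            )


class TestDeltaScore:
    def _setup(self):
        probs = np.array(
            [
                [0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3],
                [0.1 / 3, 0.9, 0.1 / 3, 0.1 / 3],
                [0.1 / 3, 0.1 / 3, 0.9, 0.1 / 3],
                [0.1 / 3, 0.1 / 3, 0.1 / 3, 0.9],
            ]
        )
        pwm = PWM("m4", probs)
        lom = pwm.log_odds()
        genome = {"chr1": "TTTTT" + lom.consensus + "TTTTT"}
        [site] = [
            s
            for s in scan_sites(
                lom, genome["chr1"], threshold=lom.max_score - 1e-9, chrom="chr1"
            )
            if s.strand == "+"
        ]
        return lom, genome, site

    def test_snp_delta_is_column_difference(self):
        lom, genome, site = self._setup()
        # consensus ACGT at [5,9); mutate the C (pos 6) to A
        v = VariantRecord("chr1", 6, "C", "A")
        expected = lom.matrix[1, 0] - lom.matrix[1, 1]
        delta = delta_pwm_score(v, site, genome, lom)
        assert delta == pytest.approx(expected, abs=1e-9)
        assert is_motif_mutation(v, site, genome, lom)

    def test_variant_outside_window_is_zero(self):
        lom, genome, site = self._setup()
        v = VariantRecord("chr1", 0, "T", "A")
        assert delta_pwm_score(v, site, genome, lom) == 0.0

    def test_shifting_indel_preserving_motif_not_mutation(self):
        """An InDel just outside the motif shifts it within the rescanned
        window but leaves a perfect match: no mutation call."""
        lom, genome, site = self._setup()
        v = VariantRecord("chr1", 3, "TT", "T")  # deletes one flanking T
        assert abs(delta_pwm_score(v, site, genome, lom)) < 2.0

    def test_two_bit_boundary_inclusive(self):
        """A PWM column with an exact log2(0.8/0.2) = 2-bit A-vs-C gap:
        the mutation flag fires at exactly two bits ("at least")."""
        probs = np.array(
            [
                [0.94, 0.02, 0.02, 0.02],
                [0.80, 0.20, 1e-12, 0.20 - 1e-12],
                [0.94, 0.02, 0.02, 0.02],
            ]
        )
        probs = probs / probs.sum(axis=1, keepdims=True)
        lom = PWM("exact2", probs).log_odds()
        # G flanks: neither strand of a G-run resembles the A-rich motif
        genome = {"chr1": "GGGGG" + "AAA" + "GGGGG"}
        [site] = [
            s
            for s in scan_sites(
                lom, genome["chr1"], threshold=lom.max_score - 1e-9, chrom="chr1"
            )
            if s.strand == "+"
        ]
        v = VariantRecord("chr1", 6, "A", "C")
        delta = delta_pwm_score(v, site, genome, lom)
        assert delta == pytest.approx(-2.0, abs=1e-6)
        assert is_motif_mutation(v, site, genome, lom)
        # just under the boundary must not flag
        assert not is_motif_mutation(v, site, genome, lom, min_bits=2.0 + 1e-5)


class TestImpactCategory:
    def _setup(self):
        probs = np.array(
            [
                [0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3],
                [0.1 / 3, 0.9, 0.1 / 3, 0.1 / 3],
                [0.1 / 3, 0.1 / 3, 0.9, 0.1 / 3],
                [0.1 / 3, 0.1 / 3, 0.1 / 3, 0.9],
            ]
        )
        lom = PWM("m4", probs).log_odds()
        seq = "T" * 20 + lom.consensus + "T" * 30 + lom.consensus + "T" * 20
        genome = {"chr1": seq}
        siteA = BindingSite("chr1", 20, 24, "+", lom.max_score, "A")
        siteB = BindingSite("chr1", 54, 58, "+", lom.max_score, "B")
        region = CoBindingRegion(siteA=siteA, siteB=siteB, flank=10)
        return lom, genome, region

    def test_spacing_alteration(self):
        lom, genome, region = self._setup()
        indel = VariantRecord("chr1", 35, "TT", "T")
        cat = impact_category(region, [indel], genome, lom, lom)
        assert cat == ImpactCategory.SPACING_ALTERATION

    def test_motif_mutation_priority_over_spacing(self):
        lom, genome, region = self._setup()
        snp = VariantRecord("chr1", 21, "C", "T")  # disrupts siteA
        indel = VariantRecord("chr1", 35, "TT", "T")
        cat = impact_category(region, [snp, indel], genome, lom, lom)
        assert cat == ImpactCategory.MOTIF_A_MUTATION
        # order independence
        cat2 = impact_category(region, [indel, snp], genome, lom, lom)
        assert cat2 == cat

    def test_variant_free(self):
        lom, genome, region = self._setup()
        assert impact_category(region, [], genome, lom, lom) == ImpactCategory.VARIANT_FREE

    def test_snp_between_sites_is_no_effect(self):
        lom, genome, region = self._setup()
        snp = VariantRecord("chr1", 35, "T", "A")
        assert impact_category(region, [snp], genome, lom, lom) == ImpactCategory.NO_EFFECT

    def test_motif_b_mutation(self):
        lom, genome, region = self._setup()
        snp = VariantRecord("chr1", 55, "C", "T")
        assert impact_category(region, [snp], genome, lom, lom) == ImpactCategory.MOTIF_B_MUTATION


class TestEnrichmentOddsRatio:
    def test_arithmetic(self):
        r = enrichment_odds_ratio(10, 90, 5, 95)
        assert r.odds_ratio == pytest.approx((10 / 90) / (5 / 95))
        assert r.log2_odds_ratio == pytest.approx(1.078, abs=1e-3)
        assert not r.corrected

    def test_identity(self):
        r = enrichment_odds_ratio(20, 80, 40, 160)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.log2_odds_ratio == pytest.approx(0.0)

    def test_haldane_correction(self):
        r = enrichment_odds_ratio(0, 90, 5, 95)
        assert r.corrected
        assert r.odds_ratio == pytest.approx((0.5 / 90.5) / (5.5 / 95.5))

    def test_empty_margin_error(self):
        with pytest.raises(VariantError):
            enrichment_odds_ratio(0, 0, 5, 95)
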