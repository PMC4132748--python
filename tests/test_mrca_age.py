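"""Haplotype-decay MRCA age estimation."""

import math

import numpy as np
import pytest

from macrorate.mrca_age import (
    SUPPORT_DROP_LOG10,
    CarrierHaplotype,
    Marker,
    MarkerMap,
    enumerate_weighted_haplotypes,
    estimate_g,
    genetic_positions,
    haplotype_relative_likelihood,
    recombination_fraction,
)
from macrorate.synthgen import simulate_haplotype_decay
from conftest import build_toy_map


class TestGeneticPositions:
    def test_default_one_cm_per_mb(self):
        assert genetic_positions([0, 1_000_000]) == [0.0, 1.0]

    def test_anchor_interpolation_midpoint(self):
        got = genetic_positions(
            [1_000_000], anchors=[(0, 0.0), (2_000_000, 2.0)]
        )
        assert got == [pytest.approx(1.0)]

    def test_nonuniform_anchor_segments(self):
        anchors = [(0, 0.0), (1_000_000, 0.5), (2_000_000, 2.5)]
        got = genetic_positions([500_000, 1_500_000], anchors=anchors)
        assert got[0] == pytest.approx(0.25)
        assert got[1] == pytest.approx(1.5)

    def test_full_span_maps_to_its_megabases(self):
        cm = genetic_positions([41_000_000, 44_200_000])
        assert cm[1] - cm[0] == pytest.approx(3.2)

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            genetic_positions([5, 3])


class TestRecombinationFraction:
    def test_zero_distance(self):
        assert recombination_fraction(0.0) == 0.0

    def test_large_distance_asymptote(self):
        assert recombination_fraction(1e6) == pytest.approx(0.5)

    def test_one_centimorgan(self):
        # Haldane: (1 - exp(-0.02)) / 2
        assert recombination_fraction(1.0) == pytest.approx(0.00990066, abs=1e-7)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            recombination_fraction(-0.1)


def ancestral_hap(marker_map):
    return CarrierHaplotype(
        alleles=tuple(m.ancestral for m in marker_map.markers)
    )


class TestRelativeLikelihood:
    def test_certain_retention_at_g_zero(self, toy_map):
        hap = ancestral_hap(toy_map)
        ratio = haplotype_relative_likelihood(hap, toy_map, g=0, marker_mu=0.0)
        inv_freq = math.prod(
            1 / m.frequencies[m.ancestral] for m in toy_map.markers
        )
        assert ratio == pytest.approx(inv_freq, rel=1e-9)
        assert ratio >= 1

    def test_unlinked_free_map_is_g_independent(self):
        # all markers exactly at the disease locus position: r = 0
        markers = tuple(
            Marker(f"m{k}", 1000 + k, 0.5, "A", {"A": 0.4, "G": 0.6})
            for k in range(5)
        )
        mmap = MarkerMap(markers, disease_cm=0.5)
        hap = ancestral_hap(mmap)
        values = {
            haplotype_relative_likelihood(hap, mmap, g, marker_mu=0.0)
            for g in (0, 10, 500)
        }
        assert len({round(v, 12) for v in values}) == 1

    def test_random_haplotype_ratio_decays_to_one(self, toy_map):
        # at very large g every marker term tends to p_i: ratio -> 1
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(50):
            alleles = tuple(
                str(
                    rng.choice(
                        list(m.frequencies),
                        p=list(m.frequencies.values()),
                    )
                )
                for m in toy_map.markers
            )
            hap = CarrierHaplotype(alleles=alleles)
            ratios.append(
                haplotype_relative_likelihood(hap, toy_map, g=10_000_000)
            )
        # once every rho_i has decayed, the ratio is 1 for any haplotype
        assert ratios == pytest.approx([1.0] * len(ratios), abs=1e-6)

    def test_ancestral_hap_likelihood_nonincreasing_in_g(self, toy_map):
        hap = ancestral_hap(toy_map)
        values = [
            haplotype_relative_likelihood(hap, toy_map, g) for g in range(0, 200, 5)
        ]
        assert all(b <= a for a, b in zip(values, values[1:]))

    def test_missing_alleles_contribute_one(self, toy_map):
        full = ancestral_hap(toy_map)
        masked = CarrierHaplotype(
            alleles=(None,) + full.alleles[1:], weight=1.0
        )
        # masking the first marker divides out exactly its term
        m0 = toy_map.markers[0]
        r0 = float(toy_map.recombination_fractions()[0])
        g = 40
        rho = (1 - r0) ** g
        term = (rho + (1 - rho) * m0.frequencies[m0.ancestral]) / m0.frequencies[
            m0.ancestral
        ]
        assert haplotype_relative_likelihood(
            full, toy_map, g
        ) == pytest.approx(
            term * haplotype_relative_likelihood(masked, toy_map, g), rel=1e-9
        )

    def test_unknown_allele_raises(self, toy_map):
        hap = CarrierHaplotype(
            alleles=("T",) + tuple(m.ancestral for m in toy_map.markers[1:])
        )
        with pytest.raises(ValueError):
            haplotype_relative_likelihood(hap, toy_map, g=10)


class TestEstimateG:
    def test_all_ancestral_pushes_to_lower_end(self, toy_map):
        carriers = [[ancestral_hap(toy_map)] for _ in range(10)]
        est = estimate_g(carriers, toy_map, g_range=(1, 300))
        assert est.g_hat == 1

    def test_flat_likelihood_gives_full_support(self):
        markers = tuple(
            Marker(f"m{k}", 1000 + k, 0.5, "A", {"A": 0.4, "G": 0.6})
            for k in range(4)
        )
        mmap = MarkerMap(markers, disease_cm=0.5)
        carriers = [[ancestral_hap(mmap)] for _ in range(5)]
        est = estimate_g(carriers, mmap, g_range=(1, 100))
        assert est.support == (1, 100)

    def test_support_endpoints_satisfy_the_drop(self, toy_map):
        carriers = simulate_haplotype_decay(73, toy_map, 30, seed=42)
        est = estimate_g(carriers, toy_map, g_range=(1, 500))
        ll = est.loglik10
        peak = ll[est.g_hat]
        lo, hi = est.support
        assert ll[lo] >= peak - SUPPORT_DROP_LOG10
        assert ll[hi] >= peak - SUPPORT_DROP_LOG10
        if lo > 1:
            assert ll[lo - 1] < peak - SUPPORT_DROP_LOG10
        if hi < 500:
            assert ll[hi + 1] < peak - SUPPORT_DROP_LOG10

    def test_point_recovery_is_unbiased_across_replicates(self, toy_map):
        g_true = 73
        ghats = [
            estimate_g(
                simulate_haplotype_decay(g_true, toy_map, 30, seed=500 + rep),
                toy_map,
            ).g_hat
            for rep in range(40)
        ]
        assert abs(np.median(ghats) - g_true) <= 10

    def test_too_few_haplotypes_raise(self, toy_map):
        with pytest.raises(ValueError):
            estimate_g([[ancestral_hap(toy_map)]], toy_map)


class TestEnumerateHaplotypes:
    def test_homozygous_genotype_single_haplotype(self, toy_map):
        genotype = [(m.ancestral, m.ancestral) for m in toy_map.markers]
        haps = enumerate_weighted_haplotypes(genotype, toy_map)
        assert len(haps) == 1 and haps[0].weight == 1.0

    def test_one_het_marker_weights_follow_partner_frequency(self, toy_map):
        genotype = [(m.ancestral, m.ancestral) for m in toy_map.markers]
        genotype[3] = ("A", "G")
        haps = enumerate_weighted_haplotypes(genotype, toy_map)
        assert len(haps) == 2
        by_allele = {h.alleles[3]: h.weight for h in haps}
        freq = toy_map.markers[3].frequencies
        # taking "A" leaves partner "G": weight proportional to p(G)
        expect_a = freq["G"] / (freq["G"] + freq["A"])
        assert by_allele["A"] == pytest.approx(expect_a, rel=1e-12)

    @pytest.mark.parametrize("k", [2, 5])
    def test_k_het_markers_enumerate_2k_with_unit_mass(self, toy_map, k):
        genotype = [(m.ancestral, m.ancestral) for m in toy_map.markers]
        for i in range(k):
            genotype[i] = ("A", "G")
        haps = enumerate_weighted_haplotypes(genotype, toy_map)
        assert len(haps) == 2**k
        assert sum(h.weight for h in haps) == pytest.approx(1.0, abs=1e-12)

    def test_combinatorial_guard(self):
        mmap = build_toy_map(n_markers=22)
        genotype = [("A", "G")] * 22
        with pytest.raises(ValueError, match="heterozygous"):
            enumerate_weighted_haplotypes(genotype, mmap)


class TestDecayRecovery:
    def test_retention_frequency_matches_rho(self, toy_map):
        g = 50
        carriers = simulate_haplotype_decay(g, toy_map, 5000, seed=77)
        r = toy_map.recombination_fractions()
        for i, marker in enumerate(toy_map.markers):
            rho = (1 - r[i]) ** g
            # a non-retained draw can still be the ancestral allele
            p_anc = rho + (1 - rho) * marker.frequencies[marker.ancestral]
            obs = np.mean(
                [haps[0].alleles[i] == marker.ancestral for haps in carriers]
            )
            se = math.sqrt(p_anc * (1 - p_anc) / 5000)
            assert abs(obs - p_anc) < 5 * se + 1e-9
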