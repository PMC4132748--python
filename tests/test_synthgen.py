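"""Distributional and determinism checks of the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy import stats

from macrorate.lineages import aggregate_generation_counts, min_mutation_events
from macrorate.synthgen import (
    PAPER_STAR_DESIGN,
    DepthSimConfig,
    StarSimConfig,
    geometric_steps,
    observed_generation_counts,
    one_step,
    simulate_depth_track,
    simulate_haplotype_decay,
    simulate_pedigree,
    simulate_smm_spectrum,
    simulate_star_transmissions,
)


class TestDeterminism:
    def test_star_transmissions_reproducible(self):
        config = StarSimConfig(mu=5e-3, groups=PAPER_STAR_DESIGN)
        a = simulate_star_transmissions(config, seed=123)
        b = simulate_star_transmissions(config, seed=123)
        assert a == b

    def test_depth_track_reproducible(self):
        cfg = DepthSimConfig(true_copy_number=40, genome_doc=5.0, length=500)
        a = simulate_depth_track(cfg, seed=9)
        b = simulate_depth_track(cfg, seed=9)
        assert np.array_equal(a.depths, b.depths)

    def test_spectrum_reproducible(self):
        a = simulate_smm_spectrum(100.0, 50, seed=5)
        b = simulate_smm_spectrum(100.0, 50, seed=5)
        assert a == b


class TestStepDistributions:
    def test_no_zero_steps(self):
        rng = np.random.default_rng(0)
        for draw in (geometric_steps(0.2), one_step()):
            steps = draw(rng, 10_000)
            assert not np.any(steps == 0)

    def test_geometric_mean_magnitude(self):
        rng = np.random.default_rng(1)
        steps = geometric_steps(0.2)(rng, 50_000)
        assert np.mean(np.abs(steps)) == pytest.approx(5.0, rel=0.05)
        assert abs(np.mean(np.sign(steps))) < 0.02  # symmetric


class TestStarTransmissions:
    def test_zero_rate_keeps_ancestral_allele_everywhere(self):
        sim = simulate_star_transmissions(
            StarSimConfig(mu=0.0, groups=PAPER_STAR_DESIGN, ancestral_allele=30),
            seed=1,
        )
        for group in sim.groups:
            for fam in group.families:
                assert fam.linked_alleles == frozenset({30})
        assert min_mutation_events(sim.groups) == 0
        assert sim.mutated_meioses == 0

    def test_branch_mutation_fraction_matches_poisson_zero_class(self):
        # over replicates, P(branch with >= 1 event) = 1 - exp(-mu g)
        mu, reps = 5e-3, 500
        hit = {87: 0, 73: 0, 61: 0, 72: 0}
        tot = {87: 0, 73: 0, 61: 0, 72: 0}
        for rep in range(reps):
            sim = simulate_star_transmissions(
                StarSimConfig(mu=mu, groups=PAPER_STAR_DESIGN), seed=2_000 + rep
            )
            for group, events in zip(sim.groups, sim.branch_events):
                if group.g_mrca is None:
                    continue
                for k in events:
                    tot[group.g_mrca] += 1
                    hit[group.g_mrca] += k >= 1
        for g in hit:
            p = -math.expm1(-mu * g)
            se = math.sqrt(p * (1 - p) / tot[g])
            assert abs(hit[g] / tot[g] - p) < 4 * se

    def test_branch_event_counts_pass_poisson_gof(self):
        # chi-squared goodness of fit on the g = 87 branches, alpha = 0.01
        mu, g = 5e-3, 87
        counts = []
        for rep in range(500):
            sim = simulate_star_transmissions(
                StarSimConfig(mu=mu, groups=((g, (0, 0)),)), seed=3_000 + rep
            )
            counts.extend(sim.branch_events[0])
        observed = np.bincount(counts, minlength=3)[:3].astype(float)
        observed = np.append(observed, len(counts) - observed.sum())
        lam = mu * g
        probs = [math.exp(-lam) * lam**k / math.factorial(k) for k in range(3)]
        probs.append(1 - sum(probs))
        expected = np.array(probs) * len(counts)
        stat = float(np.sum((observed - expected) ** 2 / expected))
        assert stat < stats.chi2.ppf(0.99, df=3)

    def test_outputs_feed_the_lineage_module(self):
        sim = simulate_star_transmissions(
            StarSimConfig(mu=0.02, groups=PAPER_STAR_DESIGN), seed=7
        )
        counts = aggregate_generation_counts(sim.groups)
        observed = observed_generation_counts(sim)
        assert observed.t0_total == counts.t0_total
        assert len(observed.mutated_lineages) == len(
            counts.mutated_lineages
        ) + sim.mutated_meioses


class TestDepthTrack:
    def test_diploid_baseline_mean(self):
        track = simulate_depth_track(
            DepthSimConfig(true_copy_number=2, genome_doc=30.0, length=20_000),
            seed=4,
        )
        assert track.depths.mean() == pytest.approx(30.0, rel=0.02)

    def test_poisson_mean_variance_agree(self):
        track = simulate_depth_track(
            DepthSimConfig(true_copy_number=40, genome_doc=5.0, length=20_000),
            seed=5,
        )
        assert track.depths.mean() == pytest.approx(100.0, rel=0.02)
        assert track.depths.var() == pytest.approx(100.0, rel=0.1)

    def test_gc_bias_shifts_dcn_proportionally(self):
        cfg = DepthSimConfig(
            true_copy_number=40, genome_doc=5.0, length=20_000, gc_bias_factor=0.8
        )
        track = simulate_depth_track(cfg, seed=6)
        dcn = 2 * track.depths.mean() / 5.0
        assert dcn == pytest.approx(32.0, rel=0.03)  # biased low by 20%


class TestSmmSpectrum:
    def test_tiny_theta_is_monomorphic(self):
        mono = sum(
            len(simulate_smm_spectrum(1e-6, 20, seed=100 + s).counts) == 1
            for s in range(20)
        )
        assert mono == 20

    def test_mutation_count_matches_coalescent_expectation(self):
        theta, n, reps = 5.0, 10, 1000
        muts, lengths = [], []
        for s in range(reps):
            _, diag = simulate_smm_spectrum(
                theta, n, seed=4_000 + s, diagnostics=True
            )
            muts.append(diag["n_mutations"])
            lengths.append(diag["total_branch_length"])
        harmonic = sum(1 / k for k in range(1, n))
        assert np.mean(lengths) == pytest.approx(2 * harmonic, rel=0.05)
        # E[mutations] = theta/2 * E[L] = theta * sum_{k=1}^{n-1} 1/k
        assert np.mean(muts) == pytest.approx(theta * harmonic, rel=0.05)

    def test_spectrum_is_valid_input_for_theta_module(self):
        spectrum = simulate_smm_spectrum(50.0, 100, seed=8)
        assert sum(spectrum.counts.values()) == 100
        assert all(c >= 1 for c in spectrum.counts.values())


class TestHaplotypeDecay:
    def test_g_zero_returns_ancestral_everywhere(self, toy_map):
        carriers = simulate_haplotype_decay(0, toy_map, 20, seed=9)
        ancestral = tuple(m.ancestral for m in toy_map.markers)
        assert all(haps[0].alleles == ancestral for haps in carriers)


class TestPedigree:
    def test_mendelian_exact_when_rate_zero(self):
        ped = simulate_pedigree([3], [10, 20, 30, 40], mu=0.0, seed=10)
        for ind in ped.individuals:
            if ind.father is None:
                continue
            dad, mum = ped[ind.father], ped[ind.mother]
            assert ind.alleles[0] in dad.alleles
            assert ind.alleles[1] in mum.alleles

    def test_trio_template_yields_two_meioses(self):
        from macrorate.lineages import count_meioses

        ped = simulate_pedigree([1], [11, 23, 37, 52], mu=0.0, seed=11)
        assert count_meioses(ped, {i.iid for i in ped.individuals}) == 2

    def test_large_rate_changes_transmissions_at_expected_frequency(self):
        mu, changed, total = 0.5, 0, 0
        for s in range(300):
            ped = simulate_pedigree([16], list(range(10, 60)), mu=mu, seed=s)
            for ind in ped.individuals:
                if ind.father is None:
                    continue
                dad, mum = ped[ind.father], ped[ind.mother]
                total += 2
                changed += ind.alleles[0] not in dad.alleles
                changed += ind.alleles[1] not in mum.alleles
        p = -math.expm1(-mu)
        se = math.sqrt(p * (1 - p) / total)
        # a mutated transmission can coincide with a parental allele, so the
        # observed change rate sits slightly below 1 - exp(-mu)
        assert p - 6 * se - 0.05 < changed / total <= p + 4 * se
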