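import numpy as np
import pytest

from cpg_mutspec.core import GenomeSequence
from cpg_mutspec.spectrum import (build_spectrum, count_dinucleotide_abundance,
                                  encode)
from cpg_mutspec.synthetic import (CloneFamilyConfig, MetricNoise, RateTable,
                                   RegionBoost, clone_call_keys_vs_reference,
                                   generate_annotations, generate_genome,
                                   simulate_clone_family, simulate_mutations,
                                   transition_matrix)


def _cpg_freq(genome):
    n_cg = total = 0
    for seq in genome.contigs.values():
        codes = encode(seq)
        n_cg += int(((codes[:-1] == 1) & (codes[1:] == 2)).sum())
        total += len(seq) - 1
    return n_cg / total


class TestRateTable:
    def test_rejects_bad_keys(self):
        with pytest.raises(ValueError):
            RateTable({("C", "G", "C"): 1.0})   # alt == ref
        with pytest.raises(ValueError):
            RateTable({("A", "G", "T"): 1.0})   # purine ref

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            RateTable({("C", "G", "T"): 0.0})

    def test_uniform_has_24_entries(self):
        assert len(RateTable.uniform().rates) == 24

    def test_boosted_matrix(self):
        mat = RateTable.cpg_ct_boosted(10).as_matrix()
        assert mat[2, 3] == 10.0       # context (C, G), alt T
        assert mat.sum() == 23 + 10.0


class TestGenerateGenome:
    def test_determinism(self):
        g1 = generate_genome(5000, 0.5, 1.0, seed=42)
        g2 = generate_genome(5000, 0.5, 1.0, seed=42)
        assert g1 == g2
        assert g1 != generate_genome(5000, 0.5, 1.0, seed=43)

    def test_independence_case(self):
        # gc 0.5, o/e 1.0 -> CpG frequency ~ 0.25 * 0.25 = 0.0625
        g = generate_genome(1_000_000, 0.5, 1.0, seed=1)
        assert _cpg_freq(g) == pytest.approx(0.0625, rel=0.05)

    def test_suppressed_cpg_case(self):
        # o/e 0.25 at gc 0.42 -> CpG frequency ~ 0.25 * 0.21 * 0.21
        g = generate_genome(1_000_000, 0.42, 0.25, seed=2)
        target = 0.25 * 0.21 * 0.21
        assert _cpg_freq(g) == pytest.approx(target, rel=0.05)

    def test_matches_stationary_expectation(self):
        # oracle: dinucleotide counts vs the chain's own stationary values
        gc, oe = 0.46, 0.6
        g = generate_genome(800_000, gc, oe, seed=3)
        P = transition_matrix(gc, oe)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = encode(g.contigs["chr1"]).astype(int)
        counts = np.zeros((4, 4))
        np.add.at(counts, (codes[:-1], codes[1:]), 1)
        freq = counts / counts.sum()
        expect = p[:, None] * P
        assert np.abs(freq - expect).max() < 0.004

    def test_gc_fraction_realized(self):
        g = generate_genome(500_000, 0.35, 1.0, seed=4)
        codes = encode(g.contigs["chr1"])
        gc = ((codes == 1) | (codes == 2)).mean()
        assert gc == pytest.approx(0.35, abs=0.01)

    def test_multi_contig_lengths(self):
        g = generate_genome(1003, 0.5, 1.0, n_contigs=3, seed=5)
        assert [g.length(c) for c in g] == [335, 334, 334]

    def test_infeasible_combination_reports_bound(self):
        with pytest.raises(ValueError, match="must be <"):
            generate_genome(1000, 0.9, 3.0, seed=0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_genome(1000, 0.0, 1.0)
        with pytest.raises(ValueError):
            generate_genome(1000, 0.5, 0.0)


class TestGenerateAnnotations:
    def test_empty_fractions(self, medium_genome):
        ann = generate_annotations(medium_genome, fractions={}, seed=0)
        assert len(ann.repeats) == 0 and len(ann.cgi) == 0

    def test_sine_fraction_conserved(self, medium_genome):
        ann = generate_annotations(medium_genome, fractions={"sine": 0.1},
                                   seed=1)
        sine_bases = sum(len(iv) for iv in ann.repeats if iv.label == "SINE")
        assert sine_bases == pytest.approx(0.1 * medium_genome.total_length,
                                           rel=0.02)

    def test_reproducible(self, medium_genome):
        a1 = generate_annotations(medium_genome, fractions={"sine": 0.05},
                                  n_genes=3, seed=9)
        a2 = generate_annotations(medium_genome, fractions={"sine": 0.05},
                                  n_genes=3, seed=9)
        assert list(a1.repeats) == list(a2.repeats)
        assert [t.exons for t in a1.transcripts] == \
            [t.exons for t in a2.transcripts]

    def test_repeats_nonoverlapping(self, medium_annotations):
        track = medium_annotations.repeats
        assert track.merged_span() == track.total_span

    def test_genome_too_short(self):
        g = generate_genome(1000, 0.5, 1.0, seed=0)
        with pytest.raises(ValueError, match="too short"):
            generate_annotations(g, fractions={"line": 0.9}, seed=0)

    def test_cpg_bias_places_sines_on_cpg_rich_windows(self):
        g = generate_genome(100_000, 0.5, 0.7, seed=6)
        biased = generate_annotations(g, fractions={"sine": 0.05},
                                      cpg_bias_in_sine=True, seed=7)
        plain = generate_annotations(g, fractions={"sine": 0.05}, seed=7)

        def density(ann):
            codes = encode(g.contigs["chr1"])
            is_cg = (codes[:-1] == 1) & (codes[1:] == 2)
            mask = ann.repeats.coverage_mask("chr1", g.length("chr1"))[:-1]
            return is_cg[mask].mean()

        assert density(biased) > density(plain) * 1.3

    def test_tss_at_gene_boundaries(self, medium_annotations):
        by_id = {t.transcript_id: t for t in medium_annotations.transcripts}
        for tss in medium_annotations.tss:
            tx = by_id[tss.name]
            expected = tx.span[0] + 1 if tx.strand == "+" else tx.span[1]
            assert tss.pos == expected


class TestSimulateMutations:
    def test_zero_mutations(self, medium_genome):
        assert simulate_mutations(medium_genome, RateTable.uniform(), 0) == []

    def test_support_restriction(self, medium_genome):
        # only CpG C>T has rate: every mutation is C>T at CpG
        calls = simulate_mutations(
            medium_genome, RateTable({("C", "G", "T"): 1.0}), 500, seed=1)
        assert len(calls) == 500
        assert all(c.mut_class == "C>T" and c.is_cpg for c in calls)
        # on the plus strand that is either C>T followed by G, or G>A
        # preceded by C
        for c in calls[:50]:
            seq = medium_genome.contigs[c.position.contig]
            i = c.position.pos - 1
            if c.ref_base == "C":
                assert c.alt_base == "T" and seq[i + 1] == "G"
            else:
                assert (c.ref_base, c.alt_base) == ("G", "A")
                assert seq[i - 1] == "C"

    def test_no_duplicate_sites(self, medium_genome):
        calls = simulate_mutations(medium_genome, RateTable.uniform(), 5000,
                                   seed=2)
        keys = [(c.position.contig, c.position.pos) for c in calls]
        assert len(keys) == len(set(keys))

    def test_determinism(self, medium_genome):
        a = simulate_mutations(medium_genome, RateTable.uniform(), 100, seed=3)
        b = simulate_mutations(medium_genome, RateTable.uniform(), 100, seed=3)
        assert a == b

    def test_exceeding_eligible_sites_errors(self):
        g = GenomeSequence({"c1": "ACGTACGT"})
        with pytest.raises(ValueError, match="eligible"):
            simulate_mutations(g, RateTable.uniform(), 1000)

    def test_uniform_rates_match_multinomial_expectation(self, medium_genome):
        # oracle: exact multinomial expectation from counted abundances
        n = 12_000
        calls = simulate_mutations(medium_genome, RateTable.uniform(), n,
                                   seed=4)
        ab = count_dinucleotide_abundance(medium_genome)
        total_ab = sum(ab.values())
        from collections import Counter
        got = Counter((c.mut_class, c.three_prime_base) for c in calls)
        for (mc, nb), count in got.items():
            p = ab[(mc[0], nb)] / total_ab / 3.0
            expect = n * p
            sd = np.sqrt(n * p * (1 - p))
            assert abs(count - expect) < 3.5 * sd, (mc, nb)

    def test_region_boost_concentrates_cpg_ct(self, medium_genome,
                                              medium_annotations):
        from cpg_mutspec.intervals import IntervalTrack
        sine = IntervalTrack(iv for iv in medium_annotations.repeats
                             if iv.label == "SINE")
        calls = simulate_mutations(
            medium_genome, RateTable.uniform(), 8000, seed=5,
            boost=RegionBoost(track=sine, factor=8.0, cpg_ct_only=True))
        cpg_ct = [c for c in calls if c.is_cpg_ct]
        in_sine = sum(1 for c in cpg_ct
                      if sine.contains_point(c.position.contig, c.position.pos))
        frac = in_sine / len(cpg_ct)
        # SINE fraction ~0.1 of sites; with 8x boost expect ~8*0.1/(8*0.1+0.9)
        assert frac > 0.3


class TestSpectrumRecovery:
    def test_rate_ratio_recovered(self):
        # spectrum of simulated mutations recovers the designed rate ratios
        genome = generate_genome(1_500_000, 0.5, 1.0, seed=10)
        fold = 6.0
        calls = simulate_mutations(genome, RateTable.cpg_ct_boosted(fold),
                                   12_000, seed=11)
        table = build_spectrum(genome, calls)
        cpg_rate = table.normalized_rate[("C>T", "G")]
        others = [table.normalized_rate[cell]
                  for cell in table.normalized_rate
                  if cell != ("C>T", "G")]
        est = cpg_rate / np.mean(others)
        # 99% CI via log-normal propagation from observed counts
        n_cpg = table.counts[("C>T", "G")]
        var_mean = sum(table.counts[c] / table.abundance[(c[0][0], c[1])] ** 2
                       for c in table.counts if c != ("C>T", "G")) / 23 ** 2
        mean_others = np.mean(others) / 1e9
        se = np.sqrt(1 / n_cpg + var_mean / mean_others ** 2)
        assert abs(np.log(est) - np.log(fold)) < 2.576 * se


class TestCloneFamily:
    def _config(self, **kw):
        base = dict(n_clones=3, n_private_per_clone=50, seed=21)
        base.update(kw)
        return CloneFamilyConfig(**base)

    def test_shared_counts_by_construction(self, medium_genome):
        fam = simulate_clone_family(
            medium_genome, RateTable.uniform(),
            self._config(shared={(0, 1): 5}))
        keys0 = {c.key for c in fam.clones[0]}
        keys1 = {c.key for c in fam.clones[1]}
        keys2 = {c.key for c in fam.clones[2]}
        assert len(keys0 & keys1) == 5
        assert not keys0 & keys2 and not keys1 & keys2

    def test_preexisting_have_parental_reads(self, medium_genome):
        fam = simulate_clone_family(
            medium_genome, RateTable.uniform(),
            self._config(n_preexisting_subclonal=10,
                         preexisting_cell_fraction=0.4))
        pre = [t for t in fam.truth if t.origin == "preexisting"]
        assert pre
        # Binomial(100, 0.2) is essentially never 0
        assert all(fam.parental_alt[(t.contig, t.pos, t.ref, t.alt)] > 0
                   for t in pre)

    def test_ledger_complete(self, medium_genome):
        fam = simulate_clone_family(
            medium_genome, RateTable.uniform(),
            self._config(shared={(0, 2): 3}, n_preexisting_subclonal=5))
        emitted = sorted((i, c.key) for i, cl in enumerate(fam.clones)
                         for c in cl)
        ledgered = sorted((t.clone, (t.contig, t.pos, t.ref, t.alt))
                          for t in fam.truth)
        assert emitted == ledgered

    def test_determinism(self, medium_genome):
        cfg = self._config(fail_fraction=0.2,
                           metric_noise=MetricNoise(depth_sd=5))
        f1 = simulate_clone_family(medium_genome, RateTable.uniform(), cfg)
        f2 = simulate_clone_family(medium_genome, RateTable.uniform(), cfg)
        assert f1.clones == f2.clones
        assert f1.truth == f2.truth

    def test_subset_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            CloneFamilyConfig(n_clones=2, shared={(0, 5): 1})

    def test_reference_swap_keys(self, medium_genome):
        fam = simulate_clone_family(
            medium_genome, RateTable.uniform(),
            self._config(shared={(0, 1): 4}))
        vs_parent = clone_call_keys_vs_reference(fam, 0, None)
        vs_sister = clone_call_keys_vs_reference(fam, 0, 1)
        assert len(vs_parent) == 54
        assert len(vs_parent - vs_sister) == 4  # the designed shared SNVs
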