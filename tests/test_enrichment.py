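import math

import numpy as np
import pytest

from cpg_mutspec.annotations import AnnotationSet, Transcript, TSSRecord
from cpg_mutspec.core import GenomeSequence, GenomicPosition, SNVCall
from cpg_mutspec.enrichment import (assign_regions, cgi_shore_counts,
                                    dmr_ratio, retrotransposon_rates,
                                    sine_subfamily_enrichment,
                                    tss_distance_profile,
                                    z_test_two_proportions)
from cpg_mutspec.intervals import Interval, IntervalTrack
from cpg_mutspec.synthetic import (RateTable, RegionBoost,
                                   generate_annotations, generate_genome,
                                   simulate_mutations)


def cpg_call(pos, contig="c1"):
    return SNVCall(GenomicPosition(contig, pos), "C", "T",
                   three_prime_base="G", is_cpg=True)


def plain_call(pos, contig="c1"):
    return SNVCall(GenomicPosition(contig, pos), "T", "A",
                   three_prime_base="A", is_cpg=False)


@pytest.fixture
def simple_annotations():
    # transcript span 100-400 (0-based), CDS 100-160 and 340-400
    tx = Transcript("tx1", "c1", "+", [(100, 160), (340, 400)])
    return AnnotationSet(
        repeats=IntervalTrack([Interval("c1", 50, 80, "AluY", "SINE"),
                               Interval("c1", 500, 600, "L1", "LINE")]),
        cgi=IntervalTrack([Interval("c1", 40, 70)]),
        tss=[TSSRecord("c1", 1000, "+")],
        dmr=IntervalTrack([Interval("c1", 200, 260)]),
        transcripts=[tx],
    )


class TestAssignRegions:
    def test_cds_precedence(self, simple_annotations):
        res = assign_regions([cpg_call(150)], simple_annotations)
        assert res.table.loc[0, "compartment"] == "CDS"

    def test_intron(self, simple_annotations):
        res = assign_regions([cpg_call(250)], simple_annotations)
        assert res.table.loc[0, "compartment"] == "intron"

    def test_intergenic(self, simple_annotations):
        res = assign_regions([cpg_call(800)], simple_annotations)
        assert res.table.loc[0, "compartment"] == "intergenic"

    def test_flags_independent_of_compartment(self, simple_annotations):
        # position 60 (1-based) is inside both the SINE and the CGI
        res = assign_regions([cpg_call(60)], simple_annotations)
        row = res.table.loc[0]
        assert row["in_sine"] and row["in_cgi"]
        assert row["compartment"] == "intergenic"
        assert row["repeat_subfamily"] == "AluY"

    def test_partition_property(self, medium_genome, medium_annotations):
        calls = simulate_mutations(medium_genome, RateTable.uniform(), 2000,
                                   seed=1)
        res = assign_regions(calls, medium_annotations)
        assert sum(res.compartment_counts.values()) == len(calls)


class TestRetrotransposonRates:
    def test_all_cpg_in_sine(self, simple_annotations):
        calls = [cpg_call(60), cpg_call(70), plain_call(550)]
        df = retrotransposon_rates(calls, simple_annotations).set_index(
            "repeat_class")
        assert df.loc["SINE", "pct_cpg_ct"] == 100.0
        assert df.loc["LINE", "pct_cpg_ct"] == 0.0

    def test_empty_repeat_track_errors(self):
        with pytest.raises(ValueError, match="empty"):
            retrotransposon_rates([], AnnotationSet())

    def test_uniform_null_matches_site_share(self, medium_genome,
                                             medium_annotations):
        calls = simulate_mutations(medium_genome, RateTable.uniform(), 15_000,
                                   seed=2)
        df = retrotransposon_rates(calls, medium_annotations).set_index(
            "repeat_class")
        # expected SINE share of CpG C>T = SINE share of CpG sites
        from cpg_mutspec.enrichment import _site_masks
        sine = IntervalTrack(iv for iv in medium_annotations.repeats
                             if iv.label == "SINE")
        cpg, _ = _site_masks(medium_genome, "chr1")
        in_sine = sine.coverage_mask("chr1", medium_genome.length("chr1"))
        p_expect = (cpg & in_sine).sum() / cpg.sum()
        n1 = df.loc["SINE", "n_cpg_ct"] / (df.loc["SINE", "pct_cpg_ct"] / 100)
        observed_p = df.loc["SINE", "pct_cpg_ct"] / 100
        se = math.sqrt(p_expect * (1 - p_expect) / n1)
        assert abs(observed_p - p_expect) < 2.576 * se

    def test_boosted_sine_rate_detected(self, medium_genome,
                                        medium_annotations):
        sine = IntervalTrack(iv for iv in medium_annotations.repeats
                             if iv.label == "SINE")
        calls = simulate_mutations(
            medium_genome, RateTable.uniform(), 10_000, seed=3,
            boost=RegionBoost(track=sine, factor=5.0, cpg_ct_only=True))
        df = retrotransposon_rates(calls, medium_annotations).set_index(
            "repeat_class")
        assert df.loc["SINE", "pct_cpg_ct"] > df.loc["SINE", "pct_noncpg_ct"]
        assert df.loc["SINE", "p_value"] < 0.01


class TestSubfamilyEnrichment:
    def test_identical_cohorts_all_ratios_one(self, medium_genome,
                                              medium_annotations):
        calls = simulate_mutations(medium_genome, RateTable.uniform(), 5000,
                                   seed=4)
        df = sine_subfamily_enrichment(calls, calls, medium_annotations)
        present = df[df["n_ipsc"] > 0]
        assert np.allclose(present["ratio"], 1.0)
        assert np.allclose(present["ratio_rel"], 1.0)

    def test_empty_subfamily_flagged(self, medium_genome, medium_annotations):
        calls = simulate_mutations(medium_genome, RateTable.uniform(), 2000,
                                   seed=5)
        mix_missing = [c for c in calls]
        df = sine_subfamily_enrichment(mix_missing, calls, medium_annotations)
        zero_rows = df[(df["n_germline"] == 0) & (df["kind"] == "subfamily")]
        assert zero_rows["ratio"].isna().all()

    def test_boosted_aluy_ratio(self, medium_genome, medium_annotations):
        aluy = IntervalTrack(iv for iv in medium_annotations.repeats
                             if iv.name == "AluY")
        ipsc = simulate_mutations(
            medium_genome, RateTable.uniform(), 15_000, seed=6,
            boost=RegionBoost(track=aluy, factor=4.0, cpg_ct_only=True))
        germ = simulate_mutations(medium_genome, RateTable.uniform(), 15_000,
                                  seed=7)
        df = sine_subfamily_enrichment(ipsc, germ, medium_annotations)
        df = df[df["kind"] == "group"].set_index("subfamily")
        # AluJ is un-boosted -> anchor ~= its own ratio; AluY ~ 4x after scaling
        n = df.loc["AluY", "n_ipsc"] + df.loc["AluY", "n_germline"]
        se = 2.576 * math.sqrt(4 / n)  # generous log-scale CI
        assert abs(math.log(df.loc["AluY", "ratio_rel"]) - math.log(4.0)) < se


class TestDMRRatio:
    def test_empty_dmr_track_errors(self, medium_genome):
        with pytest.raises(ValueError, match="empty"):
            dmr_ratio([], AnnotationSet(), medium_genome)

    def test_all_calls_outside_gives_zero(self, medium_genome,
                                          medium_annotations):
        outside = []
        for c in simulate_mutations(medium_genome,
                                    RateTable({("C", "G", "T"): 1}), 300,
                                    seed=8):
            if not medium_annotations.dmr.contains_point(c.position.contig,
                                                         c.position.pos):
                outside.append(c)
        with pytest.warns(UserWarning):  # non-CpG side has no calls at all
            r = dmr_ratio(outside, medium_annotations, medium_genome)
        assert r.cpg_ratio == 0.0

    def test_uniform_null_ratio_one(self, medium_genome, medium_annotations):
        calls = simulate_mutations(medium_genome, RateTable.uniform(), 20_000,
                                   seed=9)
        r = dmr_ratio(calls, medium_annotations, medium_genome)
        # 99% CI on the log ratio from the four observed counts
        c_in = r.cpg_rate_in * r.sites_cpg_in
        c_out = r.cpg_rate_out * r.sites_cpg_out
        se = math.sqrt(1 / c_in + 1 / c_out)
        assert abs(math.log(r.cpg_ratio)) < 2.576 * se

    def test_boosted_dmr_recovered(self, medium_genome, medium_annotations):
        calls = simulate_mutations(
            medium_genome, RateTable.uniform(), 20_000, seed=10,
            boost=RegionBoost(track=medium_annotations.dmr, factor=3.0,
                              cpg_ct_only=True))
        r = dmr_ratio(calls, medium_annotations, medium_genome)
        c_in = r.cpg_rate_in * r.sites_cpg_in
        c_out = r.cpg_rate_out * r.sites_cpg_out
        se = math.sqrt(1 / c_in + 1 / c_out)
        assert abs(math.log(r.cpg_ratio) - math.log(3.0)) < 2.576 * se
        # the non-CpG ratio stays at 1
        n_in = r.noncpg_rate_in * r.sites_noncpg_in
        n_out = r.noncpg_rate_out * r.sites_noncpg_out
        se_n = math.sqrt(1 / n_in + 1 / n_out)
        assert abs(math.log(r.noncpg_ratio)) < 2.576 * se_n


class TestCgiShore:
    @pytest.fixture
    def ann(self):
        return AnnotationSet(cgi=IntervalTrack([Interval("c1", 10_000, 10_600)]))

    def test_inside_cgi(self, ann):
        df = cgi_shore_counts({"cl": [cpg_call(10_100)]}, ann)
        assert (df.loc[0, "n_cgi"], df.loc[0, "n_shore"]) == (1, 0)

    def test_one_bp_outside_is_shore(self, ann):
        # CGI covers 1-based 10001..10600
        df = cgi_shore_counts({"cl": [cpg_call(10_000), cpg_call(10_601)]}, ann)
        assert (df.loc[0, "n_cgi"], df.loc[0, "n_shore"]) == (0, 2)

    def test_shore_boundary_5kb(self, ann):
        inside = cpg_call(10_600 + 5_000)       # last shore base
        outside = cpg_call(10_600 + 5_001)      # 5,001 bp outside
        df = cgi_shore_counts({"cl": [inside, outside]}, ann)
        assert df.loc[0, "n_shore"] == 1

    def test_per_clone_rows(self, ann):
        df = cgi_shore_counts({"a": [cpg_call(10_100)], "b": []}, ann)
        assert list(df["clone"]) == ["a", "b"]
        assert df.loc[1, "n_cgi"] == 0


class TestTssProfile:
    @pytest.fixture
    def ann(self):
        return AnnotationSet(tss=[TSSRecord("c1", 1000, "+"),
                                  TSSRecord("c1", 5000, "-")])

    def test_call_at_tss_first_bin(self, ann):
        df = tss_distance_profile([cpg_call(1000)], ann, bins=[0, 100, 1000])
        assert df.loc[0, "n_calls"] == 1

    def test_distance_arithmetic(self, ann):
        df = tss_distance_profile([cpg_call(1500)], ann,
                                  bins=[0, 499, 501, 10_000])
        assert list(df["n_calls"]) == [0, 1, 0]

    def test_empty_tss_errors(self):
        with pytest.raises(ValueError, match="empty"):
            tss_distance_profile([], AnnotationSet(), bins=[0, 1])

    def test_nearest_matches_bruteforce(self, medium_genome,
                                        medium_annotations):
        calls = simulate_mutations(medium_genome, RateTable.uniform(), 1000,
                                   seed=11)
        tss_pos = [t.pos for t in medium_annotations.tss]
        for c in calls[:1000]:
            brute = min(abs(c.position.pos - p) for p in tss_pos)
            got = medium_annotations.nearest_tss_distance(
                c.position.contig, c.position.pos)
            assert got == brute

    def test_germline_ratio(self, ann):
        ipsc = [cpg_call(1000), cpg_call(1001), cpg_call(4000)]
        germ = [cpg_call(1002)]
        df = tss_distance_profile(ipsc, ann, bins=[0, 10, 10_000],
                                  germline_calls=germ, n_clones=1,
                                  n_individuals=1)
        assert df.loc[0, "ratio_to_germline"] == pytest.approx(2.0)
        assert math.isnan(df.loc[1, "ratio_to_germline"])


class TestZTest:
    def test_equal_proportions(self):
        z, p = z_test_two_proportions(30, 100, 30, 100)
        assert (z, p) == (0.0, 1.0)

    def test_hand_computed_example(self):
        # pooled p = 0.4, se = sqrt(0.4*0.6*0.02) = 0.0692820
        z, p = z_test_two_proportions(50, 100, 30, 100)
        assert z == pytest.approx(0.2 / math.sqrt(0.24 * 0.02), rel=1e-9)
        assert z == pytest.approx(2.886751, abs=1e-6)
        assert p == pytest.approx(0.0038924, abs=1e-6)

    def test_swap_negates_z(self):
        z1, p1 = z_test_two_proportions(50, 100, 30, 100)
        z2, p2 = z_test_two_proportions(30, 100, 50, 100)
        assert z1 == -z2 and p1 == p2

    def test_degenerate_equal_extremes(self):
        assert z_test_two_proportions(0, 10, 0, 20) == (0.0, 1.0)
        assert z_test_two_proportions(10, 10, 20, 20) == (0.0, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            z_test_two_proportions(1, 0, 1, 10)
        with pytest.raises(ValueError):
            z_test_two_proportions(11, 10, 1, 10)
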