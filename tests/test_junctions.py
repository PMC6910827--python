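"""Junction forensics: orientation, homology/insertion calls, statistics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chi2

from mnthripsis import junctions as jx, simulate as sim
from mnthripsis.types import Breakend, GenomicInterval, Junction, Side


from _oracles import brute_force_splits


class TestOrientation:
    def test_event_type_mapping(self, small_genome):
        t = sim.simulate_junction_corpus(small_genome, 60, seed=3)
        for tj in t.junctions:
            got = jx.classify_orientation(tj.junction).value
            assert got in sim.expected_orientations(tj.event_kind)

    def test_inversion_yields_both_closed_orientations(self, small_genome):
        t = sim.simulate_junction_corpus(small_genome, 80, seed=5)
        inv = [
            tj.junction.orientation.value
            for tj in t.junctions
            if tj.event_kind == "inversion"
        ]
        assert set(inv) <= {"head_head", "tail_tail"}
        assert len(set(inv)) == 2

    def test_swap_invariance(self):
        a = Breakend("chr1", 100, Side.TAIL)
        b = Breakend("chr1", 90_000, Side.HEAD)
        assert (
            jx.classify_orientation(Junction(a, b))
            == jx.classify_orientation(Junction(b, a))
        )


class TestSpectrum:
    def _jx(self, pos_a, pos_b, side_a, side_b, chrom_b="chr1"):
        return Junction(
            Breakend("chr1", pos_a, side_a), Breakend(chrom_b, pos_b, side_b)
        )

    def test_counts_one_of_each(self):
        jxs = [
            self._jx(0, 1_000_000, Side.TAIL, Side.HEAD),
            self._jx(0, 1_000_000, Side.HEAD, Side.TAIL),
            self._jx(0, 1_000_000, Side.HEAD, Side.HEAD),
            self._jx(0, 1_000_000, Side.TAIL, Side.TAIL),
        ]
        spec = jx.orientation_spectrum(jxs)
        assert spec.as_counts() == (1, 1, 1, 1)
        assert spec.total == 4

    def test_short_span_excluded(self):
        jxs = [self._jx(0, 9_000, Side.TAIL, Side.HEAD)]
        assert jx.orientation_spectrum(jxs, min_span=10_000).total == 0
        # strictly-greater rule: exactly 10 kb is still excluded
        jxs = [self._jx(0, 10_000, Side.TAIL, Side.HEAD)]
        assert jx.orientation_spectrum(jxs, min_span=10_000).total == 0

    def test_translocations_always_count(self):
        jxs = [self._jx(0, 5, Side.TAIL, Side.HEAD, chrom_b="chr2")]
        assert jx.orientation_spectrum(jxs).total == 1

    def test_empty(self):
        assert jx.orientation_spectrum([]).total == 0


class TestMultinomialTest:
    def test_perfect_fit(self):
        res = jx.multinomial_uniform_test((5, 5, 5, 5))
        assert res["statistic"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_asymptotic_extreme(self):
        res = jx.multinomial_uniform_test((10, 0, 0, 0))
        assert res["statistic"] == pytest.approx(30.0)
        assert res["method"] == "exact" if res["n"] < 20 else "asymptotic"
        # compare with the chi-square(3) tail at the same statistic
        assert float(chi2.sf(30.0, 3)) == pytest.approx(1.44e-6, rel=0.05)

    def test_asymptotic_used_at_large_n(self):
        res = jx.multinomial_uniform_test((40, 0, 0, 0))
        assert res["method"] == "asymptotic"
        assert res["p_value"] == pytest.approx(float(chi2.sf(120.0, 3)))

    def test_exact_small_case(self):
        # n=2 over 4 cells: only the (2,0,0,0)-type outcomes reach
        # statistic 6.0; there are 4 of them, each with probability 1/16
        res = jx.multinomial_uniform_test((2, 0, 0, 0))
        assert res["method"] == "exact"
        assert res["statistic"] == pytest.approx(6.0)
        assert res["p_value"] == pytest.approx(0.25)

    def test_exact_matches_asymptotic_at_moderate_n(self):
        counts = (40, 30, 20, 10)
        exact = jx.multinomial_uniform_test(counts, exact_threshold=1000)["p_value"]
        asym = jx.multinomial_uniform_test(counts, exact_threshold=0)["p_value"]
        assert abs(exact - asym) < 0.02

    def test_empty_spectrum_errors(self):
        with pytest.raises(ValueError):
            jx.multinomial_uniform_test((0, 0, 0, 0))

    def test_pooling_is_summation(self):
        a = jx.OrientationSpectrum(3, 1, 0, 2)
        b = jx.OrientationSpectrum(5, 2, 1, 0)
        pooled = a + b
        assert pooled.as_counts() == (8, 3, 1, 2)
        res = jx.multinomial_uniform_test(pooled)
        assert res["n"] == 14


class TestJunctionHomology:
    def test_matches_oracle_and_truth_on_corpus(self, small_genome):
        t = sim.simulate_junction_corpus(small_genome, 80, seed=17)
        flank = 250
        records = sim.render_junction_records(t, flank_len=flank)
        for tj, rec in zip(t.junctions, records):
            left, right = sim.junction_flanks(t.genome, tj.junction, flank)
            feat = jx.junction_homology(rec.contig, left, right)
            oracle = brute_force_splits(rec.contig, left, right)
            assert oracle == (feat.microhomology_len, feat.insertion_len)
            assert feat.microhomology_len == tj.microhomology_len
            assert feat.insertion_len == tj.insertion_len

    def test_planted_homology_gives_shift_ambiguity(self, small_genome):
        t = sim.simulate_junction_corpus(
            small_genome, 10, seed=23, p_blunt=0.0, p_microhomology=1.0,
            p_insertion=0.0, microhomology_range=(5, 5),
        )
        flank = 200
        for tj, rec in zip(t.junctions, sim.render_junction_records(t, flank)):
            if not tj.planted:
                continue
            left, right = sim.junction_flanks(t.genome, tj.junction, flank)
            # by construction a 5 bp homology is exactly 6 equivalent splits
            n = len(rec.contig)
            valid = [
                i
                for i in range(n + 1)
                if rec.contig[:i] == left[:i] and rec.contig[i:] == right[-(n - i):]
            ]
            assert len(valid) == 6
            assert jx.junction_homology(rec.contig, left, right).microhomology_len == 5

    # hand-built flanks are breakend-centered: first half retained
    # approach + second half reference continuation (and mirrored right)
    LEFT_RETAINED = "ACGTACGTACGTACGTACGT"
    LEFT_BEYOND = "GGATTACAGGATTACAGGAT"
    RIGHT_RETAINED = "TTGCATGCATGCATGCATGC"
    RIGHT_BEFORE = "CAGGCTAACAGGCTAACAGG"

    def test_blunt_concatenation(self):
        contig = self.LEFT_RETAINED + self.RIGHT_RETAINED
        feat = jx.junction_homology(
            contig,
            self.LEFT_RETAINED + self.LEFT_BEYOND,
            self.RIGHT_BEFORE + self.RIGHT_RETAINED,
            min_anchor=5,
        )
        assert (feat.microhomology_len, feat.insertion_len, feat.feature_class) == (
            0, 0, "blunt",
        )

    def test_nontemplated_insert(self):
        ins = "CCCCCCCCCCCC"  # 12 bp matching neither flank boundary
        contig = self.LEFT_RETAINED + ins + self.RIGHT_RETAINED
        feat = jx.junction_homology(
            contig,
            self.LEFT_RETAINED + self.LEFT_BEYOND,
            self.RIGHT_BEFORE + self.RIGHT_RETAINED,
            min_anchor=5,
        )
        assert (feat.microhomology_len, feat.insertion_len) == (0, 12)
        assert feat.insertion_seq == ins
        assert feat.feature_class == "insertion"

    def test_flanks_longer_than_contig_flanks(self, small_genome):
        """Classification is unchanged when the caller supplies wider
        reference context than the contig carries."""
        t = sim.simulate_junction_corpus(small_genome, 20, seed=29)
        records = sim.render_junction_records(t, flank_len=200)
        for tj, rec in zip(t.junctions, records):
            left, right = sim.junction_flanks(t.genome, tj.junction, 320)
            feat = jx.junction_homology(rec.contig, left, right)
            assert feat.microhomology_len == tj.microhomology_len
            assert feat.insertion_len == tj.insertion_len

    def test_short_contig_errors(self):
        with pytest.raises(ValueError, match="min_anchor"):
            jx.junction_homology("ACGT", "AC", "GT", min_anchor=10)

    def test_unanchored_contig_flagged(self):
        feat = jx.junction_homology("A" * 50, "C" * 50, "G" * 50, min_anchor=10)
        assert feat.feature_class == "unclassifiable"


class TestTemplatedInsertion:
    def test_verbatim_copy_found(self, small_genome):
        chrom = "chr2"
        seq = small_genome.sequence_str(chrom)
        insert = seq[500_000:500_080]
        feat = jx.detect_templated_insertion(insert, {chrom: seq})
        assert feat is not None and feat.templated
        assert feat.template_locus == GenomicInterval(chrom, 500_000, 500_080)
        assert feat.template_strand == "+"

    def test_reverse_complement_hit(self, small_genome):
        chrom = "chr2"
        seq = small_genome.sequence_str(chrom)
        insert = jx._revcomp(seq[500_000:500_080])
        feat = jx.detect_templated_insertion(insert, {chrom: seq})
        assert feat is not None and feat.template_strand == "-"
        assert feat.template_locus == GenomicInterval(chrom, 500_000, 500_080)

    def test_below_min_len_is_nontemplated(self, small_genome):
        chrom = "chr2"
        seq = small_genome.sequence_str(chrom)
        assert jx.detect_templated_insertion(seq[1000:1010], {chrom: seq}) is None

    def test_absent_sequence_is_nontemplated(self, small_genome):
        rng = np.random.default_rng(0)
        insert = "".join(rng.choice(list("ACGT"), size=60))
        chrom = "chr2"
        found = jx.detect_templated_insertion(
            insert, {chrom: small_genome.sequence_str(chrom)}
        )
        assert found is None


class TestOscillationsAndDensity:
    def test_two_state_oscillation(self):
        assert jx.copy_number_oscillations([3, 2, 3, 2, 3]) == (4, 2)

    def test_uniform_profile(self):
        assert jx.copy_number_oscillations([3]) == (0, 1)

    def test_three_states_signature(self):
        assert jx.copy_number_oscillations([3, 4, 2]) == (2, 3)

    def test_breakpoint_percentages_sum_to_100(self, small_genome):
        t = sim.simulate_shattering(small_genome, 6, 0.4, seed=3, min_fragment=150_000)
        jxs = [tj.junction for tj in t.junctions]
        res = jx.breakpoints_per_chromosome(jxs, ["chr1", "chr2"])
        assert sum(v["percent"] for v in res.values()) == pytest.approx(100.0)
        assert res["chr2"]["percent"] == pytest.approx(100.0)

    def test_translocation_splits_between_chromosomes(self):
        t = Junction(Breakend("chr5", 100, Side.TAIL), Breakend("chr8", 100, Side.HEAD))
        res = jx.breakpoints_per_chromosome([t], ["chr5", "chr8"])
        assert res["chr5"]["percent"] == pytest.approx(50.0)
        assert res["chr8"]["percent"] == pytest.approx(50.0)

    def test_empty_is_all_zero(self):
        res = jx.breakpoints_per_chromosome([], ["chr1"])
        assert res["chr1"] == {"count": 0, "percent": 0.0}


class TestChromothripsisReport:
    def test_shattering_panel(self, default_genome):
        import copy

        g = copy.deepcopy(default_genome)
        t = sim.simulate_shattering(g, 20, 0.4, seed=4)
        segs = [
            s
            for s in sim.render_quantal_segments(t, 50_000, 0.0, 0)
            if s.clone_id == t.clone_id and s.interval.chrom == t.spec.aneuploid_chrom
        ]
        profile = [round(s.quantal) for s in segs]
        records = sim.render_junction_records(t)
        feats = []
        for tj, rec in zip(t.junctions, records):
            left, right = sim.junction_flanks(t.genome, tj.junction, 300)
            feats.append(jx.junction_homology(rec.contig, left, right, tj.junction.name))
        panel = jx.chromothripsis_report(
            profile, [r for r in records], feats, t.spec.aneuploid_chrom,
            [c for c, _ in t.spec.chromosomes],
        )
        assert panel["n_orientation_classes"] == 4
        assert panel["cn_distinct_states"] == 2
        assert panel["cn_transitions"] >= 4
        assert panel["n_junctions_other"] == 0

    def test_empty_inputs_defined(self):
        panel = jx.chromothripsis_report([], [], [], "chr2", ["chr1", "chr2"])
        assert panel["n_junctions"] == 0
        assert panel["orientation_test"] is None
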