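"""Aligner correctness: index completeness, brute-force equivalence of the
ungapped classifier, Smith-Waterman optimality, and gapped rescue of
indel-bearing reads."""

import numpy as np
import pytest

import oracles
from readrescue import align, stats, synthetic_data as sd
from readrescue._seq import revcomp
from readrescue.io_formats import Read, ReadSet
from readrescue.synthetic_data import Genome


def _read(seq, rid="r"):
    return Read(rid, seq, "I" * len(seq))


def _random_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


class TestSeedIndex:
    def test_repeated_kmer_found_at_both_copies(self):
        g = Genome("g", "t", {"chr1": "ACGTACGT"})
        idx = align.build_index(g, 4)
        hits = idx.hits("ACGT")
        assert ("chr1", 0, "+") in hits and ("chr1", 4, "+") in hits

    def test_palindromic_kmer_reported_on_both_strands(self):
        g = Genome("g", "t", {"chr1": "TTTGAATTCTTT"})
        idx = align.build_index(g, 6)
        hits = idx.hits("GAATTC")  # its own reverse complement
        assert ("chr1", 3, "+") in hits and ("chr1", 3, "-") in hits

    def test_index_matches_substring_scan_for_random_kmers(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 10_000)
        g = Genome("g", "t", {"chr1": seq})
        idx = align.build_index(g, 12)
        rc = revcomp(seq)
        for _ in range(100):
            pos = int(rng.integers(0, 10_000 - 12))
            kmer = seq[pos:pos + 12]
            expected = set()
            start = seq.find(kmer)
            while start != -1:
                expected.add(("chr1", start, "+"))
                start = seq.find(kmer, start + 1)
            start = rc.find(kmer)
            while start != -1:
                expected.add(("chr1", len(seq) - start - 12, "-"))
                start = rc.find(kmer, start + 1)
            assert set(idx.hits(kmer)) == expected

    def test_k_larger_than_chromosome_rejected(self):
        g = Genome("g", "t", {"chr1": "ACGTACGT"})
        with pytest.raises(Exception):
            align.build_index(g, 12)


class TestAlignUngapped:
    def test_exact_substring_is_unique_with_zero_mismatches(self, host_genome,
                                                            host_index):
        seq = host_genome.chromosomes["chr1"][1000:1050]
        rec = align.align_ungapped(_read(seq), host_index, 3)
        assert (rec.mapping_class, rec.chrom, rec.start, rec.mismatches) == \
            ("unique", "chr1", 1000, 0)

    def test_read_from_two_copy_repeat_is_multi(self):
        rng = np.random.default_rng(9)
        unit = _random_seq(rng, 60)
        seq = _random_seq(rng, 500) + unit + _random_seq(rng, 500) + unit \
            + _random_seq(rng, 500)
        idx = align.build_index(Genome("g", "t", {"chr1": seq}), 12)
        rec = align.align_ungapped(_read(unit[:50]), idx, 3)
        assert rec.mapping_class == "multi"

    def test_four_substitutions_exceed_the_bound(self, host_genome,
                                                 host_index):
        seq = list(host_genome.chromosomes["chr1"][2000:2050])
        for i in (5, 15, 25, 35):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        rec = align.align_ungapped(_read("".join(seq)), host_index, 3)
        assert rec.mapping_class == "unaligned"

    @pytest.mark.parametrize("read_len,max_mm", [(22, 2), (50, 3)])
    def test_classes_match_exhaustive_hamming_scan(self, read_len, max_mm):
        """Both candidate paths (exhaustive for short reads, pigeonhole
        seeding for long ones) must agree with brute force."""
        rng = np.random.default_rng(21)
        g = Genome("g", "t", {"chr1": _random_seq(rng, 2000),
                              "chr2": _random_seq(rng, 1000)})
        idx = align.build_index(g, 12)
        for _ in range(60):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            pos = int(rng.integers(0, len(g.chromosomes[chrom]) - read_len))
            seq = list(g.chromosomes[chrom][pos:pos + read_len])
            for i in rng.choice(read_len, size=int(rng.integers(0, 5)),
                                replace=False):
                seq[i] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rec = align.align_ungapped(_read(seq), idx, max_mm)
            expected = oracles.brute_placements(g, seq, max_mm)
            if not expected:
                assert rec.mapping_class == "unaligned"
            else:
                best = min(mm for *_, mm in expected)
                n_best = sum(1 for *_, mm in expected if mm == best)
                assert rec.mismatches == best
                assert rec.mapping_class == \
                    ("unique" if n_best == 1 else "multi")
                assert (rec.chrom, rec.start, rec.strand, rec.mismatches) \
                    in expected

    def test_reverse_complement_flips_strand_only(self, host_genome,
                                                  host_index):
        seq = host_genome.chromosomes["chr2"][300:350]
        fwd = align.align_ungapped(_read(seq), host_index, 3)
        rev = align.align_ungapped(_read(revcomp(seq)), host_index, 3)
        assert (fwd.chrom, fwd.start, fwd.end) == (rev.chrom, rev.start,
                                                   rev.end)
        assert {fwd.strand, rev.strand} == {"+", "-"}


class TestClassifyReadset:
    def test_error_free_unique_simulation_is_all_unique(self, host_genome,
                                                        host_index):
        rs = sd.simulate_wgs_reads(host_genome, 300, 50, seed=3)
        t = align.classify_readset(rs, host_index, 3)
        assert t.proportions == {"unique": 1.0, "multi": 0.0, "unaligned": 0.0}

    def test_contaminant_spike_shows_up_as_unaligned(self, host_genome,
                                                     host_index,
                                                     contaminant_genome):
        host = sd.simulate_wgs_reads(host_genome, 2000, 50, seed=4)
        mixed = sd.mix_contaminants(host, [(contaminant_genome, 0.3)],
                                    sd.SimulationParams(error_rate=0.0),
                                    seed=5)
        t = align.classify_readset(mixed, host_index, 3)
        n = t.n_total
        assert abs(t.n_unaligned / n - 0.30) <= 3 * np.sqrt(0.3 * 0.7 / n)

    def test_proportions_stable_under_shuffling(self, host_genome,
                                                host_index):
        rs = sd.simulate_wgs_reads(host_genome, 200, 50, 0.02, seed=6)
        t1 = align.classify_readset(rs, host_index, 2)
        shuffled = ReadSet(list(reversed(rs.reads)), rs.truth)
        t2 = align.classify_readset(shuffled, host_index, 2)
        assert (t1.n_unique, t1.n_multi, t1.n_unaligned) == \
            (t2.n_unique, t2.n_multi, t2.n_unaligned)
        assert abs(sum(t1.proportions.values()) - 1.0) < 1e-12

    def test_empty_readset_is_flagged(self, host_index):
        t = align.classify_readset(ReadSet([]), host_index)
        assert t.empty and t.n_total == 0


class TestMappabilityByLength:
    def test_full_length_matches_classify(self, host_genome, host_index):
        rs = sd.simulate_wgs_reads(host_genome, 150, 40, seed=7)
        df = align.mappability_by_length(rs, host_index, lengths=(40,),
                                         max_mismatches=2)
        t = align.classify_readset(rs, host_index, 2)
        row = df.iloc[0]
        assert (row.n_unique, row.n_multi, row.n_unaligned) == \
            (t.n_unique, t.n_multi, t.n_unaligned)

    def test_repeat_straddling_read_resolves_with_length(self):
        rng = np.random.default_rng(31)
        repeat = _random_seq(rng, 100)
        bridge = _random_seq(rng, 2)
        unique_tail = _random_seq(rng, 60)
        decoy_tail = _random_seq(rng, 60)
        seq = (_random_seq(rng, 300) + repeat + bridge + unique_tail
               + _random_seq(rng, 300) + repeat + bridge + decoy_tail
               + _random_seq(rng, 300))
        idx = align.build_index(Genome("g", "t", {"chr1": seq}), 12)
        # read starts 18 bp before the end of the first repeat copy
        start = 300 + 100 - 18
        read = ReadSet([_read(seq[start:start + 40], "straddle")])
        df = align.mappability_by_length(read, idx, lengths=(20, 40),
                                         max_mismatches=0)
        assert df[df.length == 20].iloc[0].n_multi == 1
        assert df[df.length == 40].iloc[0].n_unique == 1

    def test_multi_proportion_never_increases_with_length(self, host_genome,
                                                          host_index):
        rs = sd.simulate_wgs_reads(host_genome, 150, 40, seed=8)
        df = align.mappability_by_length(rs, host_index,
                                         lengths=(20, 25, 30, 35, 40),
                                         max_mismatches=0)
        multi = df.p_multi.to_numpy()
        assert (np.diff(multi) <= 1e-12).all()

    def test_too_short_reads_skip_that_length(self, host_genome, host_index):
        rs = sd.simulate_wgs_reads(host_genome, 50, 30, seed=9)
        df = align.mappability_by_length(rs, host_index, lengths=(25, 40))
        assert not df[df.length == 25].iloc[0].skipped
        assert df[df.length == 40].iloc[0].skipped


class TestMismatchSweep:
    def test_error_free_reads_identical_across_mm(self, host_genome,
                                                  host_index):
        rs = sd.simulate_wgs_reads(host_genome, 150, 50, seed=10)
        df = align.mismatch_sweep(rs, host_index)
        assert df.p_aligned.nunique() == 1

    def test_single_substitution_needs_one_mismatch(self, host_genome,
                                                    host_index):
        seq = list(host_genome.chromosomes["chr1"][5000:5050])
        seq[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[20]]
        rs = ReadSet([_read("".join(seq))])
        df = align.mismatch_sweep(rs, host_index)
        assert df[df.max_mismatches == 0].iloc[0].p_aligned == 0.0
        assert (df[df.max_mismatches >= 1].p_aligned == 1.0).all()

    def test_aligned_proportion_grows_with_allowance_under_errors(
            self, host_genome, host_index):
        rs = sd.simulate_wgs_reads(host_genome, 400, 75, error_rate=0.01,
                                   seed=11)
        df = align.mismatch_sweep(rs, host_index, mm_values=(0, 3))
        a0 = df[df.max_mismatches == 0].iloc[0].p_aligned
        a3 = df[df.max_mismatches == 3].iloc[0].p_aligned
        assert a3 > a0  # ~53% of 75mers carry >= 1 error at 1%


class TestSmithWaterman:
    def test_perfect_match_scores_match_times_length(self):
        aln = align.smith_waterman("ACGT", "ACGT",
                                   align.ScoringScheme(match=2))
        assert aln.score == 8 and aln.gaps == 0 and aln.cigar == (("M", 4),)

    def test_all_mismatch_pair_has_empty_alignment(self):
        aln = align.smith_waterman("AAAA", "TTTT")
        assert aln.score == 0 and aln.cigar == ()

    def test_scores_equal_independent_dp_oracle(self):
        rng = np.random.default_rng(41)
        scheme = align.ScoringScheme()
        for _ in range(40):
            a = _random_seq(rng, int(rng.integers(5, 26)))
            b = _random_seq(rng, int(rng.integers(5, 26)))
            if rng.random() < 0.5:  # related pair: b contains a mutated a
                b = b[:5] + a + b[5:]
            aln = align.smith_waterman(a, b, scheme)
            assert aln.score == oracles.sw_score(
                a, b, scheme.match, scheme.mismatch, scheme.gap_open,
                scheme.gap_extend)

    def test_traceback_reproduces_the_score(self):
        rng = np.random.default_rng(43)
        scheme = align.ScoringScheme()
        for _ in range(25):
            a = _random_seq(rng, 20)
            b = a[:8] + _random_seq(rng, 3) + a[10:]
            aln = align.smith_waterman(a, b, scheme)
            score = (aln.matched * scheme.match
                     + aln.mismatches * scheme.mismatch)
            for op, n in aln.cigar:
                if op in ("I", "D"):
                    score += scheme.gap_open + (n - 1) * scheme.gap_extend
            assert score == aln.score

    def test_score_invariant_under_joint_reverse_complement(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            a = _random_seq(rng, 15)
            b = _random_seq(rng, 40)
            s1 = align.smith_waterman(a, b).score
            s2 = align.smith_waterman(revcomp(a), revcomp(b)).score
            assert s1 == s2


class TestRealignGapped:
    def test_error_free_read_agrees_with_ungapped(self, host_genome,
                                                  host_index):
        seq = host_genome.chromosomes["chr1"][7000:7050]
        u = align.align_ungapped(_read(seq), host_index, 3)
        gpd = align.realign_gapped(_read(seq), host_index)
        assert (gpd.chrom, gpd.start, gpd.strand, gpd.mapping_class) == \
            (u.chrom, u.start, u.strand, "unique")

    def test_one_base_deletion_rescued_at_truth_locus(self, host_genome,
                                                      host_index):
        ref = host_genome.chromosomes["chr1"][8000:8051]
        seq = ref[:25] + ref[26:]  # 50 bp read with a 1 bp deletion
        u = align.align_ungapped(_read(seq), host_index, 3)
        gpd = align.realign_gapped(_read(seq), host_index)
        assert u.mapping_class == "unaligned"
        assert gpd.mapping_class == "unique" and gpd.gaps >= 1
        assert gpd.chrom == "chr1" and abs(gpd.start - 8000) <= 2

    def test_divergent_reads_recovered_above_forty_percent(self, host_genome,
                                                           host_index):
        base = sd.simulate_wgs_reads(host_genome, 800, 50, seed=51)
        div = sd.diverge_reads(base, 0.05, seed=52)
        u = stats.roc_from_truth(
            align.align_readset(div, host_index, 3), div.truth, 5)
        g = stats.roc_from_truth(
            align.realign_readset(div, host_index), div.truth, 5)
        assert g.sensitivity >= 0.40
        assert g.sensitivity > u.sensitivity
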