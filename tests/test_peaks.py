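"""Peak caller calibration and the peak characterization toolbox."""

import numpy as np
import pytest

import oracles
from readrescue import align, peaks, synthetic_data as sd
from readrescue.align import AlignmentRecord
from readrescue.errors import DataIntegrityError, InvalidParameterError
from readrescue.peaks import Peak, PeakCallParams
from readrescue.synthetic_data import Genome


def _rec(rid, chrom, start, end, strand):
    return AlignmentRecord(rid, chrom, start, end, strand, 0, 0, end - start,
                           "unique")


def _flat_genome(length, name="chr1"):
    return Genome("g", "t", {name: "A" * length})


class TestCoveragePileup:
    def test_no_alignments_is_all_zero(self):
        g = _flat_genome(1000)
        cov = peaks.coverage_pileup([], g, 200)
        assert cov["chr1"].sum() == 0

    def test_single_plus_read_covers_extension(self):
        g = _flat_genome(1000)
        cov = peaks.coverage_pileup([_rec("r", "chr1", 100, 150, "+")], g, 200)
        assert (cov["chr1"][100:300] == 1).all()
        assert cov["chr1"].sum() == 200

    def test_minus_read_extends_leftwards(self):
        g = _flat_genome(1000)
        cov = peaks.coverage_pileup([_rec("r", "chr1", 500, 550, "-")], g, 200)
        assert (cov["chr1"][350:550] == 1).all()

    def test_total_mass_matches_interval_oracle(self):
        rng = np.random.default_rng(3)
        g = _flat_genome(5000)
        recs = []
        expected = 0
        for i in range(300):
            start = int(rng.integers(0, 4950))
            strand = "+" if rng.random() < 0.5 else "-"
            recs.append(_rec(f"r{i}", "chr1", start, start + 50, strand))
            if strand == "+":
                expected += min(200, 5000 - start)
            else:
                expected += min(200, start + 50)
        cov = peaks.coverage_pileup(recs, g, 200)
        assert cov["chr1"].sum() == expected

    def test_out_of_bounds_alignment_rejected(self):
        g = _flat_genome(100)
        with pytest.raises(DataIntegrityError):
            peaks.coverage_pileup([_rec("r", "chr1", 80, 130, "+")], g, 200)


class TestPoissonPvalue:
    def test_zero_observation_has_unit_tail(self):
        assert peaks.poisson_pvalue(0, 3.0) == 1.0

    def test_closed_form_at_k_one(self):
        assert peaks.poisson_pvalue(1, 1.0) == pytest.approx(1 - np.exp(-1),
                                                             rel=1e-12)

    def test_matches_high_precision_summation(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            lam = float(rng.uniform(0.1, 500))
            k = int(rng.integers(0, 800))
            assert peaks.poisson_pvalue(k, lam) == pytest.approx(
                oracles.poisson_upper_tail(k, lam), rel=1e-9, abs=1e-300)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(InvalidParameterError):
            peaks.poisson_pvalue(3, 0.0)


def _simulate_tracks(genome, index, n_sites, seed, n_reads=6000,
                     enrichment=6.0):
    sites = sd.plant_binding_sites(genome, "CAGGTG", n_sites, 1500,
                                   seed=seed)
    tp = sd.SimulationParams(n_reads=n_reads, enrichment=enrichment,
                             seed=seed + 1)
    cp = sd.SimulationParams(n_reads=n_reads, seed=seed + 2)
    tr = sd.simulate_chip_reads(genome, sites, tp)
    ct = sd.simulate_chip_reads(genome, sites, cp, control=True,
                                read_prefix="c")
    t_u = [r for r in align.align_readset(tr, index, 3)
           if r.mapping_class == "unique"]
    c_u = [r for r in align.align_readset(ct, index, 3)
           if r.mapping_class == "unique"]
    tcov = peaks.coverage_pileup(t_u, genome, 200)
    ccov = peaks.coverage_pileup(c_u, genome, 200)
    return sites, tcov, ccov, len(t_u), len(c_u)


class TestCallPeaks:
    def test_treatment_equal_control_yields_no_peaks(self):
        g = sd.generate_genome(100_000, 0.41, 1, seed=41,
                               taxon_id="h_sapiens")
        idx = align.build_index(g, 12)
        rs = sd.simulate_chip_reads(
            g, sd.SiteSet([]), sd.SimulationParams(n_reads=4000, seed=42),
            control=True)
        recs = [r for r in align.align_readset(rs, idx, 3)
                if r.mapping_class == "unique"]
        cov = peaks.coverage_pileup(recs, g, 200)
        out = peaks.call_peaks(cov, cov, PeakCallParams(), len(recs),
                               len(recs))
        assert out == []

    def test_empty_treatment_yields_no_peaks(self):
        g = _flat_genome(50_000)
        zero = {"chr1": np.zeros(50_000, dtype=np.int64)}
        ones = {"chr1": np.ones(50_000, dtype=np.int64)}
        assert peaks.call_peaks(zero, ones, PeakCallParams(), 0, 100) == []

    def test_planted_sites_recovered_across_seeds(self):
        hit_rates = []
        for seed in (60, 70, 80, 90, 100):
            g = sd.generate_genome(120_000, 0.41, 1, seed=seed,
                                   taxon_id="h_sapiens")
            idx = align.build_index(g, 12)
            sites, tcov, ccov, nt, nc = _simulate_tracks(g, idx, 20, seed)
            called = peaks.call_peaks(tcov, ccov, PeakCallParams(), nt, nc)
            hit = sum(
                1 for s in sites
                if any(p.chrom == s.chrom and abs(p.summit - s.center) <= 150
                       for p in called))
            hit_rates.append(hit / len(sites))
        assert all(r >= 0.9 for r in hit_rates)  # >= 18 of 20 sites

    def test_lowering_cutoff_never_adds_peaks(self):
        g = sd.generate_genome(120_000, 0.41, 1, seed=111,
                               taxon_id="h_sapiens")
        idx = align.build_index(g, 12)
        sites, tcov, ccov, nt, nc = _simulate_tracks(g, idx, 10, 112,
                                                     enrichment=2.0)
        n_prev = None
        for cutoff in (0.05, 0.005, 1e-5, 1e-9):
            n = len(peaks.call_peaks(tcov, ccov,
                                     PeakCallParams(p_cutoff=cutoff), nt, nc))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_null_window_false_rate_bounded(self):
        """With enrichment 0 and independent treatment/control, the fraction
        of scanned windows below the cutoff stays within 3x the nominal
        rate (the local-lambda floor keeps the test conservative)."""
        from scipy import stats as sps

        g = sd.generate_genome(150_000, 0.41, 1, seed=131,
                               taxon_id="h_sapiens")
        idx = align.build_index(g, 12)
        n_sig = 0
        n_windows = 0
        params = PeakCallParams()
        for seed in (201, 202, 203):
            tr = sd.simulate_chip_reads(
                g, sd.SiteSet([]),
                sd.SimulationParams(n_reads=5000, seed=seed), control=True)
            ct = sd.simulate_chip_reads(
                g, sd.SiteSet([]),
                sd.SimulationParams(n_reads=5000, seed=seed + 50),
                control=True, read_prefix="c")
            t_u = [r for r in align.align_readset(tr, idx, 3) if r.aligned]
            c_u = [r for r in align.align_readset(ct, idx, 3) if r.aligned]
            tcov = peaks.coverage_pileup(t_u, g, 200)["chr1"]
            ccov = peaks.coverage_pileup(c_u, g, 200)["chr1"]
            w, ext = params.window, params.fragment_extension
            tcum = np.concatenate(([0], np.cumsum(tcov)))
            ccum = np.concatenate(([0], np.cumsum(ccov)))
            starts = np.arange(0, len(tcov) - w + 1, w)
            k = (tcum[starts + w] - tcum[starts]) // ext
            bg = (ccum[-1] / ext) * (w / len(tcov)) * (len(t_u) / len(c_u))
            pv = sps.poisson.sf(k - 1, bg)
            n_sig += int((pv < params.p_cutoff).sum())
            n_windows += len(starts)
        assert n_sig / n_windows <= 3 * params.p_cutoff

    def test_zero_control_falls_back_with_warning(self):
        g = _flat_genome(50_000)
        tcov = {"chr1": np.ones(50_000, dtype=np.int64)}
        zero = {"chr1": np.zeros(50_000, dtype=np.int64)}
        with pytest.warns(UserWarning, match="control"):
            peaks.call_peaks(tcov, zero, PeakCallParams(), 100, 0)


class TestIntersectPeakSets:
    def _peaks(self, triples):
        return [Peak(c, s, e, s, 1, 1.0, 0.001) for c, s, e in triples]

    def test_identical_sets_fully_overlap(self):
        a = self._peaks([("chr1", 0, 100), ("chr1", 500, 700)])
        out = peaks.intersect_peak_sets(a, a)
        assert out["n_overlap_a"] == 2 and out["n_a_only"] == 0

    def test_disjoint_chromosomes_never_overlap(self):
        a = self._peaks([("chr1", 0, 100)])
        b = self._peaks([("chr2", 0, 100)])
        assert peaks.intersect_peak_sets(a, b)["n_overlap_a"] == 0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)

        def random_set(n):
            out = []
            for _ in range(n):
                chrom = f"chr{int(rng.integers(1, 4))}"
                s = int(rng.integers(0, 10_000))
                out.append((chrom, s, s + int(rng.integers(50, 400))))
            return self._peaks(out)

        a, b = random_set(200), random_set(200)
        got = peaks.intersect_peak_sets(a, b, min_overlap=25)
        assert got == oracles.brute_peak_overlap(a, b, min_overlap=25)


class TestAnnotatePeaks:
    def test_no_genes_means_all_intergenic(self):
        pk = [Peak("chr1", 100, 400, 200, 5, 1.0, 1e-4)]
        props = peaks.annotate_peaks(pk, [])
        assert props["intergenic"] == 1.0 and pk[0].category == "intergenic"

    def test_summit_upstream_of_tss_is_promoter(self, host_genome):
        genes = sd.generate_gene_models(host_genome, 5, seed=3)
        g = next(g for g in genes if g.strand == "+")
        summit = g.tss - 1000
        pk = [Peak(g.chrom, summit - 50, summit + 50, summit, 5, 1.0, 1e-4)]
        peaks.annotate_peaks(pk, [g])
        assert pk[0].category == "promoter"

    def test_categories_match_linear_scan_oracle(self, host_genome):
        rng = np.random.default_rng(11)
        genes = sd.generate_gene_models(host_genome, 20, seed=5)
        pk = []
        for i in range(300):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, len(host_genome.chromosomes[chrom]) - 400))
            pk.append(Peak(chrom, s, s + 400, s + int(rng.integers(0, 400)),
                           3, 1.0, 1e-4))
        props = peaks.annotate_peaks(pk, genes)
        for p in pk:
            assert p.category == oracles.annotate_summit(p.chrom, p.summit,
                                                         genes)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)


class TestTssDensity:
    def test_summits_at_tss_peak_the_curve_at_zero(self, host_genome):
        genes = sd.generate_gene_models(host_genome, 10, seed=7)
        pk = [Peak(g.chrom, max(g.tss - 100, 0), g.tss + 100, g.tss, 5, 1.0,
                   1e-4) for g in genes]
        curve = peaks.tss_density(pk, genes)
        assert abs(curve.grid[np.argmax(curve.density)]) <= \
            curve.grid[1] - curve.grid[0]

    def test_curve_integrates_to_one(self, host_genome):
        rng = np.random.default_rng(13)
        genes = sd.generate_gene_models(host_genome, 10, seed=9)
        pk = []
        for i in range(100):
            s = int(rng.integers(0, 50_000))
            pk.append(Peak("chr1", s, s + 200, s + 100, 3, 1.0, 1e-4))
        curve = peaks.tss_density(pk, genes)
        area = np.trapezoid(curve.density, curve.grid)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_uniform_summits_give_flat_distances(self, host_genome):
        """Uniform random summits produce TSS distances compatible with a
        uniform law over the window (KS test)."""
        from scipy import stats as sps

        rng = np.random.default_rng(17)
        # single gene centred in a long chromosome, uniform summits nearby
        genes = [g for g in sd.generate_gene_models(host_genome, 1, seed=11)]
        g = genes[0]
        dists = rng.uniform(-5000, 5000, size=2000).astype(int)
        pk = [Peak(g.chrom, 0, 1, 0, 1, 1.0, 1e-4) for _ in dists]
        signed = dists if g.strand == "+" else -dists
        pk = [Peak(g.chrom, max(g.tss + d, 0), max(g.tss + d, 0) + 1,
                   max(g.tss + d, 0), 1, 1.0, 1e-4) for d in signed]
        observed = []
        for p in pk:
            d = p.summit - g.tss if g.strand == "+" else g.tss - p.summit
            observed.append(d)
        ks = sps.kstest(observed, sps.uniform(loc=-5000, scale=10_000).cdf)
        assert ks.pvalue > 0.001

    def test_empty_input_is_flagged(self, host_genome):
        genes = sd.generate_gene_models(host_genome, 3, seed=13)
        curve = peaks.tss_density([], genes)
        assert curve.empty


class TestChromDistribution:
    def test_single_chromosome_concentration(self, host_genome):
        pk = [Peak("chr1", i * 1000, i * 1000 + 400, i * 1000 + 100, 3, 1.0,
                   1e-4) for i in range(5)]
        df = peaks.chrom_distribution(pk, host_genome)
        assert df[df.chrom == "chr1"].iloc[0].proportion == 1.0
        assert df[df.chrom == "chr2"].iloc[0]["count"] == 0

    def test_empty_peak_list_is_flagged(self, host_genome):
        df = peaks.chrom_distribution([], host_genome)
        assert df.empty_.all() if hasattr(df, "empty_") else df["empty"].all()

    def test_proportions_match_direct_counts(self, host_genome):
        rng = np.random.default_rng(19)
        pk = []
        for i in range(120):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            s = int(rng.integers(0, 20_000))
            pk.append(Peak(chrom, s, s + 300, s + 100, 3, 1.0, 1e-4))
        df = peaks.chrom_distribution(pk, host_genome)
        n1 = sum(1 for p in pk if p.chrom == "chr1")
        assert df[df.chrom == "chr1"].iloc[0]["count"] == n1
        assert df.proportion.sum() == pytest.approx(1.0, abs=1e-12)


class TestLowComplexity:
    def test_dinucleotide_repeat_is_flagged(self):
        g = Genome("g", "t", {"chr1": "ACGT" * 50 + "AC" * 60 + "TGCA" * 50})
        pk = [Peak("chr1", 180, 340, 250, 3, 1.0, 1e-4)]
        frac, flags = peaks.low_complexity_fraction(pk, g)
        assert flags == [True] and frac == 1.0

    def test_random_sequence_rarely_flagged(self):
        rng = np.random.default_rng(23)
        false_flags = 0
        n = 1000
        for i in range(n):
            seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 64))
            if peaks.dust_score(seq) > 2.0:
                false_flags += 1
        assert false_flags / n <= 0.05

    def test_peaks_on_planted_repeats_flag_more_often(self):
        g = sd.generate_genome(
            100_000, 0.45, 1,
            repeat_spec={"unit_len": 2, "copies": 60, "n_loci": 6}, seed=29,
            taxon_id="h_sapiens")
        on_repeat = [Peak("chr1", max(s - 100, 0), e + 100, (s + e) // 2, 3,
                          1.0, 1e-4) for _, s, e in g.repeat_loci]
        rng = np.random.default_rng(31)
        off_repeat = []
        while len(off_repeat) < 6:
            s = int(rng.integers(0, 99_000))
            if all(not (s < e + 500 and s + 500 > rs)
                   for _, rs, e in g.repeat_loci):
                off_repeat.append(Peak("chr1", s, s + 500, s + 250, 3, 1.0,
                                       1e-4))
        frac_on, _ = peaks.low_complexity_fraction(on_repeat, g)
        frac_off, _ = peaks.low_complexity_fraction(off_repeat, g)
        assert frac_on > frac_off
        assert frac_on == 1.0

    def test_peak_outside_genome_rejected(self):
        g = _flat_genome(100)
        with pytest.raises(DataIntegrityError):
            peaks.low_complexity_fraction(
                [Peak("chr1", 50, 150, 60, 1, 1.0, 1e-4)], g)
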