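"""End-to-end rescue pipeline.

Simulate (or load) a ChIP-Seq experiment, align ungapped, triage the
rejects taxonomically (cluster -> database search -> LCA), realign the
host-legitimate rejects with the gapped aligner, call ordinary and
recovered peak sets, and characterize both.  Every stage writes its tables
under the output directory and the run is bit-identical under a fixed
config (all stage seeds derive from ``config.seed``).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import align, cluster, io_formats, peaks, synthetic_data, taxonomy
from .errors import InvalidParameterError

DEFAULT_CONTAMINANTS = (
    {"name": "ecoli", "taxon_id": "e_coli", "length": 80_000, "gc": 0.50,
     "fraction": 0.10},
    {"name": "pacnes", "taxon_id": "p_acnes", "length": 60_000, "gc": 0.60,
     "fraction": 0.05},
    {"name": "msilvanus", "taxon_id": "m_silvanus", "length": 60_000,
     "gc": 0.62, "fraction": 0.05},
)


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    The headline constants — 3 allowed mismatches for the primary aligner,
    0.75 clustering identity, 0.10 LCA score window, p-value cutoff 0.005
    and 200 bp fragment extension for peak calling — are the defaults here.
    """

    seed: int = 0
    # host genome & sites
    host_length: int = 500_000
    host_gc: float = 0.41
    host_chroms: int = 4
    host_taxon_id: str = "h_sapiens"
    repeat_spec: dict | None = field(
        default_factory=lambda: {"unit_len": 4, "copies": 40, "n_loci": 10})
    motif: str = "CAGGTG"
    n_sites: int = 60
    n_divergent_sites: int = 30
    site_min_gap: int = 2_000
    # read simulation
    read_length: int = 50
    n_reads: int = 60_000
    n_control_reads: int = 40_000
    error_rate: float = 0.01
    fragment_mean: float = 200.0
    fragment_sd: float = 40.0
    enrichment: float = 4.0
    divergent_sub_rate: float = 0.05
    divergent_indel_spacing: int = 25
    contaminants: tuple = DEFAULT_CONTAMINANTS
    # preprocessing
    adapter: str | None = None
    min_mean_quality: float = 20.0
    min_read_length: int = 20
    # ungapped alignment
    max_mismatches: int = 3
    seed_k: int = 12
    # clustering
    cluster_identity: float = 0.75
    # taxonomy
    score_window: float = 0.10
    search_min_score_fraction: float = 0.5
    max_hits: int = 10
    # gapped realignment
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    realign_min_score_fraction: float = 0.55
    realign_min_seed_hits: int = 2
    seed_stride: int = 5
    # peak calling
    p_cutoff: float = 0.005
    fragment_extension: int = 200
    peak_window: int = 200
    min_peak_len: int = 400
    merge_gap: int = 200
    # annotation
    n_genes: int = 60
    promoter_span: int = 3000
    downstream_span: int = 3000
    # bookkeeping
    write_intermediates: bool = True

    def __post_init__(self):
        if not 0 < self.cluster_identity <= 1:
            raise InvalidParameterError("cluster_identity must be in (0, 1]")
        if not 0 <= self.score_window <= 1:
            raise InvalidParameterError("score_window must be in [0, 1]")
        if not 0 < self.p_cutoff < 1:
            raise InvalidParameterError("p_cutoff must be in (0, 1)")
        if not 0 <= self.max_mismatches <= 3:
            raise InvalidParameterError("max_mismatches must be 0..3")
        frac = sum(c["fraction"] for c in self.contaminants)
        if frac >= 1:
            raise InvalidParameterError("contaminant fractions must sum to < 1")

    @property
    def scheme(self) -> align.ScoringScheme:
        return align.ScoringScheme(self.match, self.mismatch, self.gap_open,
                                   self.gap_extend,
                                   self.realign_min_score_fraction)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "contaminants" in data:
            data["contaminants"] = tuple(data["contaminants"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["contaminants"] = [dict(c) for c in self.contaminants]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RescueReport:
    """Structured results of one pipeline run (counts are a closed ledger:
    every input read lands in exactly one bucket of each stage)."""

    config: dict
    ledger: dict
    mappability: dict
    taxonomy_breakdown: dict        # rank -> list of row dicts
    recovery: dict
    overlap: dict
    annotation: dict                # peak set -> category proportions
    chrom_distribution: dict        # peak set -> list of row dicts
    low_complexity: dict            # peak set -> fraction
    truth_eval: dict
    ordinary_peaks: list = field(default_factory=list, repr=False)
    recovered_peaks: list = field(default_factory=list, repr=False)

    def summary_dict(self) -> dict:
        return {
            "config": self.config, "ledger": self.ledger,
            "mappability": self.mappability,
            "taxonomy_breakdown": self.taxonomy_breakdown,
            "recovery": self.recovery, "overlap": self.overlap,
            "annotation": self.annotation,
            "chrom_distribution": self.chrom_distribution,
            "low_complexity": self.low_complexity,
            "truth_eval": self.truth_eval,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1, sort_keys=True,
                      default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in ss.spawn(n)]


def run_rescue_pipeline(config: PipelineConfig, outdir) -> RescueReport:
    """Run the full rescue workflow; see module docstring for the stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline_log.jsonl"
    log_fh = open(log_path, "w")
    t_start = time.time()

    def log(stage, **kv):
        rec = {"stage": stage, "elapsed_s": round(time.time() - t_start, 2), **kv}
        log_fh.write(json.dumps(rec, sort_keys=True, default=_jsonable) + "\n")
        log_fh.flush()

    seeds = _stage_seeds(config.seed)
    tree = synthetic_data.toy_taxonomy()

    # --- simulate inputs -------------------------------------------------
    host = synthetic_data.generate_genome(
        config.host_length, config.host_gc, config.host_chroms,
        repeat_spec=config.repeat_spec, seed=seeds[0], name="host",
        taxon_id=config.host_taxon_id,
    )
    sites = synthetic_data.plant_binding_sites(
        host, config.motif, config.n_sites, config.site_min_gap, seed=seeds[1])
    div_sites = synthetic_data.plant_binding_sites(
        host, config.motif, config.n_divergent_sites, config.site_min_gap,
        seed=seeds[2], avoid=sites)
    genes = synthetic_data.generate_gene_models(host, config.n_genes,
                                                seed=seeds[3])
    params = synthetic_data.SimulationParams(
        read_length=config.read_length, n_reads=config.n_reads,
        error_rate=config.error_rate, fragment_mean=config.fragment_mean,
        fragment_sd=config.fragment_sd, enrichment=config.enrichment,
        divergent_sub_rate=config.divergent_sub_rate,
        divergent_indel_spacing=config.divergent_indel_spacing, seed=seeds[4],
    )
    treatment = synthetic_data.simulate_chip_reads(
        host, sites, params, divergent_sites=div_sites, read_prefix="t")
    control_params = dataclasses.replace(
        params, n_reads=config.n_control_reads, seed=seeds[5])
    control = synthetic_data.simulate_chip_reads(
        host, sites, control_params, control=True, read_prefix="c")

    contaminant_genomes = []
    for i, spec in enumerate(config.contaminants):
        g = synthetic_data.generate_genome(
            spec["length"], spec["gc"], 1, seed=seeds[6] + i,
            name=spec["name"], taxon_id=spec["taxon_id"])
        contaminant_genomes.append((g, spec["fraction"]))
    treatment = synthetic_data.mix_contaminants(
        treatment, contaminant_genomes, params, seed=seeds[7])
    log("simulate", n_treatment=len(treatment), n_control=len(control),
        n_sites=len(sites), n_divergent_sites=len(div_sites),
        n_contaminant_genomes=len(contaminant_genomes))

    if config.write_intermediates:
        io_formats.write_fasta(host.chromosomes, outdir / "host.fa")
        io_formats.write_fastq(treatment, outdir / "treatment.fastq")
        io_formats.write_fastq(control, outdir / "control.fastq")
        taxonomy.taxonomy_to_tsv(tree, outdir / "taxonomy.tsv")
        io_formats.write_gene_models(genes, outdir / "genes.gff")
        _sites_bed(sites, outdir / "sites_ordinary.bed")
        _sites_bed(div_sites, outdir / "sites_divergent.bed")

    # --- preprocess ------------------------------------------------------
    n_input = len(treatment)
    if config.adapter:
        treatment = io_formats.ReadSet(
            [io_formats.trim_adapter(r, config.adapter) for r in treatment],
            treatment.truth)
    treatment, n_filtered = io_formats.filter_by_quality(
        treatment, config.min_mean_quality, config.min_read_length)
    control, n_filtered_c = io_formats.filter_by_quality(
        control, config.min_mean_quality, config.min_read_length)
    log("preprocess", n_filtered_treatment=n_filtered,
        n_filtered_control=n_filtered_c)

    # --- primary (ungapped) alignment ------------------------------------
    index = align.build_index(host, config.seed_k)
    t_records = align.align_readset(treatment, index, config.max_mismatches)
    c_records = align.align_readset(control, index, config.max_mismatches)
    t_table = align.tabulate_records(t_records)
    c_table = align.tabulate_records(c_records)
    by_class: dict[str, list] = {align.UNIQUE: [], align.MULTI: [],
                                 align.UNALIGNED: []}
    for rec in t_records:
        by_class[rec.mapping_class].append(rec)
    unaligned_ids = [r.read_id for r in by_class[align.UNALIGNED]]
    unaligned_reads = treatment.subset(unaligned_ids)
    log("align_ungapped", **{f"n_{k}": getattr(t_table, f"n_{k}")
                             for k in ("unique", "multi", "unaligned")})
    if config.write_intermediates:
        io_formats.write_tsv(align.records_to_frame(t_records),
                             outdir / "alignments_treatment.tsv")

    # --- cluster the rejects ---------------------------------------------
    min_cluster_len = 2 * config.seed_k
    clusterable = io_formats.ReadSet(
        [r for r in unaligned_reads if len(r) >= min_cluster_len],
        {r.id: unaligned_reads.truth[r.id]
         for r in unaligned_reads if len(r) >= min_cluster_len}
        if unaligned_reads.truth else None)
    n_unclustered = len(unaligned_reads) - len(clusterable)
    clusters = cluster.greedy_cluster(clusterable, config.cluster_identity)
    log("cluster", n_clusters=len(clusters), n_unclustered=n_unclustered)

    # --- database search + LCA on cluster seeds --------------------------
    ref_db = taxonomy.ReferenceDatabase(
        [host] + [g for g, _ in contaminant_genomes], k=config.seed_k)
    seed_reads = {c.seed_id for c in clusters}
    seed_lookup = {r.id: r for r in clusterable if r.id in seed_reads}
    seed_taxa = {}
    for c in clusters:
        hits = taxonomy.search_database(
            seed_lookup[c.seed_id], ref_db, config.scheme,
            config.search_min_score_fraction, config.max_hits)
        assignment = taxonomy.lca_assign(hits, tree, config.score_window,
                                         read_id=c.seed_id)
        seed_taxa[c.seed_id] = assignment.taxon_id
    read_taxa = cluster.propagate_seed_labels(clusters, seed_taxa)
    partition = taxonomy.partition_legitimate(read_taxa, tree,
                                              config.host_taxon_id)
    breakdown_tables = {}
    for rank in ("kingdom", "species"):
        df = taxonomy.taxonomy_report(partition.breakdown, tree, rank)
        breakdown_tables[rank] = df.to_dict(orient="records")
        if config.write_intermediates:
            io_formats.write_tsv(df, outdir / f"taxonomy_{rank}.tsv")
    log("taxonomy", n_legitimate=len(partition.legitimate),
        n_contaminant=len(partition.contaminant),
        n_unassigned=len(partition.unassigned))

    # --- gapped realignment of legitimate rejects ------------------------
    legit_reads = clusterable.subset(partition.legitimate)
    r_records = align.realign_readset(
        legit_reads, index, config.scheme,
        seed_stride=config.seed_stride,
        min_seed_hits=config.realign_min_seed_hits)
    r_table = align.tabulate_records(r_records)
    recovered_unique = [r for r in r_records if r.mapping_class == align.UNIQUE]
    n_unaligned = t_table.n_unaligned
    recovery = {
        "n_unaligned": n_unaligned,
        "n_legitimate": len(partition.legitimate),
        "n_realigned": r_table.n_unique + r_table.n_multi,
        "n_realigned_unique": r_table.n_unique,
        "legitimate_fraction_of_unaligned":
            len(partition.legitimate) / n_unaligned if n_unaligned else 0.0,
        "realigned_fraction_of_legitimate":
            (r_table.n_unique + r_table.n_multi) / len(partition.legitimate)
            if partition.legitimate else 0.0,
        "recovery_rate":
            (r_table.n_unique + r_table.n_multi) / n_unaligned
            if n_unaligned else 0.0,
    }
    log("realign_gapped", **{k: v for k, v in recovery.items()})
    if config.write_intermediates:
        io_formats.write_tsv(align.records_to_frame(r_records),
                             outdir / "alignments_recovered.tsv")

    # --- peak calling -----------------------------------------------------
    peak_params = peaks.PeakCallParams(
        fragment_extension=config.fragment_extension,
        p_cutoff=config.p_cutoff, window=config.peak_window,
        min_peak_len=config.min_peak_len, merge_gap=config.merge_gap)
    c_unique = [r for r in c_records if r.mapping_class == align.UNIQUE]
    t_unique = by_class[align.UNIQUE]
    control_cov = peaks.coverage_pileup(c_unique, host,
                                        config.fragment_extension)
    ordinary_cov = peaks.coverage_pileup(t_unique, host,
                                         config.fragment_extension)
    recovered_cov = peaks.coverage_pileup(recovered_unique, host,
                                          config.fragment_extension)
    ordinary_peaks = peaks.call_peaks(ordinary_cov, control_cov, peak_params,
                                      len(t_unique), len(c_unique))
    # the recovered track reuses the ordinary control as its background
    recovered_peaks = peaks.call_peaks(recovered_cov, control_cov, peak_params,
                                       max(len(recovered_unique), 1),
                                       len(c_unique))
    overlap = peaks.intersect_peak_sets(ordinary_peaks, recovered_peaks)
    overlap_summary = {k: v for k, v in overlap.items() if k != "pairs"}
    log("call_peaks", n_ordinary=len(ordinary_peaks),
        n_recovered=len(recovered_peaks), **overlap_summary)

    # --- characterization -------------------------------------------------
    annotation = {}
    chrom_dist = {}
    low_complexity = {}
    for name, pset in (("ordinary", ordinary_peaks),
                       ("recovered", recovered_peaks)):
        annotation[name] = peaks.annotate_peaks(
            pset, genes, config.promoter_span, config.downstream_span)
        chrom_dist[name] = peaks.chrom_distribution(pset, host).to_dict(
            orient="records")
        low_complexity[name], _ = peaks.low_complexity_fraction(pset, host)
        if config.write_intermediates:
            io_formats.write_tsv(peaks.peaks_to_frame(pset),
                                 outdir / f"peaks_{name}.tsv")

    # --- truth-based evaluation (only possible on synthetic data) --------
    truth_eval = _truth_eval(sites, div_sites, ordinary_peaks, recovered_peaks,
                             treatment, partition, config)

    # --- ledger ----------------------------------------------------------
    ledger = {
        "n_input": n_input,
        "n_filtered_out": n_filtered,
        "n_unique": t_table.n_unique,
        "n_multi": t_table.n_multi,
        "n_unaligned": t_table.n_unaligned,
        "n_legitimate": len(partition.legitimate),
        "n_contaminant": len(partition.contaminant),
        "n_unassigned": len(partition.unassigned),
        "n_unclustered": n_unclustered,
        "alignment_balanced":
            n_input == n_filtered + t_table.n_total,
        "triage_balanced":
            t_table.n_unaligned == len(partition.legitimate)
            + len(partition.contaminant) + len(partition.unassigned)
            + n_unclustered,
    }
    assert ledger["alignment_balanced"] and ledger["triage_balanced"], ledger

    report = RescueReport(
        config=dataclasses.asdict(config) | {
            "contaminants": [dict(c) for c in config.contaminants]},
        ledger=ledger,
        mappability={
            "treatment": {"n_unique": t_table.n_unique,
                          "n_multi": t_table.n_multi,
                          "n_unaligned": t_table.n_unaligned,
                          **{f"p_{k}": v
                             for k, v in t_table.proportions.items()}},
            "control": {"n_unique": c_table.n_unique,
                        "n_multi": c_table.n_multi,
                        "n_unaligned": c_table.n_unaligned,
                        **{f"p_{k}": v
                           for k, v in c_table.proportions.items()}},
        },
        taxonomy_breakdown=breakdown_tables,
        recovery=recovery,
        overlap=overlap_summary,
        annotation=annotation,
        chrom_distribution=chrom_dist,
        low_complexity=low_complexity,
        truth_eval=truth_eval,
        ordinary_peaks=ordinary_peaks,
        recovered_peaks=recovered_peaks,
    )
    report._genes = genes  # gene models kept for figure rendering
    report.to_json(outdir / "report.json")
    log("done")
    log_fh.close()
    return report


def make_figures(report: RescueReport, outdir):
    """Render the report's figures with TSV twins (thin wrapper; see
    :mod:`readrescue.figures`)."""
    from .figures import make_figures as _make

    return _make(report, outdir)


def _sites_bed(sites, path):
    import pandas as pd

    rows = [{"chrom": s.chrom, "start": s.start, "end": s.end,
             "name": f"site_{i}", "score": s.strength, "strand": "."}
            for i, s in enumerate(sites)]
    io_formats.write_bed(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
        path)


def _site_hit_rate(sites, peak_list, tol: int = 150) -> float:
    """Fraction of sites with a peak summit within +-tol of the site."""
    if not len(sites):
        return 0.0
    hit = 0
    for s in sites:
        for pk in peak_list:
            if pk.chrom == s.chrom and abs(pk.summit - s.center) <= tol \
                    + (s.end - s.start) // 2:
                hit += 1
                break
    return hit / len(sites)


def _truth_eval(sites, div_sites, ordinary_peaks, recovered_peaks,
                treatment, partition, config) -> dict:
    true_contam = 0
    if treatment.truth:
        true_contam = sum(1 for t in treatment.truth.values()
                          if t.taxon_id != config.host_taxon_id)
    clustered_ids = (set(partition.legitimate) | set(partition.contaminant)
                     | set(partition.unassigned))
    contam_in_pool = est_contam = 0
    if treatment.truth:
        contam_in_pool = sum(
            1 for rid in clustered_ids
            if treatment.truth[rid].taxon_id != config.host_taxon_id)
        est_contam = len(partition.contaminant)
    return {
        "ordinary_site_hit_rate": _site_hit_rate(sites, ordinary_peaks),
        "divergent_site_hit_rate": _site_hit_rate(div_sites, recovered_peaks),
        "divergent_site_hit_rate_ordinary":
            _site_hit_rate(div_sites, ordinary_peaks),
        "true_contaminant_reads_total": true_contam,
        "true_contaminant_reads_in_triaged_pool": contam_in_pool,
        "estimated_contaminant_reads": est_contam,
        "contaminant_fraction_true":
            contam_in_pool / len(clustered_ids) if clustered_ids else 0.0,
        "contaminant_fraction_estimated":
            est_contam / len(clustered_ids) if clustered_ids else 0.0,
    }
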