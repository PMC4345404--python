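#!/usr/bin/env python
"""Generate the synthetic ChIP-Seq experiment used by the later analyses.

Writes the host genome, planted binding sites (ordinary + divergent),
treatment/control FASTQ with contamination, the toy taxonomy and gene
models under scratch/data/, plus a one-row summary of the simulated
conditions under results/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from readrescue import io_formats, synthetic_data as sd, taxonomy
from readrescue.pipeline import PipelineConfig, _sites_bed, _stage_seeds

OUT = Path("scratch/data")
RESULTS = Path("results")
SEED = 11


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = PipelineConfig(seed=SEED, host_length=200_000, host_chroms=3,
                         n_sites=24, n_divergent_sites=12, n_reads=24_000,
                         n_control_reads=16_000, n_genes=30,
                         # repeat-rich host so the read-length experiment has
                         # multi-reads to move
                         repeat_spec={"unit_len": 6, "copies": 80,
                                      "n_loci": 40})
    seeds = _stage_seeds(cfg.seed)
    host = sd.generate_genome(cfg.host_length, cfg.host_gc, cfg.host_chroms,
                              repeat_spec=cfg.repeat_spec, seed=seeds[0],
                              name="host", taxon_id=cfg.host_taxon_id)
    sites = sd.plant_binding_sites(host, cfg.motif, cfg.n_sites,
                                   cfg.site_min_gap, seed=seeds[1])
    div = sd.plant_binding_sites(host, cfg.motif, cfg.n_divergent_sites,
                                 cfg.site_min_gap, seed=seeds[2], avoid=sites)
    genes = sd.generate_gene_models(host, cfg.n_genes, seed=seeds[3])
    params = sd.SimulationParams(
        read_length=cfg.read_length, n_reads=cfg.n_reads,
        error_rate=cfg.error_rate, fragment_mean=cfg.fragment_mean,
        fragment_sd=cfg.fragment_sd, enrichment=cfg.enrichment,
        seed=seeds[4])
    treatment = sd.simulate_chip_reads(host, sites, params,
                                       divergent_sites=div)
    control = sd.simulate_chip_reads(
        host, sites,
        dataclasses.replace(params, n_reads=cfg.n_control_reads,
                            seed=seeds[5]),
        control=True, read_prefix="c")
    contams = []
    for i, spec in enumerate(cfg.contaminants):
        g = sd.generate_genome(spec["length"], spec["gc"], 1,
                               seed=seeds[6] + i, name=spec["name"],
                               taxon_id=spec["taxon_id"])
        contams.append((g, spec["fraction"]))
        io_formats.write_fasta(g.chromosomes, OUT / f"{spec['name']}.fa")
    treatment = sd.mix_contaminants(treatment, contams, params, seed=seeds[7])

    io_formats.write_fasta(host.chromosomes, OUT / "host.fa")
    io_formats.write_fastq(treatment, OUT / "treatment.fastq")
    io_formats.write_fastq(control, OUT / "control.fastq")
    io_formats.write_gene_models(genes, OUT / "genes.gff")
    _sites_bed(sites, OUT / "sites_ordinary.bed")
    _sites_bed(div, OUT / "sites_divergent.bed")
    taxonomy.taxonomy_to_tsv(sd.toy_taxonomy(), OUT / "taxonomy.tsv")
    cfg.to_yaml(OUT / "config.yaml")

    summary = pd.DataFrame([{
        "host_bp": host.total_length, "n_chroms": cfg.host_chroms,
        "n_sites": len(sites), "n_divergent_sites": len(div),
        "n_treatment_reads": len(treatment),
        "n_control_reads": len(control),
        "contaminant_fraction": sum(f for _, f in contams),
        "read_length": cfg.read_length, "error_rate": cfg.error_rate,
    }])
    io_formats.write_tsv(summary, RESULTS / "01_simulation_summary.tsv")
    print(summary.to_string(index=False))
    print(f"\nwrote experiment inputs to {OUT}/")


if __name__ == "__main__":
    main()
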