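#!/usr/bin/env python
"""Where do the unaligned reads come from?

Takes the treatment reads the ungapped aligner rejected, clusters them at
75% identity, searches each cluster seed against the labeled reference set,
assigns taxa by LCA, and partitions the pool into host-legitimate /
contaminant / unassigned.  Writes the rank rollups and the partition table.
Requires 01_simulate_data.py.
"""

from pathlib import Path

import pandas as pd

from readrescue import align, cluster, io_formats, taxonomy
from readrescue.synthetic_data import Genome

DATA = Path("scratch/data")
RESULTS = Path("results")
HOST_TAXON = "h_sapiens"


def main():
    host = Genome("host", HOST_TAXON, io_formats.read_fasta(DATA / "host.fa"))
    index = align.build_index(host, 12)
    treatment = io_formats.read_fastq(DATA / "treatment.fastq")
    tree = taxonomy.taxonomy_from_tsv(DATA / "taxonomy.tsv")
    contams = []
    for fa in sorted(DATA.glob("*.fa")):
        if fa.stem == "host":
            continue
        taxon = {"ecoli": "e_coli", "pacnes": "p_acnes",
                 "msilvanus": "m_silvanus"}.get(fa.stem, fa.stem)
        contams.append(Genome(fa.stem, taxon, io_formats.read_fasta(fa)))

    records = align.align_readset(treatment, index, 3)
    pool = treatment.subset([r.read_id for r in records if not r.aligned])
    print(f"{len(pool)} unaligned reads enter the triage")

    clusters = cluster.greedy_cluster(pool, threshold=0.75)
    print(f"{len(clusters)} clusters at 75% identity "
          f"(largest {max(len(c) for c in clusters)})")

    db = taxonomy.ReferenceDatabase([host] + contams)
    lookup = {r.id: r for r in pool}
    seed_taxa = {}
    for c in clusters:
        hits = taxonomy.search_database(lookup[c.seed_id], db)
        seed_taxa[c.seed_id] = taxonomy.lca_assign(
            hits, tree, read_id=c.seed_id).taxon_id
    labels = cluster.propagate_seed_labels(clusters, seed_taxa)
    part = taxonomy.partition_legitimate(labels, tree, HOST_TAXON)

    table = pd.DataFrame([{
        "n_unaligned": len(pool),
        "n_legitimate": len(part.legitimate),
        "n_contaminant": len(part.contaminant),
        "n_unassigned": len(part.unassigned),
        "legitimate_fraction": round(part.legitimate_fraction, 4),
    }])
    io_formats.write_tsv(table, RESULTS / "03_partition.tsv")
    print(table.to_string(index=False), "\n")

    for rank in ("kingdom", "species"):
        df = taxonomy.taxonomy_report(part.breakdown, tree, rank)
        io_formats.write_tsv(df, RESULTS / f"03_taxonomy_{rank}.tsv")
        print(f"-- {rank} rollup --")
        print(df.to_string(index=False), "\n")

    # the full per-read table is bulky; it lives with the raw run data
    pd.Series(labels, name="taxon_id").rename_axis("read_id") \
        .to_frame().reset_index() \
        .to_csv(DATA / "read_assignments.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
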