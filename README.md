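# readrescue

**Triage and rescue of unaligned ChIP-Seq reads.**

In a typical ChIP-Seq experiment a large fraction of reads — often around
40%, sometimes far more — fail to align to the reference genome and are
silently discarded before peak calling. Those rejects are not noise: part
of the pool is foreign DNA (bacterial and other-metazoan contamination
picked up during library preparation), and part is perfectly legitimate
host DNA that an ungapped, mismatch-bounded aligner cannot place because it
comes from polymorphic or indel-bearing regions. `readrescue` implements
the workflow that separates the two and turns the legitimate fraction back
into biology:

1. **Classify** reads as uniquely aligned / multi-mapped / unaligned with an
   ungapped aligner allowing ≤ 3 mismatches (best-stratum counting).
2. **Cluster** the unaligned pool greedily at 75% identity; each cluster is
   represented by its seed (centroid) read.
3. **Search** the seeds against a labeled multi-genome reference set with a
   gapped seed-and-extend Smith–Waterman aligner, and **assign taxa** by
   lowest common ancestor (LCA) of the near-top hits.
4. **Partition** reads into host-legitimate, contaminant and unassigned.
5. **Realign** the legitimate rejects with the gap-tolerant aligner and call
   **recovered peaks** (Poisson local-λ model, p < 0.005) alongside the
   ordinary peak set, then compare, annotate and characterize both.

Everything runs on synthetic data with recorded ground truth — genomes,
taxonomy, planted transcription-factor binding sites, contaminated read
sets — so the whole pipeline is testable end to end with no downloads.

## The models in brief

*Ungapped classification.* A read maps to a locus if it matches end-to-end
with at most *m* substitutions (*m* ≤ 3). Only placements at the minimal
mismatch count compete: exactly one ⇒ `unique`, several ⇒ `multi`, none ⇒
`unaligned`. Candidate loci come from an exact k-mer index via the
pigeonhole principle (*m*+1 disjoint seeds), with an exhaustive scan for
reads too short to seed, so results equal brute force by construction.

*Gapped rescue.* Candidate windows are anchored by k-mer seed hits and
scored with affine-gap Smith–Waterman (match +2, mismatch −3, gap open −5,
gap extend −2); an alignment is accepted when its score reaches 55% of the
maximum attainable. A 1-bp indel shifts every downstream base of a read, so
the ungapped aligner rejects such reads while local alignment absorbs the
gap — this asymmetry is the entire rescue margin.

*Peak calling.* Reads are extended to 200 bp fragments; non-overlapping
200 bp windows are tested with an exact Poisson upper tail against
λ_local = max(genome-wide background, 1/5/10-kb local control rates) scaled
to treatment depth; adjacent enriched windows are merged and a peak must
span ≥ 400 bp (two windows), which keeps the null clean at p < 0.005.

*Statistics.* Chi-square equality of proportions for mappability
comparisons, Welch's unequal-variance t-test for fold-enrichment tables,
and a decoy-based aligner ROC (sensitivity = reads placed within 5 bp of
their simulated origin; negatives are decoy-genome reads).

## Worked example

```python
from readrescue.pipeline import PipelineConfig, run_rescue_pipeline

report = run_rescue_pipeline(PipelineConfig(seed=1), "out/")
print(report.recovery)
```

With the default configuration (500 kb host genome, 75,000 treatment reads
of which 20% are bacterial contamination, 60 ordinary and 30
divergent-only binding sites) this prints:

```
{'n_unaligned': 31038, 'n_legitimate': 14339, 'n_realigned': 11088,
 'n_realigned_unique': 11088,
 'legitimate_fraction_of_unaligned': 0.462,
 'realigned_fraction_of_legitimate': 0.773,
 'recovery_rate': 0.357}
```

Reading: 41% of treatment reads failed the primary alignment; taxonomic
triage classifies 46% of those as host-legitimate (the rest is the planted
bacterial contamination, recovered essentially exactly — the report's
estimate is 0.4832 vs a true 0.4833); 77% of the legitimate rejects
realign with the gapped aligner, so 35.7% of all previously unaligned
reads are rescued. Peak calling on the rescued reads finds all 30
divergent-only sites as recovered peaks with zero overlap with the 60
ordinary peaks — new signal, not a re-discovery.

The same workflow is broken into narrative steps under `analysis/`
(`01_simulate_data.py` … `05_full_pipeline.py`), each writing its tables
under `results/`. The command-line interface wraps the same library:

```bash
readrescue run --outdir out --seed 1        # full pipeline + figures
readrescue simulate --outdir sim --seed 1   # just the synthetic inputs
```

## Layout

```
src/readrescue/     library: synthetic_data, io_formats, align, cluster,
                    taxonomy, peaks, stats, pipeline, figures, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. end-to-end acceptance properties
scripts/acceptance.py
docs/methods.md     model, assumptions, parameter choices, limitations
```
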