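# Methods

This note documents the models behind `readrescue`, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical conventions. Nothing here states a result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Coordinates and formats

All internal coordinates are 0-based, half-open. BED output keeps that
convention; GFF-lite is 1-based inclusive, converted exactly at the
boundary. FASTQ is Sanger (Phred+33); qualities are stored as the encoded
string so round-trips are byte-identical. Bases are coded A/C/G/T/N; code
N never matches anything, i.e. an N on either side of a comparison counts
as a mismatch — the simplest defensible rule for both aligners.

## Synthetic data generator

The generator defines the study conditions; every pipeline input is
produced with recorded ground truth.

**Genomes** are i.i.d. draws at a configurable GC fraction (host default
0.41, a metazoan-like value). `repeat_spec` plants perfect tandem repeats
(recorded in `Genome.repeat_loci`) as the only low-complexity structure; a
random 4-letter genome has essentially none otherwise.

**Fragment model.** Fragment length ~ Normal(200, 40) truncated to
[read_length, 600]. For a site-derived fragment the site center falls
uniformly within the fragment, so plus-strand 5′ ends sit upstream of the
summit and minus-strand ends downstream — the strand-asymmetric peak shape
that fragment-extension peak callers rely on. A fraction
enrichment/(enrichment+1) of treatment fragments is site-derived
(enrichment default 4, i.e. 80% of fragments at sites when sites exist);
input-control runs are entirely uniform background.

**Errors and qualities.** Per-base substitution errors at `error_rate`
(default 1%, substituting to a uniformly different base). Quality strings
are Phred 40 with a linear 3′ decay to 30 — enough to exercise the
mean-quality filter; no attempt to model real error/quality coupling.

**Two divergence models.** "Legitimate but unmappable" reads exist in two
forms, used for different experiments:

* *Per-read divergence* (`diverge_reads`): each base independently mutates
  at `divergence_rate` (default 5%), 90% substitutions / 10% 1-bp indels.
  Used for the aligner sensitivity/ROC analyses, where the quantity of
  interest is per-read recoverability.
* *Divergent sites* (pipeline simulation): the region around a
  divergent-only binding site (±2 fragment lengths) is rewritten once into
  a donor haplotype with substitutions at `divergent_sub_rate` (5%) and a
  1-bp indel every `divergent_indel_spacing` bases (default 25, random
  phase). With 50 bp reads and 25 bp spacing every read overlapping the
  region carries at least one interior indel, so the region is invisible
  to the ungapped aligner and reachable only through gapped realignment.
  A per-read model cannot give that guarantee (at 5% divergence roughly a
  third of 50 bp reads carry no indel and ≤ 3 substitutions and would
  align anyway), and the recovered-vs-ordinary disjointness property is
  exactly the point of the divergent-site simulation — hence the
  haplotype model. Truth coordinates for donor-derived reads are mapped
  back to the reference through the indel offsets.

**Contamination.** `mix_contaminants` draws a deterministic
round(fraction × total) reads per source genome (uniform loci, same error
model) and shuffles under the seed. Deterministic counts mean the
parameter-recovery tests measure classification error, not the generator's
own sampling noise. Contaminant abundances are free configuration, not
estimates of real laboratory contamination. Defaults: three bacterial
genomes at 10/5/5% of the treatment run.

**Determinism.** Every generator, and the pipeline as a whole, is
byte-reproducible under a fixed seed; pipeline stage seeds are spawned
from the config seed via `numpy.random.SeedSequence`.

## Ungapped aligner (primary classification)

End-to-end placement with at most `max_mismatches` (0–3) substitutions, no
gaps. Candidates come from an exact k-mer index (k = 12 default): a read
of length ≥ (m+1)·k is cut into m+1 disjoint seeds, and the pigeonhole
principle guarantees any placement with ≤ m mismatches contains one exact
seed, so the search is complete. Shorter reads fall back to an exhaustive
Hamming scan over both strands; either way results equal brute force (this
is tested against an independent window-comparison oracle). Uniqueness is
best-stratum: only placements with the minimal mismatch count compete;
ties make a read `multi`, and the reported record is the leftmost
best-stratum hit.

## Gapped realigner (rescue)

Seed-and-extend: k-mers sampled every 5 bases on both strands are looked
up in the index; hits projected to read-start coordinates are clustered
into candidate windows (anchors more than read_length/2 apart separate);
windows with ≥ 2 seed hits (≥ 1 for database search, where sensitivity on
short queries matters more than speed) are aligned with affine-gap
Smith–Waterman–Gotoh. Scoring defaults: match +2, mismatch −3, gap open −5
(first gap base), gap extend −2; acceptance at ≥ 55% of the maximal score
(match × read length). A second window within 5% of the best score marks
the read `multi` — the gapped analog of best-stratum tying; the 5% window
is our declared convention, not a value inherited from any external tool.
The DP kernels are numba-compiled; traceback reproduces the score exactly
(tested), and scores are checked against an independent plain-Python DP.

## Clustering

Greedy centroid clustering in input order (order-dependence is inherent to
single-pass greedy clustering; the order is therefore part of the
configuration and fixed). Identity = matched positions in an optimal
global alignment (match +1, mismatch −1, gap −1) divided by the shorter
length; among score-optimal alignments the one with the most matches is
counted (lexicographic DP), which makes the value symmetric and
independent of traceback order. The threshold defaults to 0.75. A 5-mer
profile prefilter skips seeds sharing < 20% of the read's distinct 5-mers;
it is a pure speed optimization, tested not to change the clustering, and
can be disabled. Random 50 bp pairs score ≈ 0.60 identity under this
metric, comfortably below the threshold, so unrelated reads do not merge.

## Taxonomic triage

Cluster seeds are searched against the packaged reference set (host +
contaminant genomes; never a remote database). One best hit per genome is
kept at ≥ 50% of the maximal score. Hits within 10% of the top score vote,
and the read is assigned their LCA on the taxonomy tree; the 10% window is
declared configuration. Members inherit their seed's assignment — the
pipeline counts individual reads, so all members are realigned, not only
seeds. Partition rule: assignments inside the host subtree are legitimate,
other below-root taxa are contaminant, and root-level LCAs are reported as
unassigned — a root assignment is uninformative and counting it either way
would inflate that class. The toy taxonomy holds the bacterial
contaminants, four metazoans and two plants under kingdom/family/species
ranks.

## Peak calling

Reads (uniquely aligned only, by default — multi-reads are reported but
unused, switchable in config) are extended to 200 bp fragments. The window
statistic is floor(coverage sum / extension) over non-overlapping 200 bp
windows — fragment-equivalents, slightly conservative versus a true
fragment count because boundary fragments contribute fractionally. The
null expectation is λ_local = max(λ_bg, λ_1k, λ_5k, λ_10k), all derived
from the control and scaled by treatment/control depth, so the test is
never anti-conservative; an empty control falls back to the treatment's
genome-wide rate with a warning. Windows with exact Poisson upper-tail
p < 0.005 are merged (gap ≤ 200 bp) and a merged region must span
≥ 400 bp — two independent windows — so an isolated single-window
fluctuation is never reported. That design choice is what lets a raw
p < 0.005 cutoff (no multiple-testing correction by default; a
Benjamini–Hochberg flag exists) coexist with a clean null: planted sites
at ≥ 30× coverage span several windows and always qualify, while the
zero-enrichment null yields zero peaks in the acceptance tests. Summit =
leftmost argmax of treatment coverage inside the region. Duplicate
fragments are kept.

The recovered-peak track is called against the *ordinary* control
coverage rather than a separately rescued control: the control is
genome-wide background either way, and this halves the pipeline cost; the
choice is recorded in the run report.

## Peak characterization

Annotation assigns each peak one category by summit position with
precedence 5′UTR > 3′UTR > exon > intron > promoter (strand-aware 3 kb
upstream of the TSS) > downstream (3 kb past the gene) > intergenic.
TSS density is a Gaussian kernel (bandwidth 300 bp) over signed,
strand-aware summit→nearest-TSS distances within ±5 kb, renormalized to
integrate to 1 on the window. Low complexity uses a DUST-style score on
64 bp windows — Σ c_t(c_t−1)/2 over triplet counts, divided by
(window−3) — flagged above 2.0; a peak is low-complexity when flagged
windows merge into a run of ≥ 30 bp. Random sequence scores ≈ 0.008 and
is flagged < 5% of the time (measured in the tests); a perfect
dinucleotide repeat scores ≈ 8.

## Statistics

Chi-square equality of proportions is the Pearson statistic on the
groups × {success, failure} table with df = groups − 1 (no continuity
correction; expected cells < 1 raise a flag). Welch's t uses the
Satterthwaite df; p-values are two-sided by default. The aligner ROC
defines its negative class explicitly — the usual "specificity of an
aligner" is ill-posed, so the simulation includes decoy-genome reads:
TN = decoy reads left unaligned, FP = decoy reads aligned anywhere plus
host reads placed > 5 bp from their true locus (strand required). The
5 bp tolerance matches common read-simulator evaluation practice.

## Problem sizes

Defaults were chosen so a full pipeline run (500 kb host over 4
chromosomes, 75,000 treatment + 40,000 control reads, 3 contaminant
genomes, 90 planted sites) completes in well under a minute on one CPU,
and the entire test suite — including five-seed acceptance sweeps at
n = 10,000–20,000 reads per run — in a few minutes. These sizes are the
package's own scaling of the workflow to desk scale; the algorithms are
size-independent and the config exposes every dimension.

## What passing tests do and do not show

The synthetic data has i.i.d. genome composition, uniform fragment
sampling, position-independent errors, no PCR duplicates, no paired ends,
single-transcript gene models and perfectly labeled references. Passing
the acceptance suite therefore demonstrates internal correctness of the
algorithms and calibration of the statistics under the stated models —
not performance on real libraries, where repeat structure, GC bias,
duplicated fragments and incomplete reference databases all bite. The
contamination fractions recovered exactly here would be blurred on real
data by database incompleteness and horizontal sequence similarity.

## Known limitations

* Adapter trimming is exact-match suffix/prefix only.
* The ungapped aligner caps mismatches at 3 by design (matching the
  classification experiment it reproduces).
* Database search reports one hit per genome (the best), so within-genome
  paralogy does not produce multiple votes.
* The low-complexity detector finds compositional bias only; it is not a
  repeat-family annotator.
* `identity`'s fast path packs (score, matches) into one integer for
  sequences < 128 bp; longer sequences use the reference two-matrix DP.
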