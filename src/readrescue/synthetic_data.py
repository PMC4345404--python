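"""Synthetic inputs for the unaligned-read rescue pipeline.

Everything the pipeline consumes is generated here with recorded ground
truth: host genomes with planted transcription-factor binding sites,
ChIP/input read sets with strand-asymmetric fragment placement, contaminant
read admixtures drawn from foreign genomes on a toy taxonomy, and
wgsim-style whole-genome reads for aligner benchmarking.

Two divergence models coexist (both produce "legitimate but unmappable"
reads, i.e. reads an ungapped mismatch-bounded aligner rejects but a gapped
aligner places):

* :func:`diverge_reads` applies per-read divergence — 90% substitutions,
  10% 1-bp indels at a configurable per-base rate.  Used for the aligner
  sensitivity/ROC experiments.
* "divergent sites" in :func:`simulate_chip_reads` are modelled as
  polymorphic donor haplotype regions: substitutions plus a 1-bp indel
  every ``divergent_indel_spacing`` bases applied once to the region, so
  *every* read spanning the region carries indels and the region is
  reachable only through gapped realignment.

All generators are deterministic under a fixed seed (byte-identical
output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, revcomp
from .errors import InvalidParameterError, PlacementError
from .io_formats import GeneModel, Read, ReadSet, ReadTruth
from .taxonomy import TaxonomyTree, build_taxonomy

__all__ = [
    "Genome", "Site", "SiteSet", "SimulationParams",
    "generate_genome", "plant_binding_sites", "simulate_chip_reads",
    "mix_contaminants", "simulate_wgs_reads", "diverge_reads",
    "generate_gene_models", "toy_taxonomy", "build_taxonomy",
]


@dataclass
class Genome:
    """A named reference genome: ordered chromosome name -> ACGT sequence."""

    name: str
    taxon_id: str
    chromosomes: dict[str, str]
    repeat_loci: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.chromosomes:
            raise InvalidParameterError("genome needs at least one chromosome")
        for chrom, seq in self.chromosomes.items():
            if not seq:
                raise InvalidParameterError(f"chromosome {chrom!r} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][start:end]


@dataclass(frozen=True)
class Site:
    chrom: str
    start: int
    end: int
    strength: float = 1.0

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SiteSet:
    """Planted binding sites; non-overlapping, within chromosome bounds."""

    sites: list[Site] = field(default_factory=list)

    def __len__(self):
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


@dataclass
class SimulationParams:
    """Knobs of the read simulator.

    ``enrichment`` is the ratio of site-derived to background fragments in
    treatment mode; ``divergence_rate`` is the per-base rate of the per-read
    divergence model (90% substitutions / 10% 1-bp indels);
    ``divergent_sub_rate``/``divergent_indel_spacing`` parameterize the
    polymorphic-haplotype model for divergent sites."""

    read_length: int = 50
    n_reads: int = 10_000
    error_rate: float = 0.01
    fragment_mean: float = 200.0
    fragment_sd: float = 40.0
    enrichment: float = 9.0
    divergence_rate: float = 0.05
    divergent_sub_rate: float = 0.05
    divergent_indel_spacing: int = 25
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "divergence_rate", "divergent_sub_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 20:
            raise InvalidParameterError("read_length must be >= 20 bp")
        if self.n_reads < 0:
            raise InvalidParameterError("n_reads must be >= 0")
        if self.enrichment < 0:
            raise InvalidParameterError("enrichment must be >= 0")
        if self.fragment_mean < self.read_length:
            raise InvalidParameterError("fragment_mean must be >= read_length")


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def generate_genome(
    length: int,
    gc_fraction: float = 0.41,
    n_chroms: int = 1,
    repeat_spec: dict | None = None,
    seed: int = 0,
    name: str = "synth",
    taxon_id: str = "synth",
) -> Genome:
    """Random genome of ``length`` bp at the requested GC fraction.

    ``repeat_spec`` = {"unit_len", "copies", "n_loci"} plants tandem
    low-complexity repeat loci whose coordinates are recorded in
    ``Genome.repeat_loci``."""
    if length <= 0 or length < n_chroms:
        raise InvalidParameterError("genome length must be positive and >= n_chroms")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidParameterError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ])
    base = length // n_chroms
    sizes = [base + (length - base * n_chroms if i == 0 else 0) for i in range(n_chroms)]
    chroms = {}
    for i, size in enumerate(sizes):
        codes = rng.choice(4, size=size, p=p)
        chroms[f"chr{i + 1}"] = "".join(BASES[c] for c in codes) if size < 1000 else \
            np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
    genome = Genome(name, taxon_id, chroms)
    if repeat_spec:
        unit_len = int(repeat_spec["unit_len"])
        copies = int(repeat_spec["copies"])
        n_loci = int(repeat_spec["n_loci"])
        rep_len = unit_len * copies
        placed: list[tuple[str, int, int]] = []
        attempts = 0
        while len(placed) < n_loci:
            attempts += 1
            if attempts > 200 * max(n_loci, 1):
                raise PlacementError("could not place repeat loci without overlap")
            chrom = rng.choice(list(chroms))
            clen = len(genome.chromosomes[chrom])
            if clen <= rep_len:
                continue
            start = int(rng.integers(0, clen - rep_len))
            if any(c == chrom and start < e and start + rep_len > s
                   for c, s, e in placed):
                continue
            unit = "".join(BASES[c] for c in rng.integers(0, 4, size=unit_len))
            seq = genome.chromosomes[chrom]
            genome.chromosomes[chrom] = (
                seq[:start] + unit * copies + seq[start + rep_len:]
            )
            placed.append((chrom, start, start + rep_len))
        genome.repeat_loci = sorted(placed)
    return genome


def plant_binding_sites(
    genome: Genome,
    motif: str,
    n_sites: int,
    min_gap: int = 500,
    seed: int = 0,
    strength: float = 1.0,
    avoid: SiteSet | None = None,
) -> SiteSet:
    """Write ``motif`` into the genome at ``n_sites`` random non-overlapping
    loci separated by at least ``min_gap`` bp.  Mutates ``genome`` in place
    and returns the planted SiteSet.  ``avoid`` adds existing sites to the
    spacing constraint (so a second planted set keeps its distance)."""
    if n_sites == 0:
        return SiteSet([])
    mlen = len(motif)
    if any(mlen >= len(s) for s in genome.chromosomes.values()):
        raise InvalidParameterError("motif must be shorter than every chromosome")
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_names], float)
    weights = lengths / lengths.sum()
    existing = list(avoid.sites) if avoid is not None else []
    placed: list[Site] = []
    attempts = 0
    # keep min_gap clearance from chromosome ends too, so fragments fit
    while len(placed) < n_sites:
        attempts += 1
        if attempts > 500 * n_sites:
            raise PlacementError(
                f"could not place {n_sites} sites with min_gap={min_gap}"
            )
        ci = rng.choice(len(chrom_names), p=weights)
        chrom = chrom_names[ci]
        clen = int(lengths[ci])
        if clen < mlen + 2 * min_gap:
            continue
        start = int(rng.integers(min_gap, clen - mlen - min_gap))
        ok = all(
            s.chrom != chrom or abs(start - s.start) >= min_gap + mlen
            for s in placed + existing
        )
        if not ok:
            continue
        seq = genome.chromosomes[chrom]
        genome.chromosomes[chrom] = seq[:start] + motif + seq[start + mlen:]
        placed.append(Site(chrom, start, start + mlen, strength))
    placed.sort(key=lambda s: (s.chrom, s.start))
    return SiteSet(placed)


# ---------------------------------------------------------------------------
# Divergent (polymorphic) haplotype regions
# ---------------------------------------------------------------------------

@dataclass
class _DonorRegion:
    chrom: str
    ref_start: int
    ref_end: int
    seq: str                 # donor haplotype sequence of the region
    ref_map: np.ndarray      # donor position -> reference position


def _build_donor_region(
    genome: Genome, chrom: str, ref_start: int, ref_end: int,
    sub_rate: float, indel_spacing: int, rng: np.random.Generator,
) -> _DonorRegion:
    ref = genome.chromosomes[chrom][ref_start:ref_end]
    n = len(ref)
    subs = rng.random(n) < sub_rate
    phase = int(rng.integers(0, max(indel_spacing, 1)))
    indel_pos = set(range(phase, n, indel_spacing)) if indel_spacing > 0 else set()
    out: list[str] = []
    ref_map: list[int] = []
    for i, base in enumerate(ref):
        if i in indel_pos:
            if rng.random() < 0.5:
                continue  # 1-bp deletion
            out.append(BASES[int(rng.integers(0, 4))])  # 1-bp insertion
            ref_map.append(ref_start + i)
        b = base
        if subs[i]:
            b = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
        out.append(b)
        ref_map.append(ref_start + i)
    return _DonorRegion(chrom, ref_start, ref_end, "".join(out),
                        np.array(ref_map, dtype=np.int64))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _quality_string(read_length: int) -> str:
    """Flat Phred 40 with a linear 3' decay to 30 (Sanger encoding)."""
    if read_length == 1:
        return chr(40 + 33)
    q = 40 - np.round(10 * np.arange(read_length) / (read_length - 1)).astype(int)
    return "".join(chr(int(v) + 33) for v in q)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        cur = out[i]
        if cur in BASES:
            out[i] = BASES[(BASES.index(cur) + int(rng.integers(1, 4))) % 4]
        else:
            out[i] = BASES[int(rng.integers(0, 4))]
    return "".join(out)


def _truncnorm_fragment(params: SimulationParams, rng) -> int:
    lo = params.read_length
    hi = int(3 * params.fragment_mean)
    f = rng.normal(params.fragment_mean, params.fragment_sd)
    return int(min(max(f, lo), hi))


def simulate_chip_reads(
    genome: Genome,
    sites: SiteSet,
    params: SimulationParams,
    control: bool = False,
    divergent_sites: SiteSet | None = None,
    read_prefix: str | None = None,
) -> ReadSet:
    """Single-end ChIP (or input-control) reads from ``genome``.

    Treatment mode: a fraction enrichment/(enrichment+1) of fragments is
    site-derived — the site center falls uniformly within the fragment, so
    plus- and minus-strand reads flank the summit from opposite sides — and
    the rest is uniform background.  Control mode is all background.

    Fragments over ``divergent_sites`` are cut from a polymorphic donor
    haplotype of the surrounding region (built once per site); their truth
    coordinates are mapped back to the reference.
    """
    L = params.read_length
    rng = np.random.default_rng(params.seed)
    enrich_frac = 0.0 if control else params.enrichment / (params.enrichment + 1.0)
    all_sites = list(sites) + (list(divergent_sites) if divergent_sites else [])
    if not control and params.enrichment > 0 and not all_sites:
        raise InvalidParameterError(
            "treatment simulation with enrichment > 0 needs at least one site"
        )
    divergent_flags = [False] * len(sites) + (
        [True] * len(divergent_sites) if divergent_sites else []
    )
    donors: dict[int, _DonorRegion] = {}
    pad = int(2 * params.fragment_mean)
    for idx, site in enumerate(all_sites):
        if divergent_flags[idx]:
            clen = len(genome.chromosomes[site.chrom])
            donors[idx] = _build_donor_region(
                genome, site.chrom,
                max(0, site.start - pad), min(clen, site.end + pad),
                params.divergent_sub_rate, params.divergent_indel_spacing, rng,
            )
    strengths = np.array([s.strength for s in all_sites], float)
    site_p = strengths / strengths.sum() if all_sites else None

    chrom_names = list(genome.chromosomes)
    clens = np.array([len(genome.chromosomes[c]) for c in chrom_names], float)
    chrom_p = clens / clens.sum()
    qual = _quality_string(L)
    prefix = read_prefix or ("c" if control else "t")

    reads: list[Read] = []
    truth: dict[str, ReadTruth] = {}
    for i in range(params.n_reads):
        rid = f"{prefix}{i}"
        strand = "+" if rng.random() < 0.5 else "-"
        if all_sites and rng.random() < enrich_frac:
            idx = int(rng.choice(len(all_sites), p=site_p))
            site = all_sites[idx]
            frag = _truncnorm_fragment(params, rng)
            offset = int(rng.integers(0, frag))  # site center within fragment
            if idx in donors:
                donor = donors[idx]
                dcenter = int(np.searchsorted(donor.ref_map, site.center))
                fs = dcenter - offset
                fs = min(max(fs, 0), len(donor.seq) - frag) if len(donor.seq) >= frag else 0
                fe = min(fs + frag, len(donor.seq))
                if strand == "+":
                    seq = donor.seq[fs:fs + L]
                    tstart = int(donor.ref_map[fs])
                else:
                    seq = revcomp(donor.seq[fe - L:fe])
                    tstart = int(donor.ref_map[fe - L])
                chrom = donor.chrom
            else:
                chrom = site.chrom
                clen = len(genome.chromosomes[chrom])
                fs = site.center - offset
                fs = min(max(fs, 0), clen - frag)
                fe = fs + frag
                if strand == "+":
                    seq = genome.chromosomes[chrom][fs:fs + L]
                    tstart = fs
                else:
                    seq = revcomp(genome.chromosomes[chrom][fe - L:fe])
                    tstart = fe - L
        else:
            ci = int(rng.choice(len(chrom_names), p=chrom_p))
            chrom = chrom_names[ci]
            clen = int(clens[ci])
            tstart = int(rng.integers(0, clen - L + 1))
            raw = genome.chromosomes[chrom][tstart:tstart + L]
            seq = raw if strand == "+" else revcomp(raw)
        seq = _apply_errors(seq, params.error_rate, rng)
        reads.append(Read(rid, seq, qual))
        truth[rid] = ReadTruth(genome.taxon_id, chrom, tstart, strand)
    return ReadSet(reads, truth)


def simulate_wgs_reads(
    genome: Genome,
    n_reads: int,
    read_length: int,
    error_rate: float = 0.0,
    mutation_rate: float = 0.0,
    seed: int = 0,
    read_prefix: str = "w",
) -> ReadSet:
    """wgsim-style whole-genome shotgun reads: uniform start positions and
    strands; haplotype substitutions at ``mutation_rate`` plus sequencing
    errors at ``error_rate``; truth records the (chrom, start, strand) of
    every read."""
    if any(read_length > len(s) for s in genome.chromosomes.values()):
        raise InvalidParameterError("read_length exceeds a chromosome length")
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chromosomes)
    clens = np.array([len(genome.chromosomes[c]) for c in chrom_names], float)
    chrom_p = clens / clens.sum()
    qual = _quality_string(read_length)
    reads, truth = [], {}
    for i in range(n_reads):
        ci = int(rng.choice(len(chrom_names), p=chrom_p))
        chrom = chrom_names[ci]
        start = int(rng.integers(0, int(clens[ci]) - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        raw = genome.chromosomes[chrom][start:start + read_length]
        seq = raw if strand == "+" else revcomp(raw)
        seq = _apply_errors(seq, mutation_rate, rng)
        seq = _apply_errors(seq, error_rate, rng)
        rid = f"{read_prefix}{i}"
        reads.append(Read(rid, seq, qual))
        truth[rid] = ReadTruth(genome.taxon_id, chrom, start, strand)
    return ReadSet(reads, truth)


def diverge_reads(
    readset: ReadSet, divergence_rate: float, seed: int = 0,
    sub_fraction: float = 0.9,
) -> ReadSet:
    """Per-read divergence model: events at ``divergence_rate`` per base,
    ``sub_fraction`` of them substitutions and the rest 1-bp indels
    (insertion/deletion equiprobable).  Truth records keep the original
    locus — these are "legitimate but polymorphic" reads."""
    if not 0 <= divergence_rate <= 1:
        raise InvalidParameterError("divergence_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for r in readset:
        chars = []
        for base in r.sequence:
            if rng.random() < divergence_rate:
                u = rng.random()
                if u < sub_fraction:  # substitution
                    if base in BASES:
                        chars.append(BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4])
                    else:
                        chars.append(base)
                elif u < sub_fraction + (1 - sub_fraction) / 2:  # deletion
                    continue
                else:  # insertion before the base
                    chars.append(BASES[int(rng.integers(0, 4))])
                    chars.append(base)
            else:
                chars.append(base)
        seq = "".join(chars)
        n = len(seq)
        qual = r.quality[:n] if n <= len(r.quality) else (
            r.quality + r.quality[-1] * (n - len(r.quality))
        )
        out.append(Read(r.id, seq, qual))
    truth = dict(readset.truth) if readset.truth is not None else None
    return ReadSet(out, truth)


def mix_contaminants(
    host_reads: ReadSet,
    contaminant_sources: list[tuple[Genome, float]],
    params: SimulationParams,
    seed: int = 0,
) -> ReadSet:
    """Spike contaminant reads into a host read set.

    Each source genome contributes its configured fraction of the *final*
    total (counts are deterministic: round(fraction x total)); reads are
    uniform draws from the source with the same read length/error model.
    Output order is a seeded shuffle; no host read is lost or duplicated.
    """
    fracs = [f for _, f in contaminant_sources]
    if any(f < 0 for f in fracs) or sum(fracs) >= 1.0:
        raise InvalidParameterError(
            "contaminant fractions must be >= 0 and sum to < 1"
        )
    n_host = len(host_reads)
    total = n_host / (1.0 - sum(fracs)) if fracs else n_host
    rng = np.random.default_rng(seed)
    reads = list(host_reads.reads)
    truth = dict(host_reads.truth) if host_reads.truth is not None else {}
    for src_i, (src_genome, frac) in enumerate(contaminant_sources):
        n_c = int(round(frac * total))
        sub = simulate_wgs_reads(
            src_genome, n_c, params.read_length, params.error_rate,
            seed=int(rng.integers(0, 2**31)),
            read_prefix=f"x{src_i}_{src_genome.name}_",
        )
        reads.extend(sub.reads)
        truth.update(sub.truth)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return ReadSet(reads, truth if host_reads.truth is not None else None)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def generate_gene_models(
    genome: Genome, n_genes: int, seed: int = 0,
    gene_len_range: tuple[int, int] = (1500, 4000),
    utr_len: int = 150,
) -> list[GeneModel]:
    """Random non-overlapping single-transcript gene models over the genome,
    with 1-4 exons and terminal UTRs; used by the peak annotation and TSS
    density analyses."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 500 * max(n_genes, 1):
            break  # best effort: genome too small for the request
        chrom = list(genome.chromosomes)[int(rng.integers(0, len(genome.chromosomes)))]
        clen = len(genome.chromosomes[chrom])
        glen = int(rng.integers(*gene_len_range))
        if clen < glen + 2:
            continue
        start = int(rng.integers(0, clen - glen))
        end = start + glen
        if any(start < e and end > s for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        # carve the span into alternating equal exons/introns, exons >= 2*utr_len
        min_exon = 2 * utr_len
        if glen < n_exons * min_exon + (n_exons - 1) * 100:
            n_exons = 1
        intron_total = glen - n_exons * min_exon
        intron = intron_total // n_exons if n_exons > 1 else 0
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append((pos, pos + min_exon))
            pos += min_exon + intron
        exons[-1] = (exons[-1][0], end)
        tss = start if strand == "+" else end - 1
        first, last = exons[0], exons[-1]
        if strand == "+":
            utr5 = ((first[0], first[0] + utr_len),)
            utr3 = ((last[1] - utr_len, last[1]),)
        else:
            utr5 = ((last[1] - utr_len, last[1]),)
            utr3 = ((first[0], first[0] + utr_len),)
        genes.append(GeneModel(f"gene{len(genes) + 1}", chrom, strand, tss,
                               tuple(exons), utr5, utr3))
        occupied[chrom].append((start, end))
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes


# ---------------------------------------------------------------------------
# Toy taxonomy
# ---------------------------------------------------------------------------

TOY_TAXONOMY_EDGES: list[tuple[str, str | None, str, str]] = [
    ("root", None, "no rank", "root"),
    ("bacteria", "root", "kingdom", "Bacteria"),
    ("enterobacteriaceae", "bacteria", "family", "Enterobacteriaceae"),
    ("e_coli", "enterobacteriaceae", "species", "Escherichia coli"),
    ("entero_sp", "enterobacteriaceae", "species", "Enterobacteriaceae sp."),
    ("p_acnes", "bacteria", "species", "Propionibacterium acnes"),
    ("m_silvanus", "bacteria", "species", "Meiothermus silvanus"),
    ("metazoa", "root", "kingdom", "Metazoa"),
    ("h_sapiens", "metazoa", "species", "Homo sapiens"),
    ("m_musculus", "metazoa", "species", "Mus musculus"),
    ("d_melanogaster", "metazoa", "species", "Drosophila melanogaster"),
    ("c_elegans", "metazoa", "species", "Caenorhabditis elegans"),
    ("plantae", "root", "kingdom", "Plantae"),
    ("a_thaliana", "plantae", "species", "Arabidopsis thaliana"),
    ("z_mays", "plantae", "species", "Zea mays"),
]


def toy_taxonomy() -> TaxonomyTree:
    """The packaged toy taxonomy: bacterial contaminant species, metazoan
    hosts and plants under a shared root."""
    return build_taxonomy(TOY_TAXONOMY_EDGES)
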