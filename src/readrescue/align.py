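"""Two short-read aligners and the mappability experiments.

* :func:`align_ungapped` — end-to-end, mismatch-bounded, no gaps; classifies
  each read as unique / multi / unaligned by best-stratum counting (only
  placements with the minimal mismatch count compete).  This is the primary
  aligner whose rejects feed the rescue branch.
* :func:`realign_gapped` — seed-and-extend Smith-Waterman with affine gaps;
  tolerant of substitutions *and* indels, it is the rescue aligner for
  "legitimate but polymorphic" reads.

Candidate placements come from an exact k-mer :class:`SeedIndex`; for the
ungapped aligner the pigeonhole rule (max_mismatches+1 disjoint seeds)
guarantees completeness when the read is long enough, and an exhaustive
Hamming scan takes over when it is not, so results always equal brute
force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from ._seq import encode, revcomp_codes
from .errors import InvalidParameterError
from .io_formats import Read, ReadSet

UNALIGNED = "unaligned"
UNIQUE = "unique"
MULTI = "multi"


@dataclass(frozen=True)
class AlignmentRecord:
    """Placement of a read on a genome (0-based half-open), or the explicit
    absence of one (mapping_class == 'unaligned', no coordinates)."""

    read_id: str
    chrom: str | None
    start: int | None
    end: int | None
    strand: str | None
    mismatches: int
    gaps: int
    score: int
    mapping_class: str

    @property
    def aligned(self) -> bool:
        return self.mapping_class != UNALIGNED


def unaligned_record(read_id: str) -> AlignmentRecord:
    return AlignmentRecord(read_id, None, None, None, None, 0, 0, 0, UNALIGNED)


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap local alignment scores.  ``gap_open`` is the score of the
    first base of a gap, ``gap_extend`` of each further base.
    ``min_score_fraction`` is the acceptance threshold as a fraction of the
    maximum attainable score (match x read length)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score_fraction: float = 0.55

    def __post_init__(self):
        if self.match <= 0 or self.mismatch >= 0:
            raise InvalidParameterError("need match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise InvalidParameterError("gap penalties must be negative")
        if not 0 <= self.min_score_fraction <= 1:
            raise InvalidParameterError("min_score_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Seed index
# ---------------------------------------------------------------------------

@dataclass
class SeedIndex:
    """Exact k-mer index over a genome (plus strand); minus-strand queries go
    through the reverse complement.  Chromosomes are concatenated; ``bounds``
    delimits them so no k-mer or placement straddles two."""

    k: int
    genome_name: str
    chrom_names: list[str]
    bounds: np.ndarray          # int64, len n_chroms + 1
    codes: np.ndarray           # uint8 concatenated genome
    _kmer_sorted: np.ndarray = field(repr=False)
    _pos_sorted: np.ndarray = field(repr=False)
    _powers: np.ndarray = field(repr=False)

    def locate(self, gpos: int) -> tuple[str, int]:
        """Global position -> (chrom name, local position)."""
        ci = int(np.searchsorted(self.bounds, gpos, side="right")) - 1
        return self.chrom_names[ci], gpos - int(self.bounds[ci])

    def chrom_span(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.bounds, gpos, side="right")) - 1
        return int(self.bounds[ci]), int(self.bounds[ci + 1])

    def lookup_value(self, val: int) -> np.ndarray:
        lo = int(np.searchsorted(self._kmer_sorted, val, side="left"))
        hi = int(np.searchsorted(self._kmer_sorted, val, side="right"))
        return self._pos_sorted[lo:hi]

    def hits(self, kmer: str) -> list[tuple[str, int, str]]:
        """All genomic occurrences of ``kmer`` on both strands, as
        (chrom, plus-strand start of the covered span, strand)."""
        if len(kmer) != self.k:
            raise InvalidParameterError(f"query must be length k={self.k}")
        fwd = encode(kmer)
        out = []
        for strand, codes in (("+", fwd), ("-", revcomp_codes(fwd))):
            if codes.max() > 3:
                continue
            val = int(codes.astype(np.int64) @ self._powers)
            for p in self.lookup_value(val):
                chrom, local = self.locate(int(p))
                out.append((chrom, local, strand))
        return sorted(out)


def build_index(genome, k: int = 12) -> SeedIndex:
    """Index every genomic k-mer of both strands (minus strand implicitly,
    via reverse-complement lookup)."""
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    lengths = [len(s) for s in genome.chromosomes.values()]
    if k > min(lengths):
        raise InvalidParameterError("k exceeds the shortest chromosome")
    names = list(genome.chromosomes)
    bounds = np.zeros(len(names) + 1, dtype=np.int64)
    bounds[1:] = np.cumsum(lengths)
    codes = np.empty(int(bounds[-1]), dtype=np.uint8)
    for i, name in enumerate(names):
        codes[bounds[i]:bounds[i + 1]] = encode(genome.chromosomes[name])
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    vals = windows.astype(np.int64) @ powers
    valid = windows.max(axis=1) <= 3
    # mask k-mers that straddle chromosome boundaries
    for b in bounds[1:-1]:
        valid[max(0, b - k + 1):b] = False
    positions = np.flatnonzero(valid)
    vals = vals[positions]
    order = np.argsort(vals, kind="stable")
    return SeedIndex(k, genome.name, names, bounds, codes,
                     vals[order], positions[order], powers)


# ---------------------------------------------------------------------------
# Ungapped aligner
# ---------------------------------------------------------------------------

def _placements_ungapped(codes_fwd, codes_rev, index: SeedIndex, max_mm: int):
    """All end-to-end placements with <= max_mm mismatches, as a list of
    (global start, strand, mm).  Uses pigeonhole seeding when the read is
    long enough for completeness, exhaustive scan otherwise."""
    L = codes_fwd.shape[0]
    k = index.k
    results: dict[tuple[int, str], int] = {}
    if L >= (max_mm + 1) * k:
        for strand, codes in (("+", codes_fwd), ("-", codes_rev)):
            codes64 = codes.astype(np.int64)
            seen_starts = set()
            for seg in range(max_mm + 1):
                off = seg * k
                window = codes[off:off + k]
                if window.max() > 3:
                    continue
                val = int(codes64[off:off + k] @ index._powers)
                for p in index.lookup_value(val):
                    start = int(p) - off
                    if start in seen_starts:
                        continue
                    seen_starts.add(start)
                    lo, hi = index.chrom_span(int(p))
                    if start < lo or start + L > hi:
                        continue
                    mm = int(_kernels.count_mismatches(index.codes, start, codes))
                    if mm <= max_mm:
                        results[(start, strand)] = mm
    else:
        for strand, codes in (("+", codes_fwd), ("-", codes_rev)):
            pos, mms = _kernels.hamming_hits(index.codes, index.bounds, codes,
                                             max_mm)
            for p, mm in zip(pos, mms):
                results[(int(p), strand)] = int(mm)
    return [(s, strand, mm) for (s, strand), mm in results.items()]


def align_ungapped(read: Read, index: SeedIndex, max_mismatches: int = 3
                   ) -> AlignmentRecord:
    """Best-stratum ungapped alignment of one read.

    mapping_class: 'unique' if exactly one placement at the minimal mismatch
    count, 'multi' if several, 'unaligned' if none; the reported coordinates
    are the best-stratum hit (leftmost on ties)."""
    if not 0 <= max_mismatches <= 3:
        raise InvalidParameterError("max_mismatches must be in 0..3")
    codes = encode(read.sequence)
    placements = _placements_ungapped(codes, revcomp_codes(codes), index,
                                      max_mismatches)
    if not placements:
        return unaligned_record(read.id)
    best_mm = min(p[2] for p in placements)
    best = sorted(p for p in placements if p[2] == best_mm)
    cls = UNIQUE if len(best) == 1 else MULTI
    start, strand, mm = best[0]
    chrom, local = index.locate(start)
    L = len(read)
    return AlignmentRecord(read.id, chrom, local, local + L, strand, mm, 0,
                           L - mm, cls)


@dataclass
class MappabilityTable:
    """Counts and proportions of unique / multi / unaligned reads."""

    n_unique: int
    n_multi: int
    n_unaligned: int

    @property
    def n_total(self) -> int:
        return self.n_unique + self.n_multi + self.n_unaligned

    @property
    def empty(self) -> bool:
        return self.n_total == 0

    @property
    def proportions(self) -> dict[str, float]:
        if self.empty:
            return {UNIQUE: 0.0, MULTI: 0.0, UNALIGNED: 0.0}
        n = self.n_total
        return {UNIQUE: self.n_unique / n, MULTI: self.n_multi / n,
                UNALIGNED: self.n_unaligned / n}


def align_readset(readset: ReadSet, index: SeedIndex, max_mismatches: int = 3
                  ) -> list[AlignmentRecord]:
    return [align_ungapped(r, index, max_mismatches) for r in readset]


def tabulate_records(records) -> MappabilityTable:
    counts = {UNIQUE: 0, MULTI: 0, UNALIGNED: 0}
    for rec in records:
        counts[rec.mapping_class] += 1
    return MappabilityTable(counts[UNIQUE], counts[MULTI], counts[UNALIGNED])


def classify_readset(readset: ReadSet, index: SeedIndex,
                     max_mismatches: int = 3) -> MappabilityTable:
    """Fig-2-style three-way mappability classification of a read set."""
    return tabulate_records(align_readset(readset, index, max_mismatches))


def mappability_by_length(
    readset: ReadSet, index: SeedIndex,
    lengths=(20, 25, 30, 35, 40), max_mismatches: int = 3,
) -> pd.DataFrame:
    """Read-length trimming experiment: reads are 3'-trimmed to each length
    and reclassified.  Lengths longer than a read are skipped (with a
    'skipped' marker row)."""
    rows = []
    for length in lengths:
        short = [r for r in readset if len(r) < length]
        if short:
            rows.append({"length": length, "skipped": True, "n_unique": 0,
                         "n_multi": 0, "n_unaligned": 0, "p_unique": np.nan,
                         "p_multi": np.nan, "p_unaligned": np.nan})
            continue
        trimmed = ReadSet([
            Read(r.id, r.sequence[:length], r.quality[:length]) for r in readset
        ])
        t = classify_readset(trimmed, index, max_mismatches)
        rows.append({"length": length, "skipped": False,
                     "n_unique": t.n_unique, "n_multi": t.n_multi,
                     "n_unaligned": t.n_unaligned,
                     **{f"p_{k}": v for k, v in t.proportions.items()}})
    return pd.DataFrame(rows)


def mismatch_sweep(readset: ReadSet, index: SeedIndex,
                   mm_values=(0, 1, 2, 3)) -> pd.DataFrame:
    """Aligned proportion as a function of the allowed mismatch count."""
    rows = []
    for mm in mm_values:
        t = classify_readset(readset, index, mm)
        rows.append({"max_mismatches": mm, "n_unique": t.n_unique,
                     "n_multi": t.n_multi, "n_unaligned": t.n_unaligned,
                     **{f"p_{k}": v for k, v in t.proportions.items()},
                     "p_aligned": t.proportions[UNIQUE] + t.proportions[MULTI]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Smith-Waterman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SWAlignment:
    """Optimal local alignment of a read against a reference window.
    Spans are 0-based half-open into the two input strings; cigar ops are
    ('M', 'I', 'D') with I consuming read only, D reference only."""

    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    mismatches: int
    gaps: int
    cigar: tuple[tuple[str, int], ...]
    matched: int = 0


def smith_waterman(read_seq: str, window_seq: str,
                   scheme: ScoringScheme = ScoringScheme()) -> SWAlignment:
    """Optimal affine-gap local alignment (Gotoh); an all-mismatch pair has
    score 0 with an empty alignment."""
    if not window_seq:
        raise InvalidParameterError("reference window must be non-empty")
    a = encode(read_seq)
    b = encode(window_seq)
    H, ptr, ptrE, ptrF, best, bi, bj = _kernels.sw_fill(
        a, b, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0:
        return SWAlignment(0, 0, 0, 0, 0, 0, 0, ())
    ops: list[str] = []
    mismatches = 0
    matched = 0
    gaps = 0
    i, j = bi, bj
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            ops.append("M")
            if a[i - 1] == b[j - 1] and a[i - 1] <= 3:
                matched += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:  # gap consuming reference
            while True:
                ops.append("D")
                gaps += 1
                ext = ptrE[i, j]
                j -= 1
                if not ext:
                    break
        else:  # gap consuming read
            while True:
                ops.append("I")
                gaps += 1
                ext = ptrF[i, j]
                i -= 1
                if not ext:
                    break
    ops.reverse()
    cigar = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += 1
        else:
            cigar.append([op, 1])
    return SWAlignment(int(best), i, bi, j, bj, mismatches, gaps,
                       tuple((o, n) for o, n in cigar), matched)


# ---------------------------------------------------------------------------
# Gapped realignment (seed and extend)
# ---------------------------------------------------------------------------

def _seed_groups(anchors: np.ndarray, span: int) -> list[tuple[int, int, int]]:
    """Cluster sorted anchor positions into candidate windows; anchors more
    than span/2 apart start a new group.  Returns (min, max, count)."""
    groups = []
    if anchors.size == 0:
        return groups
    anchors = np.sort(anchors)
    gstart = prev = int(anchors[0])
    count = 1
    for a in anchors[1:]:
        a = int(a)
        if a - prev > span // 2:
            groups.append((gstart, prev, count))
            gstart = a
            count = 0
        count += 1
        prev = a
    groups.append((gstart, prev, count))
    return groups


@dataclass(frozen=True)
class LocalHit:
    """One candidate gapped placement found by seed-and-extend."""

    score: int
    gstart: int   # global (concatenated) reference coordinates
    gend: int
    strand: str
    mismatches: int
    gaps: int
    matched: int
    read_span: int


def gapped_candidates(
    read_seq: str,
    index: SeedIndex,
    scheme: ScoringScheme = ScoringScheme(),
    seed_stride: int = 5,
    min_seed_hits: int = 2,
) -> list[LocalHit]:
    """Seed-and-extend candidates for a read, best first.

    k-mer seeds are taken every ``seed_stride`` bases on both strands; seed
    hits projected to read-start coordinates are clustered into candidate
    windows (hit +- read length); windows with >= ``min_seed_hits`` seeds
    are aligned with Smith-Waterman."""
    L = len(read_seq)
    k = index.k
    if L < k:
        return []
    codes = encode(read_seq)
    offsets = list(range(0, L - k + 1, seed_stride))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    candidates: list[LocalHit] = []
    seen = set()
    for strand, sc in (("+", codes), ("-", revcomp_codes(codes))):
        codes64 = sc.astype(np.int64)
        anchors = []
        for off in offsets:
            if sc[off:off + k].max() > 3:
                continue
            val = int(codes64[off:off + k] @ index._powers)
            pos = index.lookup_value(val)
            if pos.size:
                anchors.append(pos - off)
        if not anchors:
            continue
        for gmin, gmax, count in _seed_groups(np.concatenate(anchors), L):
            if count < min_seed_hits:
                continue
            lo, hi = index.chrom_span(max(gmin, 0))
            ws = max(lo, gmin - L)
            we = min(hi, gmax + 2 * L)
            if we - ws < k:
                continue
            aln = _sw_codes(sc, index.codes[ws:we], scheme)
            if aln.score <= 0:
                continue
            dkey = (ws + aln.ref_start, strand)
            if dkey in seen:
                continue
            seen.add(dkey)
            candidates.append(LocalHit(
                aln.score, ws + aln.ref_start, ws + aln.ref_end, strand,
                aln.mismatches, aln.gaps, aln.matched,
                aln.read_end - aln.read_start,
            ))
    candidates.sort(key=lambda c: (-c.score, c.gstart, c.strand))
    return candidates


def realign_gapped(
    read: Read,
    index: SeedIndex,
    scheme: ScoringScheme = ScoringScheme(),
    seed_stride: int = 5,
    min_seed_hits: int = 2,
    multi_window: float = 0.05,
) -> AlignmentRecord:
    """Gap/polymorphism-tolerant realignment of one read.

    The best seed-and-extend candidate is reported iff its score reaches
    ``scheme.min_score_fraction`` of the maximum attainable
    (match x read length).  mapping_class is 'multi' when a second candidate
    window scores within ``multi_window`` of the best."""
    candidates = gapped_candidates(read.sequence, index, scheme, seed_stride,
                                   min_seed_hits)
    if not candidates:
        return unaligned_record(read.id)
    best = candidates[0]
    if best.score < scheme.min_score_fraction * scheme.match * len(read):
        return unaligned_record(read.id)
    n_close = sum(1 for c in candidates
                  if c.score >= (1 - multi_window) * best.score)
    cls = UNIQUE if n_close == 1 else MULTI
    chrom, local = index.locate(best.gstart)
    return AlignmentRecord(read.id, chrom, local,
                           local + (best.gend - best.gstart), best.strand,
                           best.mismatches, best.gaps, best.score, cls)


def _sw_codes(a: np.ndarray, b: np.ndarray, scheme: ScoringScheme) -> SWAlignment:
    """smith_waterman on pre-encoded arrays (hot path of seed-and-extend)."""
    H, ptr, ptrE, ptrF, best, bi, bj = _kernels.sw_fill(
        a, b, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0:
        return SWAlignment(0, 0, 0, 0, 0, 0, 0, ())
    i, j = bi, bj
    mismatches = 0
    matched = 0
    gaps = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] <= 3:
                matched += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                gaps += 1
                ext = ptrE[i, j]
                j -= 1
                if not ext:
                    break
        else:
            while True:
                gaps += 1
                ext = ptrF[i, j]
                i -= 1
                if not ext:
                    break
    return SWAlignment(int(best), i, bi, j, bj, mismatches, gaps, (), matched)


def realign_readset(readset: ReadSet, index: SeedIndex,
                    scheme: ScoringScheme = ScoringScheme(),
                    **kwargs) -> list[AlignmentRecord]:
    return [realign_gapped(r, index, scheme, **kwargs) for r in readset]


def records_to_frame(records) -> pd.DataFrame:
    """Alignment records as the package's TSV schema."""
    return pd.DataFrame([
        {"read_id": r.read_id, "chrom": r.chrom if r.chrom else ".",
         "start": -1 if r.start is None else r.start,
         "end": -1 if r.end is None else r.end,
         "strand": r.strand or ".", "mismatches": r.mismatches,
         "gaps": r.gaps, "score": r.score, "mapping_class": r.mapping_class}
        for r in records
    ])
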