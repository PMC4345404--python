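"""Readers/writers for the plain-text formats the pipeline speaks, plus the
minimal read preprocessing (adapter trimming, mean-quality filtering) that a
ChIP-Seq run receives before alignment.

Conventions
-----------
* FASTQ is Sanger-encoded (Phred+33); qualities are kept as the encoded
  string so a read round-trips byte-identically.
* BED is 0-based half-open; GFF-lite is 1-based inclusive.  The converters
  between internal (0-based half-open) coordinates and each format are exact
  inverses on valid records.
* Parsers raise :class:`~readrescue.errors.ParseError` with the offending
  record's position; they never skip records silently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError

PHRED_OFFSET = 33


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class Read:
    """A sequenced fragment.  ``quality`` is the Phred+33 encoded string,
    always the same length as ``sequence``."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ParseError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self):
        return len(self.sequence)

    @property
    def phred_scores(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode("ascii"), dtype=np.uint8).astype(
            np.int64
        ) - PHRED_OFFSET

    @property
    def mean_quality(self) -> float:
        return float(self.phred_scores.mean()) if self.sequence else 0.0


@dataclass(frozen=True)
class ReadTruth:
    """Simulation ground truth for one read (source taxon and locus).

    ``start`` is the 0-based reference position of the read's leftmost base;
    for reads of unknown locus (e.g. a contaminant on an unindexed genome the
    coordinates still refer to that source genome)."""

    taxon_id: str
    chrom: str
    start: int
    strand: str  # '+' or '-'


@dataclass
class ReadSet:
    """A list of reads plus optional per-read ground truth.

    Invariants: read ids unique; when ``truth`` is present it covers every
    read."""

    reads: list[Read] = field(default_factory=list)
    truth: dict[str, ReadTruth] | None = None

    def __post_init__(self):
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ParseError("duplicate read ids in ReadSet")
        if self.truth is not None:
            missing = [i for i in ids if i not in self.truth]
            if missing:
                raise ParseError(
                    f"truth records missing for {len(missing)} reads "
                    f"(first: {missing[0]!r})"
                )

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def subset(self, ids) -> "ReadSet":
        keep = set(ids)
        reads = [r for r in self.reads if r.id in keep]
        truth = None
        if self.truth is not None:
            truth = {r.id: self.truth[r.id] for r in reads}
        return ReadSet(reads, truth)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path) -> ReadSet:
    """Parse a (optionally gzipped) Sanger FASTQ file into a ReadSet."""
    reads = []
    with _open(path) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
                qual = "".join(
                    chr(q + PHRED_OFFSET)
                    for q in rec.letter_annotations["phred_quality"]
                )
                reads.append(Read(rec.id, str(rec.seq).upper(), qual))
        except ValueError as exc:
            raise ParseError(f"{path}: record {len(reads) + 1}: {exc}") from exc
    return ReadSet(reads)


def write_fastq(readset: ReadSet, path) -> None:
    with _open(path, "wt") as out:
        for r in readset:
            out.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {name: sequence} (uppercased)."""
    seqs = {}
    with _open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seqs:
                raise ParseError(f"{path}: duplicate sequence name {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with _open(path, "wt") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6 / TSV
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6 table (0-based half-open, as stored internally)."""
    df = df.copy()
    for col in BED_COLUMNS:
        if col not in df.columns:
            df[col] = "." if col in ("name", "strand") else 0
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >= 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col in BED_COLUMNS[df.shape[1] :]:
        df[col] = "." if col in ("name", "strand") else 0
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ParseError(f"{path}: line {bad[0] + 1}: end <= start")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene models (GFF-lite)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model.

    ``exons``/``utr5``/``utr3`` are 0-based half-open intervals; exons are
    sorted and non-overlapping; ``tss`` sits at the transcript 5' end
    (max coordinate - 1 on the minus strand)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        ex = list(self.exons)
        if ex != sorted(ex) or any(
            ex[i][1] > ex[i + 1][0] for i in range(len(ex) - 1)
        ):
            raise ParseError(f"gene {self.gene_id}: exons overlap or unsorted")
        expected_tss = ex[0][0] if self.strand == "+" else ex[-1][1] - 1
        if self.tss != expected_tss:
            raise ParseError(
                f"gene {self.gene_id}: TSS {self.tss} not at transcript 5' end"
            )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


_GFF_COLS = [
    "chrom", "source", "feature", "start", "end", "score", "strand",
    "frame", "attrs",
]


def write_gene_models(genes: list[GeneModel], path) -> None:
    """Emit GFF-lite (tab-separated, 1-based inclusive coordinates)."""
    rows = []
    for g in genes:
        attr = f"ID={g.gene_id}"
        s, e = g.span
        rows.append((g.chrom, "readrescue", "gene", s + 1, e, ".", g.strand, ".", attr))
        for feat, ivs in (("exon", g.exons), ("five_prime_UTR", g.utr5),
                          ("three_prime_UTR", g.utr3)):
            for (a, b) in ivs:
                rows.append(
                    (g.chrom, "readrescue", feat, a + 1, b, ".", g.strand, ".", attr)
                )
    pd.DataFrame(rows, columns=_GFF_COLS).to_csv(path, sep="\t", header=False,
                                                 index=False)


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=_GFF_COLS, comment="#")
    genes: dict[str, dict] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        if row.end < row.start:
            raise ParseError(f"{path}: line {line_no}: end < start")
        gid = str(row.attrs).split("ID=")[-1].split(";")[0]
        rec = genes.setdefault(
            gid, {"chrom": row.chrom, "strand": row.strand,
                  "exon": [], "five_prime_UTR": [], "three_prime_UTR": []}
        )
        if row.feature in rec:
            rec[row.feature].append((int(row.start) - 1, int(row.end)))
    out = []
    for gid, rec in genes.items():
        exons = tuple(sorted(rec["exon"]))
        if not exons:
            raise ParseError(f"{path}: gene {gid} has no exons")
        tss = exons[0][0] if rec["strand"] == "+" else exons[-1][1] - 1
        out.append(
            GeneModel(gid, rec["chrom"], rec["strand"], tss, exons,
                      tuple(sorted(rec["five_prime_UTR"])),
                      tuple(sorted(rec["three_prime_UTR"])))
        )
    return out


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def trim_adapter(read: Read, adapter: str, min_overlap: int = 3) -> Read:
    """Remove the longest read suffix that exactly matches a prefix of
    ``adapter`` (at least ``min_overlap`` bases); quality is trimmed in step.
    No match leaves the read unchanged."""
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    seq = read.sequence
    best = 0
    for k in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            best = k
            break
    if best == 0:
        return read
    n = len(seq) - best
    return replace(read, sequence=seq[:n], quality=read.quality[:n])


def filter_by_quality(
    readset: ReadSet, min_mean_phred: float = 20.0, min_length: int = 20
) -> tuple[ReadSet, int]:
    """Keep reads with mean Phred >= threshold and length >= min_length.

    Returns (kept, discarded_count); kept + discarded == input size."""
    if min_mean_phred < 0 or min_length < 0:
        raise ValueError("thresholds must be >= 0")
    kept = [
        r for r in readset
        if len(r) >= min_length and r.mean_quality >= min_mean_phred
    ]
    truth = None
    if readset.truth is not None:
        truth = {r.id: readset.truth[r.id] for r in kept}
    return ReadSet(kept, truth), len(readset) - len(kept)
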