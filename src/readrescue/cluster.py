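"""Greedy centroid clustering of unaligned reads at an identity threshold.

The first read founds a cluster and becomes its seed; every later read joins
the first seed (in seed-creation order) it matches at >= the identity
threshold, else founds its own cluster.  Identity is the number of matched
positions in an optimal global alignment divided by the shorter sequence
length, so overlapping or nested fragments of the same template still group
together.  Like its inspiration, the result is order-dependent; the
processing order is part of the configuration and fixed by default.

A 5-mer profile prefilter prunes alignment candidates.  It is a speed
optimization only and is tested not to change the clustering on template
data; it can be disabled with ``use_prefilter=False``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._seq import encode
from .errors import InvalidParameterError
from .io_formats import ReadSet

PREFILTER_K = 5


@dataclass
class Cluster:
    """A seed read and its members (seed included), with per-member identity
    to the seed."""

    seed_id: str
    member_ids: list[str] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.member_ids)


def identity(a: str, b: str) -> float:
    """Fraction of matched positions in an optimal global alignment
    (match +1, mismatch -1, gap -1), relative to the shorter sequence.
    Symmetric; in [0, 1]."""
    if not a or not b:
        raise InvalidParameterError("identity of an empty sequence is undefined")
    matches = int(_kernels.nw_match_count(encode(a), encode(b)))
    return matches / min(len(a), len(b))


def _kmer_set(codes: np.ndarray, k: int = PREFILTER_K) -> np.ndarray:
    if codes.shape[0] < k:
        return np.empty(0, dtype=np.int64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    w = np.lib.stride_tricks.sliding_window_view(codes, k)
    vals = w.astype(np.int64) @ powers
    vals = vals[w.max(axis=1) <= 3]
    return np.unique(vals)


def greedy_cluster(
    readset: ReadSet,
    threshold: float = 0.75,
    order: str = "input",
    use_prefilter: bool = True,
    prefilter_min_share: float = 0.2,
) -> list[Cluster]:
    """Single-pass greedy clustering at ``threshold`` identity.

    order: 'input' (default, fixed) or 'length-desc'.  The returned clusters
    partition the input read ids; every member has identity >= threshold to
    its seed."""
    if not 0 < threshold <= 1:
        raise InvalidParameterError("threshold must be in (0, 1]")
    if order not in ("input", "length-desc"):
        raise InvalidParameterError(f"unknown order {order!r}")
    reads = list(readset.reads)
    if order == "length-desc":
        reads = sorted(reads, key=lambda r: -len(r))

    clusters: list[Cluster] = []
    seed_codes: list[np.ndarray] = []
    seed_lens: list[int] = []
    # inverted 5-mer index: kmer value -> growable array of seed indices, so
    # the per-read candidate count is a concatenate + bincount (no Python
    # loop over postings and no repeated array rebuilds).
    kmer_to_seeds: dict[int, _GrowArray] = defaultdict(_GrowArray)

    for read in reads:
        codes = encode(read.sequence)
        kmers = _kmer_set(codes)
        if use_prefilter and kmers.size and clusters:
            chunks = [kmer_to_seeds[int(v)].view()
                      for v in kmers if int(v) in kmer_to_seeds]
            if chunks:
                counts = np.bincount(np.concatenate(chunks),
                                     minlength=len(clusters))
                need = prefilter_min_share * kmers.size
                candidates = np.flatnonzero(counts >= need)
            else:
                candidates = np.empty(0, dtype=np.int64)
        else:
            candidates = np.arange(len(clusters))
        assigned = False
        rlen = len(read.sequence)
        for si in candidates:  # ascending == seed-creation order
            matches = int(_kernels.nw_match_count(codes, seed_codes[si]))
            ident = matches / min(rlen, seed_lens[si])
            if ident >= threshold:
                clusters[si].member_ids.append(read.id)
                clusters[si].identities.append(ident)
                assigned = True
                break
        if not assigned:
            si = len(clusters)
            clusters.append(Cluster(read.id, [read.id], [1.0]))
            seed_codes.append(codes)
            seed_lens.append(rlen)
            for v in kmers:
                kmer_to_seeds[int(v)].append(si)
    return clusters


class _GrowArray:
    """Append-only int32 array with amortized doubling (posting list)."""

    __slots__ = ("_buf", "_n")

    def __init__(self):
        self._buf = np.empty(8, dtype=np.int32)
        self._n = 0

    def append(self, value: int) -> None:
        if self._n == self._buf.size:
            new = np.empty(self._buf.size * 2, dtype=np.int32)
            new[: self._n] = self._buf
            self._buf = new
        self._buf[self._n] = value
        self._n += 1

    def view(self) -> np.ndarray:
        return self._buf[: self._n]


def propagate_seed_labels(
    clusters: list[Cluster], seed_assignments: dict[str, str]
) -> dict[str, str]:
    """Give every member read its seed's label.  Every seed must have an
    assignment (possibly 'unassigned')."""
    missing = [c.seed_id for c in clusters if c.seed_id not in seed_assignments]
    if missing:
        raise InvalidParameterError(
            f"missing assignments for {len(missing)} seeds: {missing[:5]}"
        )
    out = {}
    for c in clusters:
        label = seed_assignments[c.seed_id]
        for rid in c.member_ids:
            out[rid] = label
    return out
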