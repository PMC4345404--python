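"""Taxonomic triage of unaligned reads.

Cluster seeds are searched against a labeled multi-genome reference set with
the gapped seed-and-extend aligner; the taxa of all near-top hits are
combined by lowest common ancestor (LCA) on a rooted taxonomy tree; reads
are then partitioned into host-legitimate (inside the host subtree),
contaminant (strictly outside) and unassigned.  A root-level LCA is
uninformative and counts as unassigned, so neither class is inflated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    InvalidParameterError,
    MalformedTaxonomyError,
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: str | None  # None only for the root
    rank: str
    name: str


class TaxonomyTree:
    """Rooted tree of taxa with ranks; supports parent, subtree-membership
    and LCA queries."""

    def __init__(self, nodes: dict[str, TaxonNode], root_id: str):
        self.nodes = nodes
        self.root_id = root_id
        self._depth: dict[str, int] = {}
        self._ancestry: dict[str, tuple[str, ...]] = {}
        for tid in nodes:
            self._ancestry[tid] = tuple(self._walk(tid))
            self._depth[tid] = len(self._ancestry[tid]) - 1

    def _walk(self, tid: str):
        chain = []
        cur = tid
        while cur is not None:
            chain.append(cur)
            cur = self.nodes[cur].parent_id
        return reversed(chain)  # root first

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def parent(self, taxon_id: str) -> str | None:
        return self.nodes[taxon_id].parent_id

    def name(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].name

    def rank(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank

    def depth(self, taxon_id: str) -> int:
        """Edges from the root (root has depth 0)."""
        return self._depth[taxon_id]

    def ancestors(self, taxon_id: str) -> tuple[str, ...]:
        """Root-first chain of ancestors including the taxon itself."""
        return self._ancestry[taxon_id]

    def is_descendant(self, taxon_id: str, ancestor_id: str) -> bool:
        """True if taxon is ancestor itself or lies in its subtree."""
        return ancestor_id in self._ancestry[taxon_id]

    def lca(self, taxon_ids) -> str:
        """Lowest common ancestor of a non-empty set of taxa."""
        ids = list(taxon_ids)
        if not ids:
            raise InvalidParameterError("lca of an empty taxon set")
        for t in ids:
            if t not in self.nodes:
                raise DataIntegrityError(f"taxon {t!r} not in the taxonomy tree")
        chains = [self._ancestry[t] for t in ids]
        lca = self.root_id
        for level in zip(*chains):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        for t in reversed(self._ancestry[taxon_id]):
            if self.nodes[t].rank == rank:
                return t
        return None

    def ranks(self) -> set[str]:
        return {n.rank for n in self.nodes.values()}


def build_taxonomy(edge_list) -> TaxonomyTree:
    """Build a TaxonomyTree from (child_id, parent_id, rank, name) rows.

    The root has parent None or itself; exactly one root is required and
    cycles or orphan parents are rejected."""
    nodes: dict[str, TaxonNode] = {}
    roots = []
    for child, parent, rank, name in edge_list:
        if child in nodes:
            raise MalformedTaxonomyError(f"duplicate taxon id {child!r}")
        if parent is None or parent == child:
            roots.append(child)
            parent = None
        nodes[child] = TaxonNode(child, parent, rank, name)
    if len(roots) != 1:
        raise MalformedTaxonomyError(f"need exactly one root, found {len(roots)}")
    root = roots[0]
    for tid, node in nodes.items():
        seen = {tid}
        cur = node.parent_id
        while cur is not None:
            if cur not in nodes:
                raise MalformedTaxonomyError(
                    f"taxon {tid!r} has orphan ancestor {cur!r}"
                )
            if cur in seen:
                raise MalformedTaxonomyError(f"cycle through taxon {cur!r}")
            seen.add(cur)
            cur = nodes[cur].parent_id
    return TaxonomyTree(nodes, root)


def taxonomy_from_tsv(path) -> TaxonomyTree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = [
        (r.child_id, None if pd.isna(r.parent_id) else r.parent_id, r.rank, r.name)
        for r in df.itertuples(index=False)
    ]
    return build_taxonomy(edges)


def taxonomy_to_tsv(tree: TaxonomyTree, path) -> None:
    rows = [
        {"child_id": n.taxon_id, "parent_id": n.parent_id or "",
         "rank": n.rank, "name": n.name}
        for n in tree.nodes.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Database search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hit:
    """A database match of one cluster seed."""

    seed_id: str
    subject_taxon_id: str
    score: int
    identity_fraction: float
    aligned_length: int


@dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    taxon_id: str  # a tree node or 'unassigned'
    n_supporting_hits: int
    lca_depth: int  # edges from root; -1 when unassigned


class ReferenceDatabase:
    """Labeled reference genomes plus their seed indexes (built once)."""

    def __init__(self, genomes, k: int = 12):
        from .align import build_index

        if not genomes:
            raise ConfigurationError("reference database is empty")
        self.genomes = list(genomes)
        self.indexes = [build_index(g, k) for g in self.genomes]

    def __len__(self):
        return len(self.genomes)


def search_database(
    seed_read,
    ref_db,
    scheme=None,
    min_score_fraction: float = 0.5,
    max_hits: int = 10,
) -> list[Hit]:
    """Gapped search of one cluster seed against every database genome.

    Reports at most one (best) hit per genome, keeps hits scoring at least
    ``min_score_fraction`` of the maximum attainable, sorted by score
    descending and capped at ``max_hits``.  Uses the same seed-and-extend
    machinery as the realigner, but a single seed hit suffices
    (sensitivity over speed for short queries).
    """
    from .align import ScoringScheme, gapped_candidates

    if scheme is None:
        scheme = ScoringScheme()
    if not isinstance(ref_db, ReferenceDatabase):
        ref_db = ReferenceDatabase(ref_db)
    seq = seed_read.sequence if hasattr(seed_read, "sequence") else str(seed_read)
    rid = getattr(seed_read, "id", "query")
    threshold = min_score_fraction * scheme.match * len(seq)
    hits = []
    for genome, index in zip(ref_db.genomes, ref_db.indexes):
        cands = gapped_candidates(seq, index, scheme, min_seed_hits=1)
        if not cands:
            continue
        best = cands[0]
        if best.score < threshold:
            continue
        aligned_length = best.gend - best.gstart
        ident = best.matched / max(aligned_length, 1)
        hits.append(Hit(rid, genome.taxon_id, best.score, ident, aligned_length))
    hits.sort(key=lambda h: (-h.score, h.subject_taxon_id))
    return hits[:max_hits]


def lca_assign(
    hits: list[Hit],
    tree: TaxonomyTree,
    score_window: float = 0.10,
    read_id: str | None = None,
) -> TaxonAssignment:
    """Assign a read to the LCA of all hits scoring within ``score_window``
    of the top hit; no hits means 'unassigned'."""
    if not hits:
        return TaxonAssignment(read_id or "query", UNASSIGNED, 0, -1)
    rid = read_id or hits[0].seed_id
    top = max(h.score for h in hits)
    voters = [h for h in hits if h.score >= (1 - score_window) * top]
    for h in voters:
        if h.subject_taxon_id not in tree:
            raise DataIntegrityError(
                f"hit taxon {h.subject_taxon_id!r} absent from the taxonomy tree"
            )
    taxon = tree.lca([h.subject_taxon_id for h in voters])
    return TaxonAssignment(rid, taxon, len(voters), tree.depth(taxon))


@dataclass
class PartitionResult:
    legitimate: list[str]
    contaminant: list[str]
    unassigned: list[str]
    breakdown: dict[str, int]

    @property
    def n_total(self) -> int:
        return len(self.legitimate) + len(self.contaminant) + len(self.unassigned)

    @property
    def legitimate_fraction(self) -> float:
        return len(self.legitimate) / self.n_total if self.n_total else 0.0


def partition_legitimate(
    assignments, tree: TaxonomyTree, host_taxon_id: str
) -> PartitionResult:
    """Split reads into host-legitimate / contaminant / unassigned.

    ``assignments`` maps read_id -> taxon_id (or is a list of
    TaxonAssignment).  Legitimate = host taxon or its descendants;
    contaminant = any other tree taxon *below the root*; root-level and
    'unassigned' reads count as unassigned."""
    if host_taxon_id not in tree:
        raise InvalidParameterError(f"host taxon {host_taxon_id!r} not in tree")
    if not isinstance(assignments, dict):
        assignments = {a.read_id: a.taxon_id for a in assignments}
    legit, contam, unass = [], [], []
    breakdown: Counter = Counter()
    for rid, taxon in assignments.items():
        if taxon == UNASSIGNED:
            unass.append(rid)
            continue
        if taxon not in tree:
            raise DataIntegrityError(f"assigned taxon {taxon!r} not in tree")
        breakdown[taxon] += 1
        if taxon == tree.root_id:
            unass.append(rid)  # uninformative LCA
        elif tree.is_descendant(taxon, host_taxon_id):
            legit.append(rid)
        else:
            contam.append(rid)
    return PartitionResult(sorted(legit), sorted(contam), sorted(unass),
                           dict(breakdown))


def taxonomy_report(
    breakdown: dict[str, int], tree: TaxonomyTree, rank: str
) -> pd.DataFrame:
    """Roll assigned-read counts up to the requested rank.

    Taxa with no ancestor at that rank (e.g. the root) keep their own name,
    so fractions still sum to 1 over assigned reads."""
    if rank not in tree.ranks():
        raise InvalidParameterError(f"rank {rank!r} not present in the tree")
    rolled: Counter = Counter()
    labels: dict[str, tuple[str, str]] = {}
    for taxon, count in breakdown.items():
        anc = tree.ancestor_at_rank(taxon, rank)
        key = anc if anc is not None else taxon
        rolled[key] += count
        labels[key] = (tree.name(key), tree.rank(key))
    total = sum(rolled.values())
    rows = [
        {"taxon_id": t, "name": labels[t][0], "rank": labels[t][1],
         "count": c, "fraction": c / total if total else 0.0}
        for t, c in sorted(rolled.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)
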