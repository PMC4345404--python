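"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a different mechanism than the package
(exhaustive scans, plain-Python DP, high-precision arithmetic) so agreement
is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import numpy as np

from readrescue._seq import encode, revcomp


def brute_placements(genome, seq: str, max_mm: int):
    """Every end-to-end placement of ``seq`` with <= max_mm mismatches, by
    exhaustive window comparison (N mismatches everything)."""
    out = set()
    for strand in ("+", "-"):
        target = encode(seq if strand == "+" else revcomp(seq))
        L = target.shape[0]
        for chrom, s in genome.chromosomes.items():
            codes = encode(s)
            if codes.shape[0] < L:
                continue
            w = np.lib.stride_tricks.sliding_window_view(codes, L)
            mm = ((w != target[None, :]) | (w > 3) | (target[None, :] > 3)).sum(axis=1)
            for pos in np.flatnonzero(mm <= max_mm):
                out.add((chrom, int(pos), strand, int(mm[pos])))
    return out


def sw_score(a: str, b: str, match, mismatch, gap_open, gap_extend) -> int:
    """Best local alignment score by a plain-Python affine-gap DP."""
    A = encode(a)
    B = encode(b)
    m, n = len(A), len(B)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (A[i - 1] == B[j - 1] and A[i - 1] <= 3) else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_matches(a: str, b: str) -> int:
    """Max matches among score-optimal global alignments
    (match +1, mismatch -1, gap -1), plain-Python lexicographic DP."""
    A = encode(a)
    B = encode(b)
    m, n = len(A), len(B)
    prev = [(-j, 0) for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [(-i, 0)] + [None] * n
        for j in range(1, n + 1):
            hit = A[i - 1] == B[j - 1] and A[i - 1] <= 3
            diag = (prev[j - 1][0] + (1 if hit else -1),
                    prev[j - 1][1] + (1 if hit else 0))
            up = (prev[j][0] - 1, prev[j][1])
            left = (cur[j - 1][0] - 1, cur[j - 1][1])
            cur[j] = max(diag, up, left)
        prev = cur
    return prev[n][1]


def poisson_upper_tail(k: int, lam: float, dps: int = 50) -> float:
    """P(X >= k) for X ~ Poisson(lam) by high-precision summation."""
    import mpmath

    with mpmath.workdps(dps):
        lam_mp = mpmath.mpf(lam)
        if k <= 0:
            return 1.0
        if k <= lam:
            # tail is large: 1 - lower sum is numerically safe here
            term = mpmath.exp(-lam_mp)
            acc = term
            for i in range(1, k):
                term = term * lam_mp / i
                acc += term
            return float(1 - acc)
        # deep tail: sum upward from i = k until terms vanish
        term = mpmath.exp(-lam_mp + k * mpmath.log(lam_mp)
                          - mpmath.loggamma(k + 1))
        acc = mpmath.mpf(0)
        i = k
        while True:
            acc += term
            i += 1
            term = term * lam_mp / i
            if term < acc * mpmath.mpf(10) ** (-dps):
                break
        return float(acc)


def brute_peak_overlap(a, b, min_overlap=1):
    """All-pairs interval intersection (O(n^2))."""
    pairs = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            if pa.chrom != pb.chrom:
                continue
            if min(pa.end, pb.end) - max(pa.start, pb.start) >= min_overlap:
                pairs.append((i, j))
    a_hit = {i for i, _ in pairs}
    b_hit = {j for _, j in pairs}
    return {
        "n_a": len(a), "n_b": len(b),
        "n_overlap_a": len(a_hit), "n_overlap_b": len(b_hit),
        "n_a_only": len(a) - len(a_hit), "n_b_only": len(b) - len(b_hit),
        "pairs": sorted(pairs),
    }


def lca_by_ancestor_sets(tree, taxon_ids) -> str:
    """LCA as the deepest node in the intersection of full ancestor sets."""
    sets = [set(tree.ancestors(t)) for t in taxon_ids]
    common = set.intersection(*sets)
    return max(common, key=tree.depth)


def annotate_summit(chrom, summit, genes, promoter_span=3000,
                    downstream_span=3000) -> str:
    """Category of one peak summit by per-gene linear scan (the precedence
    rules written out longhand)."""
    in_cat = {c: False for c in ("utr5", "utr3", "exon", "gene", "promoter",
                                 "downstream")}
    for g in genes:
        if g.chrom != chrom:
            continue
        for s, e in g.utr5:
            in_cat["utr5"] |= s <= summit < e
        for s, e in g.utr3:
            in_cat["utr3"] |= s <= summit < e
        for s, e in g.exons:
            in_cat["exon"] |= s <= summit < e
        gs, ge = g.span
        in_cat["gene"] |= gs <= summit < ge
        if g.strand == "+":
            in_cat["promoter"] |= gs - promoter_span <= summit < gs
            in_cat["downstream"] |= ge <= summit < ge + downstream_span
        else:
            in_cat["promoter"] |= ge <= summit < ge + promoter_span
            in_cat["downstream"] |= gs - downstream_span <= summit < gs
    for cat in ("utr5", "utr3", "exon"):
        if in_cat[cat]:
            return cat
    if in_cat["gene"]:
        return "intron"
    for cat in ("promoter", "downstream"):
        if in_cat[cat]:
            return cat
    return "intergenic"
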