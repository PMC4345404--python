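"""Statistical machinery of the rescue analyses.

Chi-square equality of proportions (mappability comparisons across read
lengths / mismatch settings), Welch's unequal-variance t-test
(fold-enrichment validation), aligner ROC from simulation truth, and GC
content.  Test statistics are computed from their defining formulas; tail
probabilities come from scipy's chi2 and t distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataIntegrityError, DegenerateInputError, InvalidParameterError


@dataclass(frozen=True)
class ProportionTable:
    """groups = [(successes, total), ...]; >= 2 groups."""

    groups: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.groups) < 2:
            raise InvalidParameterError("need >= 2 groups")
        for s, n in self.groups:
            if not 0 <= s <= n:
                raise InvalidParameterError(f"bad group ({s}, {n})")


def chisq_equal_proportions(table: ProportionTable) -> dict:
    """Pearson chi-square test that all group proportions are equal.

    The groups x {success, failure} contingency table is tested against
    expected counts under the pooled proportion; df = groups - 1.  A
    ``low_expected`` flag marks expected cells below 1."""
    groups = table.groups
    if any(n == 0 for _, n in groups):
        raise InvalidParameterError("every group needs total > 0")
    succ = np.array([s for s, _ in groups], dtype=float)
    tot = np.array([n for _, n in groups], dtype=float)
    pooled = succ.sum() / tot.sum()
    if pooled in (0.0, 1.0):
        # all successes or all failures: proportions identical by construction
        return {"statistic": 0.0, "df": len(groups) - 1, "p_value": 1.0,
                "low_expected": bool(min(tot) * min(pooled, 1 - pooled) < 1)}
    exp_s = tot * pooled
    exp_f = tot * (1 - pooled)
    obs_f = tot - succ
    stat = float((((succ - exp_s) ** 2) / exp_s).sum()
                 + (((obs_f - exp_f) ** 2) / exp_f).sum())
    df = len(groups) - 1
    return {"statistic": stat, "df": df,
            "p_value": float(sps.chi2.sf(stat, df)),
            "low_expected": bool(min(exp_s.min(), exp_f.min()) < 1)}


def welch_t_test(x, y, sides: int = 2) -> dict:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("need >= 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateInputError("both samples have zero variance")
    se2x = vx / x.size
    se2y = vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
    )
    if sides == 2:
        p = 2 * sps.t.sf(abs(t), df)
    elif sides == 1:
        p = sps.t.sf(t, df)
    else:
        raise InvalidParameterError("sides must be 1 or 2")
    return {"t": float(t), "df": float(df), "p_value": float(min(p, 1.0))}


@dataclass
class EnrichmentTable:
    """ChIP-qPCR-style fold enrichments (relative to a mock/IgG pull-down).

    targets: name -> replicate fold-enrichments of candidate peaks;
    controls: name -> replicate fold-enrichments of non-target loci."""

    targets: dict[str, list[float]]
    controls: dict[str, list[float]]

    def __post_init__(self):
        for name, vals in {**self.targets, **self.controls}.items():
            if len(vals) < 2:
                raise InvalidParameterError(f"{name}: need >= 2 replicates")
            if any(v <= 0 for v in vals):
                raise InvalidParameterError(f"{name}: enrichment must be > 0")


def enrichment_significance(
    table: EnrichmentTable, alpha_levels=(0.05, 0.01, 0.001)
) -> pd.DataFrame:
    """Per-target Welch test (two-sided) against the pooled controls.

    Verdict is the smallest alpha level passed, rendered with the usual
    star convention ('***' for 0.001), or 'ns'."""
    pooled = [v for vals in table.controls.values() for v in vals]
    levels = sorted(alpha_levels)
    stars = {a: "*" * (len(levels) - i) for i, a in enumerate(levels)}
    rows = []
    for name, vals in table.targets.items():
        res = welch_t_test(vals, pooled)
        verdict = "ns"
        for a in levels:
            if res["p_value"] < a:
                verdict = stars[a]
                break
        rows.append({"target": name, "mean_enrichment": float(np.mean(vals)),
                     "t": res["t"], "df": res["df"], "p_value": res["p_value"],
                     "verdict": verdict})
    return pd.DataFrame(rows)


@dataclass
class ROCResult:
    """Aligner accuracy against simulation truth.

    Negatives are decoy reads (source taxon != host): TN = decoy left
    unaligned; FP = decoy aligned anywhere plus host reads aligned
    off-locus.  With no decoy reads FPR has an empty denominator and is 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    tolerance: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def false_positive_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0


def roc_from_truth(
    alignments, truth: dict, tolerance: int = 5,
    host_taxon_id: str | None = None,
) -> ROCResult:
    """Confusion matrix of an aligner run on simulated reads.

    A host read is TP when placed on the truth chrom/strand within
    ``tolerance`` bp of the truth start, FN when unaligned, FP when placed
    elsewhere.  ``host_taxon_id=None`` treats every read as host."""
    tp = fp = fn = tn = 0
    for rec in alignments:
        if rec.read_id not in truth:
            raise DataIntegrityError(f"no truth for read {rec.read_id!r}")
        t = truth[rec.read_id]
        is_host = host_taxon_id is None or t.taxon_id == host_taxon_id
        if not rec.aligned:
            if is_host:
                fn += 1
            else:
                tn += 1
            continue
        if not is_host:
            fp += 1
            continue
        on_locus = (rec.chrom == t.chrom and rec.strand == t.strand
                    and abs(rec.start - t.start) <= tolerance)
        if on_locus:
            tp += 1
        else:
            fp += 1
    return ROCResult(tp, fp, fn, tn, tolerance)


def gc_content(seq_or_genome) -> float:
    """(G+C) / (A+C+G+T); N is excluded from the denominator."""
    if hasattr(seq_or_genome, "chromosomes"):
        seq = "".join(seq_or_genome.chromosomes.values())
    else:
        seq = str(seq_or_genome)
    if not seq:
        raise InvalidParameterError("empty sequence")
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    at = seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    if gc + at == 0:
        raise DegenerateInputError("GC content undefined: no A/C/G/T bases")
    return gc / (gc + at)
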