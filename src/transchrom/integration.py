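"""Downstream consequences of region categories.

Three analyses link the Shared / context-specific classification to other
molecular layers: relative expression of the gene nearest each summit,
CpG methylation of probes falling inside regions, and the repressive
H3K9me3 mark scored over regions in both contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .differential import A_SPECIFIC, B_SPECIFIC, SHARED, DifferentialResult
from .genome import GeneModel, nearest_tss
from .io_formats import AlignedReadSet, MethylationProbe
from .stats import TestResult, ks_two_sample, rank_sum, signed_rank

log = logging.getLogger(__name__)

NO_REGION = "NONE"  # background category for probes outside every region


@dataclass
class CategoryComparison:
    """Values contributing to one category's summary plus an optional test
    against the Shared baseline."""

    category: str
    values: list[float]
    median: float | None
    test: TestResult | None = None
    available: bool = True


def rpkm(read_count: int, transcript_length: int, mapped_reads: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be > 0")
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    return read_count / ((transcript_length / 1000.0) * (mapped_reads / 1e6))


def expression_from_counts(
    counts: Mapping[str, tuple[int, int]], lengths: Mapping[str, int]
) -> dict[str, tuple[float, float]]:
    """Convert per-gene context counts into per-context RPKM, using each
    context's total counts as the mapped-read denominator."""
    total_a = sum(a for a, _ in counts.values())
    total_b = sum(b for _, b in counts.values())
    return {
        gid: (rpkm(a, lengths[gid], total_a), rpkm(b, lengths[gid], total_b))
        for gid, (a, b) in counts.items()
    }


def expression_by_category(
    results: Sequence[DifferentialResult],
    genes: Sequence[GeneModel],
    expression: Mapping[str, tuple[float, float]],
    pseudocount: float = 1.0,
) -> dict[str, CategoryComparison]:
    """Relative expression (log2 RPKM ratio, A over B) of nearest genes,
    grouped by region category.

    Each summit is assigned its nearest TSS; genes hit by several regions
    count once per category.  The A-specific category carries a one-sided
    rank-sum test of whether its genes are shifted up relative to Shared
    (and symmetrically for B-specific, testing a downward shift).
    """
    genes_by_cat: dict[str, dict[str, float]] = {}
    for r in results:
        if r.category is None:
            raise ValueError("results must be classified first")
        gid, _ = nearest_tss(r.summit, genes)
        if gid not in expression:
            continue
        a, b = expression[gid]
        ratio = float(np.log2((a + pseudocount) / (b + pseudocount)))
        genes_by_cat.setdefault(r.category, {})[gid] = ratio

    out: dict[str, CategoryComparison] = {}
    shared_vals = list(genes_by_cat.get(SHARED, {}).values())
    for cat in (SHARED, A_SPECIFIC, B_SPECIFIC):
        vals = list(genes_by_cat.get(cat, {}).values())
        if not vals:
            out[cat] = CategoryComparison(cat, [], None, available=False)
            continue
        test = None
        if cat != SHARED and shared_vals:
            direction = "greater" if cat == A_SPECIFIC else "less"
            test = rank_sum(vals, shared_vals, direction=direction)
        out[cat] = CategoryComparison(cat, vals, float(np.median(vals)), test)
    return out


def filter_probes_control(
    probes: Sequence[MethylationProbe], alpha: float = 0.01
) -> list[MethylationProbe]:
    """Drop probes detectably hybridising in the no-chromosome control
    (control detection p <= alpha): these cross-hybridise with the host
    genome and would contaminate the methylation signal."""
    kept = [p for p in probes if p.control_detection_p > alpha]
    log.info("control-probe filter removed %d of %d probes", len(probes) - len(kept), len(probes))
    return kept


@dataclass
class MethylationCategoryResult:
    category: str
    betas: dict[str, list[float]]  # context -> per-probe betas (replicate-averaged)
    medians: dict[str, float]
    test: TestResult | None  # two-sided rank-sum between contexts
    available: bool = True


def methylation_by_category(
    probes: Sequence[MethylationProbe],
    results: Sequence[DifferentialResult],
    context_of: Mapping[str, str],
) -> dict[str, MethylationCategoryResult]:
    """Aggregate probe betas per (region category, context).

    A probe belongs to the first (leftmost) region containing its
    position, or to the background category when no region contains it.
    Replicate betas are averaged per probe per context so probes, not
    arrays, are the sampling unit; contexts are compared per category with
    a two-sided rank-sum test.
    """
    contexts = sorted(set(context_of.values()))
    regions = sorted(
        [r for r in results],
        key=lambda r: r.region.start,
    )
    by_cat: dict[str, dict[str, list[float]]] = {}
    for probe in probes:
        cat = NO_REGION
        for r in regions:
            if r.region.contains_point(probe.position):
                cat = r.category or NO_REGION
                break
        entry = by_cat.setdefault(cat, {c: [] for c in contexts})
        for ctx in contexts:
            cols = [s for s, c in context_of.items() if c == ctx and s in probe.betas]
            if cols:
                entry[ctx].append(float(np.mean([probe.betas[s] for s in cols])))

    out: dict[str, MethylationCategoryResult] = {}
    for cat in (SHARED, A_SPECIFIC, B_SPECIFIC, NO_REGION):
        entry = by_cat.get(cat)
        if entry is None or all(len(v) == 0 for v in entry.values()):
            out[cat] = MethylationCategoryResult(cat, {}, {}, None, available=False)
            continue
        medians = {c: float(np.median(v)) for c, v in entry.items() if v}
        test = None
        if len(contexts) == 2 and all(entry[c] for c in contexts):
            test = rank_sum(entry[contexts[0]], entry[contexts[1]], direction="two_sided")
        out[cat] = MethylationCategoryResult(cat, entry, medians, test)
    return out


@dataclass
class RepressionResult:
    """H3K9me3 scores per (context, category) with the category contrasts.

    ``within_context`` holds, per context, the rank-sum and KS comparisons
    of specific-category versus Shared region scores; ``between_context``
    holds, per category, the matched-pairs signed-rank test of the same
    regions across contexts.
    """

    scores: dict[tuple[str, str], list[float]]  # (context, category) -> per-region score
    within_context: dict[str, dict[str, TestResult]]
    between_context: dict[str, TestResult]


def repression_by_category(
    h3k9me3_readsets: Sequence[AlignedReadSet],
    results: Sequence[DifferentialResult],
    specific_category: str = A_SPECIFIC,
) -> RepressionResult:
    """Score the repressive mark over classified regions in both contexts.

    Per region and replicate the midpoint count is scaled to the median
    H3K9me3 library size and transformed log2(count + 1); replicates are
    averaged.  Within each context the specific category is compared to
    Shared (two-sided rank-sum plus KS distance); across contexts the same
    regions are compared with the matched-pairs signed-rank test.
    """
    if not h3k9me3_readsets:
        raise ValueError("need at least one H3K9me3 read set")
    contexts = sorted({rs.context for rs in h3k9me3_readsets})
    lib = np.array([rs.library_size for rs in h3k9me3_readsets], dtype=float)
    med = np.median(lib)
    starts = np.array([r.region.start for r in results], dtype=np.int64)
    ends = np.array([r.region.end for r in results], dtype=np.int64)
    order = np.argsort(starts)
    scores_mat: dict[str, np.ndarray] = {}
    for ctx in contexts:
        sets = [rs for rs in h3k9me3_readsets if rs.context == ctx]
        per_rep = []
        for rs in sets:
            mids = rs.midpoints
            idx = np.searchsorted(starts[order], mids, side="right") - 1
            valid = (idx >= 0) & (mids < ends[order][np.clip(idx, 0, None)])
            raw = np.bincount(idx[valid], minlength=len(results)).astype(float)
            unordered = np.empty_like(raw)
            unordered[order] = raw
            per_rep.append(np.log2(unordered * (med / rs.library_size) + 1.0))
        scores_mat[ctx] = np.mean(per_rep, axis=0)

    scores: dict[tuple[str, str], list[float]] = {}
    cats = [r.category for r in results]
    for ctx in contexts:
        for cat in (SHARED, specific_category):
            mask = [c == cat for c in cats]
            scores[(ctx, cat)] = [float(s) for s, m in zip(scores_mat[ctx], mask) if m]

    within: dict[str, dict[str, TestResult]] = {}
    for ctx in contexts:
        spec = scores.get((ctx, specific_category), [])
        shared = scores.get((ctx, SHARED), [])
        if spec and shared:
            within[ctx] = {
                "rank_sum": rank_sum(spec, shared, direction="two_sided"),
                "ks": ks_two_sample(spec, shared),
            }
    between: dict[str, TestResult] = {}
    if len(contexts) == 2:
        c0, c1 = contexts
        for cat in (SHARED, specific_category):
            mask = [c == cat for c in cats]
            if any(mask):
                x = [float(s) for s, m in zip(scores_mat[c0], mask) if m]
                y = [float(s) for s, m in zip(scores_mat[c1], mask) if m]
                between[cat] = signed_rank(x, y, direction="two_sided")
    return RepressionResult(scores=scores, within_context=within, between_context=between)
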