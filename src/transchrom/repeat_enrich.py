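"""Repetitive-element analyses at region summits.

Associates summits with the repeat instance covering them, profiles the
fraction of summit-centred windows covered by repeats, tests per-family
enrichment between context-specific and shared regions with a 2x2
chi-square, compares repeat ages (RepeatMasker divergence, lower =
younger) between categories, and tallies repeat lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import RepeatInstance
from .stats import TestResult, chi_square_2x2, rank_sum

SPECIFIC = "SPECIFIC"
SHARED = "SHARED"


@dataclass(frozen=True)
class RepeatEnrichmentRow:
    """One family's 2x2 enrichment result between region categories."""

    repeat_name: str
    n_specific_with: int
    n_specific_without: int
    n_shared_with: int
    n_shared_without: int
    chi2: float
    p: float
    neg_log10_p: float
    direction: str  # "specific" or "shared": the side with the higher with-repeat proportion
    significant: bool


@dataclass(frozen=True)
class AgeComparison:
    test: TestResult
    median_specific: float
    median_shared: float


def summit_repeat(summit: int, repeats: Sequence[RepeatInstance]) -> RepeatInstance | None:
    """The repeat instance containing the summit point, or None.

    ``repeats`` must be sorted by start.  With overlapping annotations the
    instance with the smallest start wins.
    """
    for r in repeats:
        if r.location.start > summit:
            break
        if r.location.contains_point(summit):
            return r
    return None


def _merged_coverage(repeats: Sequence[RepeatInstance]) -> tuple[np.ndarray, np.ndarray]:
    """Union of repeat intervals as sorted disjoint (starts, ends) arrays."""
    if not repeats:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs = sorted((r.location.start, r.location.end) for r in repeats)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def fraction_profile(
    summits: Sequence[int],
    repeats: Sequence[RepeatInstance],
    half_width: int = 5000,
    bin: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of summits whose window position is inside any repeat.

    For each offset bin in [-half_width, +half_width) the bin-centre
    position relative to every summit is tested for repeat coverage;
    returns (offsets, fractions).  This is the 10 kb summit-window repeat
    profile when half_width is 5000.
    """
    if len(summits) == 0:
        raise ValueError("summit list is empty")
    offsets = np.arange(-half_width, half_width, bin) + bin // 2
    starts, ends = _merged_coverage(repeats)
    if starts.size == 0:
        return offsets, np.zeros(offsets.size)
    positions = np.asarray(summits, dtype=np.int64)[:, None] + offsets[None, :]
    idx = np.searchsorted(starts, positions, side="right") - 1
    covered = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
    return offsets, covered.mean(axis=0)


def family_enrichment(
    categorized_summits: Sequence[tuple[str, int]],
    repeats: Sequence[RepeatInstance],
    families: Iterable[str] | None = None,
    by: str = "name",
    alpha: float = 0.05,
) -> list[RepeatEnrichmentRow]:
    """Per-family (or per-class, ``by='class'``) 2x2 chi-square enrichment.

    Rows compare, for each family, the proportion of context-specific
    versus shared summits lying inside an instance of that family.
    Rows with p <= alpha are flagged significant, mirroring the study's
    display rule; stricter control can be layered with
    :func:`transchrom.stats.bh_fdr` on the returned p-values.
    """
    repeats = sorted(repeats, key=lambda r: r.location.start)
    cats = {c for c, _ in categorized_summits}
    if SPECIFIC not in cats or SHARED not in cats:
        raise ValueError("both SPECIFIC and SHARED categories are required")
    key = (lambda r: r.name) if by == "name" else (lambda r: r.repeat_class)
    hits: list[tuple[str, str | None]] = []
    for cat, summit in categorized_summits:
        rep = summit_repeat(summit, repeats)
        hits.append((cat, key(rep) if rep is not None else None))
    if families is None:
        families = sorted({f for _, f in hits if f is not None})
    n_spec = sum(1 for c, _ in hits if c == SPECIFIC)
    n_shared = sum(1 for c, _ in hits if c == SHARED)
    rows: list[RepeatEnrichmentRow] = []
    for fam in families:
        a = sum(1 for c, f in hits if c == SPECIFIC and f == fam)
        c = sum(1 for cc, f in hits if cc == SHARED and f == fam)
        b, d = n_spec - a, n_shared - c
        res = chi_square_2x2(a, b, c, d)
        prop_spec = a / n_spec if n_spec else 0.0
        prop_shared = c / n_shared if n_shared else 0.0
        direction = "specific" if prop_spec >= prop_shared else "shared"
        p_safe = max(res.p_value, 1e-300)
        rows.append(
            RepeatEnrichmentRow(
                repeat_name=fam,
                n_specific_with=a,
                n_specific_without=b,
                n_shared_with=c,
                n_shared_without=d,
                chi2=res.statistic,
                p=res.p_value,
                neg_log10_p=float(-np.log10(p_safe)),
                direction=direction,
                significant=res.p_value <= alpha,
            )
        )
    rows.sort(key=lambda r: r.p)
    return rows


def age_comparison(
    divergences_specific: Sequence[float], divergences_shared: Sequence[float]
) -> AgeComparison:
    """Two-sided rank-sum comparison of repeat divergences between
    categories; lower divergence means younger insertions."""
    if len(divergences_specific) == 0 or len(divergences_shared) == 0:
        raise ValueError("both divergence lists must be non-empty")
    test = rank_sum(divergences_specific, divergences_shared, direction="two_sided")
    return AgeComparison(
        test=test,
        median_specific=float(np.median(divergences_specific)),
        median_shared=float(np.median(divergences_shared)),
    )


def lineage_breakdown(
    categorized_repeats: Sequence[tuple[str, RepeatInstance]],
) -> dict[str, dict[str, dict[str, float]]]:
    """Tally repeat lineages per region category.

    Returns {category: {"counts": {lineage: n}, "fractions": {lineage: f}}}
    with fractions summing to 1 within each non-empty category; repeats of
    unknown lineage are counted under "unknown".
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for cat, rep in categorized_repeats:
        counts = out.setdefault(cat, {"counts": {}, "fractions": {}})["counts"]
        counts[rep.lineage] = counts.get(rep.lineage, 0) + 1
    for cat, entry in out.items():
        total = sum(entry["counts"].values())
        entry["fractions"] = {k: v / total for k, v in entry["counts"].items()}
    return out


def write_enrichment_table(rows: Sequence[RepeatEnrichmentRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#repeat_name\tn_specific_with\tn_specific_without\tn_shared_with\tn_shared_without\t"
            "chi2\tp\tneg_log10_p\tdirection\tsignificant\n"
        )
        for r in rows:
            fh.write(
                f"{r.repeat_name}\t{r.n_specific_with}\t{r.n_specific_without}\t{r.n_shared_with}\t"
                f"{r.n_shared_without}\t{r.chi2:.4f}\t{r.p:.6g}\t{r.neg_log10_p:.4f}\t{r.direction}\t"
                f"{int(r.significant)}\n"
            )


def write_profile_table(offsets: np.ndarray, fractions_by_label: dict[str, np.ndarray], path) -> None:
    labels = sorted(fractions_by_label)
    with open(path, "w") as fh:
        fh.write("#offset\t" + "\t".join(labels) + "\n")
        for i, off in enumerate(offsets):
            vals = "\t".join(f"{fractions_by_label[l][i]:.4f}" for l in labels)
            fh.write(f"{off}\t{vals}\n")
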