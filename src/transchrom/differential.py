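"""Differential chromatin activation between two nuclear contexts.

Per-sample called regions are merged into a consensus set, reads are
counted at consensus regions and normalised to the median library size,
and each region is tested for a context difference with a negative-
binomial likelihood-ratio test using a common moment-matched dispersion.
Regions are then classified Shared / A-specific / B-specific at the study
thresholds: at least 4-fold difference in normalised means with
Benjamini-Hochberg FDR < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .genome import GenomicInterval
from .io_formats import AlignedReadSet
from .peakcall import EnrichedRegion
from .stats import bh_fdr

SHARED = "SHARED"
A_SPECIFIC = "A_SPECIFIC"
B_SPECIFIC = "B_SPECIFIC"


@dataclass(frozen=True)
class ConsensusRegion:
    """A merged cross-sample region carrying the summit of its strongest
    contributing call and the number of supporting input sets."""

    location: GenomicInterval
    summit: int
    support: int


@dataclass
class CountMatrix:
    """Read counts at consensus regions, one column per sample."""

    regions: list[ConsensusRegion]
    samples: list[tuple[str, str, int]]  # (sample_id, context, replicate)
    counts: np.ndarray  # regions x samples, raw
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("count matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def normalized(self) -> np.ndarray:
        """Counts scaled to the median library size, so values stay on a
        count-like scale suitable for the NB model."""
        med = np.median(self.library_sizes)
        return self.counts * (med / self.library_sizes)


@dataclass
class DifferentialResult:
    region: GenomicInterval
    summit: int
    mean_norm_a: float
    mean_norm_b: float
    log2fc: float
    p_value: float
    fdr: float | None = None
    category: str | None = None


def build_consensus(
    region_sets: Sequence[Sequence[EnrichedRegion]], min_support: int = 1
) -> list[ConsensusRegion]:
    """Merge called regions across samples into a consensus set.

    Regions overlapping by >= 1 bp merge transitively; a merged region is
    kept when at least ``min_support`` distinct input sets contributed to
    it.  The consensus summit is the summit of the contributing call with
    the highest fold enrichment (leftmost summit on ties).
    """
    if not region_sets:
        raise ValueError("need at least one region set")
    tagged = [
        (r, set_idx)
        for set_idx, regions in enumerate(region_sets)
        for r in regions
    ]
    if not tagged:
        return []
    tagged.sort(key=lambda t: (t[0].location.start, t[0].location.end))
    out: list[ConsensusRegion] = []
    cluster: list[tuple[EnrichedRegion, int]] = [tagged[0]]
    cur_end = tagged[0][0].location.end

    def flush() -> None:
        supports = {idx for _, idx in cluster}
        if len(supports) < min_support:
            return
        start = min(r.location.start for r, _ in cluster)
        end = max(r.location.end for r, _ in cluster)
        best = max(cluster, key=lambda t: (t[0].fold_enrichment, -t[0].summit))[0]
        out.append(
            ConsensusRegion(
                location=GenomicInterval(best.location.chrom, start, end),
                summit=best.summit,
                support=len(supports),
            )
        )

    for r, idx in tagged[1:]:
        if r.location.start < cur_end:  # >=1 bp overlap with the cluster span
            cluster.append((r, idx))
            cur_end = max(cur_end, r.location.end)
        else:
            flush()
            cluster = [(r, idx)]
            cur_end = r.location.end
    flush()
    out.sort(key=lambda c: c.location.start)
    return out


def count_and_normalize(
    consensus: Sequence[ConsensusRegion], readsets: Sequence[AlignedReadSet]
) -> CountMatrix:
    """Count read midpoints falling in each consensus region.

    Consensus regions are disjoint by construction, so midpoint assignment
    is unambiguous.  Normalisation (exposed via ``CountMatrix.normalized``)
    scales each sample to the median library size.
    """
    regions = sorted(consensus, key=lambda c: c.location.start)
    starts = np.array([c.location.start for c in regions], dtype=np.int64)
    ends = np.array([c.location.end for c in regions], dtype=np.int64)
    counts = np.zeros((len(regions), len(readsets)), dtype=np.int64)
    for j, rs in enumerate(readsets):
        if len(regions) == 0:
            continue
        mids = rs.midpoints
        idx = np.searchsorted(starts, mids, side="right") - 1
        valid = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
        counts[:, j] = np.bincount(idx[valid], minlength=len(regions))
    return CountMatrix(
        regions=list(regions),
        samples=[(rs.sample_id, rs.context, rs.replicate) for rs in readsets],
        counts=counts,
        library_sizes=np.array([rs.library_size for rs in readsets]),
    )


def _nb_loglik(k: np.ndarray, mu: float, phi: float) -> float:
    """Log-likelihood of (possibly non-integer, normalised) counts under an
    NB2 model with fixed dispersion phi (variance mu + phi mu^2); Poisson
    when phi == 0.  The gamma-function form extends smoothly to
    non-integer k."""
    mu = max(mu, 1e-8)
    if phi <= 0:
        return float(np.sum(k * np.log(mu) - mu - gammaln(k + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(k + r)
            - gammaln(r)
            - gammaln(k + 1)
            + r * np.log(r / (r + mu))
            + k * np.log(mu / (r + mu))
        )
    )


def estimate_dispersion(norm_counts: np.ndarray) -> float:
    """Common dispersion by method of moments pooled over regions:
    the median over regions of max(0, (s^2 - mu) / mu^2)."""
    mu = norm_counts.mean(axis=1)
    s2 = norm_counts.var(axis=1, ddof=1)
    ok = mu > 0
    if not np.any(ok):
        return 0.0
    phi = np.maximum(0.0, (s2[ok] - mu[ok]) / mu[ok] ** 2)
    return float(np.median(phi))


def nb_test(matrix: CountMatrix, dispersion: float | None = None) -> list[DifferentialResult]:
    """Per-region likelihood-ratio test of equal context means.

    A common dispersion is moment-estimated across regions (or fixed via
    ``dispersion``; 0 gives the Poisson model); each region is then tested
    with a 1-df chi-square LRT of one shared mean versus one mean per
    context.  log2 fold change is computed on normalised means with a
    pseudocount of 1.
    """
    contexts = [s[1] for s in matrix.samples]
    in_a = np.array([c == "A" for c in contexts])
    in_b = ~in_a
    if not in_a.any() or not in_b.any():
        raise ValueError("both contexts need at least one sample")
    norm = matrix.normalized
    phi = estimate_dispersion(norm) if dispersion is None else dispersion
    results: list[DifferentialResult] = []
    for i, region in enumerate(matrix.regions):
        k = norm[i]
        ka, kb = k[in_a], k[in_b]
        mean_a, mean_b = float(ka.mean()), float(kb.mean())
        ll_null = _nb_loglik(k, float(k.mean()), phi)
        ll_alt = _nb_loglik(ka, mean_a, phi) + _nb_loglik(kb, mean_b, phi)
        lr = max(0.0, 2.0 * (ll_alt - ll_null))
        p = float(sps.chi2.sf(lr, df=1)) if lr > 0 else 1.0
        results.append(
            DifferentialResult(
                region=region.location,
                summit=region.summit,
                mean_norm_a=mean_a,
                mean_norm_b=mean_b,
                log2fc=float(np.log2((mean_a + 1.0) / (mean_b + 1.0))),
                p_value=p,
            )
        )
    return results


def classify_regions(
    results: Sequence[DifferentialResult],
    fold_threshold: float = 4.0,
    fdr_threshold: float = 0.1,
) -> list[DifferentialResult]:
    """Attach BH FDR and the Shared / A-specific / B-specific label.

    A region is context-specific when its normalised means differ by at
    least ``fold_threshold`` (inclusive) and its FDR is strictly below
    ``fdr_threshold``; everything else is Shared.
    """
    if fold_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    qs = bh_fdr([r.p_value for r in results])
    lfc_cut = float(np.log2(fold_threshold))
    out: list[DifferentialResult] = []
    for r, q in zip(results, qs):
        if r.log2fc >= lfc_cut and q < fdr_threshold:
            cat = A_SPECIFIC
        elif r.log2fc <= -lfc_cut and q < fdr_threshold:
            cat = B_SPECIFIC
        else:
            cat = SHARED
        out.append(replace(r, fdr=q, category=cat))
    return out


def write_results_table(results: Sequence[DifferentialResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsummit\tmean_norm_A\tmean_norm_B\tlog2fc\tp_value\tfdr\tcategory\n")
        for r in results:
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t{r.summit}\t"
                f"{r.mean_norm_a:.4f}\t{r.mean_norm_b:.4f}\t{r.log2fc:.4f}\t"
                f"{r.p_value:.6g}\t{r.fdr:.6g}\t{r.category}\n"
            )
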