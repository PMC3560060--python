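"""Coordinate conventions and interval arithmetic.

Every coordinate in this package is 0-based, half-open (BED-native):
an interval ``[start, end)`` covers positions ``start .. end-1``.  All
conversions from 1-based formats happen at the IO boundary
(:mod:`transchrom.io_formats`), never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A span ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must be strictly greater than ``start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if not self.start < self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics:
        ``[a,b)`` and ``[b,c)`` do not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with a transcription start site and a spliced transcript length.

    ``transcript_length`` is the exon sum (what RPKM divides by), not the
    genomic span of ``body``.
    """

    gene_id: str
    tss: int
    transcript_length: int
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.transcript_length <= 0:
            raise ValueError("transcript_length must be > 0")
        if not self.body.contains_point(self.tss):
            raise ValueError(f"TSS {self.tss} outside gene body of {self.gene_id}")
        if self.transcript_length > len(self.body):
            raise ValueError(
                f"transcript_length {self.transcript_length} exceeds body span of {self.gene_id}"
            )


def make_window(summit: int, half_width: int, chrom_length: int, chrom: str = "chrA") -> GenomicInterval:
    """Window of ``2 * half_width`` bp centred on a summit, clipped to the
    chromosome.

    Raises ``ValueError`` when the summit itself lies outside the chromosome
    (inconsistent annotation rather than a clippable edge case).
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    if not 0 <= summit < chrom_length:
        raise ValueError(f"summit {summit} outside chromosome of length {chrom_length}")
    return GenomicInterval(chrom, max(0, summit - half_width), min(chrom_length, summit + half_width))


def nearest_tss(summit: int, genes: Sequence[GeneModel]) -> tuple[str, int]:
    """Gene whose TSS is closest to ``summit`` and the signed distance
    ``tss - summit``.

    Ties on absolute distance are broken by the lexicographically smaller
    ``gene_id`` so the assignment is deterministic.
    """
    if not genes:
        raise ValueError("gene list is empty")
    best = min(genes, key=lambda g: (abs(g.tss - summit), g.gene_id))
    return best.gene_id, best.tss - summit


def apply_exclusion(
    regions: Iterable[GenomicInterval], exclusion: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop every region that overlaps (>= 1 bp) any exclusion interval.

    Order of the surviving regions is preserved; an empty exclusion list is
    the identity.  Used to remove known deleted and alpha-satellite spans
    before any counting.
    """
    if not exclusion:
        return list(regions)
    return [r for r in regions if not any(r.overlaps(e) for e in exclusion)]
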