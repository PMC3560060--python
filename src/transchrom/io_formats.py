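"""Readers and writers for the pipeline's external formats.

All on-disk coordinates follow each format's native convention
(RepeatMasker ``.out`` is 1-based inclusive, BED is 0-based half-open);
everything in memory is 0-based half-open.  Conversions happen here and
nowhere else.  Tabular outputs are tab-separated with a header line
beginning ``#``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import GeneModel, GenomicInterval

log = logging.getLogger(__name__)

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "SVA", "Satellite")
LINEAGES = ("human", "primate", "eutherian", "ancestral", "unknown")


@dataclass
class AlignedReadSet:
    """Aligned reads of one sample on the analysis chromosome.

    Reads are kept as parallel start/end arrays; counting downstream uses
    read midpoints, so fragment geometry beyond the alignment interval is
    never modelled.  ``library_size`` is the number of retained reads after
    any mapping-quality filtering.
    """

    sample_id: str
    context: str  # "A" or "B"
    assay: str  # e.g. "H3K4me3", "H3K9me3", "input", "TF:CTCF"
    replicate: int
    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    mapq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts/ends length mismatch")
        if self.mapq is not None:
            self.mapq = np.asarray(self.mapq, dtype=np.int64)
            if self.mapq.shape != self.starts.shape:
                raise ValueError("mapq length mismatch")

    @property
    def library_size(self) -> int:
        return int(self.starts.size)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass(frozen=True)
class RepeatInstance:
    """One RepeatMasker annotation row.

    ``divergence`` is stored in milliDiv (substitutions per 1000 bp of the
    family consensus); lower divergence means a younger insertion.
    """

    location: GenomicInterval
    name: str
    repeat_class: str
    divergence: float
    lineage: str = "unknown"

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")


@dataclass(frozen=True)
class MethylationProbe:
    """A CpG methylation probe with per-sample beta values.

    ``control_detection_p`` is the detection p-value of the probe in a
    control sample that does not carry the analysis chromosome; a small
    value flags cross-hybridisation and the probe is excluded downstream.
    """

    probe_id: str
    position: int
    betas: Mapping[str, float]  # sample column -> beta in [0, 1]
    control_detection_p: float

    def __post_init__(self) -> None:
        for sample, b in self.betas.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"beta {b} for {sample} outside [0, 1]")


# ---------------------------------------------------------------------------
# reads


def apply_mapq_filter(readset: AlignedReadSet) -> AlignedReadSet:
    """Drop reads with mapping quality 0, keeping uniquely mapping reads.
    Identity when the read set carries no mapping qualities."""
    if readset.mapq is None:
        return readset
    keep = readset.mapq > 0
    return AlignedReadSet(
        sample_id=readset.sample_id,
        context=readset.context,
        assay=readset.assay,
        replicate=readset.replicate,
        chrom=readset.chrom,
        starts=readset.starts[keep],
        ends=readset.ends[keep],
        mapq=readset.mapq[keep],
    )


def read_reads(
    path: str | Path,
    sample_id: str,
    context: str,
    assay: str,
    replicate: int = 1,
    mapq_filter: bool = True,
) -> AlignedReadSet:
    """Read a BED-like alignment file (chrom, start, end[, name, score]).

    The score column is interpreted as mapping quality; with
    ``mapq_filter`` on (the default) reads with mapping quality 0 are
    dropped, keeping only uniquely mapping reads.
    """
    starts: list[int] = []
    ends: list[int] = []
    mapqs: list[int] = []
    chrom = None
    has_mapq = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate {start}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval [{start}, {end})")
            if chrom is None:
                chrom = fields[0]
            elif fields[0] != chrom:
                raise ValueError(
                    f"{path}:{lineno}: multiple chromosomes ({chrom!r}, {fields[0]!r}); "
                    "one analysis chromosome expected"
                )
            mq = 255
            if len(fields) >= 5:
                has_mapq = True
                try:
                    mq = int(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer mapping quality") from exc
                if mq < 0:
                    raise ValueError(f"{path}:{lineno}: negative mapping quality")
            starts.append(start)
            ends.append(end)
            mapqs.append(mq)

    st = np.array(starts, dtype=np.int64)
    en = np.array(ends, dtype=np.int64)
    mq_arr = np.array(mapqs, dtype=np.int64)
    if mapq_filter and has_mapq:
        keep = mq_arr > 0
        st, en, mq_arr = st[keep], en[keep], mq_arr[keep]
    return AlignedReadSet(
        sample_id=sample_id,
        context=context,
        assay=assay,
        replicate=replicate,
        chrom=chrom if chrom is not None else "NA",
        starts=st,
        ends=en,
        mapq=mq_arr if has_mapq else None,
    )


def write_reads(readset: AlignedReadSet, path: str | Path) -> None:
    """Write reads as BED5 (name=read index, score=mapping quality)."""
    with open(path, "w") as fh:
        mq = readset.mapq if readset.mapq is not None else np.full(readset.library_size, 255)
        for i, (s, e, q) in enumerate(zip(readset.starts, readset.ends, mq)):
            fh.write(f"{readset.chrom}\t{s}\t{e}\tread{i}\t{q}\n")


# ---------------------------------------------------------------------------
# RepeatMasker


def _parse_repeat_class(class_family: str) -> str:
    head = class_family.split("/")[0]
    # RepeatMasker writes e.g. LINE/L1, SINE/Alu, LTR/ERV1, DNA/hAT, Satellite/centr
    for known in REPEAT_CLASSES:
        if head == known or head.startswith(known):
            return known
    return "Other"


def read_repeatmasker_out(
    path: str | Path, lineage_map: Mapping[str, str] | None = None
) -> list[RepeatInstance]:
    """Parse a RepeatMasker ``.out`` file.

    The format has three header lines; query coordinates are 1-based
    inclusive and become 0-based half-open (``begin - 1``, ``end``).
    Percent divergence is stored as milliDiv (x10).  Unknown repeat
    classes map to ``Other`` with a logged warning.
    """
    repeats: list[RepeatInstance] = []
    lineage_map = lineage_map or {}
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 14:
            raise ValueError(f"{path}:{lineno}: expected >= 14 RepeatMasker columns")
        perc_div = float(f[1])
        chrom, qbegin, qend = f[4], int(f[5]), int(f[6])
        strand = "+" if f[8] == "+" else "-"
        name, class_family = f[9], f[10]
        repeat_class = _parse_repeat_class(class_family)
        if repeat_class == "Other" and class_family.split("/")[0] not in ("Other", "Unknown"):
            log.warning("unknown repeat class %r at %s:%d mapped to Other", class_family, path, lineno)
        repeats.append(
            RepeatInstance(
                location=GenomicInterval(chrom, qbegin - 1, qend, strand),
                name=name,
                repeat_class=repeat_class,
                divergence=perc_div * 10.0,
                lineage=lineage_map.get(name, "unknown"),
            )
        )
    return repeats


_RM_HEADER = (
    "   SW  perc perc perc  query     position in query          matching  repeat         position in repeat\n"
    "score  div. del. ins.  sequence  begin    end       (left)  repeat    class/family   begin  end    (left)  ID\n"
    "\n"
)


def write_repeatmasker_out(repeats: Sequence[RepeatInstance], path: str | Path) -> None:
    """Write repeats back out in RepeatMasker ``.out`` layout (1-based
    inclusive query coordinates, percent divergence)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats, start=1):
            loc = r.location
            strand = "+" if loc.strand != "-" else "C"
            cls = r.repeat_class if r.repeat_class != "Other" else "Unknown"
            fh.write(
                f"{1000:>5} {r.divergence / 10.0:5.1f}  0.0  0.0  {loc.chrom}  "
                f"{loc.start + 1}  {loc.end}  (0)  {strand}  {r.name}  {cls}/{r.name}  1  {len(loc)}  (0)  {i}\n"
            )


def write_lineage_table(lineages: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#family\tlineage\n")
        for name in sorted(lineages):
            fh.write(f"{name}\t{lineages[name]}\n")


def read_lineage_table(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, lineage = line.rstrip("\n").split("\t")
            out[name] = lineage
    return out


# ---------------------------------------------------------------------------
# BED intervals and genes


def write_bed(regions: Sequence[GenomicInterval], path: str | Path, names: Sequence[str] | None = None) -> None:
    """Write intervals as BED6 (score 0); lossless against :func:`read_bed`."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = names[i] if names is not None else f"region{i}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12.

    The TSS is the 5' end of the annotated strand; transcript length is the
    sum of block sizes (the spliced length RPKM divides by), not the genomic
    span.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene_id, strand = f[3], f[5]
            block_sizes = [int(s) for s in f[10].rstrip(",").split(",")]
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    tss=tss,
                    transcript_length=sum(block_sizes),
                    body=GenomicInterval(chrom, start, end, strand),
                )
            )
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as single-block BED12 rows whose block size equals
    the transcript length (block anchored at the TSS-proximal end)."""
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            block_start = 0 if b.strand == "+" else len(b) - g.transcript_length
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{b.strand}\t"
                f"{b.start}\t{b.end}\t0\t1\t{g.transcript_length},\t{block_start},\n"
            )


# ---------------------------------------------------------------------------
# methylation and expression tables


def write_methylation_table(probes: Sequence[MethylationProbe], path: str | Path) -> None:
    if not probes:
        raise ValueError("no probes to write")
    samples = list(probes[0].betas)
    with open(path, "w") as fh:
        fh.write("#probe_id\tposition\tcontrol_detection_p\t" + "\t".join(samples) + "\n")
        for p in probes:
            betas = "\t".join(f"{p.betas[s]:.6g}" for s in samples)
            fh.write(f"{p.probe_id}\t{p.position}\t{p.control_detection_p:.6g}\t{betas}\n")


def read_methylation_table(path: str | Path) -> list[MethylationProbe]:
    """Read the methylation TSV (probe_id, position, control_detection_p,
    one beta column per sample).  Betas outside [0, 1] are an error."""
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        required = ["probe_id", "position", "control_detection_p"]
        for col in required:
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        sample_cols = [c for c in header if c not in required]
        idx = {c: header.index(c) for c in header}
        probes: list[MethylationProbe] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            betas = {c: float(f[idx[c]]) for c in sample_cols}
            probes.append(
                MethylationProbe(
                    probe_id=f[idx["probe_id"]],
                    position=int(f[idx["position"]]),
                    betas=betas,
                    control_detection_p=float(f[idx["control_detection_p"]]),
                )
            )
    return probes


def write_expression_table(
    table: Mapping[str, tuple[int, int]],
    lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write per-gene read counts for the two contexts (gene_id, length,
    count_A, count_B)."""
    with open(path, "w") as fh:
        fh.write("#gene_id\tlength\tcount_A\tcount_B\n")
        for gid in sorted(table):
            a, b = table[gid]
            fh.write(f"{gid}\t{lengths[gid]}\t{a}\t{b}\n")


def read_expression_table(path: str | Path) -> tuple[dict[str, tuple[int, int]], dict[str, int]]:
    counts: dict[str, tuple[int, int]] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        for col in ("gene_id", "length", "count_A", "count_B"):
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gid = f[idx["gene_id"]]
            counts[gid] = (int(f[idx["count_A"]]), int(f[idx["count_B"]]))
            lengths[gid] = int(f[idx["length"]])
    return counts, lengths
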