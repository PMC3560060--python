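"""Synthetic transchromosomic dataset generator with ground truth.

One chromosome sequence is "measured" in two nuclear contexts, A and B.
The generator emulates the structure such a design produces:

* a repeat-annotated chromosome whose instances carry lineages and
  divergences (young human/primate insertions vs old eutherian/ancestral
  ones);
* activation (H3K4me3) regions that are either shared between contexts or
  specific to one context, with the context-specific class seeded
  preferentially inside instances of one young LTR/LINE family;
* ChIP and input read sets per context and replicate, with a mapping-
  quality-zero fraction on repeat-derived reads;
* CpG probe methylation anticorrelated with activation;
* elevated repressive H3K9me3 signal at context-specific regions in the
  context where they are silent;
* expression up-shift of genes nearest context-specific regions.

Every random draw flows from one seed, so a fixed configuration produces
a byte-identical file bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .differential import A_SPECIFIC, B_SPECIFIC, SHARED, DifferentialResult
from .genome import GeneModel, GenomicInterval
from .io_formats import (
    AlignedReadSet,
    MethylationProbe,
    RepeatInstance,
    write_bed,
    write_expression_table,
    write_genes,
    write_lineage_table,
    write_methylation_table,
    write_reads,
    write_repeatmasker_out,
)

# name, class, lineage, relative abundance within class; young lineages are
# human/primate.  Abundances skew old: most of a mammalian chromosome's
# repeat content is ancient (MIR/L2-age), with young insertions a minority.
FAMILY_CATALOG: tuple[tuple[str, str, str, float], ...] = (
    ("L1HS", "LINE", "human", 0.08),
    ("L1PA5", "LINE", "primate", 0.12),
    ("L2", "LINE", "ancestral", 0.50),
    ("L1MEc", "LINE", "eutherian", 0.30),
    ("AluY", "SINE", "primate", 0.15),
    ("AluSx", "SINE", "primate", 0.15),
    ("MIRb", "SINE", "ancestral", 0.70),
    ("LTR12C", "LTR", "primate", 0.12),
    ("THE1A", "LTR", "primate", 0.13),
    ("MLT1B", "LTR", "eutherian", 0.75),
    ("MER20", "DNA", "eutherian", 0.40),
    ("Charlie1", "DNA", "eutherian", 0.60),
    ("SVA_D", "SVA", "human", 1.0),
    ("ALR", "Satellite", "ancestral", 1.0),
)
YOUNG_LINEAGES = ("human", "primate")
ENRICHABLE_CLASSES = ("LTR", "LINE")
REPEAT_LENGTH_RANGE = {
    "LINE": (600, 1500),
    "SINE": (250, 350),
    "LTR": (400, 1000),
    "DNA": (200, 800),
    "SVA": (700, 1600),
    "Satellite": (300, 2000),
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic design.

    Defaults are the package's reference conditions: a 2 Mb chromosome
    with 800 repeats, 60 shared and 30 context-specific activation
    regions, 12-fold ChIP enrichment over a 0.02 reads/bp background,
    three replicates per context, methylation means 0.10 (active) /
    0.85 (silent), 3-fold repressive-mark elevation at silenced loci and
    a +1.5 log2 expression effect at specific-region genes.
    """

    chrom_length: int = 2_000_000
    chrom: str = "chrS"
    n_repeats: int = 800
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "LINE": 0.25, "SINE": 0.35, "LTR": 0.20, "DNA": 0.12, "SVA": 0.04, "Satellite": 0.04,
        }
    )
    div_young_mean: float = 50.0
    div_young_sd: float = 20.0
    div_old_mean: float = 250.0
    div_old_sd: float = 60.0
    n_shared_regions: int = 60
    n_specific_regions: int = 30
    p_specific_at_young_repeat: float = 0.8
    enrichment_fold: float = 12.0
    background_rate: float = 0.02  # reads per bp
    n_replicates: int = 3
    library_jitter: float = 0.2
    read_length: int = 50
    region_half_width: int = 500
    min_region_separation: int = 5000
    edge_margin: int = 10_000
    methyl_active_mean: float = 0.10
    methyl_silent_mean: float = 0.85
    beta_concentration: float = 50.0
    probes_per_region: int = 3
    n_background_probes: int = 150
    cross_hyb_fraction: float = 0.05
    h3k9me3_fold: float = 3.0
    expression_log2_effect: float = 1.5
    n_background_genes: int = 40
    mq0_fraction: float = 0.15
    specific_context: str = "A"  # context in which specific regions are active
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_specific_at_young_repeat, self.mq0_fraction, self.cross_hyb_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for f_ in (self.enrichment_fold, self.h3k9me3_fold):
            if f_ < 1.0:
                raise ValueError("fold parameters must be >= 1")
        if self.specific_context not in ("A", "B"):
            raise ValueError("specific_context must be 'A' or 'B'")

    @staticmethod
    def hard_mode(**overrides) -> "SimConfig":
        """Lower-power preset (5-fold enrichment) for power exploration."""
        return SimConfig(enrichment_fold=5.0, **overrides)


@dataclass(frozen=True)
class TruthRegion:
    category: str  # A_SPECIFIC / B_SPECIFIC / SHARED
    location: GenomicInterval
    summit: int
    gene_id: str
    seeded_family: str | None  # enriched-family instance hosting the summit, if any


@dataclass
class SimTruth:
    regions: list[TruthRegion]
    enriched_family: str
    gene_log2_effects: dict[str, float]
    probe_means: dict[str, dict[str, float]]  # probe_id -> context -> true mean beta


@dataclass
class SimBundle:
    """The in-memory dataset: every file the generator writes, as objects."""

    cfg: SimConfig
    repeats: list[RepeatInstance]
    lineage_map: dict[str, str]
    readsets: list[AlignedReadSet]
    genes: list[GeneModel]
    expression_counts: dict[str, tuple[int, int]]
    gene_lengths: dict[str, int]
    probes: list[MethylationProbe]
    exclusion: list[GenomicInterval]
    truth: SimTruth


def _place_repeats(cfg: SimConfig, rng: np.random.Generator) -> list[RepeatInstance]:
    classes = sorted(cfg.class_weights)
    weights = np.array([cfg.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    chosen_classes = rng.choice(classes, size=cfg.n_repeats, p=weights)
    fams_by_class = {
        c: [f for f in FAMILY_CATALOG if f[1] == c] for c in classes
    }
    fam_probs = {
        c: np.array([f[3] for f in fl]) / sum(f[3] for f in fl)
        for c, fl in fams_by_class.items()
    }
    lengths = np.empty(cfg.n_repeats, dtype=np.int64)
    fams: list[tuple[str, str, str, float]] = []
    for i, c in enumerate(chosen_classes):
        lo, hi = REPEAT_LENGTH_RANGE[c]
        lengths[i] = rng.integers(lo, hi + 1)
        fam_list = fams_by_class[c]
        fams.append(fam_list[rng.choice(len(fam_list), p=fam_probs[c])])
    total = int(lengths.sum())
    free = cfg.chrom_length - total
    if free <= cfg.n_repeats:
        raise ValueError("infeasible placement: repeats exceed chromosome length")
    gaps = rng.exponential(size=cfg.n_repeats + 1)
    gaps = np.floor(gaps / gaps.sum() * free).astype(np.int64)
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    repeats = []
    for i in range(cfg.n_repeats):
        name, cls, lineage, _ = fams[i]
        young = lineage in YOUNG_LINEAGES
        mean = cfg.div_young_mean if young else cfg.div_old_mean
        sd = cfg.div_young_sd if young else cfg.div_old_sd
        div = max(0.0, float(rng.normal(mean, sd)))
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(
            RepeatInstance(
                location=GenomicInterval(cfg.chrom, int(starts[i]), int(starts[i] + lengths[i]), strand),
                name=name,
                repeat_class=cls,
                divergence=div,
                lineage=lineage,
            )
        )
    return repeats


def _default_exclusion(cfg: SimConfig) -> list[GenomicInterval]:
    # two fixed 5 kb zones standing in for deleted / satellite spans
    a = int(cfg.chrom_length * 0.05)
    b = int(cfg.chrom_length * 0.90)
    return [
        GenomicInterval(cfg.chrom, a, a + 5000),
        GenomicInterval(cfg.chrom, b, b + 5000),
    ]


def _far_enough(pos: int, taken: list[int], sep: int) -> bool:
    return all(abs(pos - t) >= sep for t in taken)


def _blocked(pos: int, cfg: SimConfig, exclusion: Sequence[GenomicInterval]) -> bool:
    if not cfg.edge_margin <= pos < cfg.chrom_length - cfg.edge_margin:
        return True
    pad = cfg.region_half_width + 200
    return any(e.start - pad < pos < e.end + pad for e in exclusion)


def _place_regions(
    cfg: SimConfig,
    rng: np.random.Generator,
    repeats: list[RepeatInstance],
    exclusion: Sequence[GenomicInterval],
) -> tuple[list[tuple[str, int, str | None]], str, list[RepeatInstance]]:
    """Choose summit positions; returns (category, summit, seeded_family)
    triples, the enriched family name and the (possibly extended) repeat
    annotation.

    Seeding is constructive: when a specific region is drawn to sit inside
    the enriched family but no free instance remains, a new non-overlapping
    instance of that family is inserted into the annotation, so
    ``p_specific_at_young_repeat = 1`` guarantees every specific summit
    lies within an enriched-family instance.
    """
    young = [
        f
        for f in FAMILY_CATALOG
        if f[2] in YOUNG_LINEAGES and f[1] in ENRICHABLE_CLASSES
    ]
    fam_entry = young[rng.integers(len(young))]
    enriched_family = fam_entry[0]
    repeats = sorted(repeats, key=lambda r: r.location.start)
    instances = [
        r for r in repeats
        if r.name == enriched_family and not _blocked(r.location.midpoint, cfg, exclusion)
    ]
    order = rng.permutation(len(instances))
    instances = [instances[i] for i in order]
    specific_cat = A_SPECIFIC if cfg.specific_context == "A" else B_SPECIFIC

    taken: list[int] = []
    placed: list[tuple[str, int, str | None]] = []

    def uniform_summit() -> int:
        for _ in range(20_000):
            pos = int(rng.integers(cfg.edge_margin, cfg.chrom_length - cfg.edge_margin))
            if not _blocked(pos, cfg, exclusion) and _far_enough(pos, taken, cfg.min_region_separation):
                return pos
        raise ValueError("infeasible placement: could not find a free summit position")

    def insert_instance() -> RepeatInstance:
        lo, hi = REPEAT_LENGTH_RANGE[fam_entry[1]]
        starts = np.array([r.location.start for r in repeats])
        ends = np.array([r.location.end for r in repeats])
        for _ in range(20_000):
            length = int(rng.integers(lo, hi + 1))
            pos = int(rng.integers(cfg.edge_margin, cfg.chrom_length - cfg.edge_margin - length))
            mid = pos + length // 2
            if _blocked(mid, cfg, exclusion) or not _far_enough(mid, taken, cfg.min_region_separation):
                continue
            i = int(np.searchsorted(starts, pos + length))
            clash = (i > 0 and ends[i - 1] > pos) or (i < len(starts) and starts[i] < pos + length)
            if clash:
                continue
            mean, sd = cfg.div_young_mean, cfg.div_young_sd
            inst = RepeatInstance(
                location=GenomicInterval(cfg.chrom, pos, pos + length, "+"),
                name=enriched_family,
                repeat_class=fam_entry[1],
                divergence=max(0.0, float(rng.normal(mean, sd))),
                lineage=fam_entry[2],
            )
            repeats.insert(i, inst)
            return inst
        raise ValueError("infeasible placement: no room for an enriched-family instance")

    inst_iter = iter(instances)
    for _ in range(cfg.n_specific_regions):
        seeded = None
        summit = None
        if rng.random() < cfg.p_specific_at_young_repeat:
            for cand in inst_iter:
                mid = cand.location.midpoint
                if _far_enough(mid, taken, cfg.min_region_separation):
                    summit, seeded = mid, enriched_family
                    break
            if summit is None:  # existing instances exhausted: construct one
                inst = insert_instance()
                summit, seeded = inst.location.midpoint, enriched_family
        if summit is None:
            summit = uniform_summit()
        taken.append(summit)
        placed.append((specific_cat, summit, seeded))
    for _ in range(cfg.n_shared_regions):
        summit = uniform_summit()
        taken.append(summit)
        placed.append((SHARED, summit, None))
    return placed, enriched_family, repeats


def _triangular_mids(
    rng: np.random.Generator, summit: int, half_width: int, n: int
) -> np.ndarray:
    return rng.triangular(summit - half_width, summit, summit + half_width, size=n).astype(np.int64)


def _make_readset(
    cfg: SimConfig,
    rng: np.random.Generator,
    context: str,
    assay: str,
    replicate: int,
    enriched: Sequence[tuple[int, float]],  # (summit, fold) entries for this sample
    repeat_cov: tuple[np.ndarray, np.ndarray],
) -> AlignedReadSet:
    jitter = float(rng.uniform(1.0 - cfg.library_jitter, 1.0 + cfg.library_jitter))
    half_read = cfg.read_length // 2
    n_bg = int(rng.poisson(cfg.background_rate * cfg.chrom_length * jitter))
    mids = [rng.integers(half_read, cfg.chrom_length - half_read, size=n_bg)]
    width = 2 * cfg.region_half_width
    for summit, fold in enriched:
        extra = int(rng.poisson((fold - 1.0) * cfg.background_rate * width * jitter))
        mids.append(_triangular_mids(rng, summit, cfg.region_half_width, extra))
    mid = np.sort(np.concatenate(mids))
    mid = np.clip(mid, half_read, cfg.chrom_length - half_read)
    starts = mid - half_read
    ends = starts + cfg.read_length
    cov_s, cov_e = repeat_cov
    idx = np.searchsorted(cov_s, mid, side="right") - 1
    in_repeat = (idx >= 0) & (mid < cov_e[np.clip(idx, 0, None)])
    mq = np.where(
        in_repeat & (rng.random(mid.size) < cfg.mq0_fraction), 0, 30
    ).astype(np.int64)
    return AlignedReadSet(
        sample_id=f"{assay}_{context}_{replicate}",
        context=context,
        assay=assay,
        replicate=replicate,
        chrom=cfg.chrom,
        starts=starts,
        ends=ends,
        mapq=mq,
    )


def _merged_cov(repeats: Sequence[RepeatInstance]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted((r.location.start, r.location.end) for r in repeats)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts), np.array(ends)


def simulate_dataset(cfg: SimConfig) -> SimBundle:
    """Generate the full dataset for one configuration.

    Deterministic for a fixed config (including its seed): two calls
    return identical bundles and, via :func:`write_bundle`, byte-identical
    files.
    """
    rng = np.random.default_rng(cfg.seed)
    repeats = _place_repeats(cfg, rng)
    exclusion = _default_exclusion(cfg)
    placed, enriched_family, repeats = _place_regions(cfg, rng, repeats, exclusion)
    repeat_cov = _merged_cov(repeats)
    specific_cat = A_SPECIFIC if cfg.specific_context == "A" else B_SPECIFIC
    silent_context = "B" if cfg.specific_context == "A" else "A"

    # --- genes: one per region plus background genes far from any summit
    genes: list[GeneModel] = []
    gene_lengths: dict[str, int] = {}
    truth_regions: list[TruthRegion] = []
    gene_effects: dict[str, float] = {}
    summits = [s for _, s, _ in placed]
    for i, (cat, summit, seeded) in enumerate(placed):
        gid = f"gene_r{i:03d}"
        tss = summit + int(rng.integers(-800, 801))
        length = int(rng.integers(1000, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            body = GenomicInterval(cfg.chrom, tss, tss + length, "+")
        else:
            body = GenomicInterval(cfg.chrom, tss - length + 1, tss + 1, "-")
        genes.append(GeneModel(gid, tss, length, body))
        gene_lengths[gid] = length
        hw = cfg.region_half_width
        truth_regions.append(
            TruthRegion(cat, GenomicInterval(cfg.chrom, summit - hw, summit + hw), summit, gid, seeded)
        )
        gene_effects[gid] = cfg.expression_log2_effect if cat == specific_cat else 0.0
    for i in range(cfg.n_background_genes):
        for _ in range(20_000):
            tss = int(rng.integers(cfg.edge_margin, cfg.chrom_length - cfg.edge_margin))
            if _far_enough(tss, summits, cfg.min_region_separation):
                break
        else:
            raise ValueError("infeasible placement: background genes")
        gid = f"gene_x{i:03d}"
        length = int(rng.integers(1000, 3001))
        genes.append(GeneModel(gid, tss, length, GenomicInterval(cfg.chrom, tss, tss + length, "+")))
        gene_lengths[gid] = length
        gene_effects[gid] = 0.0

    # --- expression counts: baseline Poisson, specific-region genes shifted
    # up in the specific context
    expression_counts: dict[str, tuple[int, int]] = {}
    for g in genes:
        base = float(rng.integers(100, 401))
        eff = gene_effects[g.gene_id]
        mean_spec = base * (2.0**eff)
        mean_other = base
        mean_a = mean_spec if cfg.specific_context == "A" else mean_other
        mean_b = mean_spec if cfg.specific_context == "B" else mean_other
        expression_counts[g.gene_id] = (
            int(rng.poisson(mean_a)),
            int(rng.poisson(mean_b)),
        )

    # --- reads: H3K4me3 at active regions per context, H3K9me3 at
    # silenced specific regions, input as pure background
    readsets: list[AlignedReadSet] = []
    for assay in ("H3K4me3", "input", "H3K9me3"):
        for context in ("A", "B"):
            for rep in range(1, cfg.n_replicates + 1):
                enriched: list[tuple[int, float]] = []
                if assay == "H3K4me3":
                    for cat, summit, _ in placed:
                        if cat == SHARED or (
                            cat == specific_cat and context == cfg.specific_context
                        ):
                            enriched.append((summit, cfg.enrichment_fold))
                elif assay == "H3K9me3":
                    if context == silent_context:
                        enriched = [
                            (summit, cfg.h3k9me3_fold)
                            for cat, summit, _ in placed
                            if cat == specific_cat
                        ]
                readsets.append(
                    _make_readset(cfg, rng, context, assay, rep, enriched, repeat_cov)
                )

    # --- methylation probes: anticorrelated with activation
    probes: list[MethylationProbe] = []
    probe_means: dict[str, dict[str, float]] = {}
    sample_cols = [f"{c}_{r}" for c in ("A", "B") for r in range(1, cfg.n_replicates + 1)]
    probe_specs: list[tuple[int, float, float]] = []  # position, mean_A, mean_B
    for cat, summit, _ in placed:
        offsets = np.linspace(
            -cfg.region_half_width + 100, cfg.region_half_width - 100, cfg.probes_per_region
        ).astype(int)
        for off in offsets:
            if cat == SHARED:
                ma = mb = cfg.methyl_active_mean
            else:
                active_in_a = cfg.specific_context == "A"
                ma = cfg.methyl_active_mean if active_in_a else cfg.methyl_silent_mean
                mb = cfg.methyl_silent_mean if active_in_a else cfg.methyl_active_mean
            probe_specs.append((summit + int(off), ma, mb))
    region_ivs = [(t.location.start, t.location.end) for t in truth_regions]
    for _ in range(cfg.n_background_probes):
        for _ in range(20_000):
            pos = int(rng.integers(0, cfg.chrom_length))
            if not any(s <= pos < e for s, e in region_ivs):
                break
        else:
            raise ValueError("infeasible placement: background probes")
        probe_specs.append((pos, cfg.methyl_silent_mean, cfg.methyl_silent_mean))
    probe_specs.sort(key=lambda t: t[0])
    k = cfg.beta_concentration
    for i, (pos, ma, mb) in enumerate(probe_specs):
        pid = f"cg{i:05d}"
        cross_hyb = rng.random() < cfg.cross_hyb_fraction
        betas: dict[str, float] = {}
        for col in sample_cols:
            mean = ma if col.startswith("A") else mb
            if cross_hyb:
                mean = 0.5  # contaminated by host signal
            betas[col] = float(rng.beta(mean * k, (1.0 - mean) * k))
        control_p = float(rng.uniform(0.0, 0.005)) if cross_hyb else float(rng.uniform(0.3, 1.0))
        probes.append(MethylationProbe(pid, pos, betas, control_p))
        probe_means[pid] = {"A": ma, "B": mb}

    truth = SimTruth(
        regions=truth_regions,
        enriched_family=enriched_family,
        gene_log2_effects=gene_effects,
        probe_means=probe_means,
    )
    return SimBundle(
        cfg=cfg,
        repeats=repeats,
        lineage_map={f[0]: f[2] for f in FAMILY_CATALOG},
        readsets=readsets,
        genes=genes,
        expression_counts=expression_counts,
        gene_lengths=gene_lengths,
        probes=probes,
        exclusion=exclusion,
        truth=truth,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files and return the path map."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["repeats"] = outdir / "repeats.out"
    write_repeatmasker_out(bundle.repeats, paths["repeats"])
    paths["lineages"] = outdir / "lineages.tsv"
    write_lineage_table(bundle.lineage_map, paths["lineages"])
    paths["genes"] = outdir / "genes.bed"
    write_genes(bundle.genes, paths["genes"])
    paths["exclusion"] = outdir / "exclusion.bed"
    write_bed(bundle.exclusion, paths["exclusion"])
    paths["methylation"] = outdir / "methylation.tsv"
    write_methylation_table(bundle.probes, paths["methylation"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression_table(bundle.expression_counts, bundle.gene_lengths, paths["expression"])
    for rs in bundle.readsets:
        p = outdir / "reads" / f"{rs.sample_id}.bed"
        write_reads(rs, p)
        paths[f"reads/{rs.sample_id}"] = p

    paths["truth_regions"] = outdir / "truth_regions.tsv"
    with open(paths["truth_regions"], "w") as fh:
        fh.write("#chrom\tstart\tend\tsummit\tcategory\tgene_id\tseeded_family\n")
        for t in bundle.truth.regions:
            fam = t.seeded_family or "."
            fh.write(
                f"{t.location.chrom}\t{t.location.start}\t{t.location.end}\t{t.summit}\t"
                f"{t.category}\t{t.gene_id}\t{fam}\n"
            )
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "enriched_family": bundle.truth.enriched_family,
                "gene_log2_effects": bundle.truth.gene_log2_effects,
                "probe_means": bundle.truth.probe_means,
                "config": {k: v for k, v in asdict(bundle.cfg).items()},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


def truth_confusion(
    truth_regions: Sequence[TruthRegion],
    predicted: Sequence[DifferentialResult],
    match_tolerance: int = 500,
) -> dict[str, dict[str, float]]:
    """Per-category precision/recall of predicted region labels.

    A prediction matches a truth region of the same category when their
    summits lie within ``match_tolerance`` bp; each truth region can be
    matched once.  Precision is 1 when a category has no predictions.
    """
    out: dict[str, dict[str, float]] = {}
    for cat in (A_SPECIFIC, B_SPECIFIC, SHARED):
        truths = [t.summit for t in truth_regions if t.category == cat]
        preds = [p.summit for p in predicted if p.category == cat]
        matched_truth: set[int] = set()
        n_matched_pred = 0
        for ps in preds:
            best = None
            for ti, ts in enumerate(truths):
                if ti in matched_truth:
                    continue
                d = abs(ps - ts)
                if d <= match_tolerance and (best is None or d < best[1]):
                    best = (ti, d)
            if best is not None:
                matched_truth.add(best[0])
                n_matched_pred += 1
        precision = n_matched_pred / len(preds) if preds else 1.0
        recall = len(matched_truth) / len(truths) if truths else 1.0
        out[cat] = {
            "precision": precision,
            "recall": recall,
            "n_truth": float(len(truths)),
            "n_predicted": float(len(preds)),
        }
    return out
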