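"""End-to-end orchestration.

Each stage is a function over files, so the CLI subcommands and
:func:`run_all` share one code path and a stage run in isolation produces
exactly the intermediate that the full run writes.  All outputs are
tab-separated text with deterministic row order; a JSON manifest records
parameters and input/output checksums so a rerun can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .differential import (
    A_SPECIFIC,
    B_SPECIFIC,
    SHARED,
    DifferentialResult,
    build_consensus,
    classify_regions,
    count_and_normalize,
    nb_test,
    write_results_table,
)
from .genome import GenomicInterval, apply_exclusion
from .integration import (
    expression_by_category,
    expression_from_counts,
    filter_probes_control,
    methylation_by_category,
    repression_by_category,
)
from .io_formats import (
    apply_mapq_filter,
    read_bed,
    read_expression_table,
    read_genes,
    read_lineage_table,
    read_methylation_table,
    read_reads,
    read_repeatmasker_out,
)
from .peakcall import EnrichedRegion, PeakCallConfig, call_regions, write_regions_bed
from .repeat_enrich import (
    SHARED as R_SHARED,
    SPECIFIC as R_SPECIFIC,
    age_comparison,
    family_enrichment,
    fraction_profile,
    lineage_breakdown,
    summit_repeat,
    write_enrichment_table,
    write_profile_table,
)
from .simulate import SimConfig, simulate_dataset, truth_confusion, write_bundle

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and operating points of a full run.

    The default thresholds are the study's printed operating points:
    peaks at empirical FDR 0.001 with minimum 5-fold enrichment over
    input; context-specific classification at >= 4-fold difference with
    BH FDR < 0.1; repeat profiles over a 10 kb summit window; family
    enrichment displayed at p <= 0.05.
    """

    input_dir: str = "."
    outdir: str = "results"
    chrom_length: int = 2_000_000
    seed: int = 0
    simulate_first: bool = False
    mapq_filter: bool = True
    chip_assay: str = "H3K4me3"
    control_assay: str = "input"
    repressive_assay: str = "H3K9me3"
    # peak calling
    peak_window: int = 1000
    peak_step: int = 100
    peak_min_fold: float = 5.0
    peak_target_fdr: float = 0.001
    peak_merge_gap: int = 200
    # differential classification
    min_support: int = 1
    fold_threshold: float = 4.0
    fdr_threshold: float = 0.1
    # repeat analyses
    profile_half_width: int = 5000
    profile_bin: int = 100
    enrichment_alpha: float = 0.05
    # methylation
    detection_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or not 0 < self.fdr_threshold <= 1:
            raise ValueError("invalid classification thresholds")

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)

    def peak_config(self) -> PeakCallConfig:
        return PeakCallConfig(
            window=self.peak_window,
            step=self.peak_step,
            min_fold=self.peak_min_fold,
            target_fdr=self.peak_target_fdr,
            merge_gap=self.peak_merge_gap,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def _sample_files(reads_dir: Path, assay: str) -> list[tuple[str, str, int, Path]]:
    """Discover <assay>_<context>_<replicate>.bed files."""
    out = []
    for p in sorted(reads_dir.glob(f"{assay}_*_*.bed")):
        stem = p.stem
        parts = stem.rsplit("_", 2)
        if len(parts) != 3:
            continue
        _, context, rep = parts
        out.append((stem, context, int(rep), p))
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate(sim_cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    bundle = simulate_dataset(sim_cfg)
    return write_bundle(bundle, outdir)


def stage_callpeaks(cfg: PipelineConfig) -> dict[str, list[EnrichedRegion]]:
    """Call enriched regions of the ChIP assay against the matched input
    (same context and replicate) for every sample; writes one BED per
    sample under <outdir>/peaks and returns the calls."""
    indir = Path(cfg.input_dir)
    reads_dir = _require(indir / "reads")
    exclusion_path = indir / "exclusion.bed"
    exclusion = read_bed(exclusion_path) if exclusion_path.exists() else []
    peaks_dir = Path(cfg.outdir) / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, list[EnrichedRegion]] = {}
    for sample_id, context, rep, path in _sample_files(reads_dir, cfg.chip_assay):
        chip = read_reads(path, sample_id, context, cfg.chip_assay, rep, cfg.mapq_filter)
        ctrl_path = _require(reads_dir / f"{cfg.control_assay}_{context}_{rep}.bed")
        control = read_reads(
            ctrl_path, ctrl_path.stem, context, cfg.control_assay, rep, cfg.mapq_filter
        )
        regions = call_regions(chip, control, cfg.chrom_length, cfg.peak_config())
        kept_locs = apply_exclusion([r.location for r in regions], exclusion)
        kept_set = {(l.start, l.end) for l in kept_locs}
        regions = [r for r in regions if (r.location.start, r.location.end) in kept_set]
        out[sample_id] = regions
        write_regions_bed(regions, peaks_dir / f"{sample_id}.peaks.bed")
    if not out:
        raise FileNotFoundError(f"no {cfg.chip_assay} read files found under {reads_dir}")
    return out


def _read_chip_readsets(cfg: PipelineConfig, assay: str):
    reads_dir = Path(cfg.input_dir) / "reads"
    readsets = []
    for sample_id, context, rep, path in _sample_files(reads_dir, assay):
        readsets.append(read_reads(path, sample_id, context, assay, rep, cfg.mapq_filter))
    return readsets


def _read_peaks_bed(path: Path) -> list[EnrichedRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            out.append(
                EnrichedRegion(
                    location=GenomicInterval(f[0], start, end),
                    summit=start + int(f[9]),
                    fold_enrichment=float(f[6]),
                    poisson_p=float(f[7]),
                    empirical_fdr=float(f[8]),
                )
            )
    return out


def stage_diff(cfg: PipelineConfig) -> list[DifferentialResult]:
    """Consensus, counting, NB testing and classification; reads the
    per-sample peak BEDs written by the peak-calling stage."""
    peaks_dir = Path(cfg.outdir) / "peaks"
    peak_files = sorted(peaks_dir.glob(f"{cfg.chip_assay}_*.peaks.bed"))
    if not peak_files:
        raise FileNotFoundError(f"no peak files under {peaks_dir}; run callpeaks first")
    region_sets = [_read_peaks_bed(p) for p in peak_files]
    consensus = build_consensus(region_sets, min_support=cfg.min_support)
    readsets = _read_chip_readsets(cfg, cfg.chip_assay)
    matrix = count_and_normalize(consensus, readsets)
    results = classify_regions(
        nb_test(matrix), fold_threshold=cfg.fold_threshold, fdr_threshold=cfg.fdr_threshold
    )
    outdir = Path(cfg.outdir)
    write_results_table(results, outdir / "differential.tsv")
    from .io_formats import write_bed

    for cat in (SHARED, A_SPECIFIC, B_SPECIFIC):
        regs = [r.region for r in results if r.category == cat]
        write_bed(regs, outdir / f"regions_{cat}.bed")
    return results


def read_results_table(path: str | Path) -> list[DifferentialResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                DifferentialResult(
                    region=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    summit=int(f[3]),
                    mean_norm_a=float(f[4]),
                    mean_norm_b=float(f[5]),
                    log2fc=float(f[6]),
                    p_value=float(f[7]),
                    fdr=float(f[8]),
                    category=f[9],
                )
            )
    return out


def _categorized_summits(results: Sequence[DifferentialResult]) -> list[tuple[str, int]]:
    out = []
    for r in results:
        if r.category == SHARED:
            out.append((R_SHARED, r.summit))
        elif r.category in (A_SPECIFIC, B_SPECIFIC):
            out.append((R_SPECIFIC, r.summit))
    return out


def stage_repeats(cfg: PipelineConfig) -> dict:
    """Repeat-family enrichment, summit-window profiles, divergence-based
    age comparison and lineage tallies over the classified regions."""
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.outdir)
    results = read_results_table(_require(outdir / "differential.tsv"))
    lineage_path = indir / "lineages.tsv"
    lineage_map = read_lineage_table(lineage_path) if lineage_path.exists() else None
    repeats = read_repeatmasker_out(_require(indir / "repeats.out"), lineage_map)
    repeats.sort(key=lambda r: r.location.start)
    summits = _categorized_summits(results)

    fam_rows = family_enrichment(summits, repeats, alpha=cfg.enrichment_alpha)
    write_enrichment_table(fam_rows, outdir / "repeat_family_enrichment.tsv")
    class_rows = family_enrichment(summits, repeats, by="class", alpha=cfg.enrichment_alpha)
    write_enrichment_table(class_rows, outdir / "repeat_class_enrichment.tsv")

    spec_summits = [s for c, s in summits if c == R_SPECIFIC]
    shared_summits = [s for c, s in summits if c == R_SHARED]
    profiles = {}
    if spec_summits:
        profiles["specific"] = fraction_profile(
            spec_summits, repeats, cfg.profile_half_width, cfg.profile_bin
        )[1]
    if shared_summits:
        offsets, frac = fraction_profile(
            shared_summits, repeats, cfg.profile_half_width, cfg.profile_bin
        )
        profiles["shared"] = frac
    offsets = np.arange(-cfg.profile_half_width, cfg.profile_half_width, cfg.profile_bin) + cfg.profile_bin // 2
    write_profile_table(offsets, profiles, outdir / "repeat_profile.tsv")

    categorized_reps = []
    div_spec, div_shared = [], []
    for cat, summit in summits:
        rep = summit_repeat(summit, repeats)
        if rep is None:
            continue
        categorized_reps.append((cat, rep))
        (div_spec if cat == R_SPECIFIC else div_shared).append(rep.divergence)
    age = age_comparison(div_spec, div_shared) if div_spec and div_shared else None
    with open(outdir / "repeat_age.tsv", "w") as fh:
        fh.write("#median_div_specific\tmedian_div_shared\tstatistic\tp_value\tn_specific\tn_shared\n")
        if age is not None:
            fh.write(
                f"{age.median_specific:.2f}\t{age.median_shared:.2f}\t{age.test.statistic:.4f}\t"
                f"{age.test.p_value:.6g}\t{len(div_spec)}\t{len(div_shared)}\n"
            )
    lineages = lineage_breakdown(categorized_reps)
    with open(outdir / "lineage_breakdown.tsv", "w") as fh:
        fh.write("#category\tlineage\tcount\tfraction\n")
        for cat in sorted(lineages):
            for lin in sorted(lineages[cat]["counts"]):
                fh.write(
                    f"{cat}\t{lin}\t{int(lineages[cat]['counts'][lin])}\t"
                    f"{lineages[cat]['fractions'][lin]:.4f}\n"
                )
    return {"family": fam_rows, "class": class_rows, "age": age, "lineages": lineages}


def stage_integrate(cfg: PipelineConfig) -> dict:
    """Expression, methylation and repressive-mark consequences of the
    region classification."""
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.outdir)
    results = read_results_table(_require(outdir / "differential.tsv"))
    out: dict = {}

    genes = read_genes(_require(indir / "genes.bed"))
    counts, lengths = read_expression_table(_require(indir / "expression.tsv"))
    expr = expression_from_counts(counts, lengths)
    expr_cmp = expression_by_category(results, genes, expr)
    out["expression"] = expr_cmp
    with open(outdir / "expression_by_category.tsv", "w") as fh:
        fh.write("#category\tn_genes\tmedian_log2_ratio\ttest_p\ttest_direction\n")
        for cat in (SHARED, A_SPECIFIC, B_SPECIFIC):
            c = expr_cmp[cat]
            if not c.available:
                fh.write(f"{cat}\t0\tNA\tNA\tNA\n")
                continue
            p = f"{c.test.p_value:.6g}" if c.test else "NA"
            d = c.test.direction if c.test else "NA"
            fh.write(f"{cat}\t{len(c.values)}\t{c.median:.4f}\t{p}\t{d}\n")

    probes = filter_probes_control(
        read_methylation_table(_require(indir / "methylation.tsv")), cfg.detection_alpha
    )
    context_of = {}
    if probes:
        context_of = {col: col.split("_")[0] for col in probes[0].betas}
    meth = methylation_by_category(probes, results, context_of)
    out["methylation"] = meth
    with open(outdir / "methylation_by_category.tsv", "w") as fh:
        fh.write("#category\tcontext\tn_probes\tmedian_beta\tbetween_context_p\n")
        for cat, res in meth.items():
            if not res.available:
                fh.write(f"{cat}\tNA\t0\tNA\tNA\n")
                continue
            p = f"{res.test.p_value:.6g}" if res.test else "NA"
            for ctx in sorted(res.betas):
                med = f"{res.medians[ctx]:.4f}" if ctx in res.medians else "NA"
                fh.write(f"{cat}\t{ctx}\t{len(res.betas[ctx])}\t{med}\t{p}\n")

    k9 = _read_chip_readsets(cfg, cfg.repressive_assay)
    if k9:
        spec_cat = A_SPECIFIC if any(r.category == A_SPECIFIC for r in results) else B_SPECIFIC
        rep = repression_by_category(k9, results, specific_category=spec_cat)
        out["repression"] = rep
        with open(outdir / "repression.tsv", "w") as fh:
            fh.write("#context\tcategory\tn_regions\tmedian_log2_norm\trank_sum_p\tks_distance\tks_p\tmatched_pairs_p\n")
            for (ctx, cat), vals in sorted(rep.scores.items()):
                med = f"{np.median(vals):.4f}" if vals else "NA"
                wt = rep.within_context.get(ctx, {})
                rs_p = f"{wt['rank_sum'].p_value:.6g}" if "rank_sum" in wt else "NA"
                ks_d = f"{wt['ks'].statistic:.4f}" if "ks" in wt else "NA"
                ks_p = f"{wt['ks'].p_value:.6g}" if "ks" in wt else "NA"
                mp = rep.between_context.get(cat)
                mp_p = f"{mp.p_value:.6g}" if mp else "NA"
                fh.write(f"{ctx}\t{cat}\t{len(vals)}\t{med}\t{rs_p}\t{ks_d}\t{ks_p}\t{mp_p}\n")
    return out


def run_all(cfg: PipelineConfig, sim_cfg: SimConfig | None = None) -> dict:
    """Run every stage in order and write a manifest.

    With ``simulate_first`` the synthetic dataset is generated into
    ``input_dir`` before the analysis stages run.  Reruns with identical
    inputs and configuration are byte-identical.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate_first:
        sim_cfg = sim_cfg or SimConfig(seed=cfg.seed, chrom_length=cfg.chrom_length)
        stage_simulate(sim_cfg, cfg.input_dir)
    results: dict = {}
    try:
        results["peaks"] = stage_callpeaks(cfg)
        results["differential"] = stage_diff(cfg)
        results["repeats"] = stage_repeats(cfg)
        results["integration"] = stage_integrate(cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    indir = Path(cfg.input_dir)
    input_files = sorted(p for p in indir.rglob("*") if p.is_file() and outdir not in p.parents)
    output_files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "parameters": asdict(cfg),
        "inputs": {str(p.relative_to(indir)): _sha256(p) for p in input_files},
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in output_files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
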