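# Methods

## The design being modelled

A transchromosomic system measures one DNA sequence in two regulatory
environments: the chromosome's native nucleus (context B in this
package) and a host nucleus of another species (context A). Regions that
acquire the activating mark H3K4me3 only in the new context reveal
regulatory potential that the native environment keeps silenced — in
practice largely young, lineage-specific transposable elements. The
pipeline's job is to find those regions and characterise their repeat,
methylation, repression and expression correlates. Contexts are
symmetric throughout: nothing in the code privileges A beyond the label.

## Coordinates

All in-memory coordinates are 0-based half-open (BED convention);
overlap means ≥ 1 shared bp, so `[a,b)` and `[b,c)` never overlap.
1-based formats (RepeatMasker `.out`) are converted at the IO boundary
only. Nearest-TSS assignment uses the region summit, is strand-agnostic,
and breaks exact distance ties by lexicographically smaller gene id so
reruns are reproducible.

## Read handling

Reads are consumed as aligned intervals (BED-like, score column =
mapping quality). Reads with mapping quality 0 are dropped by default,
keeping uniquely mapping reads; all counting uses the read midpoint,
which makes results independent of read length.

## Peak calling

Windows of `window` bp advance by `step` bp (defaults 1000/100, a sharp
preset 300/30 exists for TF peaks). For each window,

* `fold = (chip_w + 1) / (control_w · s + 1)`, `s` = chip/control
  library-size ratio;
* Poisson p-value of `chip_w` with expectation `control_w · s + 1`; the
  unit pseudocount regularises empty control windows, which would
  otherwise make any chip read infinitely significant.

Windows pass at `fold ≥ min_fold` (default 5) and `p ≤ p_cut`; passing
windows merge when their spans overlap or sit within `merge_gap`
(200 bp). `p_cut` is chosen empirically: the same scoring is applied
with chip and control exchanged, and the largest cutoff whose swap
estimate `min(1, n_swapped / max(n_real, 1))` is ≤ `target_fdr`
(default 0.001) wins. The candidate set is the observed window p-values
of fold-passing windows, thinned to ≤ 64 quantiles. The summit is the
midpoint of the maximum-count step bin, leftmost on ties. A single
chromosome-wide scaled-control background is used; with one analysis
chromosome, local-lambda tiers add nothing.

The window geometry is declared, not derived: the published callers this
stage stands in for do not document comparable parameters, so defaults
were fixed once for broad histone marks.

## Differential classification

Per-sample calls merge into consensus regions (≥ 1 bp overlap,
transitive; `min_support` input sets required, default 1); the consensus
summit comes from the contributing call with the highest fold. Counts
are read midpoints per region, normalised by `median(library sizes) /
library size` — a median-library scaling rather than CPM so values stay
count-like for the NB model. The test is a 1-df likelihood-ratio test of
one mean versus one mean per context under NB2 with common dispersion

&nbsp;&nbsp;φ = median over regions of max(0, (s² − μ)/μ²)

computed on normalised counts (Poisson when φ = 0; the gamma-function
likelihood extends smoothly to the non-integer normalised counts). A
common rather than per-region dispersion is deliberate: with 2–3
replicates per context, per-region moment estimates are noise. Fold
change is `log2((μ_A + 1)/(μ_B + 1))` on normalised means — the unit
pseudocount stabilises zeros. Classification applies BH FDR across all
consensus regions, then: A-specific iff `lfc ≥ log2(4)` and `q < 0.1`
(the fold bound inclusive, the FDR bound strict), B-specific
symmetrically, Shared otherwise.

## Statistical kernels

* **chi-square 2×2** — `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, no Yates
  correction (the enrichment heat-map convention); any zero margin gives
  statistic 0, p 1.
* **rank-sum / Mann–Whitney** — for combined n ≤ 12 the p-value is exact
  by enumerating all C(n+m, n) splits of the *observed midranks*; this is
  the exact permutation null and remains valid with ties. Larger samples
  use a normal approximation with tie-corrected variance, 0.5 continuity
  correction, and an Edgeworth kurtosis term (the exact null excess
  kurtosis of the untied rank sum, −(6/5)(n²+m²+nm+N)/(nm(N+1))), which
  keeps the approximation within 0.01 of the exact p for every outcome
  at the n = m = 6 boundary.
* **signed-rank** — exact by enumerating all 2ⁿ sign assignments for
  n ≤ 12 after dropping zero differences; otherwise normal with tie and
  continuity corrections.
* **two-sample KS** — D is the supremum of the ECDF difference over
  pooled points; p from the limiting Kolmogorov distribution at
  `D·√(nm/(n+m))`.
* **BH FDR** — step-up with monotonicity enforcement, order-preserving.

Directions are stated for the first sample; "greater" always means the
first sample tends larger.

## Repeat analyses

"Repeat at summit" means point containment of the summit in a repeat
interval (smallest-start instance wins on overlapping annotations) — a
deliberately sharp criterion matching summit-resolution enrichment; the
window *profile* (fraction of summits covered at each offset of a
±5 kb window, 100-bp bins) covers the broader neighbourhood view.
Family enrichment builds, per family, the 2×2 table of
{specific, shared} × {summit in family, not} and applies the chi-square
kernel; rows at p ≤ 0.05 are flagged, mirroring the display rule of the
modelled study, while BH q-values can be layered on the returned
p-values for stricter control. Class-level tables reuse the same
machinery keyed by repeat class. Repeat age uses RepeatMasker divergence
(milliDiv) directly as the age proxy — no substitution-model correction
— compared between categories with the two-sided rank-sum test.

## Integration analyses

* **Expression** — RPKM per context from the expression count table
  (context totals as mapped-read denominators); per nearest gene the
  ratio `log2((rpkm_A+1)/(rpkm_B+1))`; genes reached by several regions
  count once per category. One-sided rank-sum tests whether
  specific-category genes are shifted relative to Shared.
* **Methylation** — probes failing the no-chromosome control detection
  filter (p ≤ 0.01) are removed as cross-hybridising; each surviving
  probe joins the first region containing its position or a background
  category. Replicate betas are averaged per probe per context so probes
  are the sampling unit; contexts are compared per category with the
  two-sided rank-sum test.
* **Repression** — per region and H3K9me3 replicate,
  `log2(median-library-normalised count + 1)`, averaged over replicates.
  Within each context, specific vs Shared by rank-sum plus KS distance;
  across contexts, the same regions by matched-pairs signed-rank.

## The synthetic generator

The generator emits what the transchromosomic design produces, with
every draw flowing from one seed (byte-identical reruns). Reference
conditions (`SimConfig` defaults): 2 Mb chromosome; 800 repeats from a
small family catalogue whose abundances skew old (eutherian/ancestral
lineages ≈ 75 % of instances, as on a real mammalian chromosome) with
divergence Normal(50, 20) milliDiv for young (human/primate) lineages
and Normal(250, 60) for old ones, truncated at 0; 60 shared and 30
context-specific regions (1 kb wide, summits ≥ 5 kb apart); specific
summits placed inside instances of one randomly chosen young LTR/LINE
family with probability 0.8 — seeding is constructive, inserting a new
non-overlapping instance when free ones run out, so probability 1 means
containment by construction; 12-fold ChIP enrichment (triangular
coverage bump) over a 0.02 reads/bp Poisson background; 3 replicates per
context with ±20 % library jitter; 15 % of repeat-overlapping reads
flagged MQ0; methylation betas Beta-distributed around 0.10 where a
region is active and 0.85 where silent or outside regions, with 5 % of
probes cross-hybridising (tiny control detection p); 3-fold H3K9me3
elevation at specific regions in the silencing context; +1.5 log2
expression effect for genes nearest specific regions. Effect sizes were
fixed once so that the pipeline at the study thresholds (4-fold,
FDR < 0.1) recovers truth with headroom; a `hard_mode` preset
(enrichment fold 5) exists for power exploration. Two fixed 5-kb
exclusion zones stand in for deleted/satellite spans; regions avoid
them.

What the generator does **not** model: nucleotide sequence, fragment-
length distributions, duplicate reads, copy number, chromatin-state
autocorrelation beyond the seeded regions, and array normalisation
artefacts. Passing recovery tests therefore demonstrates that the
pipeline's logic is correct under the stated generative assumptions, not
that it would achieve the same operating characteristics on real
libraries.

A quantitative side effect worth knowing: because specific regions sit
inside repeats, MQ0 filtering removes ~15 % of *all* reads there, so
their background (e.g. H3K9me3 in the non-elevated context) runs
slightly below Shared regions — visible as a weak within-context
difference in the active context. This mirrors the mappability depletion
that repeat-rich regions show in real data.

## Scale and runtime

Analyses run on a single 2 Mb chromosome with ~50 k reads per sample —
enough for every region to carry hundreds of reads, keeping all recovery
statistics far from their thresholds, while a full simulate-and-analyse
cycle completes in a few seconds. The repeat-age comparison is the least
powered analysis: it only sees shared summits that happen to carry a
repeat (~16 of 60), so its p-value is orders of magnitude above the
family-enrichment test's; with these conditions it still resolves the
young-vs-old contrast in ≥ 18 of 20 seeds.

## Known limitations

* The swap-FDR is a coarse estimator at small call counts (0 swapped
  calls gives estimate 0 regardless of the true rate).
* The common-dispersion NB test is anticonservative if true dispersion
  varies strongly across regions; with the generator's homogeneous noise
  this does not arise.
* Methylation probes are assigned to the *first* containing region;
  consensus regions are disjoint, so this only matters for malformed
  external input.
* The exact-mode cutoff (combined n ≤ 12) bounds enumeration cost; C(12,6)
  = 924 splits and 2¹² sign vectors are instantaneous, but the cutoff is
  a compromise, not a statistical boundary.
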