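# Methods

This note documents the models and procedures implemented in `lumipath`,
the assumptions behind them, the parameter defaults and the design choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The synthetic lineage-conversion generator

The simulator (`lumipath.simulate`) emulates an index-sorted Smart-seq2
experiment on mammary cells undergoing a Notch-driven basal→luminal fate
switch. It is first-class, tested code: its ground truth is what every
downstream stage is validated against.

**Latent state.** Each cell carries a conversion time `t ∈ [0, 1]`. Cells
are drawn from four stages (BAS, INT1, INT2, terminal luminal) occupying
disjoint `t` windows (0–0.22, 0.30–0.50, 0.52–0.74, 0.80–1.0); the gaps
mirror the discrete chase timepoints of a lineage-tracing design and make
the stages resolvable as clusters. A configurable minority (default 30%)
of terminal cells takes the HR-positive branch; these cells diverge around
the late-intermediate stage (their `t` is redrawn from 0.74–0.94) and
mature in parallel, which is what produces a forked trajectory with the
split after INT2. Wild-type (GFP-negative, default 25%) cells appear only
at the endpoints, since unperturbed cells do not occupy hybrid states.
Cells carry a graded cell-cycle activation (Beta(6, 1.5) for cycling cells,
Beta(1.2, 10) otherwise); the cycling flag is drawn with probability
`0.02 + 0.4·exp(−((t−0.55)/0.15)²)`, concentrating proliferation at
intermediate `t`.

**Gene programs.** Nine programs: `bas_early`/`bas_late` (decreasing
sigmoids in `t`, switch time τ drawn per gene from 0.16–0.28 / 0.60–0.74),
`lum_early`/`lum_late` (increasing, τ from 0.24–0.38 / 0.68–0.82),
`int_early`/`int_late` (transient Gaussian bumps, τ from 0.30–0.40 /
0.56–0.66, width 0.12), `hr_pos` (increasing sigmoid gated on the HRpos
branch), `cc` (baseline plus activation-scaled bonus, 1.6–2.5× fold) and
`housekeeping` (constant; means span four orders of magnitude so detected-
gene counts co-vary with depth — the complexity confound the adjusted
proportion score corrects). Sigmoid sharpness k = 12. The τ windows are
deliberately bimodal within the basal and luminal programs: the package
models the observed asynchrony of marker switching (early *Acta2*/*Myh11*
vs late *Krt5*) as two switch-time modes, which is also what makes the six
temporal patterns a well-posed recovery target. Late-luminal genes that
are HRneg progenitor markers (*Elf5*, *Kit*, *Aldh1a3*, ...) are never
activated on the HRpos branch — the two luminal identities share the early
luminal program but not the late one.

Canonical mouse symbols are seeded into each program (markers, TFs, *Epcam*
and *Itga6* as the EpCAM/CD49f FACS surrogates, 13 `mt-*` genes, *Dcpp1*
as an absent salivary marker) so that marker-based cluster naming, FACS
gating, mito QC and contaminant rules all operate on simulated data exactly
as they would on a real dataset.

**Counts.** Per cell, program means are normalized to relative abundances,
scaled by a log-normal library size (median 3×10⁵, σ = 0.4 — realistic
Smart-seq2 depth, chosen so the pipeline's stock QC thresholds act
non-trivially), multiplied by per-gene log-normal batch factors (σ = 0.2,
batch 1 the untouched reference) and a per-cell mito load factor
(σ = 0.35), then drawn gamma–Poisson with dispersion θ = 10
(Var = μ + μ²/θ; θ = ∞ gives the Poisson limit). No extra dropout is
modeled: at Smart-seq2 depth the NB zero mass suffices. One seeded
`numpy` generator drives everything; identical configs and seeds give
byte-identical bundles.

**FACS gates** partition the (Epcam, Itga6) log-normalized plane by two
thresholds (dataset medians by default): EpCAM-low/CD49f-high = basal,
EpCAM-high/CD49f-low = luminal, the two remaining quadrants = intermediate.

**What the generator does not emulate:** read-level artifacts, UMIs,
ambient RNA, doublets, spatial structure, discrete plate effects beyond
multiplicative per-gene factors, and real gene–gene correlation beyond the
program structure. Passing tests therefore demonstrate correctness of the
algorithms under a faithful but idealized covariance structure, not
robustness to every artifact of real Smart-seq2 data.

## QC and normalization

All thresholds are strict inequalities: genes detected in >2 cells; cells
with >200 detected genes; then <10% mitochondrial reads (genes matched by
case-insensitive `mt-` prefix), >1400 features, >100,000 total counts;
stromal cells (`Epcam < 2` counts) and salivary contaminants (`Dcpp1 > 1`)
removed. Filters are per-cell predicates on raw counts, hence idempotent
and order-commuting (asserted in tests). Normalization is
`ln(1 + 10⁴·count/total)`. HVG selection is the trend-standardized
variance ("vst") convention: per-gene raw-count variance standardized
against a lowess fit (frac = 0.3) of log₁₀ variance on log₁₀ mean, with
standardized values clipped at √n_cells; scaling is per-gene z-scoring
clipped at +10. The 10⁴ scale factor, vst flavor and +10 clip follow the
standard single-cell toolchain defaults.

## Integration, clustering, UMAP

Batch integration is a locally smoothed mutual-nearest-neighbor shift:
PCA on all cells, MNN pairs (k = 20) between each non-reference batch and
the reference, correction vectors (reference − query) smoothed over the
batch with a Gaussian kernel whose bandwidth is the median anchor spread,
added to the batch embedding. Within-batch geometry is preserved up to the
smooth shift; a batch with no MNN pairs is left uncorrected with a warning.

Clustering: shared-nearest-neighbor graph with neighbor sets of size 20
(cell included), Jaccard edge weights pruned below 1/15, partitioned by
seeded Leiden (RB-configuration objective) at resolution 0.5; cluster
labels are size-ordered strings. Targeted subclustering re-runs the same
procedure on the subset's own SNN graph at resolution 0.6. UMAP uses
spread 0.4 (min_dist 0.3, the library default) with a fixed random state.

Cluster naming to the study vocabulary {BAS, INT1, INT2, HRneg, HRpos}:
the cluster with the highest mean Esr1/Pgr expression is HRpos; the rest
are ordered by (mean Krt8/Krt19) − (mean Krt5/Krt14/Acta2); the extremes
are BAS and HRneg and interior clusters become INT1, INT2, ... from basal
to luminal. FACS gate composition is reported alongside for inspection.

## Signature scores

`find_markers` is the one-vs-rest single-gene classifier AUC from the
rank-sum statistic (U/(n₁n₂), midranks for ties), with the min.pct = 0.40
expression filter and positive-only fold changes by default; rows are
ordered by log₂ fold change (de-logged means, pseudocount 1), while the
top-50 signatures for the adjusted proportion scores are taken by AUC.

`module_score` follows the expression-bin-matched control convention:
24 equal-frequency bins over gene average expression, 100 controls sampled
per set gene from its bin with a fixed seed, score = mean(set) −
mean(control union). The combined luminal score is the module score of the
union of the ER⁺ and ER⁻ luminal signatures (a single score computed on one
combined set, not an average of two scores). Cell-cycle phase: S and G2M
module scores; G1 iff both are negative, otherwise the argmax. Frozen
copies of the S/G2M gene lists ship in `lumipath/data/`; the basal/luminal
signature files shipped there are synthetic fixtures matching the
simulator's panel, not a published resource.

The adjusted proportion score and its Huber IRLS fit are described in the
README. Two open choices were resolved as follows: the threshold
"median expression of the signature genes" is applied **per gene** (a
single pooled median would be dominated by between-gene scale differences;
the pooled variant remains available via a flag), and the adjusted score is
the residual **plus the grand mean**, keeping it on the interpretable
[0, 1] scale. Ties at the median count as not expressed (strict `>`).
The complexity covariate is the number of genes with count > 0.

## Regulons

Regulon inference (coexpression modules, motif pruning) is out of scope;
regulons are inputs — TSV/JSON files or the simulator's truth set. AUCell
uses the top 5% of each cell's expression ranking (ties broken by
lexicographic gene id for determinism); the recovery-curve step sum is
normalized by its maximum attainable value. RSS ranks regulons per cluster;
"top-n" reporting (n = 50, or all if fewer) includes pairwise/multiway
overlap counts and cluster-exclusive flags for Venn-style summaries.

## Trajectory

Lineages: Euclidean MST over cluster centroids in the 30-PC embedding,
root-to-leaf paths from BAS in leaf-sorted order. Pseudotime: orthogonal
projection onto the piecewise-linear path, refined by up to 10 rounds of
discrete principal-curve smoothing (local averages of cells ordered by
current pseudotime, re-projection, stop when the mean shift < 10⁻⁴ of the
path length); cells of off-lineage clusters get weight 0 and undefined
pseudotime. Association testing (on lineage 1, BAS→HRneg, by default) is
the Gaussian spline regression described in the README — a deliberate
replacement of the negative-binomial GAM convention with the same
null/alternative structure on log-normalized values; the F(q, n−p)
reference was chosen over χ²_q because with ~450 cells it keeps the
permutation type-I error inside the nominal band (verified in the tests).
Knots sit at pseudotime quantiles; 8 knots is the default.

Genes entering the pattern heatmap must be significant (BH-adjusted
p < 0.05) **and** have a fitted range along pseudotime of at least ln 2
(a 2-fold change) — the effect-size floor mirrors the fold-change argument
of the standard trajectory-DE toolchain and keeps near-flat, composition-
driven profiles from consuming tree-cut groups. Smoothing is a rolling
mean over ⌈n/20⌉ cells (step 1) ordered by pseudotime (ties by cell id);
bin annotations take the modal cluster label, ties resolved to the earliest
cell's label. Pattern groups: per-gene z-scored profiles, average-linkage
hierarchical clustering on Euclidean distance, tree cut into k = 6 (all
genes) or k = 3 (top 40 by Wald statistic). Groups are named by Hungarian
matching of their mean profiles to analytic prototypes (decreasing /
transient / increasing sigmoids × early/late), which is deterministic and
always yields the fixed vocabulary; when a cut does not produce the
expected group count, positional names are used with a warning.

## Label transfer

Reference-PCA projection plus weighted kNN vote: HVGs selected on the
reference, query genes matched and z-scored with the reference's means and
SDs, query cells projected with the reference loadings, then a k = 30
nearest-neighbor vote with Gaussian kernel weights (bandwidth one third of
the k-th neighbor distance, so an exact duplicate dominates its vote and
self-transfer is the identity). Scores sum to 1 per cell; argmax ties go
to the alphabetically first label and are flagged. This replaces the
anchor-CCA machinery of the original toolchain with a first-principles
method honoring the same predicted-ID contract.

## Pipeline

`run_pipeline(RunConfig)` executes simulate → qc → cluster → score →
regulons → trajectory → transfer in dependency order, writing CSV/TSV
artifacts and a JSON report (filter counts, cluster sizes, lineages, top
regulons, pattern sizes, transfer flows). If global clustering yields four
clusters, the most basal one is split at resolution 0.6 — the mixed
basal/intermediate case. Unknown config keys are rejected. The CLI
(`lumipath <stage>|run-all|report`) is a thin wrapper; stage subcommands
re-run their (cheap, deterministic) upstream dependencies so each command
is self-contained.

## Problem sizes and determinism

Default analyses run on 500 simulated cells × ~2,500 genes — large enough
for every statistic to operate in its intended regime (e.g. ≥30 cells per
spline fit, 50-gene signatures, 20-cell expression filters) and small
enough that the full test suite and the acceptance script each finish in
about a minute. All stochastic components (simulator, Leiden, UMAP,
control-gene sampling, permutations) take explicit seeds; the acceptance
script threads a single `--seed` through all of them.

## Known limitations

- The simulator's programs are conditionally independent given the latent
  state; real co-regulation beyond that is absent, so clustering and HVG
  behavior on real data may be less clean.
- The Gaussian spline association test is calibrated on log-normalized
  Smart-seq2-depth data; for shallow UMI counts an NB-GAM would be more
  appropriate.
- Batch integration handles smooth shifts; it is not designed for
  batch-specific cell types (MNN pairs would be missing, and that batch is
  left uncorrected).
- Cluster naming assumes the canonical markers are present; datasets
  lacking them fall back to polarity ordering only.
- Resolution selection is taken as given (0.5/0.6); cluster-stability
  diagnostics are not automated.
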