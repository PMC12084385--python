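# lumipath

Single-cell transcriptomic analysis of **basal-to-luminal lineage
conversion** in the mammary epithelium. When constitutively active Notch1
(N1ICD) is induced in basal cells, they progressively shut down the basal
program (*Acta2*, *Krt5*, ...) and switch on luminal genes, passing through
hybrid intermediate states before resolving into the two luminal identities
(hormone-receptor-negative progenitors and HR-positive cells). `lumipath`
re-implements the full Smart-seq2 analysis that maps this conversion — QC,
batch integration, SNN/Leiden clustering, hybrid-state scoring, regulon
specificity, trajectory inference with temporal pattern classification, and
cross-dataset label transfer — as a tested, reusable Python library, and
ships a negative-binomial simulator with complete ground truth so that every
stage is verifiable without any data download.

It is aimed at computational biologists who want either (a) the pipeline,
applied to their own cells × genes count matrices, or (b) the bespoke
statistics as standalone functions.

## The statistics at the core

**Adjusted proportion score** (hybrid-state score). For a marker set
$G$ (|G| = 50), with per-gene threshold $\theta_g = \mathrm{median}_i\,x_{ig}$
over cells $i$ of log-normalized expression $x$:

$$\mathrm{raw}_i = \frac{|\{g \in G : x_{ig} > \theta_g\}|}{|G|},\qquad
\mathrm{adj}_i = r_i + \overline{\mathrm{raw}},$$

where $r_i$ is the residual of a Huber M-estimator regression
(c = 1.345, MAD scale, IRLS) of raw on per-cell transcriptome complexity
(number of detected genes). The robust fit removes the technical dependence
of the raw proportion on sequencing depth while ignoring the biologically
bimodal extremes.

**Regulon specificity score (RSS).** Per-cell regulon activity is the AUCell
statistic: the area under the regulon's gene-recovery curve over the top 5%
of the cell's expression ranking, normalized to its maximum. For a regulon
activity vector $p$ (normalized to sum 1 over cells) and cluster indicator
distribution $q$:

$$\mathrm{RSS}(r, c) = 1 - \sqrt{\mathrm{JSD}(p, q)}\in[0,1]$$

with the Jensen–Shannon divergence in base-2 logs.

**Trajectory association test.** Lineages are root-to-leaf paths of the
minimum spanning tree over cluster centroids in PCA space, rooted at BAS;
pseudotime is arc length along the (refined) principal path. Per gene,
expression is regressed on a cubic B-spline basis of pseudotime (8 knots at
quantiles) and a Wald statistic tests that all consecutive differences of
the fitted values at the knots vanish; p-values use an F(q, n−p) reference
with Benjamini–Hochberg adjustment. Significant genes (≥2-fold fitted
range) are rolling-window smoothed along pseudotime and cut into 6 (or 3)
average-linkage groups — the early/late basal, transient intermediate and
early/late luminal conversion patterns.

## Worked example

```bash
python examples/03_hybrid_state_scores.py
```

prints, for the default simulated bundle (500 cells, seed 7):

```
mean adjusted proportion scores per cluster (basal falls, luminal rises along the conversion):
       adj_bas  adj_lum
BAS      1.000    0.154
INT1     0.788    0.269
INT2     0.100    0.858
HRneg    0.039    1.000
HRpos    0.039    0.136

Spearman of (adj_lum - adj_bas) vs true conversion time: 0.888
```

Reading: BAS cells express essentially all 50 basal markers above their
medians and almost no luminal markers; the INT clusters are genuine hybrids
(both scores intermediate); HRneg cells have completed the switch. HRpos
cells score low on *both* signatures because the luminal signature is built
from HRneg progenitor markers, which the HR-positive identity never
acquires. The 0.89 rank correlation shows the score pair recovers the
latent conversion time. The other `examples/` scripts walk through
simulation, clustering, regulon specificity (Pgr/Esr1 exclusive to HRpos),
trajectory patterns (two lineages forking after INT2; 300 genes in six
temporal groups) and label transfer (≈98% agreement on an independently
simulated query).

Each stage is also exposed as a thin CLI:

```bash
lumipath run-all --out run/ --seed 7
lumipath report --out run/
```

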