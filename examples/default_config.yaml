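# Default pipeline configuration for a full run on simulated data:
#   lumipath run-all --config examples/default_config.yaml --out run/
# Values mirror the study pipeline's settings; unknown keys are rejected.

seed: 7
outdir: run

sim:                       # synthetic lineage-conversion bundle
  n_cells: 500
  n_batches: 3
  hr_branch_fraction: 0.30
  nb_dispersion: 10.0
  seed: 7

qc:                        # strict thresholds
  min_cells_per_gene: 2    # genes kept when detected in > 2 cells
  min_features_basic: 200  # cells kept with > 200 detected genes
  max_mito_fraction: 0.10  # < 10% mitochondrial reads
  min_features: 1400       # > 1400 detected genes
  min_total_counts: 100000 # > 100,000 counts (Smart-seq2 depth)

n_hvg: 2000                # highly variable genes for PCA
n_pcs: 30                  # principal components for clustering and UMAP
k_neighbors: 20            # SNN graph neighbors
resolution: 0.5            # global Leiden resolution
subcluster_resolution: 0.6 # split of a mixed basal/intermediate cluster
umap_spread: 0.4
reference_batch: batch1    # balanced representation of all cell types

min_pct: 0.40              # marker test: expressed in >= 40% of the cluster
n_top_markers: 50          # signature size for adjusted proportion scores

aucell_top_fraction: 0.05  # AUCell ranking window
n_top_regulons: 50         # per-cluster shortlist for overlap reporting

trajectory_origin: BAS
n_assoc_hvg: 4000          # genes entering the association test
n_knots: 8                 # spline knots along pseudotime
n_top_genes: 40            # genes for the coarse (k=3) pattern cut
assoc_alpha: 0.05          # BH-adjusted significance level
assoc_min_amplitude: 0.6931471805599453  # ln 2: >= 2-fold fitted range

transfer_k: 30             # kNN vote size for label transfer
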