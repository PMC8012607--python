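# cytopheno

Phenotype-landscape analysis for single-cell mass cytometry (CyTOF) of
tumour models — in particular patient-derived tumour xenografts (PDTXs),
where every sample mixes human tumour cells with mouse stroma. The
package is aimed at computational biologists who need the full chain from
raw marker intensities to phenotype-level statistics:

1. **Pre-processing** — arcsinh transform, per-sample median-signal
   outlier filter (±2·IQR), low-event sample discard, cosine
   normalisation, equal-depth downsampling per model.
2. **Clustering** — PhenoGraph-style kNN-Jaccard graph + modularity
   community detection, with a subsample stability scan: for each
   neighbourhood size k the clustering is repeated on 90% subsamples and
   every pair of runs is compared by the adjusted Rand index (ARI).
3. **Diversity** — per-model phenotype prevalence, Simpson's score
   `1 − Σ p_i²`, and per-subpanel coefficients of variation.
4. **Cross-platform transfer** — a model-specific nearest-centroid
   classifier (shrinkage disabled) with discriminant
   `δ_k(x) = Σ_j (x_j − c_kj)²/(s_j + s0)² − 2 log π_k`, softmax
   posteriors, and rejection of cells whose top-two posterior gap is
   below 0.9; validated by matching vs non-matching centroid
   correlations.
5. **Spatial statistics** — the Davis & Peebles two-point ratio
   `w(r) = (N_R/N_D)·DD/DR` against uniform random catalogues (w ≈ 1
   under complete spatial randomness, w > 1 = clustering), for
   phenotypes with ≥100 cells per image.
6. **Association statistics** — signed Earth Mover's Distance between
   marker distributions, kNN density-resampled mutual information
   (DREMI), hypergeometric alteration enrichment with Bonferroni
   control, correlation-ranked gene-set enrichment, Spearman
   phenotype-drug correlations.
7. **Compositional models** — drug-response AUC from isotonic fits of
   viability plates, and L1-penalised linear / Cox models on phenotype
   log-ratios `log(p_i/p_ref)` with cross-validated λ, quartile
   Kaplan-Meier curves and log-rank tests.

A first-class synthetic-data module generates every input with known
ground truth (Gaussian phenotype templates with a subpanel-structured
variance hierarchy, Dirichlet compositions, Thomas-process spatial
patterns, Hill-curve plates, Weibull proportional-hazards survival), so
the whole pipeline is testable without access-controlled cohort data.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import cytopheno as cp
from cytopheno import preprocess, synthetic

# 8 synthetic PDTX models, 4 phenotypes (3 human + mouse stroma)
templates, comps = synthetic.well_separated_preset(n_models=8, n_phenotypes=4, seed=0)
table, truth = synthetic.simulate_cell_table(templates, comps, cells_per_model=400, seed=0)

normed = preprocess.cosine_normalize(table)
res = cp.cluster_graph(normed, seed=0)          # kNN-Jaccard + Leiden
ari = cp.adjusted_rand_index(res.labels, truth.labels)
print(f"clusters: {len(set(res.labels))}   ARI vs truth: {ari:.3f}")

prev = cp.compute_prevalence(res, normed.obs["model_id"].to_numpy())
print("Simpson:", prev.apply(cp.simpson_score, axis=1).round(3).to_dict())

clf = cp.train_centroid_classifier(table, truth.labels,
                                   shared_markers=table.markers[:10], seed=0)
target, ttruth = synthetic.simulate_cell_table(templates, comps,
                                               cells_per_model=300, noise_sd=0.1, seed=1)
out = cp.classify_cells(clf, target.subset_markers(table.markers[:10]))
mask = out.labels != "unclassified"
print(f"transfer accuracy: {(out.labels[mask] == ttruth.labels[mask]).mean():.3f}"
      f"   unclassified: {(~mask).mean():.3f}")
```

prints

```
clusters: 4   ARI vs truth: 0.998
Simpson: {'M01': 0.285, 'M02': 0.587, 'M03': 0.424, 'M04': 0.472,
          'M05': 0.667, 'M06': 0.535, 'M07': 0.596, 'M08': 0.608}
transfer accuracy: 1.000   unclassified: 0.008
```

The four graph communities recover the four generating phenotypes almost
exactly (ARI 0.998); Simpson's score separates near-monoclonal models
(M01, 0.29) from diverse ones (M05, 0.67); and the 10-marker centroid
classifier transfers the labels to an independently drawn noisy target
with 100% accuracy on the 99% of cells it accepts.

The same stages are available from the shell:

```sh
cytopheno run --preset demo --seed 0 --out out/          # full pipeline + manifest
cytopheno simulate --n-models 8 --out sim/
cytopheno cluster --input sim/cells.tsv --k 50 --out clu/
```

Every `run` writes a `manifest.json` recording each stage's parameters
and the SHA-256 of each artefact; re-running a configuration reproduces
the manifests bit for bit.

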