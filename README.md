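# tarsomorph

Quantitative locomotor ecomorphology from tarsal (ankle-bone) measurements.

Linear measurements of the astragalus and calcaneum carry a strong
locomotor signal in mammals: ground-dwellers, climbers, diggers, runners
and swimmers occupy different regions of tarsal shape space. `tarsomorph`
turns a taxa × measurement table — extant species with known locomotor
modes plus fossil species without them — into:

* a **size-free shape space**: per-specimen geometric-mean size removal
  (Mosimann shape ratios), per-variable Box-Cox transformation at the
  maximum-likelihood exponent λ, and per-variable z-scoring;
* **morphospaces**: PCA on the covariance matrix of the pooled sample, and
  canonical LDA trained on the extant locomotor groups with fossils
  superimposed through the extant-trained axes;
* **fossil locomotor classification** by regularized discriminant analysis
  (RDA): each group's covariance is shrunk toward the pooled covariance
  (λ) and then toward a scaled identity (γ), with (γ, λ) selected on a
  grid by cross-validated or bootstrap misclassification;
* **group-separation tests**: pairwise PERMANOVA (pseudo-F on Euclidean
  distances, permutation p-values), Benjamini–Yekutieli FDR adjustment,
  and the Bayes factor bound BFB = 1/(−e·p·ln p) attached to every p;
* **phylogenetic signal**: Blomberg's K per ordination axis on a
  majority-rule consensus of a posterior tree sample, with permutation
  significance;
* **disparity**: sum of ranges, sum of variances and mean pairwise
  distance per group, with bootstrap confidence intervals, full
  rarefaction across sample sizes, and Wilcoxon / Bhattacharyya /
  permutation comparisons between groups.

A synthetic-data module generates measurement tables with known group
structure, a shared allometric size factor, "robust"-offset fossil
clusters, and birth–death trees with Brownian traits, so every stage of
the pipeline can be validated against a recoverable ground truth.

## Worked example

```python
import tarsomorph as tm

# synthetic study system: 85 extant taxa in 6 locomotor groups,
# 40 Palaeocene + 5 Cretaceous fossils, 29 measurements
table, truth = tm.generate_measurements(tm.SimConfig(seed=1))

shape = tm.standardize_table(table)          # size-free, Box-Cox, z-scored
pca = tm.pca_covariance(shape)
print(round(pca.variance_fraction[:3].sum(), 4))
# 0.6016    <- fraction of total variance on PC1-3

extant = shape.values[~table.is_fossil.to_numpy()]
da, model = tm.lda_fit(extant, table.locomotor[~table.is_fossil])
print(round(1 - model.error_estimates["apparent"], 3))
# 0.965     <- resubstitution accuracy of the linear rule on extant taxa

fossil_scores = tm.da_project(da, shape.values[table.is_fossil.to_numpy()])
pm = tm.pairwise_permanova(pca.scores, table.time_subset, n_perm=1999, seed=1)
print(pm[["group_a", "group_b", "p_raw", "BFB"]].to_string(index=False))
#    group_a    group_b  p_raw       BFB
# Cretaceous Palaeocene 0.3470  1.001645
# Cretaceous     extant 0.0005 96.798885
# Palaeocene     extant 0.0005 96.798885
```

Both fossil strata are generated well outside the extant morphospace, so
their PERMANOVA p-values against the extant sample hit 0.0005 — the
smallest attainable with 1999 permutations — with a Bayes factor bound of
≈97:1, the strongest odds in favour of a real separation such a p-value
can justify. The two fossil strata themselves differ only by a small
latent shift and are not distinguishable at these sample sizes.

The same analysis runs from the shell against a YAML config:

```bash
tarsomorph simulate --out data/ --seed 1 --n-trees 100
tarsomorph run --config config.yaml --out results/ --seed 1
```

producing CSV score/loading/test tables, a consensus Newick tree and a
JSON manifest recording every per-stage seed.

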