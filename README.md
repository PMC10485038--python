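# sgasnf

Phenotyping of small-for-gestational-age (SGA) pregnancies by
similarity network fusion.

A fetus measuring below the 10th weight centile may be
constitutionally small or growth-restricted by placental dysfunction;
the clinical SGA/FGR dichotomy (EFW < 3rd centile and/or abnormal
fetoplacental Doppler) captures this imperfectly. `sgasnf` implements
an integrative alternative for researchers in maternal–fetal medicine
and multi-omic patient subtyping: one patient-similarity network is
built per data domain — clinical features, fetoplacental ultrasound,
cord-blood ¹H-NMR metabolomics, maternal-blood ¹H-NMR metabolomics —
and the networks are fused by cross-diffusion into a single network
whose spectral clusters define data-driven phenotypes. The package
covers the full workflow: synthetic multi-omic cohort generation,
chained-equation multiple imputation, fusion, cluster-number selection,
NMI feature ranking, train/test validation, and diagnostic/survival
comparison of the phenotypes against the clinical classification.

## Method

Per domain, pairwise Euclidean distances on standardized features feed
a locally scaled exponential kernel

    W(i,j) = exp( −d(i,j)² / (μ·ε_ij) ),   ε_ij = (mean_K(i) + mean_K(j) + d(i,j)) / 3,

where mean_K(i) is patient i's mean distance to its K nearest
neighbours. Each kernel yields a global transition matrix P (diag 1/2,
off-diagonal row mass 1/2) and a KNN-sparsified local matrix S; fusion
iterates

    P_v ← S_v · ( Σ_{u≠v} P_u / (m−1) ) · S_vᵀ

for T rounds with symmetrisation and renormalisation, and averages the
diffused networks. The number of clusters is chosen by the eigengap of
the normalized-Laplacian spectrum (rotation cost as a secondary
criterion); partitions come from k-means on the row-normalized spectral
embedding. Feature relevance is the normalized mutual information
between each feature's single-feature clustering and the fused labels.
Phenotypes are compared with the clinical rule via sensitivity,
specificity, predictive values, likelihood ratios, diagnostic odds
ratios (bootstrap-compared), DeLong ROC tests, Kaplan–Meier/log-rank
curves and Cox regression on the diagnosis-to-delivery interval.

See `docs/methods.md` for the full model description, parameter
defaults and limitations.

## Worked example

```python
from sgasnf import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1), outdir="run1")
print(report.chosen_k, report.cluster_sizes)
print(report.nmi_ranking.head(3)[["feature", "domain", "nmi"]])
print(report.validation["accuracy"], round(report.survival["cox_hr"], 2))
```

prints

```
2 [209, 365]
              feature    domain       nmi
0    sflt1_plgf_ratio  clinical  0.242737
1         systolic_bp  clinical  0.230013
2  gestational_age_dx  clinical  0.195678
```

followed by `0.9415 6.64`. Reading: the eigengap selects two
phenotypes (209 vs 365 of 574 synthetic patients); the features most
concordant with the fused clustering are the angiogenic ratio, blood
pressure and gestational age at diagnosis — the early-onset,
hypertensive placental-dysfunction signature; a top-20-NMI logistic
classifier trained on a 70% split recovers the 30% test split's own
clustering with 94.2% accuracy; and membership of the high-risk cluster
carries a 6.6-fold delivery hazard after adjustment for gestational age
at diagnosis. The same run writes `report.txt`, cluster labels, the
fused matrix, the NMI ranking and diagnostic tables under `run1/`.

The same pipeline is scriptable from the shell:

```sh
sgasnf simulate --n 574 --seed 1 --outdir cohort/
sgasnf run-all --seed 1 --outdir run1/
```

and accepts externally supplied per-domain TSV tables (patients ×
features, `NA` for missing) in place of simulated ones, e.g. for
replication against the study's deposited clinical/ultrasound and
metabolomics data.

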