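# Methods

`sgasnf` re-implements, as a tested pipeline, a machine-learning
phenotyping of small-for-gestational-age (SGA) pregnancies: similarity
network fusion (SNF) over four clinical/omic data blocks, spectral
clustering with data-driven selection of the number of clusters,
feature relevance by normalized mutual information (NMI), train/test
cluster validation, and a head-to-head diagnostic and survival
comparison of the resulting phenotypes against the clinical SGA/FGR
classification. Because the patient-level data are external deposits,
the package ships a synthetic cohort generator that emulates the
cohort's statistical structure; every pipeline stage is exercised and
tested end-to-end on generated cohorts.

## Synthetic cohort generator

The generator draws `n = 574` patients with two latent phenotypes,
sampled i.i.d. with probabilities 216/574 and 358/574: an early-onset,
high-risk phenotype ("cluster A") and a late-onset, lower-risk one
("cluster B"). Four data domains are produced per patient — clinical
(gestational age at diagnosis, systolic/diastolic/mean blood pressure,
sFlt-1/PlGF ratio), fetoplacental ultrasound (EFW, EFW centile,
umbilical and uterine artery PI z-scores, cerebroplacental-ratio
z-scores at diagnosis and before delivery), cord-blood NMR metabolomics
(glutamine, creatine, LDL/HDL particle ratio, valine, IDL
triglycerides, tyrosine, BNP) and maternal-blood NMR metabolomics
(tyrosine, creatine, 2-oxoisovaleric acid, glutamic acid, LDL
triglycerides).

*Feature distributions.* Each feature is Gaussian per cluster with the
published cluster-wise median as the mean and IQR/1.349 as the SD (for
a normal distribution the IQR is 1.349 SD). EFW uses the published mean
± SD directly. Right-skewed markers (sFlt-1/PlGF ratio, cord BNP) are
log-normal, parameterised by the median and the IQR of the log. The
sFlt-1/PlGF per-cluster values are not published per cluster; the
defaults (median 85 vs 12) are clinically typical of early- vs
late-onset placental dysfunction and are set once in
`cohort.default_features`. Within a domain, features share an
exchangeable correlation (default rho = 0.2) induced by a single
per-patient latent factor; the source data's covariance is not
published, and 0.2 is a modest, realistic within-panel correlation.

*Missingness.* Missing data are injected per patient-row within a
domain — a patient either has the domain's panel measured or not, which
is how missingness arises in practice (an unmeasured metabolomics
sample) and how it was reported for the source cohort: blood pressure
missing for 11.4% of patients, ultrasound 4.1%, each metabolomics panel
31.3%. Gestational age and the angiogenic ratio are always observed.
The mechanism is MCAR; the source cohort's mechanism is uncharacterised,
so tests say nothing about MAR/MNAR robustness. Pre-masking values are
retained internally so imputation error can be measured.

*Outcomes.* Binary outcomes are independent Bernoulli draws at
cluster-specific probabilities: preeclampsia 55.1%/8.96%, stillbirth
6.94%/0%, adverse perinatal outcome 44.4%/13.4%, abnormal cord BNP
48.3%/9.3% (clusters A/B). The diagnosis-to-delivery interval is
exponential per cluster with mean 4 weeks (A) and 42 weeks (B), fixing
the ground-truth hazard ratio at 42/4 = 10.5 with cluster A delivering
sooner; every delivery is an observed event. The published cluster-wise
median intervals cannot be reconciled with an HR of 10.5 under any
proportional-hazards model, so the generator honours the hazard ratio
(the quantity the survival analysis estimates) rather than the medians;
the interval scales are therefore ground truth for Cox-recovery tests,
not a calibration of absolute delivery timing.

What the generator does *not* emulate: raw NMR spectra and lipoprotein
deconvolution, longitudinal ultrasound series, non-Gaussian marginal
shapes beyond log-normality, informative missingness, and the
dependence between outcomes (e.g. stillbirth and APO are drawn
independently). Passing tests demonstrate that the pipeline recovers
structure of this idealised kind; they do not certify performance on
the real cohort.

## Preprocessing

Missing cells are imputed by chained equations: each incomplete
feature is regressed on the other features of the same domain with
Bayesian ridge regression, sweeping the features in random order for
`n_sweeps = 10` passes, and imputed values are sampled from the
posterior predictive so the m completed datasets differ (multiple
imputation; `sklearn.IterativeImputer` with `sample_posterior=True`).
Imputation never crosses domains, keeping the blocks separable as
fusion inputs. The pipeline default is m = 5 imputations pooled by
cell-wise averaging into a single completed matrix before fusion; the
average stabilises quickly in m, and m = 50 (the count advocated for
~30% incomplete cases) is supported and tested. Pooling by averaging is
a design choice — how the original analysis fed 50 imputations into one
clustering is unspecified — and `pool_imputations(..., "first")` plus
per-imputation runs allow consensus-style sensitivity checks.

After pooling, strictly positive features with sample skewness above 2
(the angiogenic ratio, cord BNP) receive a natural-log transform; this
variance-stabilising step is standard for such markers and prevents
single extreme values from dominating Euclidean distances. Every
feature is then standardized to mean 0, SD 1 (population SD); constant
features map to zeros with a warning.

## Similarity network fusion

Per domain, pairwise Euclidean distances d(i,j) on the standardized
matrix feed a locally scaled exponential kernel

    W(i,j) = exp(-d(i,j)^2 / (mu * eps_ij)),
    eps_ij = (mean_K(i) + mean_K(j) + d(i,j)) / 3,

with mean_K(i) the mean distance from i to its K nearest neighbours.
Kernels are floored at machine epsilon so an extreme outlier cannot
underflow to a disconnected row. Each W yields a global transition
matrix P (off-diagonal row mass 1/2, diagonal 1/2) and a local
KNN-truncated, row-stochastic matrix S (ties broken by ascending
patient index, so results are platform-independent). Fusion iterates

    P_v <- S_v @ (sum_{u != v} P_u / (m - 1)) @ S_v^T

for T rounds; after every round each network is symmetrised, ridged
(eta = 1e-8 on the diagonal, guarding against numerically negative
eigenvalues) and renormalised, so row-stochasticity and symmetry hold
at each step. The fused network is the average of the m diffused
networks, polished by alternating renormalisation/symmetrisation until
it is simultaneously symmetric and row-stochastic to 1e-10.

Hyperparameters default to K = 20 neighbours, mu = 0.5, T = 20
iterations — the documented defaults of the SNF toolchain the study
applied; the study itself does not state its settings. All three are
exposed in the configuration and CLI.

## Clustering and model selection

Spectral clustering uses the symmetric normalized Laplacian
L = I − D^{-1/2} W D^{-1/2}; the embedding is the k eigenvectors of the
smallest eigenvalues, row-normalized, partitioned by k-means with 20
restarts at a fixed seed (k-means is chosen over rotation
discretisation for transparency; the embedding retry logic guards the
rare empty-cluster outcome). The number of clusters is scored for
k = 2..k_max by (i) the eigengap — the difference between consecutive
ascending Laplacian eigenvalues, the primary criterion — and (ii) a
rotation cost: the residual of aligning the k-eigenvector embedding to
its nearest cluster-indicator matrix by alternating Procrustes
rotations, reported as a secondary criterion.

Cluster coherence is a silhouette computed from the similarity-derived
dissimilarity d = 1 − W/max_offdiag(W) (diagonal zeroed). The
off-diagonal maximum is used because a fused network's diagonal holds
self-similarity mass (1/2) that would compress all between-patient
dissimilarities towards 1. Because diffusion concentrates similarity
mass on near neighbours, absolute silhouette values under this linear
conversion are small even for clean partitions; the statistic is useful
for comparing partitions of the same network, and its absolute value is
not comparable to silhouettes computed under other conversions.

## Feature relevance and data-type contributions

A feature's relevance is the NMI (arithmetic-mean normalization)
between the fused cluster labels and a single-feature spectral
clustering built with the same kernel settings (K, mu) and the same k —
continuous features are partitioned by clustering rather than quantile
binning, mirroring the applied toolchain's feature ranking. Constant
features score 0 with a warning; ties in the ranking break by domain
then name.

Fused-network edges are decomposed by supporting data type with an
explicit rule (the source analysis reports contribution percentages
without defining "support"): affinities are rank-normalized to (0, 1]
over off-diagonal pairs; the edge set is the pairs above the
`edge_quantile` (default 0.9) of the fused ranks; a domain supports an
edge when its rank for that pair is at least `support_ratio` (default
0.5) times the fused rank; percentages are over (edge, domain)
attributions and sum to 100. Both parameters are surfaced in the
configuration and reports.

## Train/test validation

The cohort is split 70.2%/29.8% by simple random subsampling
(unstratified), the full impute-fuse-cluster analysis is re-run
independently on each part with identical parameters, and cluster
labels are matched across parts by minimum total centroid distance
(Hungarian assignment on the top-feature centroids). A multinomial
logistic regression on the training part's top-20-NMI features (L2
ridge 1e-4, intercept unpenalised; binomial when k = 2) predicts test
membership; reported metrics are the accuracy of those predictions
against the test part's own fused clustering and the AUROC of the
predicted membership probability (midrank Mann–Whitney construction,
optional percentile-bootstrap CI).

## Outcome evaluation

High-risk flags (fused cluster A — operationally, the cluster with the
shorter median diagnosis-to-delivery interval — or the clinical FGR
rule: EFW centile < 3 and/or umbilical artery PI z >= 2 and/or uterine
artery PI z >= 2 and/or cerebroplacental ratio z <= −2, cutoffs
configurable) are tabulated against each binary outcome.
`diagnostic_stats` reports sensitivity, specificity, PPV, NPV (Wilson
CIs), LR+ and LR− (log-scale Wald CIs with the Simel variance) and the
diagnostic odds ratio DOR = (TP·TN)/(FP·FN) = LR+/LR−. Zero cells make
the affected ratios NA, matching how such rows are conventionally
reported; an optional Haldane–Anscombe +0.5 correction is available and
is used inside bootstrap replicates so resampled differences stay
finite. System comparisons use percentile bootstrap CIs of paired
LR+/DOR differences (B = 2000; replicates that lose an outcome class
are skipped and counted) and the DeLong test for correlated ROC curves
(midrank placement values; identical score vectors return p = 1).

Time-to-delivery is analysed with Kaplan–Meier curves, the log-rank
test, and Cox proportional-hazards regression (lifelines; Efron tie
handling, which coincides with Breslow on the generator's tie-free
continuous intervals), optionally adjusted for gestational age at
diagnosis; proportionality is checked by the Schoenfeld-residual score
test against log(time). Monotone-likelihood failures raise with a
diagnostic instead of returning a divergent estimate.

## Pipeline determinism and problem sizes

A single master seed deterministically spawns one child seed per stage
(`numpy.random.SeedSequence`); reports regenerate byte-identically
(timings are written separately). The replication experiments in
`sgasnf.experiments` run the default study conditions at full size
(n = 574, 20 seeds for cluster recovery and transfer, 25 for Cox
coverage, 500 replicates for log-rank calibration); unit and property
tests use reduced cohorts (n = 60–200) and fewer seeds, sizes chosen so
the whole suite runs comfortably on a laptop while keeping the
statistical assertions well-powered at 3-sigma margins.

## Known limitations

- The silhouette's absolute level depends on the similarity-to-
  dissimilarity conversion; only within-analysis comparisons are
  meaningful.
- The edge-support rule behind data-type contributions is a declared
  invention; published contribution percentages depend on an
  unspecified rule and are not reproduction targets.
- MCAR missingness and independent outcomes understate real-data
  difficulty; transfer metrics on synthetic cohorts are optimistic
  relative to the published real-data values.
- The chained-equation engine is Bayesian linear regression, not
  predictive-mean matching; with strongly non-Gaussian conditionals the
  two can differ.
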