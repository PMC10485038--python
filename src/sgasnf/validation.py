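"""Train/test reproducibility of the fused clustering.

The cohort is split 70/30 by simple random subsampling, the full
fusion-and-clustering analysis is re-run independently on each part,
cluster labels are matched across parts by optimal centroid assignment,
and a ridge-regularised (multinomial) logistic classifier trained on
the training part's top-NMI features predicts the test part's cluster
membership. Agreement of those predictions with the test part's own
fused clustering measures how transferable the phenotypes are.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .datatypes import ClusterAssignment, MultiOmicCohort
from .cluster import spectral_cluster
from .preprocess import prepare_cohort
from .relevance import rank_features_by_nmi
from .snf import SNFusion


@dataclass
class SplitSpec:
    """Train/test split specification (default 70.2% train)."""

    train_fraction: float = 0.702
    seed: int = 0

    def validate(self, n: int) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if n < 20:
            raise ValueError("cohort too small to split (need n >= 20)")


def split_cohort(cohort: MultiOmicCohort, spec: SplitSpec
                 ) -> tuple[MultiOmicCohort, MultiOmicCohort]:
    """Simple random (unstratified) split, deterministic given the seed."""
    n = cohort.n_patients
    spec.validate(n)
    n_train = int(round(spec.train_fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("split leaves an empty or singleton part")
    perm = np.random.default_rng(spec.seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return cohort.subset(train_idx), cohort.subset(test_idx)


def cluster_profiles(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """k x p matrix of per-cluster feature centroids (labels in 1..k)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    return np.vstack([X[labels == c].mean(axis=0) for c in range(1, k + 1)])


def match_cluster_labels(train_assign: ClusterAssignment,
                         test_assign: ClusterAssignment,
                         train_profiles: np.ndarray,
                         test_profiles: np.ndarray) -> np.ndarray:
    """Permutation aligning test cluster labels to the training clusters.

    Solves the optimal assignment minimising total centroid distance
    (equivalently maximising total centroid similarity). Returns an
    array ``perm`` with ``perm[j-1]`` = training label matched to test
    label j; apply as ``perm[test_labels - 1]``.
    """
    if train_assign.k != test_assign.k:
        raise ValueError("cluster numbers differ between cohorts")
    k = train_assign.k
    train_profiles = np.asarray(train_profiles, dtype=float)
    test_profiles = np.asarray(test_profiles, dtype=float)
    cost = np.linalg.norm(
        train_profiles[:, None, :] - test_profiles[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(k, dtype=int)
    for train_label, test_label in zip(rows + 1, cols + 1):
        perm[test_label - 1] = train_label
    return perm


def brute_force_match(train_profiles: np.ndarray,
                      test_profiles: np.ndarray) -> np.ndarray:
    """Exhaustive-search reference for match_cluster_labels (small k)."""
    k = train_profiles.shape[0]
    best, best_cost = None, np.inf
    for p in permutations(range(k)):
        cost = sum(np.linalg.norm(train_profiles[p[j]] - test_profiles[j])
                   for j in range(k))
        if cost < best_cost:
            best_cost, best = cost, p
    return np.asarray(best) + 1


def fit_membership_classifier(X: np.ndarray, labels: np.ndarray,
                              ridge: float = 1e-4) -> LogisticRegression:
    """Multinomial logistic regression of cluster membership on features.

    L2 ridge (penalty weight ``ridge`` on the squared coefficient norm,
    intercept unpenalised) guards against perfect separation. With two
    clusters this reduces to binomial logistic regression.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if (counts < 5).any():
        small = classes[counts < 5].tolist()
        raise ValueError(f"classes with fewer than 5 members: {small}")
    if ridge <= 0:
        raise ValueError("ridge must be positive")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=5000,
                             tol=1e-10)
    clf.fit(X, labels)
    return clf


def auroc(scores, binary_labels, n_boot: int = 0, alpha: float = 0.05,
          seed: int = 0):
    """Area under the ROC curve by midranks (Mann-Whitney normalization).

    Returns the AUC, or ``(auc, (lo, hi))`` with a percentile bootstrap
    CI when ``n_boot > 0``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both outcome classes must be present")

    def _auc(s, y):
        r = rankdata(s)  # midranks handle ties
        n1 = int(y.sum())
        n0 = y.size - n1
        return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    a = float(_auc(s, y))
    if n_boot <= 0:
        return a
    rng = np.random.default_rng(seed)
    boots = []
    while len(boots) < n_boot:
        idx = rng.integers(0, s.size, s.size)
        if y[idx].min() == y[idx].max():
            continue  # resample lost a class
        boots.append(_auc(s[idx], y[idx]))
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return a, (float(lo), float(hi))


@dataclass
class TransferResult:
    """Outputs of the train/test transferability analysis."""

    accuracy: float
    auroc: float
    top_features: list[str]
    train_assign: ClusterAssignment
    test_assign: ClusterAssignment
    matched_test_labels: np.ndarray
    predicted_test_labels: np.ndarray


def _stack_blocks(standardized: dict) -> tuple[np.ndarray, list[str]]:
    mats, names = [], []
    for dom, block in standardized.items():
        mats.append(block.values.to_numpy(dtype=float))
        names.extend(block.feature_names)
    return np.hstack(mats), names


def transfer_validation(
    cohort: MultiOmicCohort,
    k: int = 2,
    K: int = 20,
    mu: float = 0.5,
    T: int = 20,
    top_n: int = 20,
    ridge: float = 1e-4,
    train_fraction: float = 0.702,
    n_imputations: int = 5,
    n_sweeps: int = 10,
    seed: int = 0,
) -> TransferResult:
    """Split, re-fuse, match, classify: the full transferability workflow."""
    seeds = [int(s) % 2**31
             for s in np.random.SeedSequence(seed).generate_state(6)]
    train, test = split_cohort(cohort, SplitSpec(train_fraction, seeds[0]))

    parts = {}
    for name, part, s_prep, s_clust in (
        ("train", train, seeds[1], seeds[2]),
        ("test", test, seeds[3], seeds[4]),
    ):
        _, standardized = prepare_cohort(part, n_imputations=n_imputations,
                                         n_sweeps=n_sweeps, seed=s_prep)
        fusion = SNFusion(K=K, mu=mu, T=T).fit(standardized)
        assign = spectral_cluster(fusion.fused_affinity_, k, seed=s_clust,
                                  source=f"fused:{name}")
        parts[name] = (standardized, assign)

    std_train, train_assign = parts["train"]
    std_test, test_assign = parts["test"]
    ranking = rank_features_by_nmi(std_train, train_assign, k=k, K=K, mu=mu,
                                   seed=seeds[5])
    top = ranking.head(top_n)["feature"].tolist()

    X_train, names = _stack_blocks(std_train)
    X_test, _ = _stack_blocks(std_test)
    col = {n: i for i, n in enumerate(names)}
    sel = [col[f] for f in top]
    Xtr, Xte = X_train[:, sel], X_test[:, sel]

    perm = match_cluster_labels(
        train_assign, test_assign,
        cluster_profiles(Xtr, train_assign.labels, k),
        cluster_profiles(Xte, test_assign.labels, k))
    matched = perm[test_assign.labels - 1]

    clf = fit_membership_classifier(Xtr, train_assign.labels, ridge=ridge)
    predicted = clf.predict(Xte)
    accuracy = float((predicted == matched).mean())
    # score for the high-risk phenotype = cluster label 1 of the training run
    target = int(clf.classes_[0])
    proba = clf.predict_proba(Xte)[:, list(clf.classes_).index(target)]
    auc = auroc(proba, (matched == target).astype(int))
    return TransferResult(accuracy, float(auc), top, train_assign, test_assign,
                          matched, np.asarray(predicted))
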