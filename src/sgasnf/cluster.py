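"""Spectral clustering of a patient similarity network and model selection.

The partitioning uses the symmetric normalized Laplacian
L = I - D^{-1/2} W D^{-1/2}: the embedding is the k eigenvectors of the
smallest eigenvalues, row-normalized, clustered by k-means. The number
of clusters is chosen by the eigengap (difference of consecutive
ascending Laplacian eigenvalues) with a rotation-based discretisation
cost as a secondary criterion. Cluster coherence is quantified by a
silhouette computed from the similarity-derived dissimilarity
d = 1 - W / max(W).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .datatypes import ClusterAssignment


def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("similarity matrix must be square")
    if (W < -1e-12).any():
        raise ValueError("similarity matrix must be nonnegative")
    W = (W + W.T) / 2.0
    d = W.sum(axis=1)
    if (d <= 0).any():
        raise ValueError("zero-degree patients in the similarity matrix")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = -W * inv_sqrt[:, None] * inv_sqrt[None, :]
    L[np.diag_indices_from(L)] += 1.0
    return (L + L.T) / 2.0


def spectral_embedding(W: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized matrix of the k smallest-eigenvalue eigenvectors."""
    L = _normalized_laplacian(W)
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    return vecs / norms[:, None]


def spectral_cluster(W: np.ndarray, k: int, seed: int = 0,
                     source: str = "fused", max_tries: int = 5
                     ) -> ClusterAssignment:
    """Partition a similarity network into k clusters.

    Deterministic given ``seed`` (k-means with 20 restarts on the
    spectral embedding); invariant to patient permutation up to label
    renaming. Retries with a fresh k-means seed if a cluster comes back
    empty, then raises.
    """
    n = W.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    U = spectral_embedding(W, k)
    for attempt in range(max_tries):
        km = KMeans(n_clusters=k, n_init=20, random_state=(seed + attempt) % 2**31)
        labels = km.fit_predict(U)
        if np.unique(labels).size == k:
            return ClusterAssignment(labels + 1, k=k, source=source)
    raise RuntimeError(f"could not produce {k} non-empty clusters "
                       f"after {max_tries} k-means attempts")


def estimate_k(W: np.ndarray, k_max: int = 8) -> pd.DataFrame:
    """Score candidate cluster numbers k = 2..k_max.

    Returns a frame with the eigengap (lambda_{k+1} - lambda_k of the
    ascending normalized-Laplacian spectrum; larger is better) and the
    rotation cost (discretisation residual of the k-eigenvector
    embedding; smaller is better), plus ``best_k_eigengap`` /
    ``best_k_rotation`` in ``.attrs``.
    """
    n = W.shape[0]
    if not (2 <= k_max < n):
        raise ValueError(f"need 2 <= k_max < n, got k_max={k_max}, n={n}")
    L = _normalized_laplacian(W)
    vals, vecs = eigh(L)
    if np.linalg.matrix_rank(W) < 2:
        raise ValueError("degenerate similarity matrix (rank < 2)")
    rows = []
    for k in range(2, k_max + 1):
        gap = vals[k] - vals[k - 1]  # ascending, 0-based: (k+1)-th minus k-th
        U = vecs[:, :k]
        norms = np.linalg.norm(U, axis=1)
        norms[norms == 0] = 1.0
        cost = _rotation_cost(U / norms[:, None])
        rows.append({"k": k, "eigengap": gap, "rotation_cost": cost})
    out = pd.DataFrame(rows)
    out.attrs["best_k_eigengap"] = int(out.loc[out["eigengap"].idxmax(), "k"])
    out.attrs["best_k_rotation"] = int(out.loc[out["rotation_cost"].idxmin(), "k"])
    return out


def _rotation_cost(U: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> float:
    """Alignment cost of an eigenvector matrix to an indicator structure.

    Alternates between snapping the rotated embedding to its nearest
    cluster-indicator matrix and re-solving the optimal rotation
    (Procrustes via SVD); the returned cost 2*(n - sum of singular
    values) is 0 for a perfectly block-structured embedding.
    """
    n, k = U.shape
    # greedy near-orthogonal initial rotation: pick maximally spread rows
    picked = [0]
    c = np.abs(U @ U[0])
    for _ in range(1, k):
        c += np.abs(U @ U[picked[-1]])
        picked.append(int(np.argmin(c)))
    R = U[picked].T  # k x k
    last = None
    for _ in range(max_iter):
        X = U @ R
        idx = np.argmax(X, axis=1)
        Xd = np.zeros_like(X)
        Xd[np.arange(n), idx] = 1.0
        u, s, vt = np.linalg.svd(Xd.T @ U)
        cost = 2.0 * (n - s.sum())
        if last is not None and abs(last - cost) < tol:
            break
        last = cost
        R = (u @ vt).T
    return float(cost)


def silhouette_from_similarity(W: np.ndarray, labels: np.ndarray
                               ) -> tuple[float, np.ndarray]:
    """Silhouette of a partition under d = 1 - W / max(W).

    Returns the mean score and the per-patient scores (in [-1, 1]).
    """
    labels = np.asarray(labels, dtype=int)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    if (counts == 0).any():
        raise ValueError("every cluster must be non-empty")
    W = np.asarray(W, dtype=float)
    # scale by the largest off-diagonal similarity: the diagonal carries
    # self-similarity mass (1/2 in fused networks) that would otherwise
    # compress every between-patient dissimilarity towards 1
    off = ~np.eye(W.shape[0], dtype=bool)
    d = 1.0 - W / W[off].max()
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    scores = silhouette_samples(d, labels, metric="precomputed")
    return float(scores.mean()), scores


def cluster_crosstab(a: ClusterAssignment, b: ClusterAssignment) -> pd.DataFrame:
    """Contingency table of label overlaps between two assignments."""
    if a.n_patients != b.n_patients:
        raise ValueError("assignments cover different patients")
    tab = pd.crosstab(pd.Series(a.labels, name=a.source),
                      pd.Series(b.labels, name=b.source))
    return tab.reindex(index=range(1, a.k + 1), columns=range(1, b.k + 1),
                       fill_value=0)
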