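"""Similarity network fusion (SNF).

One patient-similarity network is built per data domain from Euclidean
distances with a locally scaled exponential kernel,

    W(i,j) = exp(-d(i,j)^2 / (mu * eps_ij)),
    eps_ij = (mean_K(i) + mean_K(j) + d(i,j)) / 3,

where mean_K(i) is the mean distance from patient i to its K nearest
neighbours. Each raw kernel W yields a global transition matrix P
(off-diagonal row-normalised to mass 1/2, diagonal 1/2) and a local
KNN-truncated transition matrix S. Fusion cross-diffuses the networks:

    P_v  <-  S_v @ (sum_{u != v} P_u / (m-1)) @ S_v^T

for T rounds, symmetrising, ridging and renormalising after every
round; the fused network is the renormalised average of the m diffused
P's. Cross-diffusion propagates similarity supported by several domains
and suppresses domain-specific noise.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform


def euclidean_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between the rows of a complete matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D patients x features matrix")
    if np.isnan(X).any():
        raise ValueError("distance matrix requires a complete (imputed) matrix")
    return squareform(pdist(X, metric="euclidean"))


def _check_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any() or (D < 0).any():
        raise ValueError("distance matrix must be nonnegative and complete")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def affinity(D: np.ndarray, K: int = 20, mu: float = 0.5) -> np.ndarray:
    """Locally scaled exponential kernel (raw kernel W) from distances.

    Values lie in (0, 1]; W(i,j) = 1 whenever d(i,j) = 0. The local
    scale eps_ij averages each patient's K-nearest-neighbour distance
    with the pair distance, so the kernel adapts to local density.
    """
    D = _check_distance(D)
    n = D.shape[0]
    if not (1 <= K < n):
        raise ValueError(f"K must satisfy 1 <= K < n, got K={K}, n={n}")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not D.any():
        warnings.warn("all distances are zero; returning uniform affinity 1")
        return np.ones_like(D)
    # mean distance of each patient to its K nearest neighbours (self excluded)
    D_off = D.copy()
    np.fill_diagonal(D_off, np.inf)
    knn_mean = np.sort(D_off, axis=1)[:, :K].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + D) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(D**2) / (mu * eps))
    W = np.where(D == 0, 1.0, W)  # includes the eps == 0 corner
    # floor at machine epsilon: keeps extreme outliers connected instead
    # of letting the exponential underflow to an all-zero row
    W = np.maximum(W, np.finfo(float).eps)
    return (W + W.T) / 2.0


def global_kernel(W: np.ndarray) -> np.ndarray:
    """Full transition matrix P: off-diagonal mass 1/2 per row, diag 1/2."""
    W = np.asarray(W, dtype=float)
    off = W.sum(axis=1) - np.diag(W)
    if (off <= 0).any():
        bad = np.where(off <= 0)[0]
        raise ValueError(f"disconnected patient rows (no off-diagonal mass): "
                         f"{bad.tolist()}")
    P = W / (2.0 * off[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """KNN-truncated transition matrix S.

    Row i keeps only patient i's K most similar neighbours (largest W,
    ties broken by ascending patient index), renormalised to sum 1.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (1 <= K < n):
        raise ValueError(f"K must satisfy 1 <= K < n, got K={K}, n={n}")
    S = np.zeros_like(W)
    for i in range(n):
        row = W[i].copy()
        row[i] = -np.inf
        # stable sort of -row: ties resolve to the lower patient index
        nbrs = np.argsort(-row, kind="stable")[:K]
        mass = W[i, nbrs].sum()
        if mass <= 0:
            raise ValueError(f"patient {i} has zero similarity to its {K} "
                             "nearest neighbours")
        S[i, nbrs] = W[i, nbrs] / mass
    return S


def _global_normalize(P: np.ndarray) -> np.ndarray:
    off = P.sum(axis=1) - np.diag(P)
    out = P / (2.0 * off[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def fuse(w_list: list[np.ndarray], K: int = 20, T: int = 20,
         ridge: float = 1e-8, return_history: bool = False):
    """Cross-diffuse m raw kernels into one fused similarity network.

    Returns the fused matrix (symmetric; rows sum to 1 up to the final
    symmetrisation). With ``return_history`` also returns the maximum
    element-wise change of the diffused networks per round.
    """
    if len(w_list) < 2:
        raise ValueError("fusion needs at least two domain kernels")
    shapes = {w.shape for w in w_list}
    if len(shapes) != 1:
        raise ValueError(f"domain kernels differ in shape: {shapes}")
    n = w_list[0].shape[0]
    m = len(w_list)
    P = [global_kernel(W) for W in w_list]
    P = [(p + p.T) / 2.0 for p in P]
    S = [local_kernel(W, K) for W in w_list]
    eye = np.eye(n)
    history = []
    for _ in range(T):
        new_P = []
        for v in range(m):
            M = (sum(P[u] for u in range(m) if u != v)) / (m - 1)
            p = S[v] @ M @ S[v].T
            p = (p + p.T) / 2.0 + ridge * eye  # exact symmetry
            p = _global_normalize(p)  # rows sum to 1 exactly
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-8)
            new_P.append(p)
        history.append(max(np.abs(new_P[v] - P[v]).max() for v in range(m)))
        P = new_P
    fused = sum(P) / m
    # alternate renormalization and symmetrization until the average is
    # both symmetric and row-stochastic (converges in a few steps)
    for _ in range(100):
        fused = _global_normalize(fused)
        fused = (fused + fused.T) / 2.0
        if np.abs(fused.sum(axis=1) - 1.0).max() < 1e-10:
            break
    if return_history:
        return fused, np.asarray(history)
    return fused


class SNFusion:
    """Similarity network fusion as a fit-style estimator.

    ``fit`` takes a list/dict of complete, standardized patients x
    features matrices (one per domain, same patient order) and exposes:

    - ``kernels_`` : per-domain raw kernels W
    - ``fused_affinity_`` : the fused patient similarity network
    - ``iteration_deltas_`` : per-round max change (convergence trace)
    """

    def __init__(self, K: int = 20, mu: float = 0.5, T: int = 20):
        self.K = K
        self.mu = mu
        self.T = T

    def get_params(self, deep: bool = True) -> dict:
        return {"K": self.K, "mu": self.mu, "T": self.T}

    def set_params(self, **params) -> "SNFusion":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, Xs) -> "SNFusion":
        if isinstance(Xs, dict):
            self.domains_ = list(Xs.keys())
            mats = list(Xs.values())
        else:
            mats = list(Xs)
            self.domains_ = [getattr(X, "domain", f"domain_{i}")
                             for i, X in enumerate(mats)]
        # accept FeatureBlocks or plain matrices
        mats = [X.values.to_numpy(dtype=float) if hasattr(X, "values") and
                hasattr(X, "domain") else np.asarray(X, dtype=float)
                for X in mats]
        self.kernels_ = [
            affinity(euclidean_distance_matrix(X), K=self.K, mu=self.mu)
            for X in mats
        ]
        self.fused_affinity_, self.iteration_deltas_ = fuse(
            self.kernels_, K=self.K, T=self.T, return_history=True)
        return self

    def fit_transform(self, Xs) -> np.ndarray:
        return self.fit(Xs).fused_affinity_
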