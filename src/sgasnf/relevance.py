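"""Feature relevance to the fused clustering and data-type contributions.

Each feature's relevance is the normalized mutual information (NMI,
arithmetic-mean normalization) between the fused cluster labels and a
single-feature spectral clustering built with the same kernel settings
as the fusion. The fused network's edges are additionally decomposed by
supporting data type: an edge (a strongly similar patient pair in the
fused network) is credited to every domain whose rank-normalized
affinity for that pair reaches a fraction of the fused value.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import normalized_mutual_info_score

from .datatypes import ClusterAssignment, FeatureBlock
from .cluster import spectral_cluster
from .snf import affinity, euclidean_distance_matrix


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Symmetric; 1 iff the partitions are identical up to relabeling;
    normalized by the arithmetic mean of the entropies.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("NMI needs at least two observations")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def rank_features_by_nmi(
    blocks: dict[str, FeatureBlock] | Sequence[FeatureBlock],
    fused: ClusterAssignment,
    k: int | None = None,
    K: int = 20,
    mu: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every feature by NMI with the fused cluster labels.

    Each feature is clustered on its own (single-column affinity with
    the fusion's kernel settings, spectral clustering into k groups) and
    compared to the fused labels. Returns a frame sorted by descending
    NMI (ties by domain then name) with a 1-based ``rank`` column.
    Constant features score 0 with a warning.
    """
    if k is None:
        k = fused.k
    if isinstance(blocks, dict):
        items = list(blocks.values())
    else:
        items = list(blocks)
    rows = []
    for block in items:
        if not block.is_complete():
            raise ValueError(f"block {block.domain!r} has missing cells")
        X = block.values.to_numpy(dtype=float)
        for j, name in enumerate(block.feature_names):
            col = X[:, j:j + 1]
            if col.std() == 0:
                warnings.warn(f"constant feature {name!r}: NMI set to 0")
                score = 0.0
            else:
                W = affinity(euclidean_distance_matrix(col), K=K, mu=mu)
                assign = spectral_cluster(W, k, seed=seed,
                                          source=f"feature:{name}")
                score = nmi(assign.labels, fused.labels)
            rows.append({"feature": name, "domain": block.domain, "nmi": score})
    out = pd.DataFrame(rows).sort_values(
        by=["nmi", "domain", "feature"], ascending=[False, True, True],
        kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _rank_normalize(M: np.ndarray) -> np.ndarray:
    """Map the off-diagonal upper triangle to (0, 1] by midrank / count."""
    n = M.shape[0]
    iu = np.triu_indices(n, 1)
    r = rankdata(M[iu]) / iu[0].size
    R = np.zeros_like(M, dtype=float)
    R[iu] = r
    return R + R.T


def datatype_contribution(
    w_list: Sequence[np.ndarray],
    fused_w: np.ndarray,
    edge_quantile: float = 0.9,
    support_ratio: float = 0.5,
    domains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percentage of fused-network edges supported by each data type.

    The edge set is the patient pairs whose rank-normalized fused
    affinity exceeds ``edge_quantile``. A domain supports an edge when
    its rank-normalized affinity for that pair is at least
    ``support_ratio`` times the fused rank-normalized value. Percentages
    are over (edge, supporting-domain) attributions and sum to 100.
    """
    if not (0 < edge_quantile < 1):
        raise ValueError("edge_quantile must be in (0, 1)")
    n = fused_w.shape[0]
    for W in w_list:
        if W.shape != fused_w.shape:
            raise ValueError("domain and fused matrices are not aligned")
    F = _rank_normalize(np.asarray(fused_w, dtype=float))
    iu = np.triu_indices(n, 1)
    edge_mask = F[iu] > edge_quantile
    if not edge_mask.any():
        raise ValueError("empty edge set at this quantile")
    fused_vals = F[iu][edge_mask]
    supports = []
    for W in w_list:
        R = _rank_normalize(np.asarray(W, dtype=float))
        supports.append(int((R[iu][edge_mask] >= support_ratio * fused_vals).sum()))
    total = sum(supports)
    if total == 0:
        raise ValueError("no domain supports any edge at this support ratio")
    if domains is None:
        domains = [f"domain_{i}" for i in range(len(w_list))]
    return pd.DataFrame({
        "domain": list(domains),
        "supported_edges": supports,
        "percent": [100.0 * s / total for s in supports],
    })
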