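"""Clustering of compound phenotypic profiles and expression responses.

Phenotypic feature matrices (LD50/EC50 ratio, maximal regulatory-lineage
enhancement, Th1/Th17 inhibition) are standardized and clustered by
1 - Pearson correlation with complete linkage. Expression-response profiles
are replicate-averaged, reduced by PCA to the fewest components explaining
90% of variance (genes as features), and the normalized component scores are
clustered by Euclidean distance with complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .datamodel import ExpressionMatrix, ValidationError

__all__ = [
    "standardize_features",
    "Dendrogram",
    "correlation_cluster",
    "euclidean_cluster",
    "average_replicates",
    "PCAReduction",
    "pca_reduce",
]


def standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Column-standardize a compounds x features matrix to mean 0, sample
    (n-1) standard deviation 1. Zero-variance features are an error."""
    sd = features.std(axis=0, ddof=1)
    zero = sd[(sd == 0) | sd.isna()].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance feature(s): {zero}")
    return (features - features.mean(axis=0)) / sd


@dataclass
class Dendrogram:
    """Agglomeration result: merge table with non-decreasing heights and the
    leaf order of the corresponding tree."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy linkage format
    merges: pd.DataFrame  # columns: id1, id2, height, size
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def _cluster(dist_condensed: np.ndarray, labels: list[str]) -> Dendrogram:
    Z = linkage(dist_condensed, method="complete")
    n = len(labels)
    cluster_names: dict[int, str] = {i: labels[i] for i in range(n)}
    rows = []
    for step, (a, b, h, size) in enumerate(Z):
        ia, ib = int(a), int(b)
        name_a, name_b = cluster_names[ia], cluster_names[ib]
        id1, id2 = sorted([name_a, name_b])
        rows.append({"id1": id1, "id2": id2, "height": float(h), "size": int(size)})
        cluster_names[n + step] = f"({id1}|{id2})"
    order = [labels[i] for i in leaves_list(Z)]
    return Dendrogram(
        labels=labels,
        linkage_matrix=Z,
        merges=pd.DataFrame(rows),
        leaf_order=order,
    )


def correlation_cluster(features: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of compounds under the
    1 - Pearson-correlation distance between feature rows.

    Rows are ordered lexicographically by compound id before clustering so
    that ties break deterministically.
    """
    if features.shape[0] < 2 or features.shape[1] < 2:
        raise ValidationError("need >= 2 compounds and >= 2 features")
    features = features.sort_index()
    values = features.to_numpy(dtype=float)
    if np.any(values.std(axis=1) == 0):
        raise ValidationError("constant feature row: Pearson distance undefined")
    dist = 1.0 - np.corrcoef(values)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize rounding noise
    return _cluster(squareform(dist, checks=False), [str(i) for i in features.index])


def euclidean_cluster(scores: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration under Euclidean distance between rows."""
    if scores.shape[0] < 2:
        raise ValidationError("need >= 2 instances")
    scores = scores.sort_index()
    return _cluster(
        pdist(scores.to_numpy(dtype=float), metric="euclidean"),
        [str(i) for i in scores.index],
    )


def average_replicates(
    expr: ExpressionMatrix, replicate_map: dict[str, str]
) -> ExpressionMatrix:
    """Arithmetic per-gene mean within replicate groups.

    ``replicate_map`` assigns every sample to a replicate group; samples from
    distinct doses or cell lines must be given distinct groups by the caller
    (they are never merged here).
    """
    missing = [s for s in expr.sample_ids if s not in replicate_map]
    if missing:
        raise ValidationError(f"samples without a replicate group: {missing[:10]}")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(expr.sample_ids):
        groups.setdefault(replicate_map[s], []).append(i)
    group_names = list(groups)
    values = np.column_stack(
        [expr.values[:, groups[g]].mean(axis=1) for g in group_names]
    )
    return ExpressionMatrix(expr.gene_ids, group_names, values)


@dataclass
class PCAReduction:
    """PCA of instances x genes data, truncated at a cumulative
    explained-variance target."""

    scores: pd.DataFrame  # instances x k, unit-variance (normalized) scores
    k: int
    explained_variance_ratio: np.ndarray  # all components, sums to 1

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def pca_reduce(
    data: pd.DataFrame | np.ndarray | ExpressionMatrix,
    variance_target: float = 0.90,
) -> PCAReduction:
    """Reduce instances x genes data to the smallest number of principal
    components whose cumulative explained variance reaches ``variance_target``.

    Genes are the features: each gene column is mean-centered, the SVD taken,
    and the retained scores divided by their singular-value-implied standard
    deviation (unit-variance 'normalized' scores).
    An :class:`ExpressionMatrix` (genes x samples) is transposed on entry.
    """
    if not 0 < variance_target <= 1:
        raise ValidationError("variance_target must be in (0, 1]")
    if isinstance(data, ExpressionMatrix):
        X = data.values.T
        index = list(data.sample_ids)
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
        index = [str(i) for i in data.index]
    else:
        X = np.asarray(data, dtype=float)
        index = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 instances for PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S**2))
    if total == 0:
        raise ValidationError("data has zero variance")
    evr = S**2 / total
    k = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
    k = min(k, np.count_nonzero(S > S[0] * 1e-12))
    scores = U[:, :k] * np.sqrt(n - 1)
    return PCAReduction(
        scores=pd.DataFrame(scores, index=index, columns=[f"PC{i+1}" for i in range(k)]),
        k=k,
        explained_variance_ratio=evr,
    )
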