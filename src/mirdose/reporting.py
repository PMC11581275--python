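"""Descriptive reports: PCA and Euclidean hierarchical clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA


def pca_report(values: pd.DataFrame, n_components: int | None = None) -> dict:
    """Centered PCA of samples (columns) over features (rows).

    Returns component scores per sample and explained-variance fractions,
    which sum to 1 over all retained components.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 features and 2 samples")
    X = values.to_numpy(float).T  # samples x features
    if np.allclose(X, X.mean(axis=0), atol=1e-12):
        raise ValueError("constant matrix has no principal components")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    n_components = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    total_var = X.var(axis=0, ddof=1).sum()
    fractions = pca.explained_variance_ / total_var
    return {
        "scores": pd.DataFrame(
            scores,
            index=values.columns,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        "explained_fraction": fractions,
    }


def hclust_report(values: pd.DataFrame, subset=None, linkage_method: str = "average") -> dict:
    """Agglomerative clustering of samples by Euclidean distance.

    Returns the linkage matrix, the dendrogram leaf order and the
    feature-subset matrix with columns in leaf order.
    """
    if subset is not None:
        missing = [f for f in subset if f not in values.index]
        if missing:
            raise ValueError(f"features not in matrix: {missing}")
        values = values.loc[list(subset)]
    if values.empty:
        raise ValueError("empty feature subset")
    X = values.to_numpy(float).T
    if X.shape[0] == 1:
        return {
            "linkage": np.empty((0, 4)),
            "leaf_order": list(values.columns),
            "ordered": values,
        }
    dist = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dist, method=linkage_method)
    order = hierarchy.leaves_list(Z)
    cols = [values.columns[i] for i in order]
    return {"linkage": Z, "leaf_order": cols, "ordered": values[cols]}
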