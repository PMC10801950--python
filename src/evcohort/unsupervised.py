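"""Unsupervised subject-level analyses: PCA and hierarchical clustering.

Subjects are projected onto principal components of the standardized
variable matrix and clustered with Ward linkage on a correlation distance
between subject profiles; agreement with the (withheld) diagnosis labels is
scored by adjusted Rand index and purity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .cohort import ZScoreTable


class UnsupervisedError(ValueError):
    """Invalid input to an unsupervised analysis."""


@dataclass
class PCAResult:
    """Principal-component decomposition of the centered Z-score matrix.

    ``scores`` (subjects × components) are the projections X·V; ``loadings``
    (variables × components) are orthonormal; ``explained_variance_ratio``
    is non-increasing and sums to ≤ 1.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


@dataclass
class SubjectClustering:
    """Ward tree over subjects with a flat cut and diagnosis agreement.

    ``ari`` is the adjusted Rand index between cluster labels and diagnosis
    (1 = identical partitions, ~0 at chance); ``purity`` is the fraction of
    subjects in their cluster's majority diagnosis.
    """

    linkage_matrix: np.ndarray
    subjects: list
    labels: dict
    n_clusters: int
    ari: float
    purity: float


def _require_complete(table: ZScoreTable) -> pd.DataFrame:
    if table.data.isna().any().any():
        raise UnsupervisedError(
            "table contains missing values; apply complete_case_filter before "
            "PCA / subject clustering"
        )
    return table.data


def pca_subjects(table: ZScoreTable, n_components: int | None = None) -> PCAResult:
    """PCA of the subjects via SVD of the column-centered Z-score matrix.

    Incoming variables are already unit-variance, so no further scaling is
    applied.  At most min(n−1, p) components carry variance.
    """
    data = _require_complete(table)
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    total_var = (s**2).sum()
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=data.columns, columns=comp_names),
        explained_variance_ratio=evr,
    )


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """Pairwise 1 − Pearson r between rows (subject profiles)."""
    r = np.corrcoef(x)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_subjects(
    table: ZScoreTable, n_clusters: int = 2, squared: bool = False
) -> SubjectClustering:
    """Ward clustering of subjects on the correlation distance 1 − r.

    ``squared=False`` (default) is Ward on the *unsquared* distances — the
    merge order of R's ward.D, obtained by handing sqrt(d) to scipy's ward
    (which operates ward.D2-style on squared input).  ``squared=True`` gives
    classical Ward on squared distances for comparison.  Diagnosis and sex
    are labels, never features; agreement with diagnosis is reported as ARI
    and purity.  Subjects are ordered by id internally, so the result does
    not depend on input row order.
    """
    data = _require_complete(table)
    if n_clusters < 2:
        raise UnsupervisedError(f"n_clusters must be >= 2, got {n_clusters}")
    if n_clusters > len(data):
        raise UnsupervisedError(
            f"n_clusters={n_clusters} exceeds the {len(data)} subjects"
        )
    order = np.argsort(data.index.to_numpy())
    subjects = list(data.index[order])
    x = data.to_numpy(dtype=float)[order]
    d = _correlation_distance(x)
    condensed = squareform(d, checks=False)
    z = linkage(np.sqrt(condensed) if not squared else condensed, method="ward")
    flat = fcluster(z, t=n_clusters, criterion="maxclust")
    labels = {s: int(c) for s, c in zip(subjects, flat)}
    diagnosis = table.diagnosis.loc[subjects].to_numpy()
    ari = float(adjusted_rand_score(diagnosis, flat))
    purity = 0.0
    for c in np.unique(flat):
        members = diagnosis[flat == c]
        purity += pd.Series(members).value_counts().iloc[0]
    purity /= len(subjects)
    return SubjectClustering(
        linkage_matrix=z,
        subjects=subjects,
        labels=labels,
        n_clusters=n_clusters,
        ari=ari,
        purity=float(purity),
    )


def linkage_to_newick(clustering: SubjectClustering) -> str:
    """Export the subject tree as a Newick string with merge heights."""
    tree = to_tree(clustering.linkage_matrix)
    names = [str(s) for s in clustering.subjects]

    def recurse(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


__all__ = [
    "UnsupervisedError",
    "PCAResult",
    "SubjectClustering",
    "pca_subjects",
    "cluster_subjects",
    "linkage_to_newick",
]
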