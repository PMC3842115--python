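"""Sample-level hierarchical clustering of the common-protein matrix.

Samples are compared by the Euclidean distance between their paired protein
vectors (log2 pool-relative ratios by default, raw ratios optionally) and
agglomerated with a configurable linkage.  The resulting dendrogram orders
the heatmap and lets group cohesion be quantified by cutting it into k
clusters and scoring majority-group purity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InvalidDataError
from .quantio import ExpressionMatrix

LINKAGES = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-style merge matrix plus leaf labels."""

    merges: np.ndarray          # (n-1, 4) scipy linkage matrix
    labels: tuple[str, ...]     # sample ids in original column order
    linkage: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def cut(self, k: int) -> pd.Series:
        """Cluster assignment (1..k) from cutting the tree into k clusters."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in [1, {len(self.labels)}]")
        assign = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(assign, index=list(self.labels), name="cluster")


def sample_distance_matrix(m: ExpressionMatrix, log_transform: bool = True) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample columns.

    Requires a complete matrix (run after the common-protein filter).  With
    ``log_transform`` the distance is computed on log2 ratios, treating up-
    and down-regulation symmetrically.
    """
    if not m.is_complete:
        raise InvalidDataError("distance matrix requires a complete matrix")
    x = m.values.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x)
    diff = x[:, :, None] - x[:, None, :]
    d = np.sqrt((diff ** 2).sum(axis=0))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


def hierarchical_cluster(d: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if d.shape[0] < 2:
        raise ValueError("hierarchical clustering needs at least 2 samples")
    if not np.allclose(d.to_numpy(), d.to_numpy().T):
        raise InvalidDataError("distance matrix must be symmetric")
    condensed = squareform(d.to_numpy(dtype=float), checks=False)
    merges = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(merges, tuple(d.index), linkage)


def group_purity(dend: Dendrogram, meta: pd.DataFrame, k: int) -> float:
    """Majority-group purity of the k-cluster cut, in [0, 1].

    Cuts the dendrogram into k clusters; purity is the summed majority-group
    count over clusters divided by the number of samples.  1.0 means the cut
    cosegregates entirely by sample group.
    """
    assign = dend.cut(k)
    groups = meta.set_index("sample_id")["group"].reindex(assign.index)
    total = 0
    for _, members in groups.groupby(assign):
        total += int(members.value_counts().iloc[0])
    return total / len(assign)


def to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram as Newick, sample ids as leaves and the height
    drop between merges as branch lengths."""
    tree = hierarchy.to_tree(dend.merges)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{dend.labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
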