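"""Generalized Jaccard similarity between key vectors and average-linkage
clustering of the derived distance matrix.

For two structures p1, p2 with key-frequency vectors, over the union of
their keys:

    Jac_gen = Σ_i min(c1_i, c2_i) / Σ_i max(c1_i, c2_i)

(a key absent from a structure counts 0).  Distance = 1 − similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .keys import KeyVector

__all__ = [
    "generalized_jaccard",
    "SimilarityMatrix",
    "similarity_matrix",
    "Dendrogram",
    "average_linkage_cluster",
    "mean_pairwise_similarity",
]


def generalized_jaccard(p1: KeyVector, p2: KeyVector) -> float:
    """Σ min / Σ max of key counts over the union of keys; in [0, 1]."""
    if not p1.counts and not p2.counts:
        raise ValueError("generalized Jaccard is undefined for two empty key vectors")
    num = 0
    den = 0
    for key in p1.counts.keys() | p2.counts.keys():
        a = p1.counts.get(key, 0)
        b = p2.counts.get(key, 0)
        num += min(a, b)
        den += max(a, b)
    return num / den


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Jac_gen matrix with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    @property
    def distances(self) -> np.ndarray:
        return 1.0 - self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path, distance=False) -> None:
        frame = pd.DataFrame(
            self.distances if distance else self.values,
            index=self.ids, columns=self.ids,
        )
        frame.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(ids=list(frame.index), values=frame.to_numpy(dtype=float))


def similarity_matrix(vectors) -> SimilarityMatrix:
    """Pairwise generalized Jaccard over a list of key vectors."""
    vectors = list(vectors)
    if len(vectors) < 2:
        raise ValueError("need at least two key vectors")
    ids = [v.structure_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate structure ids in similarity input")
    n = len(vectors)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = generalized_jaccard(vectors[i], vectors[j])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids=ids, values=values)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over structures."""

    ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.ids)
        return str(tree).strip()


def average_linkage_cluster(matrix: SimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering (unweighted average linkage, UPGMA) on
    distance = 1 − similarity."""
    dist = matrix.distances.copy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    return Dendrogram(ids=list(matrix.ids), linkage=Z)


def mean_pairwise_similarity(matrix: SimilarityMatrix, weights=None) -> float:
    """Summary similarity of a set of structures.

    Default: unweighted mean over all unordered pairs.  ``weights`` may
    give per-structure weights; a pair's weight is the product of its
    members' weights.
    """
    n = len(matrix.ids)
    iu = np.triu_indices(n, k=1)
    vals = matrix.values[iu]
    if weights is None:
        return float(vals.mean())
    w = np.asarray(weights, dtype=float)
    pair_w = (w[:, None] * w[None, :])[iu]
    return float(np.average(vals, weights=pair_w))
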