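"""k-nearest-neighbor affinity graphs and their Laplacians.

The adjacency is row-wise: A_ij = 1 iff j is among the k most similar
non-self entities to i, so A may be asymmetric.  The degree matrix U is
diagonal with the row sums of A and the Laplacian is L = U - A, giving the
smoothing identity (for symmetric A)

    1/2 sum_ij A_ij ||F_i - F_j||^2 = tr(F^T L F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import SimilarityMatrix

__all__ = ["GraphPair", "knn_graph"]


@dataclass
class GraphPair:
    """Adjacency A, diagonal degrees U and Laplacian L = U - A of a k-NN graph."""

    A: np.ndarray
    U: np.ndarray
    L: np.ndarray
    k: int

    @property
    def degrees(self) -> np.ndarray:
        return np.diag(self.U)


def knn_graph(S: SimilarityMatrix | np.ndarray, k: int) -> GraphPair:
    """Build the k-NN graph of a similarity matrix.

    Neighbors are the k most similar non-self entities per row; similarity
    ties are broken in favor of the lower index, so the construction is
    deterministic.
    """
    Svals = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = Svals.shape[0]
    if Svals.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    A = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        row = Svals[i].copy()
        row[i] = -np.inf  # exclude self
        # stable sort on (-similarity, index): ties go to the lower index
        order = np.lexsort((idx, -row))
        A[i, order[:k]] = 1.0
    deg = A.sum(axis=1)
    U = np.diag(deg)
    return GraphPair(A=A, U=U, L=U - A, k=k)
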