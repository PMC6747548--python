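"""Drug-drug similarity views.

Views 1-3 use cosine similarity between the drugs' binary descriptor
vectors.  View 4 compares the sets of diseases two drugs are associated
with, using a best-match-average over a precomputed disease-disease
semantic similarity matrix: for drug pair (i, j) with associated disease
sets Di (size m) and Dj (size n),

    R4_ij = [ sum_{a in Di} max_{b in Dj} D_ab
            + sum_{b in Dj} max_{a in Di} D_ba ] / (m + n).
"""

from __future__ import annotations

import numpy as np

from .datatypes import FeatureMatrix, SimilarityMatrix, ValidationError

__all__ = [
    "cosine_similarity",
    "disease_set_similarity",
    "association_similarity",
]


def cosine_similarity(X: FeatureMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity between drug column vectors of a view.

    Drugs whose feature vector is all-zero are uninformative: every
    similarity involving them, including self-similarity, is defined as 0.
    """
    V = X.values
    norms = np.linalg.norm(V, axis=0)
    nz = norms > 0
    safe = np.where(nz, norms, 1.0)
    G = (V / safe).T @ (V / safe)
    G[~nz, :] = 0.0
    G[:, ~nz] = 0.0
    np.clip(G, 0.0, 1.0, out=G)
    # exact unit diagonal for drugs with a nonzero feature vector
    G[np.diag_indices_from(G)] = np.where(nz, 1.0, 0.0)
    G = (G + G.T) / 2.0
    return SimilarityMatrix(values=G, entity_ids=list(X.drug_ids), kind=f"drug_view_{X.view_id}")


def disease_set_similarity(Di, Dj, D: SimilarityMatrix | np.ndarray) -> float:
    """Best-match-average similarity between two disease index sets.

    Empty sets have no disease profile to compare; the similarity is
    defined as 0 when either set is empty.
    """
    Dvals = D.values if isinstance(D, SimilarityMatrix) else np.asarray(D)
    Di = np.asarray(sorted(Di), dtype=int)
    Dj = np.asarray(sorted(Dj), dtype=int)
    if Di.size == 0 or Dj.size == 0:
        return 0.0
    sub = Dvals[np.ix_(Di, Dj)]
    return float((sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (Di.size + Dj.size))


def association_similarity(X4: FeatureMatrix, D: SimilarityMatrix) -> SimilarityMatrix:
    """Fourth drug similarity view from associated-disease profiles.

    ``X4`` is the binary (diseases x drugs) association view; ``D`` the
    disease-disease semantic similarity.  Two drugs associated with more
    similar disease sets score higher.  The diagonal is set to 1 for drugs
    with at least one association; a drug with no associations has an
    all-zero row and column (including its own diagonal).
    """
    if X4.view_id != 4:
        raise ValidationError("association_similarity expects the view-4 matrix")
    if X4.n_features != D.n:
        raise ValidationError(
            f"view-4 has {X4.n_features} diseases but D is {D.n} x {D.n}"
        )
    n = X4.n_drugs
    sets = [np.flatnonzero(X4.values[:, j] > 0) for j in range(n)]
    R = np.zeros((n, n))
    for i in range(n):
        if sets[i].size == 0:
            continue
        R[i, i] = 1.0
        for j in range(i + 1, n):
            if sets[j].size == 0:
                continue
            R[i, j] = R[j, i] = disease_set_similarity(sets[i], sets[j], D)
    np.clip(R, 0.0, 1.0, out=R)
    return SimilarityMatrix(values=R, entity_ids=list(X4.drug_ids), kind="drug_view_4")
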