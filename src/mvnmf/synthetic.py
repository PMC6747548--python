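"""Seeded generator of synthetic drug-disease datasets with planted structure.

The generator emulates the statistical shape the model assumes: drugs and
diseases share a low-rank non-negative latent structure; the binary
association matrix is the thresholded top of the latent drug-disease score
surface at a configurable density; the three binary feature views are
view-specific non-negative loadings of the drug factors binarized at
per-row quantiles (shared latent signal plus view-specific noise — the
structure the diversity term exploits); and the disease semantic
similarity is the cosine similarity of the latent disease factors.

Drugs and diseases are organized into ``latent_rank`` blocks (entity j
belongs to block j mod rank) with strong within-block loadings over a weak
random background, so same-block drugs have similar features and similar
disease associations.  The generator returns the full ground truth so
recovery can be verified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AssociationData, FeatureMatrix, SimilarityMatrix

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "hide_associations"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dataset generator.

    The defaults (60 drugs x 40 diseases, association density 0.006, i.e.
    about 14 known associations) mirror the sparsity of curated
    drug-disease association tables at desk scale; feature dimensions
    stand in for high-dimensional binary fingerprint/domain/annotation
    vectors.
    """

    n_drugs: int = 60
    n_diseases: int = 40
    feature_dims: tuple[int, int, int] = (100, 150, 200)
    latent_rank: int = 4
    association_density: float = 0.006
    feature_density: float = 0.1
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.association_density < 1:
            raise ValueError("association_density must be in (0, 1)")
        if not 0 < self.feature_density < 1:
            raise ValueError("feature_density must be in (0, 1)")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if not 1 <= self.latent_rank < min(self.n_drugs, self.n_diseases):
            raise ValueError("latent_rank must be below min(n_drugs, n_diseases)")
        n_pos = round(self.association_density * self.n_drugs * self.n_diseases)
        if n_pos < 1:
            raise ValueError("association_density yields zero positives")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    views: list[FeatureMatrix]  # 4 views; views[3] is the association profile
    assoc: AssociationData
    D: SimilarityMatrix
    drug_factors: np.ndarray  # G, (rank x n_drugs)
    disease_factors: np.ndarray  # P, (rank x n_diseases)
    score_matrix: np.ndarray  # G^T P, the latent association propensities
    drug_blocks: np.ndarray
    disease_blocks: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)


def _block_factors(rng, rank: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative factors with one dominant block per entity."""
    blocks = np.arange(n) % rank
    G = 0.1 * rng.random((rank, n))
    G[blocks, np.arange(n)] += 0.6 + 0.4 * rng.random(n)
    return G, blocks


def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Draw a complete synthetic dataset from ``spec`` (seeded, reproducible)."""
    if spec is None:
        spec = SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    r, nr, nd = spec.latent_rank, spec.n_drugs, spec.n_diseases
    G, drug_blocks = _block_factors(rng, r, nr)
    P, disease_blocks = _block_factors(rng, r, nd)
    scores = G.T @ P

    # associations: top entries of the latent score surface, ties by index
    n_pos = round(spec.association_density * nr * nd)
    flat = scores.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    Y = np.zeros(nr * nd)
    Y[order[:n_pos]] = 1.0
    Y = Y.reshape(nr, nd)

    drug_ids = [f"drug_{i:03d}" for i in range(nr)]
    disease_ids = [f"disease_{j:03d}" for j in range(nd)]
    assoc = AssociationData(Y=Y, drug_ids=drug_ids, disease_ids=disease_ids)

    # binary feature views: view-specific loadings of the drug factors,
    # binarized per feature row at the (1 - density) quantile, then flipped
    # independently with probability noise_rate
    views: list[FeatureMatrix] = []
    for v, dim in enumerate(spec.feature_dims, start=1):
        Q = rng.random((dim, r))
        Z = Q @ G + 0.05 * rng.random((dim, nr))
        thr = np.quantile(Z, 1.0 - spec.feature_density, axis=1, keepdims=True)
        X = (Z > thr).astype(float)
        if spec.noise_rate > 0:
            flips = rng.random(X.shape) < spec.noise_rate
            X = np.where(flips, 1.0 - X, X)
        views.append(
            FeatureMatrix(
                values=X,
                view_id=v,
                feature_ids=[f"v{v}_feat_{i:04d}" for i in range(dim)],
                drug_ids=drug_ids,
            )
        )
    views.append(assoc.as_feature_view())

    # disease similarity: cosine of the latent disease factor columns
    norms = np.linalg.norm(P, axis=0)
    Dv = (P / norms).T @ (P / norms)
    np.clip(Dv, 0.0, 1.0, out=Dv)
    Dv[np.diag_indices_from(Dv)] = 1.0
    Dv = (Dv + Dv.T) / 2.0
    D = SimilarityMatrix(values=Dv, entity_ids=disease_ids, kind="disease")

    return SyntheticDataset(
        views=views,
        assoc=assoc,
        D=D,
        drug_factors=G,
        disease_factors=P,
        score_matrix=scores,
        drug_blocks=drug_blocks,
        disease_blocks=disease_blocks,
        spec=spec,
    )


def hide_associations(
    assoc: AssociationData, fraction: float, seed: int = 0
) -> tuple[AssociationData, np.ndarray]:
    """Uniformly remove ``ceil(fraction * n_pos)`` positives for hold-out tests.

    Returns the masked association data and the held-out (drug, disease)
    index pairs.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    pairs = assoc.positive_pairs
    n_hide = int(np.ceil(fraction * len(pairs)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=n_hide, replace=False)
    held_out = pairs[np.sort(chosen)]
    Y = assoc.Y.copy()
    Y[held_out[:, 0], held_out[:, 1]] = 0.0
    if Y.sum() == 0:
        warnings.warn("all positives were hidden; no training signal remains")
    masked = AssociationData(
        Y=Y, drug_ids=list(assoc.drug_ids), disease_ids=list(assoc.disease_ids)
    )
    return masked, held_out
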