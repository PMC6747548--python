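"""Multi-view non-negative matrix factorization for drug-disease scoring.

The model jointly factorizes four drug feature views X(v) (features x
drugs) as X(v) ~ W(v) H(v), with each view's latent representation H(v)
(diseases x drugs) projected into the disease dimension, and couples them
to a non-negative drug-disease score matrix F (drugs x diseases) through

    J(F, H, W) = ||M o (F - Y)||_F^2
               + a1 sum_v ||X(v) - W(v) H(v)||_F^2
               + a2 sum_{w != v} tr(H(v)^T H(w))
               + a3 sum_v ||F - H(v)^T||_F^2
               + a4 ( sum_v tr(F^T L(v) F) + tr(F L_d F^T) )
               + a5 ||F||_1

where M is the observation mask (M = Y for a fully observed binary
association table), the diversity term sums over ordered view pairs
(12 terms), L(v) are k-NN graph Laplacians over drugs per similarity view
and L_d the disease k-NN Laplacian.  All three blocks are optimized by
multiplicative updates derived from the KKT conditions of the three
subproblems, which preserve non-negativity and keep zero entries at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationData,
    FeatureMatrix,
    Hyperparameters,
    SimilarityMatrix,
    ValidationError,
)
from .graphs import GraphPair, knn_graph
from .similarity import association_similarity, cosine_similarity

__all__ = [
    "FitTrace",
    "MultiViewNMF",
    "MultiViewNMFResults",
    "objective_terms",
    "update_f",
    "update_h",
    "update_w",
    "kkt_residuals",
]

TERM_NAMES = ("loss", "reconstruction", "diversity", "consistency", "smoothness", "sparsity")


# ---------------------------------------------------------------------------
# objective and multiplicative updates on raw arrays
# ---------------------------------------------------------------------------

def objective_terms(
    F: np.ndarray,
    H: Sequence[np.ndarray],
    W: Sequence[np.ndarray],
    X: Sequence[np.ndarray],
    Y: np.ndarray,
    M: np.ndarray,
    drug_graphs: Sequence[GraphPair] | None,
    disease_graph: GraphPair | None,
    hp: Hyperparameters,
) -> dict[str, float]:
    """Weighted value of each objective term plus their sum (``objective``)."""
    a1, a2, a3, a4, a5 = hp.alphas
    terms: dict[str, float] = {}
    terms["loss"] = float(np.sum((M * (F - Y)) ** 2))
    terms["reconstruction"] = a1 * float(
        sum(np.sum((Xv - Wv @ Hv) ** 2) for Xv, Wv, Hv in zip(X, W, H))
    )
    div = 0.0
    for v in range(len(H)):
        for w in range(len(H)):
            if w != v:
                div += float(np.sum(H[v] * H[w]))  # tr(H(v)^T H(w))
    terms["diversity"] = a2 * div
    terms["consistency"] = a3 * float(sum(np.sum((F - Hv.T) ** 2) for Hv in H))
    smooth = 0.0
    if drug_graphs:
        smooth += sum(float(np.sum(F * (g.L @ F))) for g in drug_graphs)
    if disease_graph is not None:
        smooth += float(np.sum(F * (F @ disease_graph.L)))
    terms["smoothness"] = a4 * smooth
    terms["sparsity"] = a5 * float(np.sum(np.abs(F)))
    terms["objective"] = float(sum(terms[t] for t in TERM_NAMES))
    return terms


def update_f(
    F: np.ndarray,
    H: Sequence[np.ndarray],
    Y: np.ndarray,
    M: np.ndarray,
    drug_graphs: Sequence[GraphPair] | None,
    disease_graph: GraphPair | None,
    hp: Hyperparameters,
) -> np.ndarray:
    """One multiplicative update of the score matrix F.

    Elementwise
        F <- F * (2 M o Y + 2 a3 sum_v H(v)^T + 2 a4 sum_v A(v) F + 2 a4 F A_d)
               / (2 M o F + 8 a3 F + 2 a4 sum_v U(v) F + 2 a4 F U_d + a5 B + eps)
    with B the all-ones matrix.  With ``hp.unscaled_f_shrinkage`` the
    denominator shrinkage term is the unscaled ``8 F`` variant.
    """
    _, _, a3, a4, a5 = hp.alphas
    num = 2.0 * (M * Y)
    shrink = 8.0 if hp.unscaled_f_shrinkage else 8.0 * a3
    den = 2.0 * (M * F) + shrink * F + a5  # a5 * B, B all-ones
    for Hv in H:
        num = num + 2.0 * a3 * Hv.T
    if drug_graphs:
        for g in drug_graphs:
            num = num + 2.0 * a4 * (g.A @ F)
            den = den + 2.0 * a4 * (g.U @ F)
    if disease_graph is not None:
        num = num + 2.0 * a4 * (F @ disease_graph.A)
        den = den + 2.0 * a4 * (F @ disease_graph.U)
    return F * (num / (den + hp.epsilon))


def update_h(
    H: Sequence[np.ndarray],
    v: int,
    F: np.ndarray,
    W_v: np.ndarray,
    X_v: np.ndarray,
    hp: Hyperparameters,
) -> np.ndarray:
    """One multiplicative update of view ``v``'s latent matrix H(v).

    Elementwise
        H(v) <- H(v) * (2 a1 W(v)^T X(v) + 2 a3 F^T)
                     / (2 a1 W(v)^T W(v) H(v) + a2 sum_{w != v} H(w) + 2 a3 H(v) + eps)
    """
    a1, a2, a3, _, _ = hp.alphas
    Hv = H[v]
    num = 2.0 * a1 * (W_v.T @ X_v) + 2.0 * a3 * F.T
    others = sum(H[w] for w in range(len(H)) if w != v)
    den = 2.0 * a1 * (W_v.T @ W_v @ Hv) + a2 * others + 2.0 * a3 * Hv + hp.epsilon
    return Hv * (num / den)


def update_w(
    W_v: np.ndarray,
    X_v: np.ndarray,
    H_v: np.ndarray,
    hp: Hyperparameters,
) -> np.ndarray:
    """One multiplicative update of view ``v``'s basis matrix W(v).

    The classical NMF basis rule
        W(v) <- W(v) * (X(v) H(v)^T) / (W(v) H(v) H(v)^T + eps).
    """
    num = X_v @ H_v.T
    den = W_v @ (H_v @ H_v.T) + hp.epsilon
    return W_v * (num / den)


def kkt_residuals(
    F: np.ndarray,
    H: Sequence[np.ndarray],
    W: Sequence[np.ndarray],
    X: Sequence[np.ndarray],
    Y: np.ndarray,
    M: np.ndarray,
    drug_graphs: Sequence[GraphPair] | None,
    disease_graph: GraphPair | None,
    hp: Hyperparameters,
) -> dict[str, float]:
    """Max-norm complementarity residuals |gradient o factor| per block.

    These are the stationarity conditions the multiplicative rules are the
    fixed points of; all three vanish at a local minimum of the three
    subproblems.  Computed for the scaled (KKT-consistent) score update.
    """
    a1, a2, a3, a4, a5 = hp.alphas
    grad_F = 2.0 * (M * (F - Y)) + 2.0 * a3 * (len(H) * F - sum(Hv.T for Hv in H)) + a5
    if drug_graphs:
        for g in drug_graphs:
            grad_F = grad_F + 2.0 * a4 * (g.L @ F)
    if disease_graph is not None:
        grad_F = grad_F + 2.0 * a4 * (F @ disease_graph.L)
    res = {"F": float(np.max(np.abs(grad_F * F)))}
    res_H = 0.0
    res_W = 0.0
    for v in range(len(H)):
        others = sum(H[w] for w in range(len(H)) if w != v)
        grad_H = (
            2.0 * a1 * (W[v].T @ (W[v] @ H[v] - X[v]))
            + a2 * others
            + 2.0 * a3 * (H[v] - F.T)
        )
        res_H = max(res_H, float(np.max(np.abs(grad_H * H[v]))))
        grad_W = 2.0 * a1 * ((W[v] @ H[v] - X[v]) @ H[v].T)
        res_W = max(res_W, float(np.max(np.abs(grad_W * W[v]))))
    res["H"] = res_H
    res["W"] = res_W
    return res


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class FitTrace:
    """Objective trajectory of a fit: total and per-term values per iteration."""

    objective_per_iter: list[float] = field(default_factory=list)
    term_values_per_iter: list[dict[str, float]] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.term_values_per_iter)
        df.index.name = "iteration"
        return df


class MultiViewNMF:
    """Drug-disease association model over four drug feature views.

    Parameters
    ----------
    views
        Three (features x drugs) binary feature views (chemical
        substructures, target protein domains, target GO annotations).
        The fourth view, the (diseases x drugs) association profile, is
        derived from ``associations`` so that it always reflects exactly
        the observed training associations.
    associations
        Binary (drugs x diseases) association table; also serves as the
        observation mask of the masked reconstruction loss.
    disease_similarity
        Precomputed symmetric disease-disease semantic similarity in [0, 1].
    hyperparams
        Regularization weights, k for the neighbor graphs, and the
        optimizer settings; see :class:`~mvnmf.datatypes.Hyperparameters`.
    drug_similarities
        Optional precomputed drug similarity views (R1..R4).  When omitted
        they are computed from the views (cosine for views 1-3, the
        best-match-average disease-set similarity for view 4).
    """

    def __init__(
        self,
        views: Sequence[FeatureMatrix],
        associations: AssociationData,
        disease_similarity: SimilarityMatrix,
        hyperparams: Hyperparameters | None = None,
        drug_similarities: Sequence[SimilarityMatrix] | None = None,
    ) -> None:
        if len(views) != 3:
            raise ValidationError(f"expected 3 feature views, got {len(views)}")
        self.hp = hyperparams if hyperparams is not None else Hyperparameters()
        self.assoc = associations
        self.D = disease_similarity
        drug_ids = associations.drug_ids
        for v, fm in enumerate(views, start=1):
            if fm.drug_ids != drug_ids:
                raise ValidationError(f"view {v} drug ids differ from association drug ids")
        if disease_similarity.entity_ids != associations.disease_ids:
            raise ValidationError("disease similarity ids differ from association disease ids")
        self.views = list(views) + [associations.as_feature_view()]
        self.drug_ids = drug_ids
        self.disease_ids = associations.disease_ids
        self.n_drugs = associations.n_drugs
        self.n_diseases = associations.n_diseases

        if drug_similarities is not None:
            if len(drug_similarities) != 4:
                raise ValidationError("expected 4 precomputed drug similarity views")
            self.drug_similarities = list(drug_similarities)
        else:
            self.drug_similarities = [cosine_similarity(fm) for fm in self.views[:3]]
            self.drug_similarities.append(association_similarity(self.views[3], self.D))

        k = self.hp.k_neighbors
        self.drug_graphs = [knn_graph(S, k) for S in self.drug_similarities]
        self.disease_graph = knn_graph(self.D, k)

    @classmethod
    def from_files(
        cls,
        view_paths: Sequence,
        association_path,
        disease_similarity_path,
        hyperparams: Hyperparameters | None = None,
    ) -> "MultiViewNMF":
        """Build the model from TSV/MTX files on disk."""
        from . import io

        views = [io.read_feature_matrix(p, view_id=v) for v, p in enumerate(view_paths, 1)]
        assoc = io.read_association_data(association_path)
        D = io.read_similarity_matrix(disease_similarity_path, kind="disease")
        return cls(views, assoc, D, hyperparams)

    # -- fitting ------------------------------------------------------------

    def initialize(self, seed: int | None = None) -> tuple[np.ndarray, list, list]:
        """Random uniform(0, 1) initialization of F, H(v), W(v), in that order."""
        rng = np.random.default_rng(self.hp.seed if seed is None else seed)
        F = rng.random((self.n_drugs, self.n_diseases))
        H = [rng.random((self.n_diseases, self.n_drugs)) for _ in range(4)]
        W = [rng.random((fm.n_features, self.n_diseases)) for fm in self.views]
        return F, H, W

    def fit(
        self,
        max_iter: int | None = None,
        tol: float | None = None,
        seed: int | None = None,
    ) -> "MultiViewNMFResults":
        """Run the alternating multiplicative updates until convergence.

        Each iteration updates F, then H(1)..H(4), then W(1)..W(4).  The
        loop stops when the relative objective change drops below ``tol``
        or after ``max_iter`` iterations.
        """
        hp = self.hp
        max_iter = hp.max_iter if max_iter is None else max_iter
        tol = hp.tol if tol is None else tol
        F, H, W = self.initialize(seed)
        X = [fm.values for fm in self.views]
        Y, M = self.assoc.Y, self.assoc.M
        trace = FitTrace()
        prev = objective_terms(F, H, W, X, Y, M, self.drug_graphs, self.disease_graph, hp)[
            "objective"
        ]
        for it in range(max_iter):
            F = update_f(F, H, Y, M, self.drug_graphs, self.disease_graph, hp)
            for v in range(4):
                H[v] = update_h(H, v, F, W[v], X[v], hp)
            for v in range(4):
                W[v] = update_w(W[v], X[v], H[v], hp)
            terms = objective_terms(
                F, H, W, X, Y, M, self.drug_graphs, self.disease_graph, hp
            )
            obj = terms["objective"]
            if not np.isfinite(obj):
                raise FloatingPointError(
                    f"objective became non-finite at iteration {it + 1}: {terms}"
                )
            trace.objective_per_iter.append(obj)
            trace.term_values_per_iter.append(terms)
            trace.iterations_run = it + 1
            rel = abs(prev - obj) / max(abs(prev), np.finfo(float).tiny)
            prev = obj
            if rel < tol:
                trace.converged = True
                break
        return MultiViewNMFResults(self, F, H, W, trace)


class MultiViewNMFResults:
    """Fitted factors, score matrix, and diagnostics of a MultiViewNMF fit."""

    def __init__(
        self,
        model: MultiViewNMF,
        F: np.ndarray,
        H: list[np.ndarray],
        W: list[np.ndarray],
        trace: FitTrace,
    ) -> None:
        self.model = model
        self.F = F
        self.H = H
        self.W = W
        self.trace = trace

    @property
    def converged(self) -> bool:
        return self.trace.converged

    @property
    def objective(self) -> float:
        return self.trace.objective_per_iter[-1]

    def scores_frame(self) -> pd.DataFrame:
        """The score matrix F as a labelled (drugs x diseases) DataFrame."""
        return pd.DataFrame(self.F, index=self.model.drug_ids, columns=self.model.disease_ids)

    def predict(self, drug_id: str) -> pd.DataFrame:
        """Ranked disease candidates for one drug.

        Diseases are ordered by predicted score descending, ties broken by
        disease index; the ``known`` column flags training associations.
        """
        try:
            i = self.model.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None
        scores = self.F[i]
        order = np.lexsort((np.arange(scores.size), -scores))
        return pd.DataFrame(
            {
                "disease_id": [self.model.disease_ids[j] for j in order],
                "score": scores[order],
                "known": self.model.assoc.Y[i, order].astype(bool),
            }
        )

    def kkt_residuals(self) -> dict[str, float]:
        """Complementarity residuals at the current factors (see module docs)."""
        m = self.model
        return kkt_residuals(
            self.F,
            self.H,
            self.W,
            [fm.values for fm in m.views],
            m.assoc.Y,
            m.assoc.M,
            m.drug_graphs,
            m.disease_graph,
            m.hp,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        m, t = self.model, self.trace
        terms = t.term_values_per_iter[-1] if t.term_values_per_iter else {}
        lines = [
            "Multi-view NMF drug-disease association model",
            "=" * 52,
            f"drugs: {m.n_drugs}   diseases: {m.n_diseases}   views: 4",
            f"known associations: {int(m.assoc.Y.sum())}"
            f" (density {m.assoc.Y.mean():.4f})",
            f"alphas: {m.hp.alphas}   k_neighbors: {m.hp.k_neighbors}",
            f"iterations: {t.iterations_run}   converged: {t.converged}",
            f"objective: {self.objective:.6g}",
            "-" * 52,
        ]
        for name in TERM_NAMES:
            if name in terms:
                lines.append(f"  {name:<15s} {terms[name]: .6g}")
        res = self.kkt_residuals()
        lines.append("-" * 52)
        lines.append(
            "KKT residuals (max |grad o factor|): "
            + "  ".join(f"{k}={v:.3g}" for k, v in res.items())
        )
        return "\n".join(lines)
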