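"""Per-drug ranking metrics and the five-fold cross-validation protocol.

Known associations are split into folds; in each fold the test pairs are
removed from the association matrix, from its observation mask and from the
fourth feature view (whose drug-drug similarity is recomputed from the
masked associations), the model is refit on the training data, and each
drug's test positives are ranked against its unmarked diseases.  The
headline numbers are per-drug AUC/AUPR pooled across folds and averaged,
plus recall within the top-k candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import AssociationData, FeatureMatrix, Hyperparameters, SimilarityMatrix

__all__ = [
    "CVFolds",
    "RankingMetrics",
    "auc_roc",
    "aupr",
    "recall_at_k",
    "make_cv_folds",
    "run_cv",
]


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    return s, y.astype(int)


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve of a scored binary ranking.

    Equivalent to the Mann-Whitney U statistic: the probability that a
    random positive outscores a random negative, with half credit for
    ties (the trapezoidal tie convention).
    """
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise summation.

    The curve is swept over descending unique score thresholds (tied
    scores enter together); the area uses step interpolation,
    sum_t (recall_t - recall_{t-1}) * precision_t, which avoids the
    optimistic bias of linear interpolation.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # threshold boundaries: last occurrence of each distinct score
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def recall_at_k(scores, labels, k: int) -> float:
    """Fraction of all positives found among the top-k scored items.

    Ties in score are broken by lower item index.
    """
    s, y = _as_arrays(scores, labels)
    n = s.size
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("recall@k needs at least one positive")
    order = np.lexsort((np.arange(n), -s))
    return float(y[order[:k]].sum() / n_pos)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVFolds:
    """Random partition of the known positive pairs into folds.

    ``fold_assignment`` maps each (drug index, disease index) pair to a
    fold index in 0..n_folds-1; fold sizes differ by at most one.
    """

    fold_assignment: dict[tuple[int, int], int]
    n_folds: int
    seed: int

    def test_pairs(self, fold: int) -> list[tuple[int, int]]:
        return sorted(p for p, f in self.fold_assignment.items() if f == fold)


def make_cv_folds(assoc: AssociationData, n_folds: int = 5, seed: int = 0) -> CVFolds:
    """Randomly divide the known associations into equal-size folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    pairs = [tuple(p) for p in assoc.positive_pairs]
    if len(pairs) < n_folds:
        raise ValueError(f"need at least {n_folds} positives, have {len(pairs)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    assignment = {pairs[p]: int(i % n_folds) for i, p in enumerate(perm)}
    return CVFolds(fold_assignment=assignment, n_folds=n_folds, seed=seed)


@dataclass
class RankingMetrics:
    """Per-drug ranking metrics pooled across cross-validation folds."""

    per_drug: pd.DataFrame
    mean_auc: float
    mean_aupr: float
    recall_at_k: dict[int, float] = field(default_factory=dict)
    leak_violations: int = 0

    @property
    def per_drug_auc(self) -> dict[str, float]:
        return self.per_drug.groupby("drug_id")["auc"].mean().to_dict()

    @property
    def per_drug_aupr(self) -> dict[str, float]:
        return self.per_drug.groupby("drug_id")["aupr"].mean().to_dict()

    def summary_frame(self) -> pd.DataFrame:
        rows = [("mean_auc", self.mean_auc), ("mean_aupr", self.mean_aupr)]
        rows += [(f"recall_at_{k}", v) for k, v in sorted(self.recall_at_k.items())]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _default_scorer(views, assoc_train, D, hp, seed):
    from .model import MultiViewNMF

    model = MultiViewNMF(views, assoc_train, D, hp)
    return model.fit(seed=seed).F


def run_cv(
    views: Sequence[FeatureMatrix],
    assoc: AssociationData,
    D: SimilarityMatrix,
    hp: Hyperparameters,
    folds: CVFolds,
    score_fn: Callable | None = None,
    ks: Sequence[int] | None = None,
) -> RankingMetrics:
    """Run the per-drug cross-validation protocol.

    For each fold, the test positives are zeroed out of Y, M and the
    fourth feature view before training (verified by an explicit leakage
    audit), the model is refit, and each drug holding at least one test
    positive is scored on its candidate diseases: all diseases that are
    not among its training positives.  The test positives are that drug's
    positive labels; every other candidate counts as negative.

    ``score_fn(views, assoc_train, D, hp, seed)`` may replace the model
    with any scorer returning a (drugs x diseases) score matrix; by
    default the multi-view NMF model is fit with ``hp``'s settings and a
    per-fold seed derived from ``hp.seed`` and the fold index.

    ``ks`` is the top-k grid for recall@k; values exceeding a drug's
    candidate count are skipped for that drug.
    """
    if score_fn is None:
        score_fn = _default_scorer
    if ks is None:
        ks = tuple(range(30, 241, 30))
    n_dis = assoc.n_diseases
    records = []
    recall_acc: dict[int, list[float]] = {k: [] for k in ks}
    leak_violations = 0

    for fold in range(folds.n_folds):
        test_pairs = folds.test_pairs(fold)
        Y_train = assoc.Y.copy()
        for i, j in test_pairs:
            Y_train[i, j] = 0.0
        assoc_train = AssociationData(
            Y=Y_train, drug_ids=assoc.drug_ids, disease_ids=assoc.disease_ids
        )
        X4_train = assoc_train.as_feature_view()
        # leakage audit: every test positive must be absent from the
        # training associations, the mask, and the fourth feature view
        for i, j in test_pairs:
            if (
                assoc_train.Y[i, j] != 0
                or assoc_train.M[i, j] != 0
                or X4_train.values[j, i] != 0
            ):
                leak_violations += 1

        seed = (hp.seed * folds.n_folds + fold) % (2**31)
        F = score_fn(views, assoc_train, D, hp, seed)

        by_drug: dict[int, list[int]] = {}
        for i, j in test_pairs:
            by_drug.setdefault(i, []).append(j)
        for i, test_dis in sorted(by_drug.items()):
            train_pos = np.flatnonzero(assoc_train.Y[i] > 0)
            candidates = np.setdiff1d(np.arange(n_dis), train_pos)
            labels = np.isin(candidates, test_dis).astype(int)
            if labels.sum() == 0 or labels.sum() == candidates.size:
                warnings.warn(
                    f"drug {assoc.drug_ids[i]} has no usable candidates in fold {fold}"
                )
                continue
            scores = F[i, candidates]
            rec = {
                "fold": fold,
                "drug_id": assoc.drug_ids[i],
                "n_test_pos": int(labels.sum()),
                "n_candidates": int(candidates.size),
                "auc": auc_roc(scores, labels),
                "aupr": aupr(scores, labels),
            }
            records.append(rec)
            for k in ks:
                if k <= candidates.size:
                    recall_acc[k].append(recall_at_k(scores, labels, k))

    per_drug = pd.DataFrame(
        records, columns=["fold", "drug_id", "n_test_pos", "n_candidates", "auc", "aupr"]
    )
    mean_auc = float(per_drug["auc"].mean()) if len(per_drug) else float("nan")
    mean_aupr = float(per_drug["aupr"].mean()) if len(per_drug) else float("nan")
    rak = {k: float(np.mean(v)) for k, v in recall_acc.items() if v}
    return RankingMetrics(
        per_drug=per_drug,
        mean_auc=mean_auc,
        mean_aupr=mean_aupr,
        recall_at_k=rak,
        leak_violations=leak_violations,
    )
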