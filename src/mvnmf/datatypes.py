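"""Typed containers for the matrices the model consumes.

All containers validate their declared invariants on construction so that
downstream code can rely on a single canonical orientation:

* drug feature views are (features x drugs),
* the association matrix is (drugs x diseases),
* similarity matrices are square, symmetric and valued in [0, 1].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "FeatureMatrix",
    "AssociationData",
    "SimilarityMatrix",
    "Hyperparameters",
]

#: tolerance used when checking symmetry of similarity matrices
_SYM_ATOL = 1e-10


class ValidationError(ValueError):
    """A matrix or parameter set violates a declared type invariant."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class FeatureMatrix:
    """One drug feature view.

    Views 1-3 hold binary descriptor-by-drug matrices (chemical
    substructures, target protein domains, target GO annotations).  View 4
    is the binary disease-by-drug association profile used as a fourth
    feature view; its ``feature_ids`` are disease identifiers.
    """

    values: np.ndarray
    view_id: int
    feature_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-dimensional")
        if self.view_id not in (1, 2, 3, 4):
            raise ValidationError(f"view_id must be in 1..4, got {self.view_id}")
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.drug_ids = _check_ids(self.drug_ids, "drug")
        d, n = self.values.shape
        if d != len(self.feature_ids) or n != len(self.drug_ids):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} feature ids / {len(self.drug_ids)} drug ids"
            )
        if np.any(self.values < 0):
            raise ValidationError("feature matrix has negative entries")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError(f"view {self.view_id} must be binary {{0,1}}")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationData:
    """Known drug-disease associations Y with observation mask M.

    The mask marks the observed set of pairs; for a fully observed binary
    association table the mask coincides with Y itself, which is the
    convention here (``M = Y``).
    """

    Y: np.ndarray
    drug_ids: list[str]
    disease_ids: list[str]
    M: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.M is None:
            self.M = self.Y.copy()
        self.M = np.asarray(self.M, dtype=float)
        self.drug_ids = _check_ids(self.drug_ids, "drug")
        self.disease_ids = _check_ids(self.disease_ids, "disease")
        if self.Y.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValidationError(
                f"association shape {self.Y.shape} inconsistent with ids"
            )
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValidationError("association matrix must be binary {0,1}")
        if self.M.shape != self.Y.shape or not np.array_equal(self.M, self.Y):
            raise ValidationError("mask must equal the association matrix (M = Y)")

    @property
    def n_drugs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.Y.shape[1]

    @property
    def positive_pairs(self) -> np.ndarray:
        """(n_pos, 2) array of (drug index, disease index) for each known pair."""
        return np.argwhere(self.Y > 0)

    def as_feature_view(self) -> FeatureMatrix:
        """The transposed (disease x drug) association table as view 4."""
        return FeatureMatrix(
            values=self.Y.T.copy(),
            view_id=4,
            feature_ids=list(self.disease_ids),
            drug_ids=list(self.drug_ids),
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] over drugs or diseases."""

    values: np.ndarray
    entity_ids: list[str]
    kind: str = "drug"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.entity_ids = _check_ids(self.entity_ids, "entity")
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity shape {self.values.shape} is not ({n}, {n})"
            )
        if np.any(self.values < -_SYM_ATOL) or np.any(self.values > 1 + _SYM_ATOL):
            raise ValidationError("similarity entries must lie in [0, 1]")
        if not np.allclose(self.values, self.values.T, atol=_SYM_ATOL):
            raise ValidationError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Hyperparameters:
    """Model hyperparameters.

    The five regularization weights control, in order: the weight of the
    per-view feature reconstruction (``alpha1``), the diversity penalty that
    pushes different views' latent drug representations toward orthogonality
    (``alpha2``), the consistency of the score matrix with each view's
    projection (``alpha3``), the drug/disease neighborhood smoothing
    (``alpha4``) and the l1 sparsity of the scores (``alpha5``).  Defaults
    are the values found best by grid search over {1e-2, 1e-1, 1, 10, 100}.

    ``unscaled_f_shrinkage`` selects an alternative form of the score update
    in which the consistency shrinkage enters the denominator as ``8 F``
    rather than ``8 alpha3 F``; the scaled default is the form consistent
    with the KKT stationarity conditions.
    """

    alpha1: float = 1.0
    alpha2: float = 10.0
    alpha3: float = 0.1
    alpha4: float = 0.1
    alpha5: float = 0.1
    k_neighbors: int = 5
    max_iter: int = 500
    tol: float = 1e-6
    epsilon: float = 1e-12
    seed: int = 0
    unscaled_f_shrinkage: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "alpha4", "alpha5"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be a positive integer")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be a positive integer")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")

    @property
    def alphas(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3, self.alpha4, self.alpha5)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown hyperparameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Hyperparameters":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


# hyperparameter grid used for sweeps
ALPHA_GRID: tuple[float, ...] = (1e-2, 1e-1, 1.0, 10.0, 100.0)
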