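"""Optimization and protocol audits.

Self-contained routines that verify, by direct computation, the properties
the multiplicative-update optimizer is supposed to have (objective descent,
non-negativity, zero locking, KKT stationarity at its fixed points) and
that the planted structure of the synthetic generator is recoverable by the
full pipeline.  They are used by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datatypes import Hyperparameters
from .evaluation import auc_roc
from .model import (
    MultiViewNMF,
    kkt_residuals,
    objective_terms,
    update_f,
    update_h,
    update_w,
)
from .synthetic import SyntheticSpec, generate, hide_associations

__all__ = [
    "descent_audit",
    "zero_locking_audit",
    "stationarity_audit",
    "planted_recovery_audit",
]


def descent_audit(
    n_instances: int = 20,
    n_iter: int = 200,
    base_seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> dict:
    """Fit seeded synthetic instances and audit descent and non-negativity.

    Returns the worst relative per-iteration objective increase observed
    (<= 0 means strict descent everywhere), the number of iterations whose
    relative increase exceeded 1e-8, and the minimum factor entry seen in
    any final factorization.
    """
    worst_rel_increase = -np.inf
    violations = 0
    min_entry = np.inf
    for i in range(n_instances):
        seed = (base_seed + i) % 2**31
        ds = generate(
            replace(spec, seed=seed) if spec is not None else SyntheticSpec(seed=seed)
        )
        hp = Hyperparameters(seed=seed, max_iter=n_iter, tol=1e-300)
        res = MultiViewNMF(ds.views[:3], ds.assoc, ds.D, hp).fit()
        obj = np.asarray(res.trace.objective_per_iter)
        rel = np.diff(obj) / np.maximum(np.abs(obj[:-1]), np.finfo(float).tiny)
        worst_rel_increase = max(worst_rel_increase, float(rel.max()))
        violations += int(np.sum(rel > 1e-8))
        min_entry = min(
            min_entry,
            float(res.F.min()),
            float(min(h.min() for h in res.H)),
            float(min(w.min() for w in res.W)),
        )
    return {
        "n_instances": n_instances,
        "n_iter": n_iter,
        "worst_relative_increase": worst_rel_increase,
        "violations": violations,
        "min_factor_entry": min_entry,
    }


def zero_locking_audit(seed: int = 0, n_rounds: int = 25) -> dict:
    """Zero entries must remain zero under all three multiplicative rules."""
    rng = np.random.default_rng(seed)
    ds = generate(
        SyntheticSpec(
            n_drugs=12,
            n_diseases=8,
            feature_dims=(10, 12, 14),
            latent_rank=3,
            association_density=0.15,
            seed=seed,
        )
    )
    hp = Hyperparameters(seed=seed, k_neighbors=3)
    m = MultiViewNMF(ds.views[:3], ds.assoc, ds.D, hp)
    F, H, W = m.initialize()
    X = [fm.values for fm in m.views]
    zero_mask_F = rng.random(F.shape) < 0.2
    F[zero_mask_F] = 0.0
    masks_H, masks_W = [], []
    for v in range(4):
        mh = rng.random(H[v].shape) < 0.2
        mw = rng.random(W[v].shape) < 0.2
        H[v][mh] = 0.0
        W[v][mw] = 0.0
        masks_H.append(mh)
        masks_W.append(mw)
    violations = 0
    min_entry = np.inf
    for _ in range(n_rounds):
        F = update_f(F, H, ds.assoc.Y, ds.assoc.M, m.drug_graphs, m.disease_graph, hp)
        for v in range(4):
            H[v] = update_h(H, v, F, W[v], X[v], hp)
        for v in range(4):
            W[v] = update_w(W[v], X[v], H[v], hp)
        violations += int(np.count_nonzero(F[zero_mask_F]))
        for v in range(4):
            violations += int(np.count_nonzero(H[v][masks_H[v]]))
            violations += int(np.count_nonzero(W[v][masks_W[v]]))
        min_entry = min(
            min_entry,
            float(F.min()),
            float(min(h.min() for h in H)),
            float(min(w.min() for w in W)),
        )
    return {"violations": violations, "min_factor_entry": min_entry}


def stationarity_audit(
    seed: int = 3,
    target: float = 1e-5,
    max_iter: int = 1_200_000,
    check_every: int = 50_000,
) -> dict:
    """Iterate a small instance to its fixed point and measure KKT residuals.

    The alternating updates are run well past the objective-convergence
    tolerance (their residuals decay roughly like 1/t near the
    non-negativity boundary) until the largest elementwise complementarity
    residual over the F/H/W blocks drops below ``target`` or the iteration
    cap is reached.
    """
    ds = generate(
        SyntheticSpec(
            n_drugs=10,
            n_diseases=8,
            feature_dims=(15, 20, 25),
            latent_rank=3,
            association_density=0.1,
            seed=seed,
        )
    )
    hp = Hyperparameters(seed=seed, k_neighbors=3)
    m = MultiViewNMF(ds.views[:3], ds.assoc, ds.D, hp)
    F, H, W = m.initialize()
    X = [fm.values for fm in m.views]
    Y, M = ds.assoc.Y, ds.assoc.M
    it = 0
    max_res = np.inf
    res = {}
    while it < max_iter:
        for _ in range(check_every):
            F = update_f(F, H, Y, M, m.drug_graphs, m.disease_graph, hp)
            for v in range(4):
                H[v] = update_h(H, v, F, W[v], X[v], hp)
            for v in range(4):
                W[v] = update_w(W[v], X[v], H[v], hp)
        it += check_every
        res = kkt_residuals(F, H, W, X, Y, M, m.drug_graphs, m.disease_graph, hp)
        max_res = max(res.values())
        if max_res < target:
            break
    obj = objective_terms(F, H, W, X, Y, M, m.drug_graphs, m.disease_graph, hp)
    return {
        "iterations": it,
        "max_kkt_residual": float(max_res),
        "residuals": {k: float(v) for k, v in res.items()},
        "objective": obj["objective"],
    }


def planted_recovery_audit(
    n_seeds: int = 10,
    hide_fraction: float = 0.2,
    base_seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> dict:
    """Hide a fraction of planted associations, refit, and rank them.

    For every drug with at least one hidden association, its hidden
    positives are ranked against all diseases that are not among its
    training positives; the per-drug AUCs are pooled over ``n_seeds``
    independent datasets.  A label-shuffled null re-scores the same
    rankings with permuted labels and should stay near chance (0.5).
    """
    aucs: list[float] = []
    null_aucs: list[float] = []
    for s in range(n_seeds):
        seed = (base_seed + s) % 2**31
        ds = generate(
            replace(spec, seed=seed) if spec is not None else SyntheticSpec(seed=seed)
        )
        masked, held = hide_associations(ds.assoc, hide_fraction, seed=seed + 1)
        hp = Hyperparameters(seed=seed)
        res = MultiViewNMF(ds.views[:3], masked, ds.D, hp).fit()
        rng = np.random.default_rng(seed + 2)
        by_drug: dict[int, list[int]] = {}
        for i, j in held:
            by_drug.setdefault(int(i), []).append(int(j))
        for i, test_dis in sorted(by_drug.items()):
            train_pos = np.flatnonzero(masked.Y[i] > 0)
            cand = np.setdiff1d(np.arange(ds.assoc.n_diseases), train_pos)
            labels = np.isin(cand, test_dis).astype(int)
            if labels.sum() == 0 or labels.sum() == cand.size:
                continue
            scores = res.F[i, cand]
            aucs.append(auc_roc(scores, labels))
            null_aucs.append(auc_roc(scores, rng.permutation(labels)))
    return {
        "n_seeds": n_seeds,
        "n_drug_evaluations": len(aucs),
        "mean_auc": float(np.mean(aucs)),
        "null_mean_auc": float(np.mean(null_aucs)),
        "margin": float(np.mean(aucs) - np.mean(null_aucs)),
    }
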