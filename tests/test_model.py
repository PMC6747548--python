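import numpy as np
import pytest

from mvnmf import (
    FeatureMatrix,
    Hyperparameters,
    MultiViewNMF,
    knn_graph,
    objective_terms,
    update_f,
    update_h,
    update_w,
)


def naive_objective(F, H, W, X, Y, M, drug_graphs, disease_graph, hp):
    """Element-by-element loop evaluation of every objective term."""
    a1, a2, a3, a4, a5 = hp.alphas
    total = 0.0
    for i in range(F.shape[0]):
        for j in range(F.shape[1]):
            total += (M[i, j] * (F[i, j] - Y[i, j])) ** 2
    for v in range(len(X)):
        R = X[v] - W[v] @ H[v]
        for i in range(R.shape[0]):
            for j in range(R.shape[1]):
                total += a1 * R[i, j] ** 2
    for v in range(len(H)):
        for w in range(len(H)):
            if v == w:
                continue
            for i in range(H[v].shape[0]):
                for j in range(H[v].shape[1]):
                    total += a2 * H[v][i, j] * H[w][i, j]
    for v in range(len(H)):
        for i in range(F.shape[0]):
            for j in range(F.shape[1]):
                total += a3 * (F[i, j] - H[v].T[i, j]) ** 2
    if drug_graphs:
        for g in drug_graphs:
            total += a4 * np.trace(F.T @ g.L @ F)
    if disease_graph is not None:
        total += a4 * np.trace(F @ disease_graph.L @ F.T)
    for i in range(F.shape[0]):
        for j in range(F.shape[1]):
            total += a5 * abs(F[i, j])
    return total


def random_problem(rng, nr=6, nd=4, dims=(5, 7, 9, 4), n_views=4, k=2):
    X = []
    for v in range(n_views):
        d = dims[v] if v < 3 else nd
        X.append((rng.random((d, nr)) < 0.4).astype(float))
    Y = (rng.random((nr, nd)) < 0.3).astype(float)
    M = Y.copy()
    F = rng.random((nr, nd))
    H = [rng.random((nd, nr)) for _ in range(n_views)]
    W = [rng.random((X[v].shape[0], nd)) for v in range(n_views)]
    Sd = rng.random((nr, nr))
    Sd = np.clip((Sd + Sd.T) / 2, 0, 1)
    np.fill_diagonal(Sd, 1)
    Sdis = rng.random((nd, nd))
    Sdis = np.clip((Sdis + Sdis.T) / 2, 0, 1)
    np.fill_diagonal(Sdis, 1)
    graphs = [knn_graph(Sd, k) for _ in range(n_views)]
    dgraph = knn_graph(Sdis, k)
    return F, H, W, X, Y, M, graphs, dgraph


class TestObjective:
    def test_all_zero_factors_leave_only_the_masked_loss(self):
        Y = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        F = np.zeros_like(Y)
        H = [np.zeros((3, 2)) for _ in range(4)]
        X = [np.zeros((5, 2)) for _ in range(4)]
        W = [np.zeros((5, 3)) for _ in range(4)]
        hp = Hyperparameters()
        terms = objective_terms(F, H, W, X, Y, Y, None, None, hp)
        assert terms["objective"] == pytest.approx(Y.sum())  # p ones

    def test_perfect_fit_with_zero_alphas_scores_zero(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        hp = Hyperparameters(alpha1=0, alpha2=0, alpha3=0, alpha4=0, alpha5=0)
        H = [np.zeros((2, 2)) for _ in range(4)]
        terms = objective_terms(Y.copy(), H, H, H, Y, Y, None, None, hp)
        assert terms["objective"] == 0.0

    def test_matches_naive_loop_oracle(self, rng):
        F, H, W, X, Y, M, graphs, dgraph = random_problem(rng)
        hp = Hyperparameters(seed=0)
        got = objective_terms(F, H, W, X, Y, M, graphs, dgraph, hp)["objective"]
        want = naive_objective(F, H, W, X, Y, M, graphs, dgraph, hp)
        assert got == pytest.approx(want, rel=1e-10)


class TestScoreUpdate:
    def test_zero_entries_stay_zero(self, rng):
        F, H, W, X, Y, M, graphs, dgraph = random_problem(rng)
        F[0, 1] = F[2, 3] = 0.0
        hp = Hyperparameters(seed=0)
        F2 = update_f(F, H, Y, M, graphs, dgraph, hp)
        assert F2[0, 1] == 0.0 and F2[2, 3] == 0.0
        assert np.all(F2 >= 0)

    def test_scalar_system_matches_direct_formula(self):
        # 1 drug x 1 disease, no graphs: the update is a hand-evaluable ratio
        hp = Hyperparameters(seed=0)
        f, y = 0.7, 1.0
        H = [np.array([[h]]) for h in (0.2, 0.4, 0.6, 0.8)]
        F = np.array([[f]])
        Y = M = np.array([[y]])
        a3, a5 = hp.alpha3, hp.alpha5
        num = 2 * y * y + 2 * a3 * (0.2 + 0.4 + 0.6 + 0.8)
        den = 2 * y * f + 8 * a3 * f + a5 + hp.epsilon
        got = update_f(F, H, Y, M, None, None, hp)[0, 0]
        assert got == pytest.approx(f * num / den, rel=1e-12)

    def test_update_is_stationary_at_subproblem_fixed_point(self, rng):
        F, H, W, X, Y, M, graphs, dgraph = random_problem(rng, nr=4, nd=3, k=1)
        hp = Hyperparameters(seed=0)
        for _ in range(30000):
            F = update_f(F, H, Y, M, graphs, dgraph, hp)
        F2 = update_f(F, H, Y, M, graphs, dgraph, hp)
        assert np.max(np.abs(F2 - F)) < 1e-6


class TestLatentUpdate:
    def test_zero_entries_stay_zero(self, rng):
        F, H, W, X, Y, M, *_ = random_problem(rng)
        H[1][0, 0] = 0.0
        hp = Hyperparameters(seed=0)
        H2 = update_h(H, 1, F, W[1], X[1], hp)
        assert H2[0, 0] == 0.0
        assert np.all(H2 >= 0)

    def test_reduces_to_classical_nmf_coefficient_update(self, rng):
        # with no diversity or consistency coupling and a single view the
        # rule must coincide with H <- H * (W^T X) / (W^T W H)
        hp = Hyperparameters(alpha1=1.0, alpha2=0, alpha3=0, alpha4=0, alpha5=0)
        X = rng.random((8, 6))
        W = rng.random((8, 4))
        H = rng.random((4, 6))
        F = rng.random((6, 4))
        got = update_h([H], 0, F, W, X, hp)
        want = H * (W.T @ X) / (W.T @ W @ H + hp.epsilon)
        assert np.allclose(got, want, atol=1e-10)

    def test_subproblem_complementarity_residual_vanishes(self, rng):
        # iterate the H block alone (F, W fixed) and check grad o H -> 0
        F, H, W, X, Y, M, *_ = random_problem(rng, nr=5, nd=4)
        hp = Hyperparameters(seed=0)
        for _ in range(60000):
            for v in range(4):
                H[v] = update_h(H, v, F, W[v], X[v], hp)
        a1, a2, a3 = hp.alpha1, hp.alpha2, hp.alpha3
        worst = 0.0
        for v in range(4):
            others = sum(H[w] for w in range(4) if w != v)
            grad = (
                2 * a1 * (W[v].T @ (W[v] @ H[v] - X[v]))
                + a2 * others
                + 2 * a3 * (H[v] - F.T)
            )
            worst = max(worst, np.max(np.abs(grad * H[v])))
        assert worst < 1e-6


class TestBasisUpdate:
    def test_zero_entries_stay_zero_and_nonnegative(self, rng):
        X = rng.random((6, 5))
        H = rng.random((3, 5))
        W = rng.random((6, 3))
        W[2, 1] = 0.0
        hp = Hyperparameters()
        W2 = update_w(W, X, H, hp)
        assert W2[2, 1] == 0.0 and np.all(W2 >= 0)

    def test_exact_factorization_is_a_fixed_point(self, rng):
        W = rng.random((6, 3)) + 0.1
        H = rng.random((3, 5)) + 0.1
        X = W @ H
        hp = Hyperparameters()
        W2 = update_w(W, X, H, hp)
        assert np.allclose(W2, W, atol=1e-10)

    def test_monotone_decrease_of_reconstruction_error(self, rng):
        X = rng.random((10, 8))
        W = rng.random((10, 4))
        H = rng.random((4, 8))
        hp = Hyperparameters()
        errs = []
        for _ in range(50):
            W = update_w(W, X, H, hp)
            errs.append(np.sum((X - W @ H) ** 2))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))


class TestFit:
    def test_loss_only_limit_reproduces_observed_associations(self, small_dataset):
        ds = small_dataset
        hp = Hyperparameters(
            alpha1=0, alpha2=0, alpha3=0, alpha4=0, alpha5=0, seed=1, max_iter=50,
            k_neighbors=3,
        )
        res = MultiViewNMF(ds.views[:3], ds.assoc, ds.D, hp).fit()
        obs = ds.assoc.Y > 0
        assert np.max(np.abs(res.F[obs] - ds.assoc.Y[obs])) < 1e-3

    def test_fixed_seed_gives_bit_identical_traces(self, small_dataset):
        ds = small_dataset
        hp = Hyperparameters(seed=5, max_iter=40, k_neighbors=3)
        m = MultiViewNMF(ds.views[:3], ds.assoc, ds.D, hp)
        r1, r2 = m.fit(), m.fit()
        assert r1.trace.objective_per_iter == r2.trace.objective_per_iter
        assert np.array_equal(r1.F, r2.F)

    def test_objective_non_increasing_and_factors_nonnegative(self, small_fit):
        _, res = small_fit
        obj = np.array(res.trace.objective_per_iter)
        rel = np.diff(obj) / np.maximum(np.abs(obj[:-1]), 1e-300)
        assert rel.max() <= 1e-8
        assert res.F.min() >= 0
        assert min(h.min() for h in res.H) >= 0
        assert min(w.min() for w in res.W) >= 0

    def test_trace_lengths_match_iterations(self, small_fit):
        _, res = small_fit
        t = res.trace
        assert len(t.objective_per_iter) == t.iterations_run
        assert len(t.term_values_per_iter) == t.iterations_run

    def test_kkt_residuals_shrink_with_more_iterations(self, small_dataset):
        ds = small_dataset
        hp = Hyperparameters(seed=2, k_neighbors=3, tol=1e-15)
        m = MultiViewNMF(ds.views[:3], ds.assoc, ds.D, hp)
        early = m.fit(max_iter=20).kkt_residuals()
        late = m.fit(max_iter=2000).kkt_residuals()
        assert max(late.values()) < max(early.values())

    def test_mismatched_ids_rejected(self, small_dataset):
        ds = small_dataset
        bad = FeatureMatrix(
            values=ds.views[0].values,
            view_id=1,
            feature_ids=ds.views[0].feature_ids,
            drug_ids=[f"other_{i}" for i in range(ds.assoc.n_drugs)],
        )
        with pytest.raises(Exception, match="drug ids"):
            MultiViewNMF([bad] + ds.views[1:3], ds.assoc, ds.D)


class TestPredict:
    def test_ranking_and_tie_breaking(self, small_fit):
        model, res = small_fit
        res.F = res.F.copy()
        res.F[0, :] = 0.0
        res.F[0, [1, 2, 0]] = [0.9, 0.5, 0.1]
        ranked = res.predict(model.drug_ids[0])
        top = list(ranked["disease_id"].iloc[:3])
        assert top == [model.disease_ids[1], model.disease_ids[2], model.disease_ids[0]]
        # all-equal row falls back to disease index order
        res.F[0, :] = 0.5
        ranked = res.predict(model.drug_ids[0])
        assert list(ranked["disease_id"]) == model.disease_ids

    def test_matches_argsort_oracle(self, small_fit, rng):
        model, res = small_fit
        res.F = res.F.copy()
        res.F[3] = rng.random(model.n_diseases)
        ranked = res.predict(model.drug_ids[3])
        oracle = [model.disease_ids[j] for j in np.argsort(-res.F[3], kind="stable")]
        assert list(ranked["disease_id"]) == oracle

    def test_unknown_drug_rejected(self, small_fit):
        _, res = small_fit
        with pytest.raises(KeyError):
            res.predict("nonexistent")

    def test_known_training_associations_flagged(self, small_fit):
        model, res = small_fit
        i = int(np.argmax(model.assoc.Y.sum(axis=1)))
        ranked = res.predict(model.drug_ids[i])
        known_ids = {
            model.disease_ids[j] for j in np.flatnonzero(model.assoc.Y[i] > 0)
        }
        assert set(ranked.loc[ranked["known"], "disease_id"]) == known_ids

    def test_summary_mentions_convergence_and_terms(self, small_fit):
        _, res = small_fit
        text = res.summary()
        assert "iterations" in text and "diversity" in text and "KKT" in text
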