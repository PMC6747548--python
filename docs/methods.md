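# Methods

## Problem

Drug repositioning asks which already-approved drugs might treat which
diseases. Given a sparse binary table `Y ∈ {0,1}^{Nr×Nd}` of known
drug–disease associations, the goal is to score every unobserved pair so
that true-but-unrecorded indications rank highly in each drug's candidate
list. The model integrates four complementary descriptions ("views") of
each drug:

1. binary chemical-substructure fingerprints,
2. binary target protein-domain annotations,
3. binary target gene-ontology annotations,
4. the drug's associated-disease profile (the transposed association table),

together with a precomputed disease–disease semantic similarity matrix
`D ∈ [0,1]^{Nd×Nd}` that arrives as an input (its construction from a
disease ontology is out of scope).

## Model

Each view `X(v) ∈ R^{dv×Nr}` is factorized as `X(v) ≈ W(v) H(v)` with
`W(v) ∈ R^{dv×Nd}`, `H(v) ∈ R^{Nd×Nr}`, all non-negative, so every drug
acquires a low-dimensional representation `H(v)_{·i}` that lives in the
disease dimension. A score matrix `F ∈ R^{Nr×Nd}` ties the views together.
The joint objective is

    J = ‖M ⊙ (F − Y)‖²_F                      masked reconstruction
      + α1 Σ_v ‖X(v) − W(v)H(v)‖²_F           per-view factorization
      + α2 Σ_{w≠v} tr(H(v)ᵀH(w))              diversity (orthogonality)
      + α3 Σ_v ‖F − H(v)ᵀ‖²_F                 view–score consistency
      + α4 (Σ_v tr(FᵀL(v)F) + tr(F L_d Fᵀ))   graph smoothing
      + α5 ‖F‖₁                               sparsity

with `M` the observation mask. For a fully observed binary association
table the mask equals `Y` itself, which is the convention used throughout
(`M = Y`). The diversity term sums over **ordered** view pairs (12 terms);
it discourages redundant latent representations so that each view
contributes view-specific signal. `L(v) = U(v) − A(v)` are graph
Laplacians of k-nearest-neighbor graphs built from the four drug–drug
similarity views, and `L_d` is the analogous disease-graph Laplacian built
from `D`; the smoothing terms pull the score rows (columns) of neighboring
drugs (diseases) together.

Drug similarities: views 1–3 use cosine similarity between the drugs'
binary feature columns. View 4 compares associated-disease sets `Di, Dj`
by a best-match average over `D`:

    R4_ij = [ Σ_{a∈Di} max_{b∈Dj} D_ab + Σ_{b∈Dj} max_{a∈Di} D_ba ] / (|Di|+|Dj|).

## Optimization

`J` is non-convex jointly but each block subproblem is handled by a
multiplicative update derived from its KKT stationarity conditions
(numerator = negative gradient part, denominator = positive part):

    F ← F ⊙ (2M⊙Y + 2α3 Σ_v H(v)ᵀ + 2α4 Σ_v A(v)F + 2α4 F A_d)
          / (2M⊙F + 8α3 F + 2α4 Σ_v U(v)F + 2α4 F U_d + α5 B + ε)

    H(v) ← H(v) ⊙ (2α1 W(v)ᵀX(v) + 2α3 Fᵀ)
              / (2α1 W(v)ᵀW(v)H(v) + α2 Σ_{w≠v} H(w) + 2α3 H(v) + ε)

    W(v) ← W(v) ⊙ (X(v)H(v)ᵀ) / (W(v)H(v)H(v)ᵀ + ε)

with `B` the all-ones matrix. One iteration updates `F`, then `H(1..4)`
sequentially, then `W(1..4)`. Factors are initialized uniform(0,1) from a
seeded generator (draw order: F, H(1..4), W(1..4)), so no entry starts at
zero and runs are exactly reproducible. Convergence is declared when the
relative objective change drops below `tol`, else after `max_iter`
iterations.

These rules preserve non-negativity and lock zero entries at zero. The
test suite verifies empirically (20 seeded instances × 200 iterations)
that the objective never increases beyond a 1e-8 relative slack, and that
the elementwise complementarity residuals `|∇J ⊙ factor|` of all three
blocks vanish at the updates' fixed points.

### Numerical choices

- **`8α3F` in the score denominator.** Differentiating the consistency
  term `α3 Σ_{v=1..4} ‖F − H(v)ᵀ‖²` gives `2α3(4F − Σ_v H(v)ᵀ)`, so the
  denominator's shrinkage term is `8α3F`, consistent with the numerator's
  `2α3 Σ H(v)ᵀ` and with the KKT residuals the tests check. A variant in
  which this term enters unscaled as `8F` is available via
  `Hyperparameters(unscaled_f_shrinkage=True)` for comparison; it only
  rescales the effective step, not the non-negativity or locking
  properties, but it is not stationary for `J`.
- **Denominator stabilizer** `ε = 1e-12` guards every 0/0; entries whose
  numerator and current value are zero stay exactly zero.
- **k-NN graphs** are row-wise (each row has exactly `k` ones, self
  excluded) and therefore possibly asymmetric; the smoothing updates use
  `A(v)F` / `U(v)F` exactly as written above, which is well-defined for
  asymmetric adjacency. Similarity ties are broken toward the lower
  index, making graph construction deterministic.
- **Zero-feature drugs** get cosine similarity 0 to everything, including
  themselves; a drug with no associated diseases likewise scores 0 in the
  view-4 similarity (its diagonal included). Drugs with at least one
  association have view-4 self-similarity 1, matching the cosine views.
- **Diversity sum** is over ordered pairs, i.e. each unordered view pair
  is counted twice, and the printed H-update carries the matching
  `α2 Σ_{w≠v} H(w)` denominator term.
- **Convergence diagnostics.** Near the non-negativity boundary the
  multiplicative rules approach their fixed points sublinearly (the
  complementarity residual decays roughly like 1/t), so the stationarity
  audit in `mvnmf.diagnostics` iterates small instances (10 drugs × 8
  diseases) far past the objective tolerance — up to 1.2M iterations —
  to verify residuals below 1e-5.

## Hyperparameters

| name | default | meaning |
|------|---------|---------|
| `alpha1` | 1 | weight of the per-view factorization loss |
| `alpha2` | 10 | diversity (inter-view orthogonality) penalty |
| `alpha3` | 0.1 | view–score consistency |
| `alpha4` | 0.1 | drug/disease graph smoothing |
| `alpha5` | 0.1 | l1 sparsity of F |
| `k_neighbors` | 5 | neighbors per entity in all k-NN graphs |
| `max_iter` | 500 | iteration cap |
| `tol` | 1e-6 | relative objective-change stopping threshold |
| `epsilon` | 1e-12 | denominator stabilizer |
| `seed` | 0 | initialization seed |

The five weights' defaults are the best combination from a grid search
over {1e-2, 1e-1, 1, 10, 100} per weight (`mvnmf.datatypes.ALPHA_GRID`
ships the grid for sweeps). The sources leave `k_neighbors`, `max_iter`,
`tol` and `epsilon` open; the values above are this package's choices —
`k=5` is a conventional affinity-graph neighborhood at the data sizes
involved, and the stopping pair (1e-6, 500) reaches stable rankings on
the synthetic instances while staying interactive.

## Evaluation protocol

Five-fold cross-validation over the known associations: the positives are
randomly partitioned into five equal folds (sizes differ by at most one).
Per fold, the test positives are removed from `Y`, from the mask and from
the fourth feature view, whose drug–drug similarity `R4` is recomputed
from the masked associations; the model is refit on the remainder. For
each drug with at least one test positive, its test positives are ranked
against all of its *unmarked* diseases (training positives are excluded
from the candidate set), yielding a per-drug AUC and AUPR; the headline
numbers are means over drug evaluations pooled across folds (a drug
appearing in several folds contributes once per fold). Recall@k is the
fraction of a drug's test positives found in its top-k candidates,
averaged the same way; grid values exceeding a drug's candidate count are
skipped for that drug.

- AUC uses the Mann–Whitney form with half credit for ties; AUPR uses
  step interpolation over descending unique thresholds (no linear
  interpolation, avoiding optimistic bias). Both are verified against
  brute-force oracles and scikit-learn.
- An instrumented audit inside `run_cv` counts test positives visible in
  the training inputs; the count must be exactly zero.
- Aggregation granularity (pooled per-drug across folds rather than
  per-fold averaging) was an open protocol choice; pooled averaging is
  used and reported as such.
- Identifier sets of all input files must match exactly; mismatches are
  an error rather than silently intersected.

## Synthetic data

`mvnmf.synthetic.generate` plants a shared low-rank structure: drugs and
diseases belong to `latent_rank` blocks; non-negative factors `G, P` have
a strong within-block loading over a weak background; associations are
the top `round(density·Nr·Nd)` entries of `GᵀP`; the three feature views
are independent non-negative loadings of `G`, binarized per feature row
at the `(1 − feature_density)` quantile and flipped with probability
`noise_rate`; `D` is the cosine similarity of the disease factors. The
defaults (60 drugs × 40 diseases, density 0.006, feature dims
100/150/200, rank 4, feature density 0.1, noise 0.05) mirror the sparsity
of curated association tables (~0.6% density) at desk scale; the audit
and test problem sizes (10×8 up to 60×40, 5–20 seeds) are chosen so the
whole suite runs on a laptop.

What the generator does **not** emulate: the chemical semantics of real
fingerprints (correlated substructure bits), hub drugs/diseases with
heavy-tailed degree distributions, ontology-induced block structure in
`D`, and biased (non-uniform) missingness of the known-association table.
Passing recovery tests therefore demonstrate that the optimizer finds
planted multi-view low-rank structure — not that the model attains any
particular accuracy on real pharmacological data.

## Limitations

- The objective is non-convex; multiplicative updates reach a local
  minimum that depends on the seed. Empirical descent is verified, but no
  global-optimality claim is made.
- Convergence to the non-negativity boundary is sublinear, so very tight
  stationarity targets require many iterations (see above).
- Dense similarity matrices and graphs give O(Nr² + Nd²) memory; the
  implementation targets the hundreds-of-drugs scale, not ultra-large
  pharmacopoeias.
- `D` is trusted as given; no attempt is made to validate or recompute
  disease semantic similarity.
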