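# Methods

## The model

Given two column-standardized data views on the same n subjects — genomic
features X ∈ ℝⁿˣᵖ and imaging features Y ∈ ℝⁿˣ𐞥 — sparse canonical
correlation analysis seeks loading vectors u ∈ ℝᵖ, v ∈ ℝ𐞥 whose projections
Xu and Yv are maximally correlated while most loadings are exactly or
effectively zero. This package implements the FGLGNSCCA objective

```
min_{u,v}  −uᵀXᵀYv + Ω_FGL(u) + Ω_GGL(v)
           + (γ₁/2)(‖Xu‖² − 1) + (γ₂/2)(‖Yv‖² − 1)
           + (λ₁ᵍⁿ/2) uᵀL_u u + (λ₂ᵍⁿ/2) vᵀL_v v
s.t.  uᵀXᵀXu = 1,  vᵀYᵀYv = 1
```

with three structural penalties:

* **FGL (fused paired group lasso)** over the feature chain:
  `Ω_FGL(u) = λ₁ Σᵢ ωᵢ,ᵢ₊₁ √(uᵢ² + uᵢ₊₁²)`. Adjacent features are selected
  or zeroed together, giving piecewise-contiguous supports.
* **GGL (graph-guided paired group lasso)** over a feature graph E:
  `Ω_GGL(v) = λ₂ Σ₍ⱼ,ₖ₎∈E ωⱼₖ √(vⱼ² + vₖ²)` — the same pairwise penalty on
  arbitrary edges.
* **GraphNet**: the Laplacian quadratic form `uᵀL u = Σᵢ<ⱼ Cᵢⱼ(uᵢ − uⱼ)²`,
  encouraging smooth loadings over a connectivity matrix C. C is built
  sign-insensitively (|r| or r² of the column correlations), so anticorrelated
  but connected features are still smoothed together.

By default the GraphNet coefficients are tied to the sparsity coefficients
(λ₁ᵍⁿ = λ₁, λ₂ᵍⁿ = λ₂), which is the model's literal form; they can be untied
for exploration.

## The solver

The pairwise group penalties are non-smooth; the solver handles them by
iterative reweighting. At the current u, the FGL penalty has (smoothed)
gradient λ₁ D_X u with the diagonal

```
d_X,i = ω_{i−1,i}/max(√(u_{i−1}²+u_i²), ε) + ω_{i,i+1}/max(√(u_i²+u_{i+1}²), ε)
```

(boundary weights zero; the GGL analogue sums over graph neighbours). Each
sweep then alternates two symmetric positive-definite linear solves,

```
(λ₁ D_X + γ₁ XᵀX + λ₁ᵍⁿ L_u) u = XᵀY v      then scale so uᵀXᵀXu = 1
(λ₂ D_Y + γ₂ YᵀY + λ₂ᵍⁿ L_v) v = YᵀX u      then scale so vᵀYᵀYv = 1
```

until the max absolute change in (u, v) falls below `tol`. Solves use a
Cholesky factorization with one iterative-refinement step (relative residual
≲ 1e−12); on factorization failure an escalating diagonal jitter (1e−8 then
1e−4 of the mean diagonal) is added and logged.

Numerical choices:

* **ε-guard** (default 1e−6): floors the reweighting denominators. This
  implicitly replaces each pairwise term √s by its Huber smoothing
  (s²/2ε below ε), which is exactly the function the reweighted updates
  majorize-and-descend on. `objective()` therefore records the smoothed
  form (equal to the exact penalty up to ε/2 per edge); `penalty_values()`
  reports the exact √ sums.
* **Initialization**: all-ones vectors scaled onto the constraints, with one
  seeded-random restart if the data make that degenerate (e.g. all-zero
  columns).
* **Convergence**: `tol = 1e−5` on the max loading change, `max_iter = 100`.
  The objective trace is recorded after every full sweep.
* **Monotonicity**: the reweighted solves descend on the smoothed objective,
  but the subsequent rescaling onto the quadratic constraints is not a
  descent step. In practice the trace is non-increasing to ~1e−6 per sweep;
  on weakly identified instances it can creep upward by O(1e−5) per sweep
  while the iterates still converge. Violations are logged, never hidden.
* **Fixed-point accuracy**: because D_X entries are reciprocals of
  near-zero pair norms, the self-consistency residual of the update systems
  at the `tol = 1e−5` iterate is only ~1e−2; continuing the same instance to
  `tol = 1e−12` drives it below 1e−10. The verification suite checks both
  regimes.
* **Sign**: (u, v) and (−u, −v) are equivalent; solutions are canonicalized
  so the largest-|u| entry is positive, making runs bit-reproducible.

**Baselines.** `fit_fglscca` is the identical algorithm with GraphNet terms
zero. `fit_l1scca` is the classic penalized-matrix-decomposition scheme for
plain ℓ1 penalties: alternate soft-threshold-and-ℓ2-normalize on XᵀYv / YᵀXu,
with the threshold found by bisection so that ‖u‖₁ ≤ c₁ (budgets must be ≥ 1;
defaults √p/2, √q/2).

## Structural priors from data

The model needs a chain weighting, a feature graph and connectivity matrices.
When the user supplies none, they are built from the data:

* chain weights: unit (default) or |Pearson r| of adjacent columns;
* feature graph (default `chain_plus_corr`): all chain edges (j, j+1) at unit
  weight, plus any pair with |r| above `graph_threshold` (default 0.5) at
  weight |r|. The chain fallback matters: on noisy data no pair may clear the
  threshold, and a pure correlation graph would then leave the v side with no
  sparsity penalty at all — a degenerate model that overfits freely. A pure
  `threshold_abs_corr` scheme and file-based graphs are also available.
* connectivity: C = |r| (default) or r², optionally sparsified, diagonal
  zeroed; L = diag(C·1) − C.

## Synthetic data

The generator draws a shared latent z ~ N(0,1) per subject and sets
X = z u*ᵀ + E_X, Y = z v*ᵀ + E_Y with iid N(0, δ²) noise, then standardizes
columns. The cross-covariance is rank one, so (u*, v*) is the population
canonical pair; on raw projections corr(Xu*, Yv*) = 1/(1 + δ²) for unit-norm
truths, a closed form the tests verify.

Ground-truth loadings are unit-norm, piecewise-constant signed blocks.
Defaults: p = 800 genomic features with active blocks (100–114, +) and
(400–409, −) (25 active, u*ᵢ = 0.2), q = 100 imaging features with blocks
(20–29, +) and (70–75, −) (16 active, v*ⱼ = 0.25), n = 200 subjects, noise
grid {0.5, 1, 2, 4}. At δ = 0.5 each active column then carries a 14–20%
signal-variance share — narrow, strong blocks of the kind this simulation
tradition uses; diffuse supports (10%+ of features active) dilute per-column
signal below what any method can recover at n = 200.

What the generator does **not** emulate: linkage-disequilibrium structure or
discrete genotypes on the X side, spatially correlated imaging noise, more
than one latent component, and non-Gaussian noise. Passing recovery tests
therefore demonstrate correctness of the estimator under the rank-one model,
not performance on real imaging-genetics data.

## Evaluation protocol

* **Test-fold CC**: Pearson correlation of X_test u and Y_test v, signed by
  default (so null calibration is meaningful); an `absolute` flag folds the
  sign. Zero-variance projections give 0 with a warning.
* **Repeated k-fold CV** (default 5-fold): every repeat reshuffles samples;
  each training fold is re-standardized and its mean/sd applied to the
  held-out fold; structures are rebuilt on the training fold only. All
  repeats × k fitted loading vectors are stacked (sign-aligned to the running
  mean row so averages do not cancel) into stability matrices — 50 repeats ×
  5 folds give exactly 250 rows.
* **Grid search**: all pairs from the γ grid (default 0.1, 1, 10, 100; 16
  cells) with λ₁ = λ₂ = 1 fixed; failures are recorded as NaN cells; ties
  break to the lexicographically smallest (γ₁, γ₂).
* **Noise sweep**: per noise level, `repeats` independent datasets each
  scored by one k-fold CV (independent draws, not reshuffles of one dataset,
  so dataset-level variance averages out of the cell mean). At high noise the
  test CC sits at its sampling floor (|mean| ≲ 0.05 at 20 fits/cell), where
  strict orderings between adjacent levels are not statistically resolvable;
  the qualitative decline from the signal regime is.
* **Top-k features**: mean |weight| per column of a stability matrix, sorted
  descending, index tie-break.
* **Pairwise gene–ROI tests**: Pearson r per column pair with a two-sided
  Fisher-z p-value (√(n−3)·atanh r against N(0,1)) plus Benjamini–Hochberg
  q-values; constant columns are flagged rather than dropped.

## Verification problem sizes

The verification suite and `scripts/acceptance.py` use: brute-force penalty
oracles at d ≤ 20 (100 cases); gradient checks on 50 random instances;
solver contracts on n = 100, p = 50, q = 40; the ridge-CCA limit at n = 2000,
p = q = 10 against an exact generalized-eigenvalue solution; recovery at the
standard p = 800, q = 100, n = 200, δ = 0.5 conditions over 10 seeds; and the
noise sweep at p = 200, q = 50 with 20 fits per cell — sizes chosen so the
whole battery completes in a couple of minutes on one core while still
exercising the standard conditions.

## Known limitations

* Single canonical pair only; no deflation for further components.
* The alternating scheme finds a local optimum; quality depends on the
  penalty balance (γ, λ) and the structural priors matching the truth.
* Correlation-derived graphs and connectivities are noisy at small n; with
  informative prior graphs (pathways, anatomical adjacency) supplied via
  file, results should only improve.
* The l1 baseline treats XᵀX, YᵀY as identity — standard, but a coarse
  approximation when features are strongly dependent.
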