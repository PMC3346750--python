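# Methods

## Model

Expression of the p regulated genes is conditionally Gaussian given the d
observed TF expressions and q latent factors:

    x_n = W r_n + Λ z_n + μ + ε_n,   z_n ~ N(0, I_q),   ε_n ~ N(0, σ² I_p).

The regulated genes exclude the TFs themselves (disjoint identifier sets), so
the implied graph is bipartite and acyclic, and the TFs' own joint
distribution never enters the likelihood. Latent factors are integrated out;
the marginal of x given r is N(W r + μ, C) with C = Λ Λᵀ + σ² I. The negative
log-likelihood over N samples is

    NLL = Σ_n [ p/2·log 2π + ½·log|C| + ½ δ_nᵀ C⁻¹ δ_n ],   δ_n = x_n − W r_n − μ,

and the fitted objective is NLL + λ(‖W‖₁ + ‖Λ‖₁). Only the regulation
weights and loadings are penalized: zeros there encode non-regulation, which
is the sparsity the penalty is meant to induce; the intercept and noise
variance carry no such interpretation.

Model assumptions worth keeping in mind: isotropic noise (one σ² shared by
all genes — genes are exchangeable in residual scale), linear effects,
Gaussian factors, and no TF–TF or gene–gene edges. The q = 0 limit is
per-gene linear regression on TFs; the d = 0 limit is probabilistic PCA.

## Numerics

All likelihood and gradient algebra goes through the Woodbury identity:
with M = σ² I_q + ΛᵀΛ,

    C⁻¹ = (I − Λ M⁻¹ Λᵀ)/σ²,   log|C| = (p−q)·log σ² + log|M|,

so a full objective/gradient evaluation costs O(N·p·(d+q)) plus O(p·q²);
no p×p matrix is ever formed and no N×p×p tensor materialized. M is
symmetric positive definite by construction (σ² > 0); a Cholesky failure can
only mean overflow/NaN in Λ and is reported as ill-conditioning.

Gradients of the NLL are analytic (verified against central finite
differences to <1e−5 relative error in the test suite):

    ∂NLL/∂W = −C⁻¹ Δᵀ R,        ∂NLL/∂μ = −C⁻¹ Σ_n δ_n,
    ∂NLL/∂Λ = N C⁻¹Λ − C⁻¹ S C⁻¹ Λ   (S = ΔᵀΔ, applied matrix-free),
    ∂NLL/∂σ² = N/2·tr C⁻¹ − ½ Σ_n ‖C⁻¹δ_n‖².

The noise is optimized as ν = log σ², keeping the domain unconstrained for
the quasi-Newton updates and guaranteeing positivity. The flat parameter
vector is frozen as [W row-major, Λ row-major, μ, ν], with the L1 mask
covering exactly the W and Λ blocks.

## Optimizer (OWL-QN)

The orthant-wise limited-memory quasi-Newton method handles the L1 term via
a pseudo-gradient — at zero coordinates the one-sided derivative of steepest
descent, or exactly 0 when the subgradient condition |g_i| ≤ λ already
holds — and an orthant-restricted backtracking line search (Armijo constant
1e−4, halving steps) whose projection clamps sign-crossing coordinates to
literal zeros. The L-BFGS direction (memory 10 by default) is computed from
raw loss-gradient differences and sign-aligned with the negative
pseudo-gradient coordinate-wise before the search. Convergence is declared
when the pseudo-gradient infinity norm falls below `tol` or the relative
objective decrease stays below `tol` for five consecutive iterations. The
projection mechanism is what makes reported supports exact: membership of a
gene in a regulator's set is a `!= 0` test, never a threshold.

Model fits start from W = 0, Λ entries i.i.d. N(0, 0.01), μ = 0 on centered
data, ν = log pooled variance, and run `n_restarts` seeded restarts
(default 10), keeping the best objective and reporting the cross-restart
spread. Columns of X and R are mean-centered before fitting and the
intercept restored afterwards (optionally also scaled to unit variance,
off by default — centering is standard for factor models and improves
conditioning; whether to scale depends on the expression units at hand).
During the line search, steps that drive ν outside ±690 (where exp
under/overflows) return an infinite loss and are rejected.

## Hyperparameter selection and evaluation

The evaluation protocol partitions samples into 10 outer folds (seeded
shuffle, contiguous blocks, sizes differing by at most one) and reports the
out-of-sample log-likelihood of three models per fold: the full model, the
no-hidden model (q = 0, same penalty), and a reference model of independent
per-gene Gaussians (MLE mean/variance, variances floored at 1e−8 × pooled
variance so constant genes stay finite). (λ, q) are chosen by 2-fold CV on
the first outer fold's training samples and reused for the remaining folds;
a flag retunes per fold instead. Model pairs are compared with a paired
Wilcoxon signed-rank test — exact by full enumeration of the 2ⁿ sign
assignments for n ≤ 15 nonzero differences, normal approximation above.

The default penalty grid is 8 logarithmic points on [λ_max/100, λ_max].
Because Λ = 0 is a stationary point of the likelihood (its gradient
vanishes there), a gradient-based bound at the zero solution would ignore
the loading block; λ_max is therefore the largest absolute penalized-block
gradient at the standard (seeded) initialization.

Two selection rules are provided. The default maximizes mean held-out
log-likelihood — the right criterion when the product is the *predictive*
model, and the one used by the three-model comparison. For *support
estimation* the prediction-optimal lasso penalty systematically
over-selects (small spurious weights barely hurt prediction), so
`cv_support_penalty` scores each candidate penalty by the held-out
likelihood of the unpenalized per-gene OLS refit on the support that
penalty selects (relaxed-lasso-style): spurious edges then pay their full
overfitting cost and the score peaks where the support is correct. In the
planted-recovery experiment the mean-LL rule leaves support F1 near 0.3
while the refit rule reaches F1 ≈ 1; a one-standard-error variant of the
mean rule is also available but does not bridge that gap at 2 inner folds.
The refit rule is defined for the q = 0 regression layer, where the refit
is closed form.

## Enrichment

Each hidden variable and each TF defines a gene set: the genes with nonzero
loading/weight in its column. Sets are tested against a GMT category
collection over the universe of genes present in both the model and the
collection; categories with fewer than 5 or more than 5000 members in that
universe are skipped (the GSEA convention). The score of a set is the
minimum one-sided Fisher exact (hypergeometric upper-tail) p over
categories, ties broken lexicographically. That minimum is calibrated by
drawing B (default 1000) uniform random gene sets of the same size and
scanning each against the same collection; the calibrated p is the fraction
r/B of null minima at least as extreme. r/B can be exactly zero — the
intended reading is "better than all 1000 size-matched random sets"; a
conservative (r+1)/(B+1) variant is a flag. Each gene set's randomization
uses an independent substream keyed by (seed, set index), so results do not
depend on evaluation order. FDR q-values are Benjamini–Hochberg step-up
applied to the calibrated p-values across tested sets.

## NCA baseline

Network component analysis factors the genes × samples matrix E ≈ A P with
the zero pattern of A fixed in advance; identifiability requires (1) A of
full column rank, (2) full column rank after deleting any regulator and its
connected genes — hence at least L−1 zeros per column — and (3) N ≥ L.
`make_random_connectivity` draws the minimal such random pattern (exactly
L−1 uniform zeros per column); `check_nca_criteria` diagnoses all three
conditions on a random realization. The decomposition itself is alternating
least squares on the fixed support — a full solve for P, then per-gene
restricted solves for A's rows (rows sharing a support pattern share one
normal-equation factorization) — run from `n_restarts` (default 3) random
initializations with the best final reconstruction error kept, since the
bilinear problem is nonconvex. Column scales are resolved afterwards by
normalizing A's columns with compensating row scaling of P. Singular
restricted systems receive a 1e−10 ridge jitter with a warning. Edge
pruning keeps the target number of largest-|weight| entries, ties broken by
(row, column) order.

A caveat found while validating: with only the minimal L−1 zeros per
column, the support constrains A so weakly that ALS moves along a nearly
flat manifold of equivalent factorizations and converges extremely slowly;
recovery experiments therefore plant sparser (≈30% density) identifiable
supports, which ALS solves to machine precision. The minimal-zeros pattern
remains the input convention for the method-comparison pipeline, where only
the enrichment of the pruned edges is consumed.

## Synthetic data

The generator draws R and Z as independent standard normals (upper-layer
nodes are mutually independent), plants exactly round(density·size) nonzeros
at uniform positions in W and Λ with magnitudes ± effect_scale (fixed
magnitudes make "support recovery" unambiguous), draws μ ~ N(0,1), and adds
isotropic N(0, σ²) noise. Defaults — w_density 0.05, lambda_density 0.2,
effect_scale 1.0, σ 0.5 — are the desk-scale study conditions used by the
test suite and acceptance script, with problem sizes p ≤ 120, d ≤ 10,
q ≤ 3, N ≤ 500 chosen so every experiment runs in seconds. The companion
category generator emits one planted category per hidden factor (a seeded
80% subsample of its true support, so enrichment is detectable but not a
tautology) plus uniform noise categories of size 5 to max(6, p/5).

Two experiment-level conditions deserve note. The three-model comparison
simulation uses w_density 0.3 at d = 5: the comparison mirrors a regime
where the TF layer dominates, and with a much sparser TF layer the
independent-genes reference model — which has per-gene variances — can
legitimately beat the isotropic no-hidden model, since unexplained latent
variance is then heterogeneous across genes. And the W-support recovery
experiment uses q = 0 data: with hidden factors present and a single shared
penalty, the loading block dominates prediction and pins the selected
penalty far below the support threshold; loading recovery is instead
assessed on q = 3 data by matching fitted to true columns (Hungarian
assignment on absolute correlations, since sign and permutation are not
identified).

What the generator does *not* emulate: probe-level microarray noise,
batch/array effects, heavy tails, per-gene noise variances, gene–gene
dependence beyond the shared factors, or realistic GO DAG topology. Passing
tests demonstrate correctness of the estimator under its own assumptions
and calibration of the randomization machinery — not robustness to the
violations real expression data will contain.

## Degenerate inputs and tie-breaking

Constant genes: reference-model variances are floored; fitting itself
centers columns and tolerates zero-variance genes. Empty gene sets are
excluded from enrichment (and counted in logs). All-zero differences give
Wilcoxon p = 1. q = 0 and d = 0 are first-class code paths. Category-scan
ties break lexicographically; pruning ties break by (row, column); fold
remainders spread one per fold. All randomness flows from explicit seeds
through named substreams, so every command and experiment is reproducible
bit-for-bit.
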