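# Methods

## Varying-coefficient structural equation model

Each target gene's log-expression is modelled as a linear combination
of candidate regulator expressions whose coefficients β_j(m) are
functions of a one-dimensional per-sample modulator m.  The model
assumes (i) the modulator captures the biological axis along which
regulation changes, (ii) coefficients are locally constant: samples
with similar m share a regulatory program, and (iii) regulation is
directed regulator → target, so only genes in the regulator list emit
edges and a target is never its own regressor.

For a focal sample i the coefficients are estimated by minimising

    ½ Σ_k w_k (y*_k − Σ_j β_j x*_kj)² + λ₁ Σ_j γ_j |β_j| + ½ λ₂ Σ_j β_j²

with Gaussian kernel weights w_k = exp(−(m_k − m_i)²/2h²).  The ½
factors are this package's normalisation of the penalised weighted
least-squares objective; they make the empty-model boundary exactly
λ_max = max_j |Σ_k w_k x*_kj y*_k| / γ_j (KKT condition), which anchors
the λ₁ path.  Any other scale convention is an equivalent
reparametrisation of (λ₁, λ₂).

**Standardization.**  y and each regressor column are centred and
scaled to weighted mean 0 / variance 1 under the kernel weights of the
focal sample, which eliminates the intercept from the local loss.  A
config flag (`solver.standardize: global`) switches to unweighted
moments for comparison.  Columns with zero weighted variance are
dropped (recorded in the scaling record) and receive exact-zero
coefficients; fitted coefficients are mapped back to the raw scale for
reporting and prediction.

**Solver.**  Cyclic coordinate descent on Gram-space sufficient
statistics (G = X*ᵀWX*, c = X*ᵀWy*), coordinates visited in fixed input
order, convergence when the largest per-sweep coefficient change drops
below `solver.tol` (default 1e−7; sweep budget 1e5).  Determinism is
part of the contract — no randomized coordinate order.  The inner loop
is compiled with numba; the per-fit cost is ~1 ms at n = 300, q = 12.

**Adaptive recursion.**  Iteration 1 runs with γ ≡ 1; each later
iteration rebuilds γ_j = 1/(|β̂_j| + δ) (δ default 1e−8, guarding the
division) from the previous grid winner and re-searches the (λ₁, λ₂)
grid; the loop stops as soon as the grid winner fails to improve the
incumbent criterion value, and the incumbent is returned — so the
result is never worse than the first iteration's best.  (λ₁, λ₂) are
re-selected every iteration rather than frozen after iteration 1; both
behaviours fit the loop structure, and re-selection lets the grid adapt
to the sharpened weights.

**Model selection.**  Candidate grids: λ₂ ∈ {0.01, 0.1, 1} and 30
log-spaced λ₁ values from λ_max down to 10⁻³ λ_max (computed per fit
and per γ), scored by a bias-corrected weighted AIC

    score = n_eff · ln(RSS_w / n_eff) + 2 · df · n_eff / (n_eff − df − 1),

with n_eff = Σ w_k and df the ridge-type hat-matrix trace
tr[X_A (X_AᵀWX_A + λ₂I)⁻¹ X_AᵀW] on the active set — |A| at λ₂ = 0 with
full-rank columns, → 0 as λ₂ → ∞.  The score reduces to the classical
bias-corrected AIC at uniform unit weights; models with df ≥ n_eff − 1
score +∞.  Ties break toward smaller df, then larger λ₁, then earlier
grid position (prefer sparser, more-penalised models).  This criterion
has AIC-type strength: its marginal penalty is ≈ 2 per df, so a
predictor whose local weighted correlation satisfies
n_eff·ln(1/(1−r²)) > 2 is retained.  Consequence: in regimes where the
true coefficient is 0 the per-fit spurious-inclusion probability is
roughly P(χ²₁ > 2) ≈ 0.16 before the adaptive recursion, ≈ 0.05 after
it (measured on the planted-switch conditions).  The criterion is
isolated behind `weighted_aicc` so a stricter rule can be swapped in.

## Bandwidth selection

h is chosen from a grid (default {0.25, 0.5, 1, 2, 4} × SD(m), 5 folds)
by K-fold cross-validation: each held-out sample's model is fitted from
training samples only, with kernel weights computed between the
training modulator values and the held-out sample's m (no leakage
through standardization), and scored by squared raw-scale prediction
error averaged over targets and held-out samples.  Ties resolve to the
larger (smoother) h.  The CV error profile is typically flat to ~1%
across the upper half of the grid when the truth has no modulator
dependence, so the exact argmin among large bandwidths is noise; what
is informative is small-h vs large-h error, which cleanly separates
switching from constant truths.  A per-target h is available behind a
flag; the default averages the CV error over the listed targets so one
global h serves the whole ensemble build.

## Hidden-modulator extraction

The seed signature is refined by an iterative leave-worst-out filter:
compute the first principal component (eigengene) of the current
subset, drop the gene with the lowest |Pearson r| against it, repeat
until every retained gene clears `correlation_floor` (default 0.5,
`min_size` default 10).  This is a deliberately simple coherence
surrogate for seed-refinement module extraction; the floor is a free
parameter with no published counterpart, exposed in config.  Sample
scores are the leading right singular vector of the row-centred member
submatrix scaled to unit variance (row-centring removes the
gene-specific intercepts of the single-factor model and forces exactly
zero-mean scores; under equal-variance Gaussian noise the SVD is the
maximum-likelihood factor fit).  Unit variance is chosen so default
bandwidth grids transfer across datasets — downstream kernels only see
distances, so any fixed scale is equivalent.  The global sign is fixed
against an anchor gene (default desired sign −1: high anchor
expression ⇔ low modulator); a zero anchor correlation leaves the sign
unchanged with an `OrientationAmbiguous` warning.  Multi-dimensional
modulators are out of scope.

## Regulatory effect and effect change

The effect of regulator j on target l in sample i is the sum over all
directed paths of length ≤ 2 from j to l of the product of edge
coefficients along the path.  Intermediate nodes are necessarily
regulators (only regulators have out-edges) and node repeats are
banned, so cycles cannot contribute at these lengths.  The effect
change is max−min of the effect across samples (non-negative, zero iff
the profile row is constant, permutation-invariant); a percentile
variant (p_lo, p_hi) is available and is always ≤ the max−min value —
more robust, less powerful.  The activator/inhibitor label is the sign
of the effect value of largest magnitude across samples (all-zero rows
label I); this is a documented convention, as only the labels
themselves are standard.  The change does not identify the mode of
action of the modulator, and no mode-of-action test is provided.

## Gene-set analysis

Per sample and regulator, the downstream target set defaults to direct
children (path length 1; length 2 adds grandchildren whose path
products do not cancel exactly).  Over-representation in each gene set
is the exact one-sided hypergeometric upper tail against the gene
universe (all genes of the expression matrix); no continuity-corrected
approximation is ever used, so null p-values are conservative-or-exact.
BH correction is applied within each sample across all
(regulator, set) tests by default (`bh_family: regulator` switches to
within-(sample, regulator) families).  The enrichment score
E = max(−log₁₀ q) − min(−log₁₀ q) across samples uses q-values by
default (a p-value variant sits behind `use_p`); the total score
T = 2·ln 10·Σ_c E_c converts the base-10 scores to the natural-log
scale of Fisher's combination statistic and is referred to the χ²
distribution with 2L degrees of freedom — one interpretation of a
"difference of Fisher statistics" construction, adopted because it
reduces exactly to Fisher's method when each E_c is a single −log₁₀ p.

## Synthetic data

Three seeded, bit-reproducible generators emulate exactly the
structures the method assumes, with full planted truth recorded:

* **switch** — m ~ U[−1, 1] (sorted; a permute flag scrambles order),
  regulators i.i.d. standard normal, one regulator→target coefficient
  stepping low_coef → high_coef at m = 0 (logistic ramp optional),
  decoys exactly zero, Gaussian noise (default SD 0.3, 12 regulators,
  1000 samples).
* **factor** — x_g = μ_g + b_g·z + ε with b_g = ±loading_scale
  (default 1) and noise SD 0.5, i.e. loading/noise ratio 2; defaults
  50 genes × 200 samples.
* **gsa** — a switch scenario whose planted regulator's targets are
  drawn from one designated set (targets partition into equal sets);
  decoy regulators hold constant-coefficient targets drawn from the
  whole pool so only the planted regulator's enrichment varies.
  Defaults 48 genes / 120 samples / 3 sets keep a full
  10-replicate end-to-end run near a minute.

What these generators do *not* emulate: probe/batch effects, heavy
tails, correlated regulators, multi-factor modulators, or feedback
loops.  Passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to real microarray
artefacts — normalisation and probe-to-gene collapsing are assumed
done upstream.

## Numerical and design notes

* Problem sizes in tests and the validation script (n = 120–300
  samples, 5–12 regulators, ≤ 42 targets, 10–20 replicates) are chosen
  to exercise every code path at desk scale; the algorithm
  parallelises per (target, sample), and `parallel_hint` workers never
  change results (fragments merge in canonical order).
* The switch-scenario analyses use h = 0.2 in modulator units
  (m ~ U[−1, 1]): a ±2h neighbourhood spans ~40% of the transition,
  balancing locality against effective sample size.  This value was
  fixed by that reasoning, not fitted.
* Network edges store exact-nonzero raw-scale coefficients only; the
  edge-list writer emits full `repr` precision so read∘write is
  bit-exact.
* Degenerate inputs: constant expression rows are dropped from designs
  with a warning; an all-constant design raises; a singular ridge
  system at λ₂ = 0 falls back to the pseudoinverse with a warning; a
  constant modulator is rejected at construction.
* Known limitations: AIC-strength selection admits weak spurious
  edges where the local signal-to-noise is low (see Model selection);
  path effects ignore paths of length ≥ 3; the integral p-value
  treats per-set scores as independent, which planted-truth
  simulations satisfy but correlated gene sets will not.
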