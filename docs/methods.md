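# Methods

## Model

`spotdecon` treats raw counts in both modalities as negative binomial.
The pmf convention is pinned as

    P(k | r, p) = Γ(k + r) / (Γ(r) k!) · p^k · (1 − p)^r,

so the mean is `r·p/(1−p)` and, for a shared success probability `p`,
rates are additive: `NB(r1, p) + NB(r2, p) = NB(r1 + r2, p)`. This
additivity is the load-bearing property — it is what lets a spot's
summed transcripts stay inside the NB family with a rate that is a
weighted sum of cell-type rates. The Γ-form is used throughout (rather
than binomial coefficients) so non-integer rates are handled exactly.

**Step 1 — single-cell fit.** For cell `c` of annotated type `z(c)`,
`y_gc ~ NB(s_c r_{g,z(c)}, p_g)` with `s_c` the observed library size.
The negative log-likelihood is minimized jointly over the full rate
matrix and the per-gene success logits; the likelihood factorizes over
genes, so the joint fit equals per-gene fitting but vectorizes better.
Cells with zero library size are dropped with a warning (the rate
contribution is undefined), and genes with zero total count are removed
(their rate is unidentifiable and `p_g` unconstrained).

**Step 2 — spatial MAP fit.** With `r, p` frozen,
`x_sg ~ NB(β_g v_sᵀ r_g + γ_s ε̃_g, p_g)` where `ε̃_g` is the positive
transform of the dummy type's unconstrained rate parameter. The
objective is the negative log-posterior: the data NLL plus `½ Σ_g ε_g²`
from the standard-normal prior on the unconstrained dummy rates; all
other parameters carry flat priors (no penalty). Proportions are
`w_sz = v_sz / Σ_z v_sz`, excluding the dummy type; the per-spot scaling
factor cancels in this ratio, which is why only the product
`v_sz = α_s n_sz` is ever estimated. The dummy's unnormalized weight is
reported separately as `γ_s / (γ_s + Σ_z v_sz)`.

## Optimization

No automatic-differentiation framework is used: the NB likelihood has
closed-form gradients (digamma terms for the rate, `k(1−p) − μp` for the
success logit), so both fits run Adam (β₁ = 0.9, β₂ = 0.999) on
analytically computed gradients in NumPy. Positivity is enforced by
softplus, probabilities by a sigmoid, and the dummy prior is placed on
the unconstrained parameter. Full-batch gradients are the default; a
`batch_size` option subsamples cells (or spots) per step with unbiased
rescaling when memory matters.

Two numerical choices matter in practice:

- **Initialization.** Both fits start from method-of-moments values
  rather than a cold random start. In step 1, at the `p = 0.5`
  initialization the NB mean is `s_c·r`, so rates start at the per-type
  mean count over library size (plus Normal(0, 0.1) jitter, seeded). In
  step 2, `v` starts at the per-spot total divided by the expected
  per-unit-quantity yield. With a cold start the optimizer must traverse
  a long, nearly mean-preserving (r, p) ridge and converges impractically
  slowly; from the moment start the fits reach the same minima found by
  derivative-free per-gene optimization (verified against a Nelder-Mead
  oracle in development and a simplex grid search in the tests).
- **Internal rescaling of step 2.** The natural magnitude of `v` is the
  summed library size of a spot's cells (10⁴ or more). Softplus is the
  identity at that magnitude, so a bounded-step optimizer cannot move
  the parameter usefully. `fit_st` therefore folds the median natural
  scale into the frozen rates so `v` is O(1), and gives the dummy rates
  a fixed scale constant `e0` (the mean rescaled rate) so `γ` lives in
  the same quantity units as `v`. Both are per-fit global constants,
  stored on the returned fit; proportions and dummy shares are invariant
  to them, and rescaling `γ` under its flat prior leaves the MAP of all
  other parameters unchanged.

Degenerate inputs: an all-zero spot or cell is dropped with a warning;
a gene observed once rides the (r, p) ridge, where only the fitted mean
is identifiable — the boundary behavior tests assert on the mean.
Non-finite losses abort with a diagnostic rather than continuing.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `epochs` | 50 000 | Adam steps (production setting; the tests and the acceptance script use 2000, the point past which the moment-initialized fits no longer improve at the problem sizes they run) |
| `learning_rate` | 0.01 | Adam step size; all other Adam constants at their usual values |
| `top_genes` | 5000 | genes kept, ranked by total count over cells; ties broken lexicographically |
| subsample `l, u` | none (CLI `--min-cells/--max-cells`) | per-type bounds: drop types under `l`, keep whole in `[l, u]`, sample exactly `u` above |
| `alpha` (generator) | 1.0 | per-cell count scaling before nearest-integer rounding |
| null `reps` | 1000 | Dirichlet null repetitions |
| co-localization `alpha_level` | 0.01 | two-sided Pearson significance threshold, uncorrected |

## Synthetic data

The **semi-synthetic spot generator** draws, per spot: a cell budget
`C_s ~ Unif{lb..ub}`; a type-subset size `|Z_s| ~ Unif{1..|Z|}`
(inclusive); types without replacement; unadjusted proportions from a
flat Dirichlet; per-type counts as nearest integers (half away from
zero — banker's rounding would change counts) of proportion × budget.
Repairs: if all counts round to zero the largest-proportion type gets
one cell; counts are capped at each type's available cells (sampling is
without replacement); and the total is nudged back inside `[lb, ub]`
when rounding or capping pushed it out, decrementing the largest count
or incrementing the highest-proportion type with cells to spare. Ground
truth is the per-spot normalization of the realized counts. Spot
expression sums `round(α · y_cg)` over the sampled cells, so at `α = 1`
a spot's total equals its member cells' summed library sizes exactly.
The two regimes exercised by the tests are 10–30 cells per spot
(ST-like arrays) and 1–10 (Visium-like).

The **generation/validation split** is stratified by type into disjoint
halves (odd counts favor the generation half; singleton types go to
generation with a warning), so the reference used for deconvolution
never contains a cell that built a spot.

The **fully synthetic NB generator** samples cells from the single-cell
model itself given a known parameter set. Its `random()` defaults —
log-normal rates (log-mean 0.7, log-sd 1.0), success probabilities
uniform on (0.2, 0.8), and a log-normal library-scale pool (median 5,
log-sd 0.3) — are chosen so genes look like the *top-expressed* subset
the method actually runs on: a few to a few dozen counts per gene and
cell. This matters: far below that coverage the (r, p) pair is only
jointly identified through its mean and recovery of the individual
parameters degrades, which is a property of the data, not the optimizer.

What these generators do **not** emulate: spatial autocorrelation
between neighboring spots, tissue geometry, batch effects between the
single-cell and spatial assays beyond a per-gene multiplicative bias,
ambient RNA, or cell-type-dependent capture efficiency. Passing the
synthetic benchmarks therefore demonstrates correct inference under the
model's own assumptions plus the mixing mechanics of spot assays — not
robustness to every artifact of real tissue data.

## Evaluation protocol

Per-spot RMSE is `sqrt(mean_z (w_sz − ŵ_sz)²)`. Method comparisons use
the one-sided paired Wilcoxon signed-rank test on per-spot RMSE vectors
(zeros dropped, the convention of the standard R routine). The
uninformed baseline replaces estimates with flat-Dirichlet draws and is
scored **against the ground truth** (the draw-vs-draw variant is
available behind a flag; the two differ modestly in expectation, and
draw-vs-truth is the reading that matches "how well would a guesser
do"). Co-localization is the pairwise Pearson correlation of type
proportions across spots with two-sided p-values, uncorrected by
default with an optional correction flag; zero-variance types yield
missing entries. Display scaling divides each type's proportions by
their maximum within a section, with no thresholding.

## Known limitations

- `β_g` (and with it the mixture weights) is only well identified when
  spot compositions are diverse. A data set whose spots all share one
  composition lets `β` re-warp the reference profiles and mixtures
  become interchangeable; the pure-spot recovery test therefore embeds
  pure spots in a diverse set. Fixing `β` (`fit_beta=False`) removes
  the issue when the assays are known to be bias-free.
- Absolute cell counts `n_sz` are not recoverable (only `α_s·n_sz`).
- Proportions exist only for types present in the reference; missing
  types surface through the dummy share, not as named proportions.
- The dummy share depends on the relative scale convention between `γ`
  and `v`; it is comparable across spots within a fit, which is how the
  tests use it, but not across fits with different references.
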