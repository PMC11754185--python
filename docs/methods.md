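# Methods

## Model and objective

`lrcl` fits a joint objective over per-view linear transforms Z_k
(d_k × C), simplex view weights ω, and a nonnegative label-relaxation
matrix H:

    J(Z, ω, H) = Σ_k [ ω_k E_k + ω_k ln ω_k + α tr(Z_kᵀ X_kᵀ L_k X_k Z_k) ],
    E_k = ‖X_k Z_k − Ỹ‖²_F + β ‖X_k Z_k − C_k‖²_F,
    Ỹ = Y + U ⊙ H,   H ≥ 0,   Σ_k ω_k = 1.

The per-view loss E_k carries both the relaxed-label residual and the
consistency residual, and the view weight multiplies the whole of E_k.
This is the only grouping under which all three closed-form updates below
are exact stationary conditions of one and the same J; it is the reading
the solver implements, and every update is verified against independent
numerical minimizers in the test suite rather than trusted on paper.

### Closed-form updates

Per outer iteration, in this order:

1. **Z_k** (each view):
   Z_k = [ω_k(1+β) X_kᵀX_k + α X_kᵀL_kX_k + jitter·I]⁻¹ ω_k X_kᵀ(Ỹ + βC_k).
2. **ω**: ω_k = exp(−E_k) / Σ_t exp(−E_t), computed with a max shift
   (softmax is shift-invariant, so enormous losses cannot underflow all
   weights to zero).  This is the exact minimizer of Σ(ω_k E_k + ω_k ln ω_k)
   on the simplex.
3. **H**: H = max(U ⊙ (Σ_k ω_k X_k Z_k − Y), 0), elementwise.  The
   derivation needs Σω_k = 1, which is why ω is updated before H.

Each block is an exact minimizer, so J is non-increasing across blocks and
bounded below by −ln K (the entropy of uniform weights; all other terms
are nonnegative).  The solver stops when Σ_k ‖Z_k(t) − Z_k(t−1)‖_F < tol
(default 10⁻⁸) or after `max_iter` (default 200) iterations.  On the
default synthetic conditions convergence typically takes 8–15 iterations.

### Fixed quantities

- **Ridge priors** P_k = (X_kᵀX_k + λI)⁻¹X_kᵀY are computed once on the
  training split and never re-estimated; they are prior knowledge, not a
  block of the optimization.  Consistency targets
  C_k = (1/(K−1)) Σ_{t≠k} X_t P_t are therefore also fixed.
- **Graphs.**  O_k,ij = exp(−‖x_i − x_j‖²/δ) when samples i and j share a
  training label, else 0; self-loops are excluded (a self-edge contributes
  nothing to the quadratic form and only inflates the degree matrix).
  L_k = D_k − O_k.  "Same manifold" is operationalized as "same training
  label", with no neighborhood sparsification.  Graphs are built on the
  training split only; test samples never enter L.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 1.0 | weight of the Laplacian manifold penalty |
| β | 1.0 | weight of the cross-view consistency penalty |
| δ | "auto" | Gaussian kernel width; auto = mean squared same-label pairwise distance |
| λ (`ridge_lambda`) | 1.0 | ridge penalty of the priors P_k |
| jitter | 1e−8 | diagonal added inside the Z-update inverse |
| tol | 1e−8 | stopping threshold on Σ‖ΔZ_k‖_F |
| max_iter | 200 | iteration cap |

α and β are user-set balance parameters with no canonical values; the
defaults were chosen so that on the default synthetic conditions each
penalty's magnitude is comparable to the per-view empirical risk — a
regularizer whose term is orders of magnitude below the risk would be
inert at its default, which serves nobody.  The `--grid` option of the
`fit` command selects α, β on the validation split instead, which is the
recommended route on real data.  λ defaults to 1.0; at λ = 0 the prior
requires X_kᵀX_k to be invertible and the code raises otherwise.  The
jitter keeps the Z-update well-posed when d_k exceeds the number of
training samples; at 1e−8 its effect on a well-conditioned solve is below
the convergence tolerance.

Two further conventions worth knowing:

- **Laplacian factor.**  The quadratic identity used is
  tr(Z_kᵀX_kᵀL_kX_kZ_k) = ½ Σ_ij O_ij ‖(X_kZ_k)_i − (X_kZ_k)_j‖² with
  L = D − O.  Writing the pairwise sum without the ½ would merely rescale
  α, which is free anyway.
- **Raw vs normalized losses.**  E_k is a raw squared Frobenius norm, not
  divided by N or C.  Consequently the softmax over −E_k sharpens as N
  grows: per-view loss differences of a few units already produce
  near-one-hot weights, and on realistic sample sizes the fused model is
  usually dominated by the best single view.  The symmetry is preserved in
  distribution — with equally informative views, which view wins is a coin
  flip across datasets — but a single fit should be expected to be sharp.
  Normalizing E_k by N would soften this; it is deliberately not done so
  that the weights remain the exact minimizer of the stated J.

### Initialization and determinism

Default init is deterministic: ω = 1/K, H = 0 (feasible, and the exact
block minimizers make the fixed point insensitive to the start in
practice).  `init="random"` draws ω from a symmetric Dirichlet and H from
|N(0, 0.01)|, seeded, mirroring a randomized start; both modes are logged.
Identical config and seed reproduce fits bitwise.  Ties at prediction
argmax go to the lowest class index; classes are ordered
lexicographically everywhere.

### Degenerate inputs

K = 1 with β > 0 warns and proceeds with β = 0 (consistency needs a
second view).  Constant features are scaled by 1 and flagged rather than
dropped.  Classes with fewer than 3 members cannot be split 60/20/20 and
raise.  A non-finite objective aborts with the per-view term magnitudes
in the message.

## Protocol

`fit` (CLI) follows the evaluation protocol end to end: stratified
60/20/20 train/validation/test split (sizes ⌊N·r⌋ for validation and
test, remainder to train; per-class counts within one sample of
proportionality); z-scoring with training-split statistics (on by
default — the Gaussian edge weights and ridge priors are scale-sensitive;
`--no-standardize` disables it); Fisher-score and Pearson-score feature
ranking on training rows only, combined by average rank (ties to the
smaller index), keeping 30 and 35 features per view by default, matching
the radiomics/deep feature counts of the motivating protocol; then the
alternating solver.  The validation split is reserved for `--grid`
hyperparameter selection; the test split is touched once.

## Synthetic data

The generator emulates the structure the method targets: a latent
class-informative factor *shared* across views (strength `rho_consist`,
default 0.7 — the "consistent pattern" the β-term exploits), a
class-informative factor *private* to each view, unit loading vectors,
Gaussian noise (`noise_sd`, default 1.0), class separation `sep` (default
1.0, the latent mean shift), and pure-noise distractor columns (2× the
informative count) that give feature selection real work.  Defaults are
N = 200 samples, two views of 40 and 50 informative features, balanced
classes.

What it does *not* emulate: heavy-tailed or bounded radiomics marginals,
feature correlation structure within a view, deep-feature geometry, label
noise, class imbalance beyond the `class_balance` knob.  Passing tests on
this generator therefore certify the optimization and protocol machinery
and the *direction* of regularizer effects under ideal Gaussian
conditions, not clinical performance.

## Ablation harness and what it shows

`ablate` refits three variants — full, β = 0 (no consistency), α = 0 (no
manifold) — on many fresh synthetic datasets, recording train/test AUC at
every solver iteration.  On the default conditions (50 seeds), removing
the consistency term lowers mean test AUC by ≈ 0.5 points (paired across
seeds), reproducing the directional benefit of cross-view mining.  The
manifold comparison is a null at this scale: the same-label graph penalty
acts on Gaussian data as supervised within-class shrinkage that raises
train and test AUC by the same amount (≈ +0.5 each), leaving the
train−test divergence unchanged (paired gap difference −0.03 ± 3.3 over
50 seeds).  The overfitting-protection role of the manifold term on real
fundus data does not manifest in this generator, whose class manifolds
are single Gaussian blobs — a known limitation of the synthetic stand-in,
stated here rather than papered over.

## Numerical verification

The test suite checks the solver against implementations it does not
share code with: stacked-QR least squares for the Z block, bounded scalar
and trust-region simplex minimization for ω, the per-entry quadratic
vertex for H, a restart-polished L-BFGS-B minimization of the whole J
(with ω profiled out in closed form) for the joint optimum, brute-force
double sums for the Laplacian identity, and pair enumeration for AUC.
Because the entropy weighting makes J a soft-min over per-view losses,
the joint objective has one basin per candidate "winning view"; the
oracle-equivalence instances use views of clearly different informativeness
so that the global basin is unambiguous and both optimizers must meet in
it.  With near-equal views, alternating minimization and a quasi-Newton
method can legitimately settle in different basins — a property of the
objective, not an implementation defect.

## Known limitations

- Multi-class (C > 2) fitting and accuracy work, but SP/SN/AUC reporting
  is binary-only.
- The softmax view weights are near-one-hot at realistic N (see above);
  users wanting smooth fusion should fit on normalized features and small
  N, or treat ω as a view-selection diagnostic.
- Priors are plain ridge; the consistency term inherits whatever bias the
  priors have.
- Persisted models store classes as strings; integer labels round-trip
  through `predict` as their string form.
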