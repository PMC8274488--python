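# Methods

## Model

`opfddl` classifies samples that arrive as *R* parallel feature views
("frequency bands" in the EEG setting that motivates the design): band *r*
contributes a matrix **X**^r ∈ ℝ^{m×n} with samples as columns, and all bands
share one label vector with classes 1..C.

The model couples three sets of parameters:

- a **shared class-structured dictionary** D = [D₁, …, D_C] ∈ ℝ^{m×K},
  K = C·K_c, every atom unit-norm;
- **per-band orthonormal projections** Q^r ∈ ℝ^{m×d}, (Q^r)ᵀQ^r = I, which map
  each band into its own d-dimensional subspace;
- an **adaptive Fisher weight** μ ≥ 0.

For a sample x with label l and sparse code s over D, write δ_l(s) for the code
restricted to class-l atoms and ζ_l(s) = s − δ_l(s) for the complement.  The
*within* residual x − D δ_l(s) measures how well the sample's own class block
explains it; the *between* residual x − D ζ_l(s) how well all other blocks do.
Accumulating outer products of these residuals per band gives scatter matrices
W_w^r and W_b^r (built in the original m-dimensional space; their projected
traces J_w^r = tr(Q^rᵀ W_w^r Q^r) and J_b^r are the Fisher terms).

A discriminative model makes J_w small and J_b large.  Rather than the
trace-ratio Σ J_w / Σ J_b, training minimizes its quadratic weighted
relaxation

    f(Q̃, D, μ) = μ² Σ_r J_w^r − μ Σ_r J_b^r ,

which has closed-form coordinate updates: because the stacked scatter matrices
are block-diagonal over bands, the Q-subproblem decouples and each Q^r is the
set of eigenvectors of M^r = μ²W_w^r − μW_b^r for its d algebraically smallest
eigenvalues (M^r is symmetric but indefinite, so a general symmetric
eigensolver is required and negative eigenvalues are expected); and at fixed
Q and scatters the optimal weight is μ = ΣJ_b / (2 ΣJ_w), at which point
f = −(ΣJ_b)²/(4ΣJ_w) ≤ 0.

Sparse codes are fit in each band's subspace with an ℓ1 penalty,

    min_s ‖Q^rᵀx − (Q^rᵀD)s‖² + λ‖s‖₁ ,

i.e. the dictionary is *projected* before coding — the only dimensionally
consistent reading, and the one that matches the scatter algebra, where D is
always left-multiplied by Qᵀ.  The projected atoms are deliberately not
re-normalized (atoms are unit-norm in ℝ^m; their projections need not be), so
the coding problem is exactly the one the gradient and scatter computations
assume.

## Training loop

One iteration updates, in order: **codes** (lasso per band), **projections**
(per-band eigen-solve), **dictionary** (gradient step), **μ** (closed form).
Initialization: per-class K-SVD on the column-wise concatenation of that
class's samples over all bands (the dictionary is shared, so its
initialization should see every band); initial codes by OMP against the
sample's own class block only; Q^r random with orthonormalized columns; μ = 1
until the first closed-form update replaces it.

The dictionary step uses the analytic gradient of the same quadratic weighted
objective the other updates minimize (variant `"qwo"`, the default), so the
whole loop descends one coherent function; an unweighted variant that treats
the within and between residual terms symmetrically is kept as `"unweighted"` for
comparison.  The base step λ_D = 0.05 is scaled by 1/(n·R) (gradients are sums
over all stacked columns) and halved up to 10 times whenever the step would
increase the quadratic weighted term; if every halving fails the step is
skipped.  Atoms are renormalized to unit norm after every accepted step, and
an atom whose pre-normalization norm collapses below 1e-12 keeps its previous
value.

**Stopping.** The monitored objective is the quadratic weighted term plus the
coding term (residual + ℓ1 penalty, summed over bands); training stops when
its relative change drops below `tol` (default 1e-3) or at `max_iters` (100).
Two monotonicity guarantees hold exactly and are recorded every iteration: the
projection update and the μ update never increase the quadratic weighted term
(global minimizers of their subproblems).  The monitored *sum* is not a joint
Lyapunov function — the μ update re-scales the Fisher term between iterations
and the coding step optimizes only the coding term — so individual iterations
can tick upward (about a quarter of transitions on small synthetic runs) while
every run drifts downward overall; the convergence test asserts exactly that.

## Classification

A test sample's band-r vector z is projected, and each class is scored by
least-squares reconstruction onto its *projected* sub-dictionary
P_j = Q^rᵀD_j via the Moore–Penrose pseudo-inverse:

    e_j^r = ‖Q^rᵀz − P_j P_j⁺ (Q^rᵀz)‖₂ .

Test-time scoring is plain least squares, not ℓ1 coding.  Each band votes for
its argmin class; the label with most votes wins.  Vote ties are broken by the
smaller residual summed over the tied class's voting bands, then by the lower
class index.  The residuals depend only on span(Q^r), so the eigenvector-basis
ambiguity of the Q update cannot change a decision (tested by random d×d
rotations).

For discrimination it is essential that K_c < d: once a class's projected
sub-dictionary has d or more independent columns it spans the whole subspace
and every class reconstructs every sample perfectly.

## Parameters

| name | default | meaning |
|---|---|---|
| `subspace_fraction` | 0.90 | d = round(0.9·m); keeps most variance while discarding the noisiest directions |
| `atoms_per_class` (K_c) | 20 | class block size; accuracy plateaus near 20 on real-scale feature sets. The desk-scale benchmark (m = 20, d = 18) uses 10, the smallest value of the conventional sweep grid {10,…,35}, since K_c must stay below d |
| `sparsity_weight` (λ) | 0.01 | ℓ1 weight for subspace coding |
| `dict_step` (λ_D) | 0.05 | base dictionary step, backtracked on increase |
| `tol` | 1e-3 | relative-change stopping threshold |
| `ksvd_iters` / `ksvd_sparsity` | 10 / 5 | initialization-only K-SVD budget and OMP nonzero budget T |
| `mu_ceiling` | 1e6 | cap for μ when the within scatter degenerates to ~0 |
| `standardize` | off | optional per-feature z-scoring (training statistics reused at test time) |

## Synthetic benchmark

The generator plants exactly the structure the model assumes: K_c unit-norm
latent atoms per class in a shared `latent_dim`-dimensional space, one
orthonormal lift per band into ℝ^m, class-sparse coefficients (T_true nonzeros
on own-class atoms, magnitudes uniform in [0.5, 1.5] with random signs), and
isotropic Gaussian noise rescaled per band so the empirical SNR matches the
target exactly.  Defaults: C = 3 classes, R = 3 bands, m = 20 features,
latent_dim = 12, K_c = 5 planted atoms/class, 100 samples per class, T = 3,
SNR 10 dB.  An optional leakage fraction adds one off-class atom to a random
subset of samples to stress the Fisher separation.

What it does **not** emulate: real EEG band features have heavy-tailed,
cross-correlated channels, non-stationarity across trials, and band-dependent
noise spectra; the lifts here are exactly orthonormal and the noise is white.
Passing the synthetic benchmark therefore demonstrates correct optimization
and recovery inside the model class, not performance on recorded EEG.

A structural note on the benchmark: the latent atoms are shared but the band
lifts differ, so no single m-dimensional dictionary can reproduce every band's
class subspaces exactly (each band's lifted class subspace would have to fit
inside span(D_c) plus the m−d = 2-dimensional null space of that band's
projection).  Zero training error is thus unattainable by construction; the
benchmark tests *discrimination* — whether joint training makes each sample's
own-class residual smallest — which the noiseless run passes at ≥ 99%.

## Numerical choices

- Eigenvectors are ordered by ascending eigenvalue with a deterministic sign
  (largest-magnitude entry positive), so runs are bit-reproducible.
- Scatter matrices are symmetrized once, (W + Wᵀ)/2, to kill float asymmetry;
  PSD otherwise holds by construction.
- The lasso is solved by cyclic coordinate descent with Gram precomputation
  (`alpha = λ/(2d)` maps the solver's objective onto the model's), tolerance
  1e-8, iteration cap 5·10⁴.  On overcomplete projected dictionaries the
  solution need not be unique and the cap can bind; KKT residuals stay at the
  1e-6 level there, and on well-posed instances convergence is complete.
- K-SVD uses OMP with exactly T atoms and rank-1 SVD atom updates, plus the
  standard degeneracy fixes: unused atoms are re-seeded at the
  worst-reconstructed sample, near-duplicate atoms (|corr| > 0.99) likewise.
  Because clearing transiently raises the error, the solver returns the
  incumbent-best iterate and its trace records the best-so-far error, which is
  non-increasing by construction.  Alternating minimization is init-sensitive
  at small scales, so `n_restarts` runs the fit from several initializations
  and keeps the best; exact recovery of a planted dictionary is only expected
  when the planted atoms' mutual coherence is below the OMP support-recovery
  bound 1/(2T−1).
- Ties in classification are declared at relative tolerance 1e-9.
- Training is fully deterministic given `seed`; every random draw (K-SVD
  init, projection init, generator) derives from one `numpy` Generator.

## Problem sizes used in tests and the acceptance script

Equation-level oracles run on deliberately tiny instances (m ≤ 10, K ≤ 6)
where brute-force references — central finite differences, scalar grid search,
10⁴-sample random Stiefel search, a long-run proximal solver, QR projections —
are exact and fast.  End-to-end checks use the generator defaults
(300 samples), with 5-fold stratified CV and 5 repeated 80/20 splits for the
ensemble comparison; these sizes give stable accuracy estimates at desk scale.

## Known limitations

- No minibatch or warm-restart training; each CV fold trains from scratch.
- The `"unweighted"` dictionary-gradient variant does not descend the quadratic
  weighted objective and is provided for comparison only.
- The optional MAT reader is a convenience for externally distributed feature
  sets and is not exercised by the test suite.
- Per-band sample counts must be equal (aligned trials); ragged bands are
  rejected at validation.
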