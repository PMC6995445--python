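# Methods

## Model and rationale

A functional connectivity (FC) matrix is the sample Pearson correlation of
ROI time series: after standardizing each ROI column (population 1/T
denominator for both variance and covariance, so the diagonal is exactly
one), `Q = (1/T) Σ_t (x_t − x̄)(x_t − x̄)'`. Being a Gram matrix, Q is
symmetric positive-semidefinite; the set of such matrices forms a convex
cone closed under positive combinations. Distances between FC matrices are
therefore measured two ways:

- **Geodesic distance** (affine-invariant Riemannian metric):
  `d_G(Q1, Q2) = sqrt(Σ log² λ_i)` with `λ_i` the eigenvalues of
  `Q1^{-1/2} Q2 Q1^{-1/2}`. It is a true metric (non-negative, symmetric,
  triangle inequality) and is invariant under congruence transforms
  `Q ↦ A Q A'` for invertible `A`.
- **Pearson dissimilarity**: `d_P = (1 − corr(q1, q2))/2` over the
  column-stacked matrices (diagonal included; an off-diagonal-only variant
  sits behind a flag). Bounded in [0, 1], not a metric, and degenerate in
  low dimension: the centered vectorization of any 2×2 correlation matrix
  is a positive multiple of (1, −1, −1, 1), so all such matrices are
  mutually indistinguishable.

Numerically, `Q1^{-1/2}` comes from a symmetric eigendecomposition with a
positive-definiteness check, and the inner matrix is explicitly
symmetrized before its eigendecomposition to suppress round-off asymmetry.
This eigenvalue route is equivalent to the generalized eigenproblem
`Q2 v = λ Q1 v` and was chosen for transparency. `pairwise_distances`
evaluates the same quantities with stacked (batched) eigendecompositions
over chunks of test rows; a unit test pins the batched route to the
per-pair route.

### Regularization of rank-deficient matrices

With fewer frames than ROIs the sample correlation is singular and the
geodesic distance is undefined. `regularize_database` adds `τ·I` to
*every* matrix of a comparison set whenever *any* member's minimum
eigenvalue falls below `eig_tol` (default `1e-10 ×` the largest eigenvalue
in the set), so one consistent distance function applies across all pairs
of an experiment; the applied `τ` is recorded on each matrix. The default
`τ = 1` adds the identity itself; the scale is configurable because
smaller perturbations preserve more of the original spectrum while larger
ones improve conditioning.

## Identification and inference

Identification is 1-nearest-neighbor: a test FC matrix receives the
identity of the closest training matrix; ties break to the lowest column
index with a logged warning (reproducibility over randomization). Accuracy
is the fraction of correctly labeled participants; because the assignment
of runs to train/test roles is arbitrary, both directions are computed and
averaged. Both measures are symmetric in their arguments, so the reverse
direction reuses the transposed distance matrix.

Whether a participant is identified depends on who else is in the group
(a look-alike pair hurts both members), so the group is the unit of
inference. The two-level bootstrap draws, B times, M groups of N
participants with replacement; each group's geodesic-minus-Pearson
accuracy difference is computed by *re-indexing the precomputed distance
matrices only* (cost independent of matrix dimension), and the M
differences average into one mean difference score. The B mean differences
are Fisher-z (arctanh) transformed — they are bounded scores — and tested
against zero with a two-tailed one-sample t-test. Conventions for
degenerate zero-variance inputs: all-zero values give p = 1, identical
nonzero values give p = 0, both logged. A Bonferroni reference α
(`α/k`) is exposed for reporting alongside uncorrected p-values.

Duplicate participants in a resample count with multiplicity: each copy is
a test item, and a prediction is correct when the nearest train column
belongs to the same original participant, any copy. This keeps accuracy
well-defined on multisets and consistent with treating the group as the
unit of interest.

Seed policy: one master seed; the per-mean stream b derives from
`SeedSequence((seed, b))` and draws its (M, N) index block in one C-ordered
call, so changing B leaves other means' draws untouched and growing M
extends a mean's resamples without reshuffling the prefix.

### Segment-length experiment

For each requested length, up to 50 window start indices per run are drawn
uniformly without replacement (shared by all participants so each segment
is a coherent group dataset; fewer distinct starts degrade gracefully with
a warning). Each segment's databases produce one distance-matrix pair and
a bootstrap mean accuracy over `boot_iters` group resamples; the curve
reports the mean ± SE over segments. `boot_iters = 0` is defined as "score
the segment by its plain symmetric accuracy" — the bootstrap expectation
of accuracy under resampling differs from the plain accuracy, and the
plain score is the right comparator when a single full-length segment
should reproduce the whole-run result.

## Dataset conditioning

Task runs interleave stimulus blocks with fixation; fixation behaves like
a mini resting period that leaks identity information, so only
task-related frames are kept. Per block (0-based, half-open frame ranges):
uncued blocks keep `[onset_TR + 4, offset_TR + 4)` — the first four frames
are dropped for the hemodynamic lag and four post-block frames are kept
for the lagged response; cued blocks keep
`[ceil((onset + 12 s)/TR), offset_TR + round(3 s/TR))`. Seconds convert to
frames with `ceil` at onsets (first frame at or after the time) and
`round` for the 3-second tail; per-block tails are clipped at the run end,
while a block whose own extent exceeds the run is an error. Length
equating keeps the centered window, removing the odd extra frame from the
end. All conditioning operations are pure and carry metadata through.

Subnetwork selection restricts a time series or FC matrix to the union of
named ROI groups in original ROI order; for matrices this is the principal
submatrix (all within- and between-network entries of the selected set),
which preserves PSD. The bundled 300-ROI parcellation fixture uses the
standard 7-network sizes (visual 47, somatomotor 57, dorsal attention 34,
ventral attention 34, limbic 20, frontoparietal 40, default 68), laid out
as contiguous blocks — a synthetic ordering that is irrelevant to any
principal-submatrix operation.

## Non-metric MDS

The embedding minimizes squared Kruskal stress
`S = Σ(d̂ − ‖x_i − x_j‖)² / Σ d̂²` where the disparities `d̂` are a
monotone (ties-averaged) transform of the input dissimilarities. The
optimizer alternates:

1. a SMACOF/Guttman majorization update of the configuration for fixed
   disparities, and
2. an isotonic-regression update of the disparities for the fixed
   configuration, rescaled to keep `‖d̂‖ = ‖d‖`.

Under that norm constraint the isotonic-then-rescale step is the exact
least-squares minimizer over the monotone cone intersected with the
sphere (projection onto a convex cone maximizes the correlation over the
cone), so both half-steps are provably non-increasing in S and the
recorded stress trace is monotone. Iteration stops at `max_iter`
(default 1000) or when the relative stress decrease falls below 1e-8.

The first restart initializes from classical (Torgerson) scaling — exact
when the input distances are already Euclidean, which is why embedding
exact 3-D distances recovers the configuration to numerical precision —
with a deterministic per-column sign convention; the remaining restarts
draw per-item coordinates from streams keyed on a CRC32 of the item id,
making the whole procedure equivariant under permutations of the input.
Ties in the input dissimilarities are pooled before the isotonic fit
(secondary approach), which also removes order dependence. Depending only
on rank order makes the result invariant to uniform rescaling of the
input, as befits measures with arbitrary units. Note the embedded distance
is the plain Euclidean norm, not its square, matching standard practice
for this stress function. An all-equal off-diagonal input is flagged as
degenerate (every monotone fit is constant) and returns a best-effort
configuration with a warning.

## Synthetic study generator

The generator emulates the data regime of a test-retest fingerprinting
study: N participants × C conditions × 2 runs of ROI time series whose
population correlation carries participant- and condition-specific
structure. Ground truth is a latent factor model: loadings
`L = L_base + s·L_participant + c·L_condition` with independent standard
normal entries scaled by `1/sqrt(n_factors)`, covariance
`L L' + noise_floor·I` rescaled to unit diagonal. Participant
perturbations are shared across conditions (a stable identity signature)
and condition perturbations across participants (a common task
reconfiguration). The construction is strictly positive definite by the
noise floor. Runs are i.i.d. multivariate normal draws (Cholesky
transform); an AR(1) coefficient (default 0) is available for robustness
studies and preserves the stationary spatial covariance.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `n_participants` | 100 | group size of the identification experiments |
| `n_rois` | 30 | desk-scale whole-cortex stand-in; keeps eigendecompositions cheap |
| `n_frames` | 600 | enough frames for stable FC at R = 30 |
| `subject_effect` (s) | 1.0 | strong-signal preset: identity dominates, accuracy near ceiling |
| `condition_effect` (c) | 0.2 | mild task reconfiguration |
| `n_factors` | 5 | low-rank shared structure, resembling a handful of correlated networks |
| `noise_floor` | 0.5 | bounds the spectrum well away from singularity |

`s = 0` gives every participant the same ground truth, so 1-NN
identification is at chance (exactly 1/N by exchangeability: train
matrices are i.i.d. and independent of the test matrix). The chance-level
experiment uses N = 100, R = 20, T = 200 over 1000 replicate groups —
sizes chosen so the full experiment (200,000 simulated runs) completes in
minutes on one CPU while the standard error of the mean accuracy is below
0.04 percentage points.

What the generator does *not* emulate: hemodynamics, scanner drift,
motion artifacts, heritability/family structure, or non-Gaussian
marginals. Passing tests on synthetic data therefore demonstrate the
correctness and statistical behavior of the machinery — not that real
acquisitions will reach any particular accuracy.

## Numerical choices and limitations

- FC validation tolerances: symmetry to 1e-12 relative, minimum eigenvalue
  ≥ −1e-8 (scaled by the largest entry); diagonals set to exactly 1 after
  `corrcoef`.
- Positive-definiteness threshold for the geodesic: `eig_tol` defaults to
  `1e-10 ×` the largest eigenvalue in play.
- Pearson correlations are clipped to [−1, 1] before the dissimilarity to
  absorb round-off.
- 1-NN and resampling tie-breaks: lowest index, logged.
- The bootstrap's Fisher-z is applied to the *difference* scores; an
  alternative (transforming accuracies before differencing) is available
  via `fisher_z_ttest(..., transform=False)` on pre-transformed inputs.
  Which variant a given study used is often ambiguous; the default is the
  direct reading of "transform the difference distribution".
- p-values from the t-test underflow to 0.0 for overwhelming effects;
  they are reported as computed.
- The geodesic distance requires strict positive definiteness; the package
  never silently regularizes inside a distance call — callers (or the
  higher-level experiment functions, which do it automatically for the
  geodesic measure) must opt in, so the applied τ is always visible in
  metadata.
- Other SPD geometries (Log-Euclidean, Bures–Wasserstein), tangent-space
  projection, and covariance shrinkage are out of scope by design.
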