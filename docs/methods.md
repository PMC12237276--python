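# Methods

## Model and assumptions

The pipeline treats a motor-imagery epoch purely through its spatial
covariance. The working assumptions are:

- **Second-order sufficiency.** Class information is carried by the epoch
  covariance (ERD = class-dependent variance suppression in channel groups);
  temporal waveform detail beyond the band of interest is ignored.
- **Congruence domain shift.** A subject's covariances differ from a common
  population geometry mainly by an invertible spatial mixing `A_c`:
  `M ↦ A_c M A_cᵀ`. Whitening by the subject centroid removes this shift up
  to one orthogonal rotation (see *Limitations*).
- **Two classes.** The spectrum-adaptation and SVM stages are binary; the
  multi-class extension is out of scope.

### Alignment

The affine-invariant distance is computed through the generalized
eigenvalues of `(M₂, M₁)`: `δ = sqrt(Σ log²λ_i)`. This equals
`‖log(M₁^{-1/2}M₂M₁^{-1/2})‖_F` and avoids matrix logarithms of the
non-normal product `M₁^{-1}M₂`. The Karcher mean uses the standard
fixed-point iteration

    N ← N^{1/2} exp( mean_i log(N^{-1/2} M_i N^{-1/2}) ) N^{1/2}

initialized at the arithmetic mean, declared converged when the Frobenius
norm of the mean tangent update falls below `tol = 1e-8` (cap 50 iterations;
hitting the cap raises a convergence warning that the alignment step records
in its output rather than failing). Alignment is unsupervised: the centroid
is taken over all of a subject's epochs regardless of label, before any
source/target split.

Covariances default to `X Xᵀ / T`. Alignment cancels any global scale (the
test suite verifies end-to-end prediction invariance under per-subject
amplitude scaling), so the normalization choice only conditions the Karcher
iteration. Rank-deficient epochs (`T < ch`) are an error unless shrinkage
toward `(tr(M)/ch)·I` is explicitly requested; estimation problems are never
repaired silently.

### Tangent features

Features are `upper(log Q)` at the identity reference with √2 weighting on
off-diagonals, so the feature-space Euclidean norm equals the Riemannian
distance from the reference. The identity is the natural common tangent
point *because* alignment has just moved every subject's centroid there;
this is also what makes features from different subjects comparable at all.
The unweighted variant and explicit/`set_mean` references remain selectable
for ablation.

### Kernel adaptation

All Gram matrices use one kernel family (RBF, linear, or Laplacian with the
L1 distance). The default bandwidth is `γ = 1/(d·var(X))` over the pooled
source+target features — the standard scale heuristic, since no principled
value exists a priori.

The target eigensystem keeps at most `r_max = min(n_s, n_t)` eigenpairs and
drops eigenvalues below `1e-8·λ₁` before the Nyström division
`φ̃_s = K_cross φ_t Δ_t^{-1}`. Eigenvector signs are fixed (first nonzero
component positive) for cross-platform determinism; the extrapolated columns
are deliberately not re-orthonormalized — the spectrum re-fit assumes the
raw Nyström extension.

The spectrum QP `min_σ ‖φ̃_s diag(σ) φ̃_sᵀ − K_s‖²` with the power-law cone
`σ_i ≥ μσ_{i+1} ≥ 0` expands exactly to `σᵀGσ − 2hᵀσ` with
`G_ij = (ã_iᵀã_j)²` (PSD by the Schur product theorem, ridge-stabilized by
`1e-10·I`) and `h_i = ã_iᵀK_s ã_i`. Instead of a generic QP solver the cone
is reparameterized as `σ = L t`, `t ≥ 0`, with `L` upper-triangular,
`L_ij = μ^{j-i}`; the problem becomes nonnegative least squares on the
Cholesky factor of `G` and is solved by the Lawson–Hanson NNLS with column
rescaling (the geometric growth of `μ^{j-i}` otherwise degrades
conditioning; exponents are capped at `μ^e ≤ 1e250`, which can only affect
columns whose optimal weight is zero). The transformation is exact — the
unit tests cross-check the solution against a brute-force grid search over
the feasible cone on small instances.

The union kernel stacks `Φ = [φ̃_s; φ_t]` (the target rows reuse `φ_t`) and
is PSD by construction. The SVM trains on the reconstructed source block
`K̃_s` by default (`train_on="actual"` switches to the raw `K_s`); tiny
negative eigenvalues from floating-point residue are clipped at zero before
training. The smaller of the two input labels maps to the negative class,
and a decision value of exactly zero goes to the positive class, so
predictions are deterministic and reproducible byte-for-byte.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `mu` | 1.5 | spectrum damping, `σ_i ≥ μσ_{i+1}`; ≥ 1. Larger → faster forced spectral decay, smaller feasible set, non-decreasing fit error. 1.5 is the reported sweet spot of the μ ∈ {1.0,…,5.0} sweep. |
| `eta` | 10 | SVM penalty (C); performance is nearly flat over 1–15. |
| `kernel` | rbf, `γ` auto | kernel family; the three families behave similarly on tangent features. |
| `r_max` | min(n_s, n_t) | retained eigensystem rank before the floor filter. |
| alignment space | riemannian | `log_euclidean` and `euclidean` are selectable; Riemannian and log-Euclidean behave almost identically in practice. |

## The synthetic generator

`PopulationSpec` defaults define the study conditions: 5 subjects, 8
channels, T = 512 samples/epoch, 40 epochs per class, ERD depth 0.5 in
channel pairs (0,1) vs (2,3), mixing strength ε = 0.3, no sensor noise.
Class-k covariance is the identity with the class's ERD channels' variance
multiplied by `erd_depth`; subject-c covariance is `A_c Σ_k A_cᵀ +
subject_noise·I` with `A_c = I + (ε/√ch)·G`, `G` standard normal (resampled
while the condition number exceeds 1e6). The `/√ch` normalization makes ε
the *relative action scale* of the perturbation (`E‖(A_c−I)x‖ ≈ ε‖x‖`).
Epochs are zero-mean Gaussian draws — sufficient because the pipeline
consumes only covariances.

What the generator does **not** emulate: oscillatory content and 1/f
spectra, artifacts, within-epoch nonstationarity, label noise, and
electrode-position variability that is not a linear mixing. Passing tests on
this generator therefore demonstrate the geometry and the adaptation
machinery, not performance on real EEG.

At the default conditions the task is deliberately easy (within-subject
accuracy ≈ 1.0), and ε = 0.3 is a mild shift: the cross-subject benchmark
saturates with or without alignment. The benefit of alignment becomes
visible at stronger mixing (ε ≈ 1), where the alignment-off ablation loses
roughly 15 points while the aligned pipeline stays near the within-subject
oracle; the acceptance script reports both regimes. With `erd_depth = 1`
the classes are identical and all accuracies sit at chance — the null
calibration.

Degradations: `attenuate` is a global amplitude factor — in exact arithmetic
it provably cannot change the pipeline's output, because covariances scale
by `af²` and alignment cancels any global scale (the suite asserts feature
equality to 1e-8); it exists for protocol completeness and for combination
with noise. `add_awgn` draws i.i.d. Gaussian noise with variance
`P_signal/10^(SNR/10)`; the realized SNR is within 0.1 dB of target at ≥ 1e4
samples. The band-pass is a Hamming-window FIR of the stated order (default
50) applied forward-backward, i.e. zero phase; padding is capped below the
epoch length for short epochs.

## Numerical choices

- Every eigendecomposition symmetrizes its input first; matrices whose
  smallest eigenvalue is below `1e-10·λ_max` are rejected as non-SPD.
- Equal eigenvalues keep the descending-sort order with the sign convention
  above — deterministic tie-breaks everywhere (sort order, SVM tie at 0,
  label mapping).
- All harness enumeration (task plans, sweeps) is exhaustive and ordered;
  the only stochastic element of an experiment is the synthetic data, keyed
  by a single integer seed.

## Known limitations

- **Residual rotation after alignment.** Whitening a congruence-shifted set
  by its own centroid recovers the unshifted aligned set only up to one
  orthogonal conjugation `U_c = polar(A_c N^{1/2})` shared by the subject's
  matrices. Distances are preserved exactly, but tangent features of
  different subjects are relatively rotated, which caps cross-subject
  accuracy below the within-subject oracle when the mixing is strong. This
  is intrinsic to centroid alignment, not an implementation artifact.
- The spectrum QP is convex and exactly solved, but its benefit depends on
  the Nyström extension quality; with very small target sets the retained
  rank (and hence the adapted kernel) is crude.
- Binary classification only; no probability calibration; no reader for
  vendor EEG formats (the container + generator are the supported inputs).
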