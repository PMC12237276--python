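# farka

Cross-subject motor-imagery EEG classification by Riemannian covariance
alignment and spectral kernel adaptation.

## The problem

Motor-imagery brain–computer interfaces classify imagined movements from
multichannel EEG. The discriminative signal is event-related
desynchronization (ERD): class-dependent suppression of mu/beta band power in
specific channel groups, which lives in the *spatial covariance* of each
epoch. Covariance matrices are symmetric positive-definite (SPD) and sit on a
Riemannian manifold, and classifiers built on that geometry work well *within*
a subject — but every subject's electrode coupling acts like a different
invertible spatial mixing, so a classifier trained on one person degrades
badly on another. `farka` is for researchers who need a calibration-free
(target-unlabelled) cross-subject pipeline and a controlled synthetic
test bed for it.

## The method

For subject *c* with epochs `x ∈ R^(ch×T)` and per-epoch covariances
`M_i`:

1. **Riemannian alignment (RA).** Compute the subject's centroid `N` (Karcher
   mean under the affine-invariant metric
   `δ(M₁,M₂) = ‖log(M₁^{-1/2} M₂ M₁^{-1/2})‖_F`, or the log-Euclidean /
   Euclidean mean) and whiten: `Q_i = N^{-1/2} M_i N^{-1/2}`. Every subject's
   centroid moves to the identity, removing most of the subject-specific
   mixing — unsupervised, no labels needed.
2. **Tangent-space features (RTS).** `F_i = upper(log Q_i)` with the
   off-diagonal entries weighted by √2, so `‖F_i‖₂ = δ(I, Q_i)`. Dimension
   `ch(ch+1)/2`.
3. **Knowledge kernel adaptation (KKA).** With kernel `k` (RBF, linear, or
   Laplacian), eigendecompose the target kernel `K_t φ_t = φ_t Δ_t`,
   extrapolate the eigenvectors to the labelled source rows by the Nyström
   formula `φ̃_s = K_cross φ_t Δ_t^{-1}`, then re-fit the spectrum by the
   convex QP

       min_σ ‖φ̃_s diag(σ) φ̃_sᵀ − K_s‖_F²   s.t.  σ_i ≥ μ σ_{i+1} ≥ 0,  μ ≥ 1,

   and assemble the field-agnostic kernel `K̃_{s∪t} = Φ diag(σ*) Φᵀ`,
   `Φ = [φ̃_s; φ_t]` — PSD by construction.
4. **Precomputed-kernel SVM.** Train on the reconstructed source block with
   penalty `η`; predict the target field from the target×source cross block:
   `ŷ_t = sign(K_ts (θ·y_s) + b)`.

Evaluation follows the standard cross-subject protocols: **M2S**
(leave-one-subject-out, C tasks) and **S2S** (all C(C−1) ordered pairs), with
mean task accuracy as the metric.

The synthetic generator draws zero-mean Gaussian epochs whose class
covariances carry ERD-style variance suppression in disjoint channel groups,
with per-subject invertible mixing `A_c = I + (ε/√ch)·G` as the domain shift,
plus degradation operators (amplitude attenuation, AWGN at a target SNR, and
the 8–30 Hz zero-phase FIR band-pass).

## Worked example

```python
from farka import PopulationSpec, make_population, plan_tasks, run_plan

# five synthetic subjects whose only difference is a strong spatial mixing
spec = PopulationSpec(subject_mixing_strength=1.0, seed=1)
population = make_population(spec)

plan = plan_tasks([e.subject_id for e in population], "m2s")
aligned = run_plan(population, plan)                      # full pipeline
ablated = run_plan(population, plan, align_space=None)    # alignment off

for key, acc in aligned.task_accuracies.items():
    print(f"{key}: {acc:.3f}")
print(f"mean accuracy, Riemannian alignment: {aligned.mean_accuracy:.3f}")
print(f"mean accuracy, alignment disabled:   {ablated.mean_accuracy:.3f}")
```

Output:

```
S02+S03+S04+S05->S01: 1.000
S01+S03+S04+S05->S02: 1.000
S01+S02+S04+S05->S03: 1.000
S01+S02+S03+S05->S04: 1.000
S01+S02+S03+S04->S05: 1.000
mean accuracy, Riemannian alignment: 1.000
mean accuracy, alignment disabled:   0.785
```

Each line is one leave-one-subject-out task (pooled sources → target) with
its target-field accuracy. Under a strong congruence shift the aligned
pipeline recovers perfect transfer on this draw, while the same pipeline
without the whitening step loses ~21 points. Draws vary: over many seeds the
aligned variant wins by ~15 points on average, with occasional reversals on
individual populations.

The same experiments run from the shell:

```bash
farka simulate --spec spec.toml --out data/
farka run --data data/ --mode m2s --align riemannian --kernel rbf \
          --mu 1.5 --eta 10 --out report.json
farka sweep --data data/ --mode m2s --param mu --grid 1.0:5.0:0.5 --out sweep.json
farka degrade --data data/ --snr-db 10 --seed 1 --out data_noisy/
```

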