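# Methods

## Problem and model

The package classifies ovarian-cancer subtype — high-grade serous
carcinoma (HGSOC, label 1) versus clear cell carcinoma (OCCC, label 0)
— from paired pre-operative MRI sequences: contrast-enhanced
T1-weighted imaging (T1+C) and T2-weighted imaging (T2WI). The two
sequences carry complementary information (vascularity and boundary in
T1+C; cystic/solid composition in T2WI), which motivates a
multi-sequence fusion architecture:

1. **Per-sequence feature extraction.** Each sequence j of patient i
   yields a 2D slice image x_ij; an independent MBConv feature
   extractor Feat_j (one per sequence, weights not shared) produces
   f_ij = Feat_j(x_ij). The extractor follows the EfficientNet-B2
   stage layout: a 3×3 stem convolution and seven MBConv stages
   (mobile inverted bottleneck with expansion factor 1 or 6, depthwise
   kernels 3 or 5, squeeze-excitation ratio 0.25, SiLU activations,
   batch normalization), with per-stage channels
   32, 16, 24, 48, 88, 120, 208, 352 and layer counts
   1, 2, 3, 3, 4, 4, 5, 2, followed by a 1×1 projection to a 1408-wide
   head and global average pooling. A strict-table mode pools the
   352-channel final stage directly (`head_width=352`), since the
   printed stage table omits the projection; both are available.
   Compound-scaled variants B0–B4 are generated from the B0 base via
   the standard width rounding (divisor 8) and depth ceiling rules.
2. **Late fusion.** f_i = Concat([f_i1, f_i2]) by default; element-wise
   Add is the alternative (equal dims required).
3. **Per-branch classification.** One fully connected layer per branch
   maps features to a logit s_i; σ(s_i) is the class-1 probability.
   Branches T1, T2, and fused each predict, so a patient missing a
   sequence still gets predictions from the available branches; the
   fused branch exists only when all configured sequences are present.

**Loss.** Each branch contributes a mean binary cross-entropy on
logits (the numerically stable form max(s,0) − s·y + log(1+e^−|s|)),
and the training loss is the plain sum L = L_ALL + L_T1 + L_T2 —
auxiliary deep supervision of the single-sequence branches alongside
the fused head. Branches with no data in a batch contribute 0.

**Imbalance handling.** Weighted random sampling with replacement,
weight 1/N_c for class c computed on the training partition, making
the expected class mix 1:1 per epoch regardless of the cohort ratio.

**Schedule and optimizer.** AdamW (β = 0.9/0.999, decoupled weight
decay 1e-4 applied to convolution/linear weights only — biases and
normalization parameters are excluded, the conventional rule, since
the source description of the decay scope is ambiguous). The learning
rate is base_lr × m(epoch) with 1-based epochs:
m = epoch/warmup for epoch ≤ warmup (exactly 1 at the warm-up
boundary) and m = 0.5·[cos(π·(epoch−warmup)/(num_epoch−warmup)) + 1]
afterwards, reaching 0 at the final epoch. Reference protocol:
base_lr 0.001, warm-up 25, 100 epochs, batch 32.

**Numerical core.** No deep-learning framework is declared as a
dependency; the network, its gradients, and AdamW are implemented in
`mrifusion.nn`, a compact reverse-mode automatic-differentiation
engine over numpy arrays (convolutions via sliding-window views and
einsum; batch-norm backward in closed form). Gradients of every
primitive are finite-difference tested. Weights initialize He-fan-out
(convs) / uniform-fan-in (linear); a pretrained-initialization flag
exists but requires a local weights file.

## Preprocessing and registration

All volumes are NIfTI; a cohort is a CSV manifest (patient_id, label,
t1_path, t2_path — empty path ⇒ missing sequence, retained). One
patient's T1 is drawn uniformly (seeded) as the template; other T1s
register to it with a Pearson-correlation objective and each T2
cross-modally with mutual information. The transform model is rigid
(6 DOF, Euler angles + translation about the volume center), suitable
for same-patient alignment. Optimization is multi-resolution
(SimpleITK: 3-level pyramid, shrink ×4/×2/×1, Gaussian smoothing
2/1/0 mm, regular-step gradient descent, ≤60 iterations/level, step
tolerance 1e-3). The correlation metric is evaluated densely; Mattes
MI uses 64 histogram bins and a fixed 30% regular sampling lattice —
chosen because the MI surface of smooth anatomies needs fine intensity
binning for a sharp peak, while a deterministic sample lattice keeps
cost low. Reported similarity values (`RegistrationResult`) are
recomputed by the package's own NCC (Pearson) and MI (joint-histogram,
nats, equal-width bins; equal-count optional) over the in-field
overlap region, so out-of-field zero fill never distorts them; if
optimization fails to improve that similarity, the centered initial
transform is returned, making "final ≥ initial" an invariant.
Resampling is trilinear with zero fill.

**Slice selection.** Model inputs are 2D axial slices (third array
axis, pelvic convention; configurable): `central` takes the lower
median slice; `top_k_mean` takes the k highest-variance slices
(default 3, ascending order). The source protocol does not state its
slice choice, so it is a configuration rather than a constant.
Patient-level score = mean of slice probabilities. Slices are z-scored
and replicated to 3 channels.

## Augmentation

Six operations in fixed order — center crop (fraction 0.85), scale
(0.9–1.1), horizontal flip, Gaussian noise (σ = 2% of the image
range), Gaussian smoothing (σ = 0.5–1.0 px), contrast about the mean
(0.8–1.2) — each gated independently at p = 0.3 per sample
(per-operation draws; geometric ops precede intensity ops). The output
is resized to the model resolution. Magnitudes are package defaults;
the source states only the gate probability. All six gate draws are
consumed unconditionally so the random stream does not depend on which
ops fire. Augmentation applies only in training mode; the evaluation
path never augments.

## Cohort splitting

Stratified train/validation/test at 198:50:63 proportions scaled to
the cohort (the reference protocol's exact sizes at n=311), then
k-fold (default 5) re-partitions of train+validation with the test set
fixed across folds. A `--resplit`-style full re-draw is available via
a different seed. The published cohort counts disagree internally; the
198/50/63 division is used throughout.

## Evaluation

AUC is the trapezoidal ROC area (ties half-credit — identical to the
Mann–Whitney pair-counting estimator); AP is step-interpolated
Σ(R_k−R_{k−1})P_k. Both are cross-checked in the test suite against
brute-force oracles to 1e-12. Threshold metrics (ACC/SEN/SPEC/F1) use
probability ≥ 0.5 ⇒ positive, positive class HGSOC. Fold aggregation
reports means with both population (÷n) and sample (÷(n−1)) standard
deviations, because the published ±0.0226 AUC deviation matches
neither convention exactly when recomputed from the printed per-fold
values (≈0.0238 and ≈0.0266); the means reproduce exactly at 4
decimal places and are the quantities the package asserts.

## Synthetic phantom cohorts

The clinical cohort is private, so a generator provides phantoms with
the statistical structure the method assumes. Each patient shares one
closed-form anatomy: a linear background ramp (40–80), a few random
Gaussian blobs (±20, σ 4–10 voxels), and an ellipsoidal lesion
(in-plane radii 8–14 voxels, axial 4–7; core contrast +60, rim +30) at
a random in-field position. Default grid 64×64×24 voxels at
1×1×3 mm. The class signal is split **complementarily**: class 1
raises the T1 rim by effect_t1·σ_noise and the T2 core by
effect_t2·σ_noise, where the T2 volume is a fixed monotone remap
(30·exp(v/80)) of the shared anatomy — so each modality carries only
its own share of the signal and fusion is required to see both.
Defaults: effects 3σ, noise σ=10 (≈Rician-free additive Gaussian),
T2 misalignment up to 3 voxels/3°. Misaligned or perturbed copies are
rendered analytically at transformed coordinates, so registration
fixtures have exact ground truth with no interpolation error or
out-of-field band. Generation is byte-reproducible per seed
(per-patient child streams of a SeedSequence).

What the phantoms do **not** emulate: MR physics (no Bloch equations,
bias fields, coil profiles, Rician noise), anatomical texture,
lesion-shape irregularity, or scanner/site variation. Passing the
synthetic suites therefore demonstrates that the pipeline's machinery
(alignment, complementary-feature fusion, imbalance handling,
optimization) behaves as designed — not that clinical-level accuracy
transfers to real cohorts.

## Desk-scale experiment sizes

CPU-friendly problem sizes are used for the end-to-end checks, chosen
as the package's own scaled-down protocol: cohort n=120 at the
reference class ratio (212:99), 96×96 slices, a reduced four-stage
MBConv extractor (stem 8 channels → 8/16/24/32, 64-wide head,
~48k parameters per branch), 3 slices per patient (`top_k_mean`),
10 epochs with warm-up 3 (preserving the 1:4 warm-up ratio of the
100-epoch reference schedule), batch 32. Registration checks use
64³ isotropic phantoms with perturbations up to 8 voxels and 10°.
Full-size B2 training is available through the same configs.

## Design choices on open points

- Eq. for the branch loss is implemented as the standard negative
  log-likelihood (the printed form lacks the minus sign but names
  binary cross-entropy).
- 224×224 input resolution is the default for every variant because
  that is the printed stage-1 resolution (standard B2 would use 260);
  configurable.
- Stride placement (stem 2, then 1,2,2,2,1,2,1) follows the reference
  MBConv design; the printed per-stage resolutions are consistent with
  it.
- Rigid (not affine/deformable) registration by default; affine would
  add DOF without a same-patient justification.
- Classification threshold fixed at 0.5; the source does not state one.

## Known limitations

- Training on CPU with the numpy engine is practical only at reduced
  scale; full 224×224 B2 training is supported but slow.
- No pretrained initialization is bundled; transfer learning requires
  supplying weights.
- MI registration uses a fixed sampling lattice; pathological phantoms
  with periodic structure could alias, though none of the generated
  anatomies do.
- Bootstrap confidence intervals, calibration, and significance tests
  are out of scope.
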