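# Methods

This note documents the models, the synthetic data, the evaluation
protocols and the numerical choices behind `lorentznet`, in the spirit of
a methods appendix: enough detail to re-derive every computed quantity.

## 1. Geometry

The hyperbolic space of curvature `-k` (`k > 0`) is realised as the upper
sheet of the hyperboloid `H^d_k = {x ∈ R^{d+1} : ⟨x,x⟩_L = -1/k, x₀ > 0}`
under the Lorentz bilinear form `⟨x,y⟩_L = -x₀y₀ + Σ_{i≥1} xᵢyᵢ`
(time-coordinate-first convention everywhere).  Implemented operations:
inner product, exponential/logarithm maps at the origin, geodesic
distance, projection (recompute `x₀` from the space components), tangent
feature clipping, and — for the optimizer — the Euclidean→Riemannian
gradient conversion `proj_x(J g) = J g + k⟨x, J g⟩_L x` plus the exp-map
retraction at arbitrary points.

Numerical choices, each motivated by the fact that instability is the
known failure mode of hyperbolic classifiers:

* geodesic distance is computed as `d = (2/√k) asinh(√(k·s)/2)` with
  `s = max(⟨x-y, x-y⟩_L, 0)`, the stable equivalent of
  `(1/√k) arccosh(-k⟨x,y⟩_L)` floored at 1 — exact zero for identical
  points, no cancellation for nearby ones;
* `sinh(t)/t` takes a Taylor branch (`1 + t²/6`) below `t = 10⁻⁶`;
* learnable curvature is stored as `log k`, so gradient steps cannot leave
  the positive domain;
* on-manifold checks measure the constraint residual relative to `k·x₀²`,
  the scale at which float64 cancellation makes a stricter absolute check
  unsatisfiable far from the origin.

## 2. Models

Both classifiers share a residual convolutional encoder ending in a
linear map to `R^n`, `n` = number of classes (embedding dimension defaults
to the class count; configurable).  Two encoder scales exist: the standard
4-stage basic-block residual network (widths 64–512), and a `tiny` scale
(3×3 stem, one width-16 stage, one stride-2 width-32 stage, global average
pool) whose training completes in seconds on one CPU and which all
desk-scale experiments use.  Inputs are 1-channel images, 64×64 by default
and 16×16 in the desk-scale study.

Heads:

* **Euclidean**: `logits = W z + b`, `W ∈ R^{n×d}`, `b ∈ R^n` —
  `n(d+1)` parameters.
* **Lorentz**: clip `z` to norm ≤ `r` (`r = 1.0`), exp-map to the
  hyperboloid, then score each class by the signed hyperbolic distance to
  a learnable hyperplane.  The hyperplane normal is parameterised
  `w_c = (‖z_c‖ tanh r_c, z_c)` from a direction `z_c ∈ R^d` and offset
  `r_c ∈ R`; the `tanh` form keeps `w_c` spacelike for any real offset, so
  all head parameters are unconstrained ("Euclidean reparameterisation"),
  and the logit is `(1/√k) asinh(√k ⟨w_c,x⟩_L / ‖w_c‖_L)` — again
  `n(d+1)` parameters, plus the single curvature scalar.

Hence the Lorentz variant exceeds its Euclidean twin by exactly one
trainable parameter at every configuration; the suite asserts this
invariant rather than any absolute parameter count.  With clipping at 1.0
the forward pass is finite for inputs up to 10⁴ in magnitude.

The deep-learning substrate is a purpose-built reverse-mode autodiff
engine over float64 numpy (`lorentznet.autodiff`): broadcasting
arithmetic, matmul, reductions, elementwise transcendentals, im2col
convolution, max-pooling and a fused log-sum-exp.  Every operator is
finite-difference-checked in the test suite; end-to-end input gradients
(needed for PGD) agree with finite differences to ~10⁻⁸ relative.

## 3. Training

Cross-entropy, SGD with momentum 0.9, cosine learning-rate decay.
Parameters attached to the manifold (points on the hyperboloid) take
Riemannian steps — metric-corrected gradient, exp-map retraction, no
momentum buffer (transport is out of scope); in the default models every
parameter is an unconstrained reparameterisation, so the Riemannian branch
is exercised by dedicated optimizer tests.  Two stability-relevant
choices:

* the curvature trains with a 10× damped step (`lr_scale = 0.1`);
  undamped, `k` inflates by two orders of magnitude — raising the logit
  scale is the cheapest way to increase confidence — and training then
  collapses;
* the hyperbolic head converges noticeably slower than the affine head at
  equal hyperparameters; the experiment config exposes this as a
  per-geometry epoch multiplier (default: Lorentz trains 2× the epochs).

Augmentation: per-dataset normalisation (mean/sd computed from the
training split, never hard-coded), random rotation within ±10°, horizontal
flip with probability 0.5.  All randomness flows through explicit numpy
generators; a fixed seed reproduces the loss curve bit for bit.  Splits
are stratified 80/10/10 by class, seeded, recorded in the manifest.

## 4. Synthetic data

The generator emulates the statistical structure the analysis assumes: a
known class tree with visual similarity decaying with tree distance.

* Taxonomy: balanced tree over named levels (modality, category, disease,
  subtype, …); descriptor strings encode the ancestor path, so two classes
  share a level value iff they share that ancestor.
* Prototypes: for each level-`l` ancestor a random spatial pattern with
  amplitude `0.5^l` (geometric decay: modality separates images far more
  than subtype), plus a leaf-unique pattern one decay step further.
  Patterns are Gaussian-filtered white noise (correlation length H/8),
  mirror-symmetrised about the vertical midline and normalised to unit
  pixel variance — anatomy is smooth and roughly bilaterally symmetric,
  and this also makes the rotation/flip augmentations label-preserving,
  which pixel-white-noise patterns would not be.
* Images: prototype + N(0, 1) pixel noise, affinely mapped to gray values
  (`0.5 + 0.15·raw`) and clipped to [0, 1].
* Zero-shot cohorts: ordered per-patient slice stacks; negative patients
  draw every slice from the trained normal class (class 0), positive
  patients carry ≥ 1 slice of an *unseen* disease — the normal prototype
  plus a localized Gaussian bump (σ = H/6, amplitude 2.5× the noise sd) at
  a random location, subtle enough that detection is imperfect.  Patient
  truth is the OR of slice truths.
* Out-of-sample cohort: one image per subject, `n_positive` from a trained
  disease class, the rest from the normal class (e.g. 436 subjects with
  40/396 positive/negative).

What the generator does **not** emulate: real acquisition physics,
intensity distributions of CT/MRI, anatomy, class imbalance, scanner or
site effects.  Passing the replication suite therefore shows that the
*pipeline* recovers a known hierarchy under controlled conditions — it is
evidence about the method, not about any clinical dataset.

## 5. Evaluation protocols

**Hierarchy alignment.**  Per-class centroids are arithmetic means of the
stored embeddings — raw encoder outputs for the Euclidean model; post-clip
tangent features for the Lorentz model, averaged in the tangent space and
exp-mapped for distance computation (a Karcher-mean option exists; the
tangent mean is the deterministic default).  Centroids are computed over
**all** images of the dataset, matching a protocol that averages every
image of a class.  Distances: pairwise L2 (Euclidean) or geodesic at the
trained curvature (Lorentz).  The ground-truth matrix scores a class pair
by the weighted count of differing descriptor levels, weights descending
coarse→fine (`L, L-1, …, 1`; configurable).  Both matrices are normalised
by their maximum off-diagonal entry.  Statistics over the strict upper
triangle: mean absolute difference with a seeded percentile bootstrap over
class-pair entries (n = 1000), tie-corrected Spearman rank correlation,
and a Welch two-sample t-test when contrasting two models' per-pair
deviation vectors.  Dendrograms use average-linkage agglomerative
clustering on the model distance matrix.

**Adversarial robustness.**  PGD: iterated sign-gradient ascent on the
cross-entropy, step `ε/4`, 20 iterations, random start in the budget ball,
projection onto the sup-norm ε-ball and the valid pixel range after every
step.  `ε = 0` is the identity (clean row of a sweep).  Budgets are
specified on the raw [0, 1] pixel scale — the convention of the
adversarial literature — and converted to the model's normalised input
scale internally; both published presets ship (coarse 0.03/0.06/0.12,
fine 0.003/0.006/0.012), the sweep being entirely config-driven.  On the
desk-scale models the coarse preset is the interesting regime — Top-1
drops steeply already at the smallest ε — while the fine preset barely
perturbs them.

**Out-of-sample / zero-shot rules.**  A class→outcome mapping (disjoint
positive and negative class-id sets) converts multi-class predictions to
binary calls; unmapped predictions count as errors by default (an
`exclude` policy exists).  Image-level zero-shot accuracy is
`(TP + TN)/N`; patient-level identification requires ≥ 1 truth-positive
slice predicted positive, with rates displayed to two decimals.
Bootstrap CIs (percentile, n = 1000, seeded) resample subjects/patients
for cohort metrics and images for image metrics.

## 6. The desk-scale replication study

`directional_study` runs, per seed: a fresh 12-class dataset (3-level
taxonomy, branching 3×2×2, 60 images/class, 16×16 pixels), both geometries
trained from a shared encoder initialisation (15 epochs Euclidean / 30
Lorentz, lr 0.05, batch 64), then validation Top-1/Top-5, hierarchy MAD
and Spearman rho against the generative taxonomy, and robust Top-1 at the
middle epsilon (0.06) of the coarse preset on a 48-image validation
subset.  Ten seeds give the win counts the acceptance suite asserts.  The
problem sizes are the package's desk-scale operating point: large enough
that both models exceed 90% validation Top-1 and the attack meaningfully
degrades them, small enough that the whole study runs in minutes on one
CPU.

## 7. Known limitations

* The full residual-network encoder scale is implemented and parameter-
  audited but not exercised in multi-epoch training by the test suite —
  float64 numpy on one CPU makes that a minutes-per-epoch proposition.
* Fully hyperbolic convolutions are deliberately out of scope; only the
  hybrid (Euclidean encoder, hyperbolic decoder) architecture exists.
* The Lorentz decoder's exact published parameterisation is not printed in
  the source material; the signed-distance form used here is the standard
  one from the hyperbolic-NN literature and reproduces the +1 parameter
  accounting exactly.
* Momentum is not parallel-transported for manifold-valued parameters.
* Bootstrap units (class pairs; patients; images) are stated per metric;
  alternatives (e.g. class-level resampling) would widen the MAD CI.
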