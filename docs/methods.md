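# Methods

This note documents the models implemented in `dermcrf`, the choices
made where the design was genuinely open, the synthetic data the package
is validated on, and the limits of what that validation shows.

## Problem setting

Both models address supervised pixel labeling: given training images
x^m with per-pixel ground-truth label fields y^m over a label set
L = {l_1, …, l_{N_L}}, learn a predictor of label fields for unseen
images.  The package implements the binary segmentation instance
(lesion = 1, skin = 0) end to end; types permit N_L > 2, but exact CRF
inference is deliberately restricted to the binary case (see
Limitations).

## Features

- sRGB → CIE L\*a\*b\* under the D65 white point with standard sRGB
  gamma (`skimage.color.rgb2lab`).  The choice of white point is the de
  facto standard for uncalibrated consumer imagery.
- Exposure compensation: the L\* channel is zero-meaned per image
  (`normalize_lstar`), after Lab conversion and before filtering.  A
  global lightness offset between images then has no effect on any
  feature.  The operation is idempotent and leaves a\*, b\* untouched.
- Filter bank: for each of the 3 channels and each scale
  σ ∈ (1.25, 2.5, 5, 10, 20), one Gaussian-smoothed response and one
  Laplacian-of-Gaussian response — 30 channels.  Kernels are truncated
  at 4σ (residual mass < 1e−4) with reflective boundary handling, which
  avoids dark-border artifacts near image edges.  The truncated sampled
  LoG kernel has a small nonzero DC gain; it is subtracted so constant
  images produce exactly zero LoG response (this also makes every LoG
  channel exactly invariant to global L\* offsets).  Scale-normalized
  LoG (σ²∇²G) is available behind `log_scale_normalized` but off by
  default.
- Pixel indexing is row-major and 0-based everywhere; feature rows,
  label fields and masks share the convention.

## Per-pixel model

LDA solves the generalized symmetric eigenproblem S_b q = λ S_w q
rather than inverting S_w; both scatter matrices are *unweighted* sums
over classes (sum of per-class ML covariances, sum of mean-deviation
outer products).  When cond(S_w) > 1e10 a shrinkage ridge
λ = 1e−6 · tr(S_w)/N_C is added with a warning — with 30 strongly
correlated filter channels this is the normal case, not an anomaly.
Eigenvector signs are fixed deterministically (largest-magnitude
component positive).

Class-conditional Gaussians use the ML covariance estimator (divide by
N), matching the generative model; near-singular covariances are
ridge-regularized with a warning.  The prior pools pixel counts across
all training images without per-image reweighting.  All densities are
evaluated in log space with Cholesky factorizations and normalized by
log-sum-exp, so likelihood-map rows sum to 1 even under severe
underflow.  Argmax ties break toward the lowest label index.

## CRF

The energy is a weighted sum of feature totals over a 4-connected grid:
node features accumulate per-pixel label costs; edge features accumulate
a nonnegative cost on each edge whose endpoint labels differ.  The
standard instance has one of each: node cost 1 − ℒ_{i,y_i} and edge
cost |L\*(x_i) − L\*(x_j)|.  The cost form of the node feature (rather
than summing likelihoods into a minimized energy) is what makes
w = [1, 0] reproduce the per-pixel MAP exactly; the edge feature uses
the normalized L\* channel, which is equivalent to raw L\* because
differences cancel the offset.

**Inference.** For binary labels with nonnegative edge costs the energy
is submodular and the exact MAP labeling is a minimum s-t cut.  The cut
is computed by a Dinic max-flow solver (numba-compiled) operating
directly on float64 capacities, so the optimum is exact up to float
arithmetic — no integer scaling.  Dinic's phase bound depends only on
the graph, not on capacity values, so float capacities are safe.  When
every effective edge cost is zero the solver short-circuits to the
per-pixel argmin with lowest-index tie-breaking, keeping the w = [1, 0]
fixed point exact including ties.  Any global minimizer is acceptable
where ties exist; tests compare energies, not labelings.  Edge weights
may be 0 at inference (still submodular); strict positivity is enforced
during training.

**Oracles.** `brute_force_inference`, `partition_function` and
`label_probability` enumerate all N_L^{N_P} labelings (refusing above
2^20 states) in vectorized log-space arithmetic.  They exist to pin the
scalable path: min-cut energies match enumeration on 1000 random
instances to 1e−9, and Σ_y P(y|x;w) = 1 on every tiny instance tested.

## Weight learning

Sign convention: P(y|x;w) ∝ exp(−E), so the regularized objective is
ℓ(w) = Σ_m [−E(y^m) − ln Z(x^m)] − ‖w‖²/2σ² and its gradient is
∂ℓ/∂w_k = Σ_m (E_P[Φ_k] − Φ_k(y^m)) − w_k/σ².  The convention is
validated operationally: the exact gradient matches central finite
differences of ℓ to ~1e−10 relative error on random tiny instances.
The saddle-point approximation (SPA) replaces E_P[Φ_k] with Φ_k(y\*),
the feature totals of the MAP labeling; its error vanishes as the
distribution concentrates (verified on instances whose MAP carries
> 99.9 % of the mass, where the disagreement drops below 0.1 %).

Training is projected gradient ascent.  Steps are scaled per feature by
the mean ground-truth feature total (floored at 1), so γ is meaningful
across features whose totals differ by orders of magnitude; after every
step edge weights are clipped to the floor 1e−8.  Convergence is
declared when the scaled gradient norm drops below ε.  Because SPA
updates oscillate, the best-scoring iterate is returned: scored by exact
ℓ when all instances are enumerable, otherwise by the SPA surrogate
Σ_m [E(y\*) − E(y^m)] − ‖w‖²/2σ² (the same approximation applied to
ln Z).  Defaults: w⁰ = [1, 0.1], σ² = 10, γ = 1e−3, ε = 1e−4,
N_itr = 200; training quality is insensitive to these within broad
ranges, consistent with the regularizer having little effect between
σ² = 1e−6 and ∞.

Maximum-likelihood identifiability: on data *sampled* from a CRF with
known weights (3×3 grids, exact sampling by enumeration), exact-gradient
training recovers the weight direction to within ~5–8 % from 50
instances.

## Synthetic data

The generator emulates the statistical structure the models assume
about dermoscopy: a darker, roughly elliptical lesion on lighter skin;
additive per-channel Gaussian sensor noise; a global per-image L\*
exposure offset (uncalibrated acquisition); an optionally
Gaussian-softened color transition at the lesion boundary (default
1 px), emulating low-contrast lesions; and thin dark anti-aliased
polyline streaks standing in for occluding hair.  The ground-truth mask
is the analytic ellipse membership and is never altered by noise,
exposure or hair.  Defaults: 64×64 frames, skin sRGB (0.80, 0.60, 0.52),
lesion (0.36, 0.22, 0.18) — a typical light skin tone and dark
pigmented lesion — noise sd 0.01–0.03, offsets ±10 L\*, 0–3 hairs.
Identical spec + seed reproduces identical bytes.

What it does **not** emulate: pigment-network and other dermoscopic
textures, vignetting, specular reflections, color casts or nonlinear
camera response, hair crossing densities of real scalp images, or the
irregular boundaries of real lesions.  Passing the validation suite
therefore demonstrates internal consistency of the models and their
estimators under the stated assumptions — not clinical segmentation
performance.  Published sensitivities/specificities on real atlas
datasets are not reproducible here and are not claimed.

## Validation study design and problem sizes

The validation suite and `scripts/acceptance.py` use deliberately
desk-scale problems: 32×32 scenes for cross-validation runs (40 images,
10-fold, CRF iteration cap 30), 48×48 scenes for the normalization
study, tiny (≤ 4×4) instances wherever enumeration oracles are involved,
1000 instances for the inference-exactness check, and 100 for the
gradient check.  These sizes are the package's own choices for fast,
repeatable runs; every experiment is a function in
`dermcrf.experiments` and scales up by argument.

The exposure-normalization study deserves a note.  With a purely
additive L\* offset and the 30-channel bank, supervised LDA can learn an
almost exactly offset-invariant discriminant whenever chroma or
boundary channels carry class signal, which makes normalization nearly
redundant — an interesting property of learned dimensionality reduction.
The study therefore probes the regime the compensation exists for: a
chroma-matched lesion (the skin color darkened by 12 L\* with identical
a\*, b\*), large interior-dominated lesions, and offsets of ±20 L\*, so
the class signal lives in absolute lightness and cannot be recovered by
an invariant projection.  There the normalized model's sensitivity at
matched specificity is systematically higher.

## Numerical choices and degenerate inputs

- Likelihood maps: all-underflow rows are handled by log-sum-exp;
  rows always sum to 1 within 1e−9.
- Ties: per-pixel argmax → lowest label index; brute-force enumeration
  → lexicographically smallest labeling; min-cut → any optimal cut.
- Degenerate classes: a label absent from training data raises; < 2
  samples for a covariance raises; a constant-valued class receives the
  regularization floor.
- Thresholds outside [0, 1], nonpositive σ², γ, grid dimensions or
  ellipse axes, and unknown config keys all raise immediately.
- Training aborts with the partial trace flagged if weights go
  non-finite.

## Limitations

- Multi-label (N_L > 2) MAP inference is intentionally not implemented;
  the exactness guarantee is binary-submodular.  α-expansion-style
  approximations are out of scope.
- ln Z is exact only on enumerable grids; at scale only the SPA
  surrogate of the objective is available, so "best iterate" selection
  at scale inherits SPA's bias.
- The evaluation harness micro-averages pixel counts across images;
  per-image macro-averaging is available via the per-image prediction
  lists but is not the default.
- Pixel-wise sensitivity/specificity is insensitive to boundary
  quality; no boundary-aware metric is provided.
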