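# Methods

This note records the models implemented in `waidkit`, the choices made
where the constructions are under-determined, the defaults and why, and
what the synthetic data can and cannot establish.

## Pixel features and the region covariance block

Each pixel of an 8-bit RGB patch contributes
f = [R, G, B, Gr^x, Gr^y]ᵀ with color divided by 255 and gradients
computed on the luminance (BT.601 weights 0.299/0.587/0.114) by 3×3
Sobel correlation with replicate padding. Two choices here are genuine
design decisions rather than forced by the construction:

* **Gradient operator.** Any first-order operator would do; the Sobel
  stencil is the long-standing default in the region-covariance
  literature and its 3×3 support sets the minimum patch size. The
  stencil is exposed as a module constant so a hand-applied check is
  well defined.
* **Luminance vs. per-channel gradients.** Gradients are computed on
  the luminance only, keeping the feature dimension at 5; color
  variation is already captured by the three intensity columns and the
  histogram block. Computing gradients on the normalized image keeps
  their magnitude O(1), commensurate with the color columns, so no
  column dominates the covariance.

The covariance uses the unbiased 1/(N−1) normalization and therefore
requires N ≥ 2 pixels; a constant patch gives the zero matrix, which is
legal (the ε-perturbation below restores definiteness).

## Histograms and the kernel block

Channel histograms use `bins` equal-width bins on [0, 255] (default
256, where each 8-bit value maps to its own bin). Each channel row is
normalized to unit sum *before* concatenation, so H's rows are
probability vectors — a requirement for the χ²/Jensen-Shannon kernels —
and the concatenated color histogram sums to 3. The kernel block
defaults to the linear kernel K = H Hᵀ; χ², RBF and polynomial kernels
are available behind the same interface and all yield symmetric PSD
3×3 matrices.

## CKD assembly and ε

The descriptor is blockdiag(C + εI₅, K + εI₃). Both blocks are PSD, so
any ε > 0 makes the assembly strictly positive definite (its spectrum
is the union of the two block spectra). The default is trace-scaled,
ε = 10⁻⁶ · max(1, tr(C)/5): an absolute 10⁻⁶ can drown in round-off for
high-variance patches, while scaling by the mean diagonal keeps the
perturbation a fixed six orders below the signal. Degenerate
single-color patches are allowed — they produce C = 0 and rely on ε.

## SPD geometry

The matrix logarithm is computed by eigendecomposition
U diag(log λ) Uᵀ and symmetrized; inputs are validated (relative
symmetry tolerance 10⁻⁸, eigenvalue floor 10⁻¹²) and rejected rather
than repaired, so silent PSD drift upstream is caught early. LERM is
the Frobenius norm of log differences; in batched form the n logs are
computed once and distances come from their inner products (n, not n²,
eigendecompositions). JBLD uses Cholesky log-determinants
(2·Σ log diag L); its radicand is nonnegative in exact arithmetic, so
values in [−10⁻¹⁰, 0] are clamped to zero and anything lower raises.

RBF kernels are K = exp(−γ·d²) with the *squared* measure in the
exponent — for LERM this is an exact Mercer kernel (a Gaussian on the
log-embedded matrices). JBLD is not guaranteed Mercer; when the
resulting kernel matrix has eigenvalues below −10⁻⁸ it is flagged and
its negative spectrum clipped to zero, which is the standard indefinite
kernel repair and is logged so users know it happened. The default
γ = 0.00025 matches the operating point used for the image-level
classifier; at this bandwidth kernel entries have a small dynamic range,
which is why the kernel-SVM default C is 100 rather than 1 (see
Evaluation).

## Bags and the WAID

Patches are sampled with replacement, uniformly over valid top-left
offsets; per-image seeds are derived from a master seed plus a CRC of
the image id, so a dataset's descriptors are independent of image
order. Negative (background) bags default to i.i.d. uniform RGB noise
tiles — the background class farthest from any tissue statistics; pools
of surrogate textures or benign tiles are supported alternatives. One
shared pool of 15 negative bags (default) serves all images of a
dataset.

Instance vectorization concatenates the columns of Log(D) (length 64
for 8×8 descriptors) — the tangent-space embedding that makes Euclidean
machinery meaningful on SPD inputs.

### Jensen-Shannon feature map

The additive JS kernel k(x, y) = Σ_j x_j/2·log₂((x_j+y_j)/x_j) +
y_j/2·log₂((x_j+y_j)/y_j) is approximated by an explicit per-coordinate
map so a *linear* solver can be used. For a homogeneous kernel with
signature K(λ) = k(e^{λ/2}, e^{−λ/2}), the map samples the spectrum at
frequencies jL (L = `period`, default 0.6; order r = 1 by default,
giving 2r+1 features per coordinate). The spectral weights are the
Fourier-series coefficients of the signature truncated to the window
[−π/L, π/L], computed by numerical quadrature and cached. Two
numerical points:

* Log-vectors are signed but homogeneous kernels are defined on
  nonnegative inputs, so each coordinate is split into
  (max(x,0), max(−x,0)) before the map — the standard signed-input
  extension, which doubles the dimension (WAID length
  64·2·(2r+1) + 1 = 385 at r = 1).
* A real feature map requires nonnegative spectral weights; at
  L = 0.6 the j = 2 coefficient of the truncated JS signature is
  slightly negative and is clamped to zero, so the r = 2 map coincides
  with r = 1 at that period. At L = 0.5 all weights are positive and
  accuracy strictly improves with order. The default stays at 0.6,
  where the r = 1 map tracks the exact kernel to about 1% relative
  error on nonnegative vectors (measured; the acceptance script
  recomputes it).

### The η-constrained SVM

All instances of the positive bag receive label +1, all background
instances −1, and a linear soft-margin SVM is solved at C = C₀
(default 0.01). If fewer than a fraction η (default 0.9) of the
positive bag's instances land on the positive side of the boundary, C
is multiplied by `growth` (default 2) and the problem re-solved; larger
C penalizes misclassified positives more steeply and steers the
boundary to enclose them. The schedule stops at the first satisfying C
or at C_max (default 10⁶, ≈27 solves worst case), in which case the
last boundary is returned flagged `satisfied=False` — a WAID must exist
for every image, so non-termination is reported, not raised. The
per-step (C, fraction) history is recorded on the result.

The solver is liblinear's hinge-loss dual (deterministic seed, capped
iterations, intercept handled via an augmented feature with scaling
10). The SMO solver used for kernel SVMs elsewhere in the package
stalls badly at large C on heavily overlapping instance sets, which is
exactly the regime the C-schedule explores; liblinear degrades
gracefully there, and an iteration-capped approximate solution is
accepted after one tolerance-relaxed retry, since only the induced
sign pattern feeds the schedule. No class reweighting is applied
despite the 1-positive-bag vs. 15-bag imbalance — the C-schedule
already supplies the mechanism pushing toward positive classification;
reweighting remains a user-accessible variation through the config.

Bags are canonicalized (negative bags sorted by source id) before
aggregation, making the WAID invariant to bag order.

## Synthetic data

The generator renders eosin-pink background (with low-frequency
mottling and pixel noise) and purple elliptical nuclei placed by a
Poisson process. The malignancy surrogates are the classical
morphological cues, each independently controllable: nuclei per unit
area (`nucleus_density`, expected count per 10⁴ px²), nuclear size and
size variability (radius mean/std of a truncated normal), staining
darkness (`hyperchromasia` interpolating a light-to-dark chromatin
ramp), and boundary irregularity (low-order angular harmonics of the
nucleus contour). The benign preset uses density 4, radius 4 ± 0.8 px,
hyperchromasia 0.35, irregularity 0.15; the malignant preset scales
density ×3, darkness +0.3, radius spread ×2, irregularity +0.4 —
chosen once so that each cue is individually measurable (darker mean
luminance, higher edge energy, distinguishable histograms) while the
classes still overlap at patch level.

These tiles exercise the full pipeline but are *not* simulations of
real H&E statistics: no stain variation between slides, no stromal or
glandular architecture, no imaging artifacts, no label noise. Passing
tests on them demonstrates that the descriptors measure the intended
cues and that the MIL machinery recovers bag structure — not any level
of clinical performance.

Annotated images paint malignant-preset texture into a rectangle of a
benign-preset canvas and carry a pixel mask. The patch-labeling rule
tiles the image into disjoint grid patches and labels a patch +1 only
when *strictly more than* 80% of its pixels are masked, −1 only when it
is entirely devoid of masked pixels, discarding everything between.

## Evaluation

Patch-level classification uses kernel SVMs on precomputed LERM/JBLD
RBF Gram matrices with stratified k-fold (default 10) or leave-one-out
splits; image-level classification uses an RBF kernel (γ = 0.00025) on
Euclidean distances between WAID vectors with stratified 5-fold splits.
ACC and AUC are pooled over folds; CCM (correctly classified malignant,
i.e. malignant recall) is reported at image level and — when patient
ids are supplied — at patient level by averaging each patient's
decision scores and thresholding at 0. The SVM cost defaults to
C = 100: at γ = 0.00025 the kernel entries span a narrow range near 1,
and the margin scale requires a cost well above 1 for the classifier to
use the available signal. AUC comes from the standard ROC routine and
is verified in the tests against a brute-force pairwise-concordance
oracle (ties credited ½).

Reports serialize to JSON with a schema version and a config hash;
array artifacts are written as `.npz` archives with fixed zip
timestamps, so identical config + seed reproduce every artifact byte
for byte.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at sizes chosen for fast, stable statistics: 200 patches for the
definiteness sweep; 50 random triples/pairs for the geometry and
feature-map checks; 20 replicates of the 100-instance planted-recovery
problem; 60 tiles (150×150) for the leave-one-out patch classifier; and
5 replicates of a 40-image (150×150) end-to-end WAID experiment. On one
CPU the acceptance script completes in well under a minute and the full
test suite in about a minute.

## Known limitations

* The CKD fixes d₁ = 5 and d₂ = 3; alternative per-pixel feature sets
  (e.g., per-channel gradients, filter banks) are not configurable.
* JBLD's RBF kernel is repaired by eigenvalue clipping when indefinite;
  a Stein-kernel treatment with provable PSD ranges is not implemented.
* The η-SVM solves the label assignment by the C-schedule heuristic,
  not by exact combinatorial search; with heavily overlapping bags the
  returned boundary depends on the schedule's granularity.
* Patient-level aggregation averages decision scores; majority voting
  and other fusion rules are not implemented.
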