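# Methods

## The problem

Dopamine-transporter (DaT) SPECT imaging (¹²³I-ioflupane, "DaTSCAN")
shows high tracer uptake in the striatum of healthy brains and reduced,
often asymmetric uptake in Parkinsonian syndrome (PS).  Before any
quantitative comparison across subjects, per-subject intensity scale
differences — camera calibration gain and offset, not biology — must be
removed.  `datnorm` implements two automatic intensity-normalization
methods operating on co-registered volumes (canonical grid 73 × 73 × 45),
a standard binding-ratio baseline, and the evaluation harness that
measures whether a normalization worked: cohort histogram homogeneity
(KL divergence) and downstream diagnostic classification.

## Models and procedures

### Binding-ratio baseline (`binding_ratio`)

The binding potential BP = C_VOI / C_N − 1 compares the mean count per
voxel in a volume of interest against a non-specific reference region.
`BR_all` applies this voxel-wise with the whole brain minus the striatum
as reference: Î(x) = (I(x) − C_N) / C_N, so the non-specific mean maps
to exactly 0 (a `ratio_only` flag gives Î = I/C_N instead; the two
differ by a global affine map).  BR_all cancels a multiplicative gain
exactly, but an additive offset survives as a subject-dependent residual
scale — the failure mode that motivates the two model-based methods.

### Symmetric template and masks (`template`)

The control template averages each normal-control image with its
hemisphere-midplane reflection, t = (1/N_c) Σᵢ (Iᵢ(x,y,z) + Iᵢ(−x,y,z)).
As written this is twice the symmetrized mean; it is implemented
literally (every downstream use is scale-covariant) with a
`halve` flag for users expecting a true average.  Reflection is the
index map i → D₀−1−i on axis 0, so the template is symmetric by
construction to round-off.

The striatal mask thresholds the plain mean-control image at 0.45 of its
maximum (inclusive).  The brain mask — not fully specified by any of the
printed formulas — is the template support above 10 % of its maximum,
reduced to the largest 6-connected component with interior holes filled,
which reproduces the expected brain silhouette on smooth functional
images.  The non-specific (NS) mask is brain minus striatum.

### FGMM: spatial Gaussian-mixture filtering (`fgmm`)

The image is modeled as I_Gauss(x) = I · p(x) with I the total intensity
and p a k-component Gaussian mixture over voxel coordinates (default
k = 64).  Fitting is expectation–maximization in which each voxel enters
with its intensity as a fractional multiplicity — deterministic for a
fixed seed, unlike sampling coordinates proportional to intensity.
Numerical choices:

* initialization: k-means++ centers on the intensity-weighted
  coordinates (seeded), followed by one hard-assignment moment step;
* covariance floor: component covariance eigenvalues are clamped up to
  10⁻⁴ voxel² when they fall below it.  The clamp is a no-op for any
  healthy component, so a one-component fit equals the weighted-moments
  closed form exactly — the invariant the unit tests assert;
* convergence: relative change of the intensity-weighted log-likelihood
  below 10⁻⁶, or 500 sweeps;
* only voxels with strictly positive intensity enter the fit (zero
  weight contributes nothing).

Filtering prunes components irrelevant to the striatum: with
η = 1/N (the probability a voxel would carry under uniform intensity;
η ≈ 4·10⁻⁶ on the canonical grid) a component is removed — its weight
set to zero — when its *unweighted* density f_n is strictly below η on
at least 75 % of the striatal voxels.  Surviving weights are **not**
renormalized and the reconstruction scale is frozen at fit time: the
continuous density is converted to a grid probability by dividing by
`grid_norm`, the pre-pruning sum of p over all voxel centers.  Under
this convention the unpruned reconstruction conserves total intensity
exactly, pruning is pointwise monotone decreasing, and striatal
intensity is preserved while the background — dominated by the pruned
clusters — is suppressed.  Renormalizing after pruning would inflate
striatal intensity, contradicting the method's purpose.  A
`weighted_density` flag thresholds w_n·f_n instead of f_n for
comparison.

### Linear MSE normalization (`mse_norm`)

Î(x) = a·I(x) + b with (a, b) minimizing the mean squared error against
the template over the NS region.  The closed form is

    a = (Σ I·T − N m_T m_I) / (Σ I² − N m_I²),    b = m_T − a·m_I,

with the minimum cost ξ_min = (1/N)(Σ T² − b Σ T − a Σ I·T).  The fit
uses NS voxels only but the map is applied to the whole volume,
striatum included, because the classification stage consumes striatal
voxels of normalized images.  Diagnostics Σ e·I and Σ e (orthogonality
principle) are returned with every fit.  Accumulations use numpy's
pairwise summation in double precision; the closed-form ξ_min is
verified against the directly evaluated residual mean square to 10⁻¹⁰
relative in the tests.  A constant source over NS makes the denominator
vanish and is an error; a constant template is legal (a = 0 falls out).

### Evaluation (`evaluation`)

Histograms share one bin grid over [0, cohort maximum inside the mask]
(default 50 bins — unspecified upstream; 50 is stable for ~10⁴–10⁵ NS
voxels); values outside the range are clipped into the end bins and
every bin receives ε = 10⁻¹⁰ before renormalization so logs are always
finite.  The divergence is D_KL(P‖Q) = Σ P ln(P/Q) with P the
mean-image histogram and Q the subject's — this argument order is
applied consistently.  The mean image is pooled across classes by
default (`per_class_reference` switches to per-class means).  Percentile
bands report per-bin 25th/75th percentiles of subject histograms.

### Classification (`classification`)

Striatal ROI voxels (0.45-of-max rule on the mean-control image of the
dataset under test) in fixed lexicographic order form the
voxels-as-features matrix; the PCA variant retains the smallest number
of training-fold components reaching 95 % explained variance (the
component count is otherwise arbitrary; 95 % avoids per-dataset
tuning).  A linear SVM (C = 1; nonlinear kernels deliberately excluded,
features not re-standardized since the normalization under test defines
the scale) is evaluated by leave-one-out cross-validation with PCA
fitted inside each training fold — the held-out subject never touches
its own basis.  PS is the positive class, so sensitivity counts
detected patients.

## The phantom generator (`phantom`)

What it emulates: co-registered brain volumes with high striatal uptake
(specific:non-specific ≈ 4:1 at the blob peaks in controls), reduced
and hemispherically asymmetric striatal uptake in PS (factor 0.45, the
worse side a further ×0.7, side randomized per subject), per-subject
multiplicative gain α ∈ [0.6, 1.4] and additive offset
β ∈ [0, 0.3]·background applied inside the brain support (air stays
≈ 0), isotropic Gaussian point-spread blur (σ = 1.5 voxels on the
canonical grid), additive Gaussian voxel noise (σ = 0.05·background,
clipped at 0; post-reconstruction SPECT noise is approximately
Gaussian), and mild per-subject biological spread of the striatal
amplitude (8 %).  Anatomy is specified in fractions of the grid
extents — an ellipsoidal brain and two blobs (caudate-like and
putamen-like) per hemisphere — so the same phantom renders at any grid
size; when rendering at a coarser grid the PSF σ should be scaled down
proportionally, since larger voxels of the same brain mean a smaller
PSF in voxel units.

What it does not emulate: anatomical variability between subjects
(everyone shares one brain shape), registration error, Poisson counting
statistics, scatter/attenuation artifacts, or a severity spectrum
within the PS class (all patients share one uptake deficit, jitter
aside).  Consequences: classification on the phantom is *easier* than
on clinical data — with identical anatomy the raw images are already
nearly separable by shape cues, so absolute accuracies approach 100 %
and say nothing about clinical performance.  Passing tests demonstrate
that the normalizers remove exactly the corruption the phantom injects,
not that they reach any clinical accuracy.

## Bundled study scale

The bundled 40-subject experiment (20 NC + 20 PS) renders the phantom
at 33 × 33 × 21 — a scale model of the canonical 73 × 73 × 45 grid with
identical anatomy fractions and proportionally scaled PSF — and uses
k = 16 mixture components for the FGMM arm.  These sizes keep the full
study (40 weighted-EM fits plus 320 LOO SVM fits) at a few minutes on
one CPU while preserving the canonical grid's mask geometry and
specific:non-specific contrast (striatal mask ≈ 270 voxels, NS mask
≈ 7 800 voxels, identical masked means to the full grid).

## Known limitations

* EM finds local optima; different seeds give slightly different
  mixtures.  The per-subject fit variability is visible in
  FGMM-normalized feature vectors and can cost a few LOO percentage
  points at small k, where the striatal representation is coarse.
* The KL evaluation bins over [0, max]; normalizations that produce
  negative intensities (BR_all's BP convention) fold their negative
  half into the first bin.  The per-method comparison is still
  consistent because every method is evaluated with the same rule.
* The Eq-form template is twice the symmetrized mean; (a, b) of the MSE
  fit absorb the factor, but users comparing absolute intensities
  across toolkits should set `halve=True`.
* `brain_mask` is a heuristic (threshold + largest component + hole
  fill); on non-brain images it has no particular meaning.
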