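# Methods

## Scope and model

`spectac` implements a complete simulation-and-correction chain for
dopamine-transporter brain SPECT: synthetic head phantoms, an attenuated
parallel-beam acquisition model with dual-energy-window (DEW) scatter,
OS-EM reconstruction, three attenuation-correction families (CT-based,
Chang uniform-μ, conditional-GAN), and the quantitative comparison
machinery (NMSE, SSIM, SUR, %ASI, Bland–Altman, paired tests).  The
guiding use case is the two-scanner clinical protocol summarised by the
scanner profiles `scanner_a()` (GE Infinia Hawkeye: 128³ at 0.2761 cm
after regridding, 120 views/360°, photopeak 126–154 keV, scatter window
114–126 keV, post-filter σ = 0.8 voxels) and `scanner_b()` (Siemens
Symbia: 0.2697 cm, scatter window 109–126 keV, σ = 1.2 voxels), both
reconstructed with OS-EM at 8 iterations × 4 subsets.

## Phantoms

Heads are nested ellipsoids: an outer head ellipsoid, a skull shell of
configurable thickness, an inner soft-tissue (brain) region, and two air
cavities (nasal, oral) near the anterior-inferior face.  Linear
attenuation coefficients default to 140 keV head-tissue values: soft
tissue 0.148 cm⁻¹, skull 0.24 cm⁻¹ (within the measured 0.21–0.27
range), air 0.  Bilateral striata are mirrored ellipsoids fully inside
soft tissue; their activity is `ratio × background`, split
`(1 ± a/2)` between left and right so the noiseless asymmetry index is
0 at `a = 0` and grows monotonically with `a`.  The cerebellar
background region follows the clinical convention of a rectangular 2D
ROI (10 × 6 voxels at clinical resolution) replicated over a few axial
slices.  The pseudo-CT is the exact inverse image of the μ-map under the
bilinear HU→μ model, so `ct_to_mumap(pseudo_ct)` reproduces the μ-map to
float precision — a deliberate choice that makes the CT-AC reference
exactly consistent with the phantom.

Cohorts draw uniform per-subject variation: head scale 0.92–1.08 (striatal
anatomy scales along), striatum:background uptake ratio 1.4–2.8 (spanning
normal to clearly reduced DAT binding), asymmetry 0–0.3, and a global
activity scale 0.7–1.4 emulating the wide clinical spread of injected
dose, scan timing and tracer delivery.  That activity spread matters for
the method comparison: indirect GAN inputs are normalised per volume, so
the μ-map route is intensity-invariant, whereas the direct route must
reproduce absolute counts.

What the phantoms do **not** emulate: real cranial anatomy (no scalp,
ventricles, or anatomical texture), depth-dependent collimator response,
SPECT–CT misregistration, and head motion.  Passing tests therefore
demonstrate internal consistency of the correction chain and the
direction of method differences under controlled conditions — not
clinical performance.

## Acquisition model

Projection is slice-by-slice 2D parallel-beam (parallel-hole
collimation): for each view the in-plane rotation is applied as an
explicit sparse matrix of bilinear weights, voxels are attenuated by
`exp(−∫μ)` along the ray to the detector (cumulative sum with half-voxel
self-attenuation at the source voxel), and the rotated columns are
summed.  Two rotation variants are used: a value-preserving pull
rotation for resampling μ-maps, and a Sinkhorn-balanced variant for the
emission system matrix whose final column normalisation makes in-grid
count conservation exact while keeping rows near unity (smooth,
view-consistent projections).  The back-projector is the exact sparse
transpose, so the adjoint identity holds to machine precision — the
property OS-EM's convergence relies on.

The photopeak window receives Poisson counts of the attenuated
projection plus a scatter term modelled as a wide Gaussian blur
(σ = 2 bins) of the trues scaled by a scatter fraction (default 0.3);
the lower window receives a scatter-dominated signal scaled such that
the DEW estimate `scatter × (W_p/W_s) × k` with the standard `k = 0.5`
is unbiased in expectation.  Neither `k` nor the scatter fraction is
prescribed by the protocol; both are configurable.

## Corrections

* **DEW**: per-bin subtraction, clamped at zero.
* **Bilinear CT→μ**: μ(−1000 HU) = 0, μ(0 HU) = 0.150 cm⁻¹ (water at
  140 keV), slope above 0 HU chosen so +1000 HU → 0.25 cm⁻¹ (inside the
  measured skull range); parameters configurable.
* **Chang**: brain mask = largest connected component of NAC > threshold,
  hole-filled (the post-processing is added for robustness).  The
  clinical threshold of 2 is in reconstructed count units and therefore
  scanner- and count-level-dependent; the desk experiment scales it with
  the simulated count level.  The in-mask value is the uniform
  coefficient times the voxel size, truncated at four decimals to match
  the printed clinical convention (0.148 × 0.2761 → 0.0408 voxel⁻¹).
  Thresholding is applied to the unfiltered NAC reconstruction, before
  the post-filter.  The uniform μ-map goes *into* OS-EM (the clinical
  pipeline); the classical first-order factor image is provided
  separately for comparison.  Its per-angle in-mask path lengths reuse
  the rotation machinery, and the angular average is normalised by the
  rotated unit field so μ = 0 yields factors of exactly 1.

## Conditional GAN

Generator: U-Net with per-level feature doubling from `base_features`
(48 at clinical scale), each block 3×3×3 convolution + batch-norm +
LeakyReLU(0.2); 2×2×2 max-pool encoder; nearest-neighbour upsampling
decoder; 50 % dropout at the bottleneck; 3 encoder levels without skip
connections for the indirect (NAC→μ-map) task, 2 levels with skips for
the direct (NAC→AC image) task.  The output head is a 1×1×1 convolution
with a small-slope LeakyReLU (0.01) — a tiny negative slope keeps
gradients alive where the target is zero (a hard ReLU head collapses to
the all-zero solution on sparse μ-map targets); inference clamps at
exactly zero.  Discriminator: four stride-2 convolution blocks on the
(condition, candidate) pair, global mean pooling, scalar logit.  It uses
no normalisation layers, because real and generated candidates pass
through in separate sub-batches and batch statistics would leak the
label.

Losses: cross-entropy discriminator; generator = non-saturating
adversarial term + λ·L1 with λ = 20, logged per step with the exact
decomposition.  For the indirect task both the inputs (per-volume
min-max) and the μ targets (one global factor, the cohort-maximum
coefficient, stored and inverted at prediction) are brought to [0, 1];
this keeps λ·L1 and the adversarial term on comparable scales, which is
what makes λ = 20 a stable operating point for μ-valued targets.  The
direct task trains on raw counts to keep them invariable.  Optimisation:
Adam at 0.001 for the generator; the discriminator runs at a quarter of
that rate, which keeps the adversarial game stable on small cohorts.
Learning rate halves on a monitored-L1 plateau; early stopping on the
validation L1 when a validation split exists.

Batch-norm statistics are re-estimated after training (and briefly
before each validation pass) with dropout disabled, because statistics
collected under bottleneck dropout do not match the dropout-free
inference distribution — without skip connections all information passes
the bottleneck and the mismatch is large.  Inference is deterministic.

Training regimes mirror the clinical study: `scanner_specific` (own
90/10/30 split at clinical scale), `cross_scanner` (models swapped
between scanners), `ensemble` (pooled training).  Flip augmentation
(originals + horizontal + vertical flips, 3×) applies in every regime.

## Desk-scale experiment

CPU-scale study conditions (the package's desk preset): 24³ grids at
0.90 / 0.88 cm per voxel, 24 views, skull thickness enlarged to ~1.6
voxels so the shell remains resolvable, background ROI 4 × 3 voxels;
scanner B additionally has 0.625× the counts (mirroring its lower
injected activity × acquisition time), a 1-voxel posterior/superior head
positioning offset (the two clinical systems differ in positioning and
field of view), and its own σ = 1.2 post-filter.  GAN desk preset:
8 base features, batch 2.  The frozen ordering experiment
(`pipeline.ordering_config`) uses 6 training / 3 test phantoms per
scanner, 10 epochs, and is replicated over five seeds; the acceptance
suite requires each method ordering to hold in at least four of five.
These sizes are the package's chosen desk scale; the same pipeline runs
at clinical scale (128³, 120 views, 48 features, up to 400 epochs) via
the non-desk configuration.

## Numerical choices

* Rotation matrices: bilinear weights, out-of-grid source positions
  dropped; 8 Sinkhorn row/column passes for the system-matrix variant.
* OS-EM: interleaved subsets (view i → subset i mod 4, processed in
  order), per-subset sensitivity images precomputed, ratio bins with
  forward projection below 1e-12 skipped, zero-sensitivity voxels frozen
  at 0.  A μ-map of zeros takes the identical code path as no μ-map.
* Post-filter: normalized convolution (Gaussian numerator divided by the
  filtered grid indicator), count-preserving for interior sources.
* Resampling: trilinear about the volume centre; count-unit volumes are
  rescaled by the voxel-volume ratio so total activity is preserved;
  target matrix and voxel size are both explicit because the clinical
  regridding changes the field of view.
* SSIM: 7³ uniform windows, K1 = 0.01, K2 = 0.03, sample-covariance
  normalisation, mean over interior windows; the data range defaults to
  the reference maximum.  The whole-brain mask for NMSE/SSIM is
  reference μ > 0.01 cm⁻¹ (configurable).
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; phantom generation is fully deterministic
  given its spec.

## Known limitations

* The projector has no collimator-detector response or depth-dependent
  resolution; the post-filter carries all resolution matching.
* Scatter is a stationary Gaussian-blur model, not photon transport.
* At the desk scale the striata span only a few voxels, so reconstructed
  SUR values sit well below the phantom ground truth (partial volume);
  comparisons are therefore made against the CT-AC reference, which
  shares the bias.
* On these smooth synthetic cohorts the direct NAC→AC mapping is easier
  to learn than it is clinically (shared-noise input/target pairs,
  stereotyped anatomy), and pooling two mildly different scanners can
  help rather than hurt a small-data model; the indirect-vs-direct and
  ensemble-vs-specific orderings observed on clinical data should not be
  assumed to transfer to this synthetic regime (see the acceptance-suite
  results for what actually holds here).
* Whether batch normalisation belongs in decoder blocks, the upsampling
  operator, and the discriminator's conditioning are design choices the
  clinical protocol leaves open; the defaults above are documented
  rather than uniquely determined.
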