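# Methods

This note documents the models, conventions and design choices behind
`navfuse`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the simulated validations do and do not show.

## Coordinate frames and transform algebra

All physical coordinates are millimetres in right-handed frames; anatomical
volumes use LPS internally (RAS-coded NIfTI headers and Slicer FCSV files
are converted at I/O and restored on write).  Points are column vectors and
transforms act by left multiplication, so a chain reads right-to-left from
the source image to the target image.

Transforms are stored as 4×4 homogeneous matrices tagged with named source
and target frames, and every composition checks that frames chain
head-to-tail — a mismatched chain raises rather than silently multiplying.
A matrix qualifies as rigid when `RᵀR = I` and `det R = +1` within 1e-9;
orthogonality drift below 1e-6 (e.g. from long pose-averaging chains) is
repaired by polar projection onto SO(3), larger drift is an error.
Quaternions are accepted at I/O (scalar-last), must be unit within 1e-6,
and are converted to matrices immediately.

## Paired-point registration and its statistics

All calibrations reduce to the orthogonal-Procrustes problem: given
label-paired fiducials in two frames, the least-squares rigid map is
computed by the SVD (Arun) method with a determinant-sign correction, which
guarantees a proper rotation even for coplanar configurations such as
in-plane TRUS sweep points (coplanarity is detected and flagged;
collinearity is rejected as ill-posed).  Correspondence is always by label:
cone tips are identified manually in practice, so no automatic matching
(ICP-style) is provided.

The fiducial registration error (FRE) is the RMS residual over the fitted
pairs; the target registration error (TRE) is the distance error at
label-paired points held out from the fit, reported as mean ± sample SD.
Under isotropic localization noise the implementation reproduces the
classical expectation `⟨FRE²⟩ = (1 − 2/N)·⟨FLE²⟩` within Monte-Carlo error;
this identity is used as a test oracle only, not inside any estimator.

Repeated stylus readings (10 per tip for the tank phantom, 5 for the MR
phantom, configurable) are collapsed by a robust mean: readings farther
than 3× the median absolute deviation from the per-label median are
discarded, and the per-label 3-D RMS spread about the mean is reported as a
jitter estimate.  The threshold is a conventional robust-statistics choice;
its purpose is purely to keep a single stuck/occluded tracker reading from
dragging a tip.

CAD refinement: when the cone-tip layout is known exactly from the
phantom's CAD model, the measured tank tips are replaced by CAD tips mapped
through the CAD→tank rigid fit.  This trades N independent per-tip noise
vectors for the (much smaller) uncertainty of a rigid fit over all tips,
and the Monte-Carlo test verifies the variance reduction.

## Device calibrations

* **Pivot calibration** solves the stacked linear system
  `[Rᵢ | −I](p_tip, p_pivot) = −tᵢ` in one least-squares shot.  It requires
  ≥ 10 valid poses spanning ≥ 30° of orientation; a pure-translation stream
  leaves the tip unobservable and is rejected.  The residual RMS is
  reported per coordinate, directly comparable to the per-axis tracker
  sigma.
* **3D-US probe calibration** maps stylus-measured tank tips into the
  probe-tool frame via `T_probe⁻¹ · T_tank` per observation and pools
  image/tool pairs across observations before a single rigid fit.  Pooling
  (rather than averaging per-observation transforms) is the lower-variance
  estimator and is what the monotone-improvement test checks.
* **TRUS probe calibration** lifts 2-D pixel indices to the image plane
  (z = 0, 0-based indices at pixel centers, millimetres via the pixel
  spacing) and registers them to pointer tips mapped into the probe-tool
  frame; the coplanar geometry is handled by the reflection guard.
* **MR calibration** registers the image-localized 18-cone tips to the
  stylus-measured tips in the optical reference frame (repeats averaged
  first).  The calibration records whether it is referenced to the
  table-mounted or the gantry-mounted tool, which selects the fusion-chain
  form below.
* **Table-shift tracking** averages each pose epoch (translation: mean;
  rotation: chordal mean, i.e. the mean matrix projected onto SO(3) — an
  excellent approximation for sub-degree static jitter) and returns
  `S = T_before⁻¹ · T_after`, the map from the post-move tool frame to the
  pre-move tool frame.

## The fusion chain

With a **table-referenced** MR calibration the US→MR map is

```
T_US^MR = T_ORF_TABLE^MR · S · [T_ref,after⁻¹ · T_probe] · T_US^trans
```

and with a **gantry-referenced** calibration a static table link
`T_ORF_TABLE^ORF_MR` (table tool → gantry tool at the MR epoch) is inserted
before `S`.  The two forms are algebraically identical and the noiseless
simulation verifies they produce the same matrix to 1e-9.

Chain evaluation folds the factor list left-to-right with frame checking.
Links whose matrix is exactly the identity are treated as frame bridges and
skipped, so a chain with a no-op table shift reproduces the shift-free
chain *bit for bit* — the discrete analogue of the algebraic reduction, and
a cheap guard against silent numerical drift in the degenerate case.

**Frame semantics of the simulation.**  The simulated world models a bench
experiment: phantoms are static in the tracker frame, and the MR image
frame is anchored to the world by a fixed rigid map realized through the MR
calibration.  Under this model the chain above is exact, and the zero-noise
closure property (lesion positions reproduced to < 1e-6 mm through the
entire calibrate→chain→map pipeline, in practice ~1e-13) pins down every
sign and inversion convention in the implementation.  Patient-motion
effects (a subject riding the table between scans, organ deformation) are
outside this model.

## Intra-modal affine registration

The US/US registration maximizes Mattes mutual information over a
12-parameter affine transform using SimpleITK's multi-resolution framework
(shrink ×4/×2/×1 with matched Gaussian smoothing, regular-step gradient
descent with physical-shift scaling, transform centered at the fixed-mask
centroid, 25% random metric sampling with a fixed seed, one work unit —
deterministic given inputs and seed).  Masking to the gland region is what
makes the problem well-conditioned, mirroring the manual masking step of
the clinical workflow.

An independent joint-histogram mutual-information function (32 hard bins
over the robust 0.5–99.5 percentile range of each image) is used for
reporting and as a safety guard: if the optimizer's endpoint scores a lower
MI than the initialization, the initialization is returned and flagged, so
registration can never worsen an alignment.  Hard binning was chosen over
Parzen partial-volume weighting so that the identity `MI(X, X) = H(X)`
holds exactly; the binning loss under invertible intensity remaps shrinks
with bin count, which the tests check explicitly rather than assuming.

On the synthetic phantom (speckled US pairs differing by ≤ 10° rotation,
≤ 5 mm translation, ≤ 3% anisotropic scale) the registration recovers
lesion centroids to a few tenths of a millimetre at 1.25 mm voxels.  This
shows the pipeline is implemented correctly, not that real prostate US/US
registration achieves these numbers: the synthetic appearance model
(piecewise-constant echogenicity × gamma speckle with exponential depth
attenuation) has none of the shadowing, refraction or deformation of real
tissue.

## Overlap metrics

Dice is computed on voxel counts; Hausdorff and mean boundary distance
operate on face-connected boundary voxels with distances between voxel
centers in physical millimetres — reproducible without mesh extraction, at
the cost of a grid-scale quantization that the sphere-oracle tests bound
explicitly.  Hausdorff is the exact maximum (no percentile variant); the
boundary distance is symmetrized (mean of both directed means) with the
directed values also reported.  Masks on different grids are resampled
nearest-neighbour onto the first argument's grid, and the report records
which side was resampled.  PSNR is `10·log₁₀(peak²/MSE)`; identical inputs
are reported as infinite with an explicit flag.

## Synthetic data

The generator defaults encode the reference bench conditions: a 7-cone
calibration phantom (US) and an 18-cone phantom (MR) with tips on a 20 mm
grid at cycling heights; a 4×4.5×4 cm ellipsoidal gland containing three
non-collinear 5 mm-radius lesions; MR appearance as piecewise-constant
intensities with additive Gaussian noise; US appearance as multiplicative
gamma speckle (shape 16) with exponential depth attenuation.  Lesion masks
are exact center-inclusion masks; image edges get one voxel of
partial-volume softening.

Noise convention: every `sigma` parameter is a **per-axis** standard
deviation; the corresponding 3-D RMS displacement is `σ·√3`.  Defaults:
tracker and stylus jitter 0.3 mm 3-D RMS (the middle of the 0.25–0.35 mm
optical-tracker class), rotational jitter 0.05°, image fiducial
localization 1.0 mm (US) and 0.5 mm (MR) 3-D RMS.  A master seed spawns
per-component child seeds, so whole experiments are bitwise reproducible
while replicates stay independent.

## Error propagation

`quadrature_total` is the root-sum-of-squares of an explicit component
list.  The worked example combines the intra-modal US/US registration error
(3.7 mm, from a volunteer repositioning study) with the TRUS calibration
FRE (1.18 mm) to 3.88 ≈ 3.9 mm; the budget is an explicit argument because
which components enter such a total is a modelling decision, not something
the package should hard-code.

`monte_carlo_chain_tre` is the numerical counterpart: each replicate
re-simulates every noisy observation, reruns all calibrations and the
chain, and records the mean lesion mapping error against truth.  Replicates
with degenerate calibrations are excluded and counted; more than 1% of them
aborts the run as a broken configuration.  The tests verify the three
properties that justify the quadrature picture: zero error at zero noise,
strict monotonicity in the noise scale, and first-order linearity (doubling
every σ doubles the mean TRE within 10%, using common random numbers).

## Problem sizes and determinism

Default problem sizes were chosen so the full test suite and the acceptance
script each run in a few minutes on one CPU: phantom volumes at 1.25 mm
voxels (~60³) for registration studies, 0.2 mm grids for the sphere-metric
oracles, 10⁴ replicates for the FRE expectation, 200–500 replicates for
Monte-Carlo propagation, 20–50 tracker readings per pose epoch.  All
stochastic paths take explicit seeds; SimpleITK registration runs
single-threaded with a seeded sampler.

## Known limitations

* No deformable registration, motion compensation, or slice-to-volume
  matching; the affine intra-modal registration assumes the gland moves
  approximately rigidly (plus small scale) between US acquisitions.
* The simulated world has no organ motion or tissue deformation, no US
  physics beyond speckle and attenuation, and no MR distortion; passing
  recovery tests demonstrate implementation correctness, not clinical
  accuracy.
* No anisotropic-noise (weighted) point registration and no spatial TRE(r)
  prediction map; the isotropic expectation is used as a test oracle only.
* No real tracker or imaging hardware I/O (streams are read from CSV), and
  no DICOM.
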