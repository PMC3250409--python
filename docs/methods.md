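# Methods

`bgconn` quantifies the structural and functional connectome of the seven
deep brain structures per hemisphere — caudate nucleus (CN), putamen (Pu),
external and internal globus pallidus (GPe, GPi), substantia nigra (SN),
subthalamic nucleus (STN) and thalamus (Tha) — at the level of a single
subject. Because individual 7T datasets of this kind are not publicly
shareable, the package is built around digital phantoms with known ground
truth: every stage of the analysis can be validated against quantities that
are exactly computable from the phantom's construction.

## Phantom model

A phantom is a rectangular grid (default 48×56×40 voxels at 1.5 mm
isotropic, mirroring a high-field diffusion acquisition at desk scale)
carrying:

* **Structures** — axis-aligned ellipsoids, fourteen in total (7 per
  hemisphere), pairwise disjoint after rasterization. Ellipsoids were chosen
  for their analytic volumes; they make volumetric statistics exactly
  predictable.
* **Bundles** — tubes of fixed radius (default 2.2 mm) around polyline
  centerlines joining two structures. Each covered voxel receives the local
  unit tangent as a "stick" orientation with a volume fraction (default
  0.5) and a Watson-style concentration κ (default 30, about 7° angular
  sd; κ ≥ 1e9 is treated as dispersion-free). Up to three sticks may share a
  voxel; a fourth is a construction error. When superposed fractions exceed
  0.95 they are rescaled preserving ratios so the ball-and-stick constraint
  Σf ≤ 1 always holds.
* The default phantom plants the seven canonical pathways of the
  basal-ganglia/thalamus circuit: nigrostriatal (SN–Pu), nigropallidal
  (SN–GPi), nigrothalamic (SN–Tha), subthalamopallidal (STN–GPe),
  pallidothalamic (GPi–Tha), striatopallidal (Pu–GPe) and thalamostriatal
  (Tha–CN), mirrored across hemispheres. Structure positions were chosen so
  bundle routes meet only inside shared structures and never cross
  mid-route: at a mid-route crossing, probabilistic propagation hops between
  tubes at shallow angles and fabricates connections that were never
  planted, which would make ground-truth recovery ill-defined. (Junction
  hops at a shared structure either stay on a planted route or exceed the
  curvature limit and terminate.)

**Diffusion signal.** The ball-and-stick forward model
`S(g,b) = S0[(1−Σf_k)e^{−bd} + Σ_k f_k e^{−bd(g·v_k)²}]` with S0 = 1000,
d = 1.7×10⁻³ mm²/s, single shell b = 1500 s/mm², 128 golden-spiral
directions plus 15 interleaved b0 volumes. Noise is Rician (magnitude-MR
convention) with scale `noise_sigma · S0`; the phantom's default is
noiseless, and tests that need noise state an SNR explicitly (SNR = 1/σ).
No quantitative noise level is documented for the emulated acquisition, so
phantom SNRs are choices, not derivations.

**BOLD signal.** Each structure carries a unit-variance white latent time
course; latents are jointly Gaussian with the planted inter-structure
correlation matrix (checked for positive semidefiniteness). A voxel's
course is baseline (100) + its ROI latent + slow random-phase half-period
cosine drift (amplitude 0.2) + white Gaussian noise (sd 0.5), 150 frames at
TR 2 s. With ~20–100-voxel ROIs these defaults keep the sample correlation
of ROI mean courses within 0.05 of the planted value (verified over 200
seeds in the test suite). `zone_overrides` restricts a structure's latent
to a sub-zone, used to plant focal structure–function coupling. The
generator does not emulate hemodynamic smoothness, physiological noise
spectra, motion, or distortion — so passing tests validate the statistical
machinery, not robustness to those artifacts.

**Repeat segmentations.** `perturb_segmentation` toggles ROI rim voxels:
boundary voxels drop to background and background voxels adjacent to
exactly one structure join it, each with the given probability. Interiors
are never touched. Because an ellipsoid's outer shell is slightly larger
than its inner shell, repeated segmentations drift marginally larger on
average; agreement indices are insensitive to this.

## Fiber model

FA maps come from a weighted log-linear tensor fit (OLS initialisation,
one WLS refinement with squared-signal weights) and the standard formula
`FA = sqrt(3/2)·||λ−λ̄|| / ||λ||`. Voxels with nonpositive signal are
excluded and reported. Signals are floored at 1e−6 before the log.

Crossing-fiber estimation is a greedy nonlinear-least-squares ball-and-stick
fit: sticks are added one at a time (at most three), initialised from the
tensor eigenvectors, while the incremental fitted fraction stays ≥ f_min
(default 0.05, the usual automatic-relevance ballpark). Orientation
uncertainty comes from a residual bootstrap (≥ 50 replicates): residuals
are resampled, the chosen model refitted from the point estimate, and
bootstrap fibers matched to point-estimate fibers by largest |dot|
(orientations are axes — v and −v identical everywhere in the package).
This deliberately replaces the MCMC sampler used by large-scale tools with
an estimator of the same contract (orientation sample clouds with point
fractions) that is fully testable at desk scale.

## Tractography

Streamline samples are launched from every voxel of the seed structure,
`n_samples_per_voxel` times (default 1000). A sample draws one initial
orientation and propagates two half-streamlines in opposite initial signs,
concatenated and counted once — without the concatenation, the half headed
away from the target could never be retained and the corridor oracle's
near-total retention would be unreachable. Per step: a fiber population is
chosen with probability ∝ f_k, an orientation drawn (Watson perturbation
for ground-truth fields; a bootstrap sample for estimated fields), the sign
aligned with the running direction, the position advanced by `step_size`
(default 0.75 mm, half a voxel). Termination: leaving the grid, exceeding
`max_steps` (2000), turning more than `curvature_threshold` (80°), entering
a fiber-free voxel, or entering a target structure (the entry voxel is
counted, nothing beyond it). Orientation lookup is nearest-voxel — a known
limitation, chosen because interpolation of antipodally symmetric
orientation fields is not well defined.

A sample is retained for the first target it enters (if both halves hit
targets, the positive-sign half wins — a deterministic tie-break); samples
reaching no listed structure are discarded, and
retained + discarded = launched holds exactly. Retained samples increment
the visit count of every voxel traversed (consecutive duplicates deduped; a
genuine revisit after leaving a voxel counts again, which the curvature
limit makes vanishingly rare). Per-seed-voxel tallies of retained samples
per target form the connectivity profile. Undirected pairwise maps
accumulate A→B and B→A launches. The propagation kernel is JIT-compiled
(numba) and deterministic given its integer seed; per-structure seeds are
derived from the run seed through `SeedSequence`.

## Quantification rules

* **Pathway mask**: voxels with visit counts strictly greater than 10% of
  the distribution maximum. Applied to raw counts; with the shared
  per-target normalization (counts / total retained for that target) this
  is identical on proportions.
* **Sub-territory**: voxels whose proportion of streamlines to a target is
  ≥ 50% of that proportion's maximum over the structure (non-strict: the
  statistic's own definition uses "greater or equal", and the non-strict
  form is adopted package-wide). Voxels may belong to several
  sub-territories; a dominant-target map breaks ties by the fixed order
  CN, Pu, GPe, GPi, SN, STN, Tha.
* **Voxel proportions** default to the retained-total denominator (share of
  the voxel's streamlines reaching *any* listed structure); a
  per-launched-sample denominator is available.
* **Probability of connection**: mean proportion-to-target over the
  target's sub-territory; undefined (NaN) when the sub-territory is empty,
  i.e. when no streamline reached the target at all. The 7×7 per-hemisphere
  matrix stores these row-wise (seed × target); cross-dataset aggregation
  reports mean ± sd ignoring missing cells.
* **Sub-territory volumes** are reported as proportions of the whole
  structure.

## Statistics

The agreement index AI = 1 − |V₁−V₂| / (0.5(V₁+V₂)) compares repeated
segmentation volumes (1 = identical; −1 when one volume vanishes; symmetric
and scale-invariant). Hemispheric asymmetry of any per-dataset quantity is
tested with a paired two-sided t-test (left/right of the same dataset) and
a two-sample Kolmogorov–Smirnov test with exact small-sample p-values for
n ≤ 10, both at α = 0.05 and uncorrected across pairs (a Bonferroni-minded
user can divide α; the battery reports raw p-values). Note that at n = 5
the exact KS test can only reject when the two samples separate completely
(D = 1, p ≈ 0.008), which caps its power near 0.78 even at a 3-sd shift —
the t-test is the sensitive member of the pair at these sample sizes.

## Functional connectivity

Preprocessing: drop the first frame (150 → 149), rescale each slice's mean
intensity per frame to the reference (first retained) frame, regress out a
drift basis per voxel (intercept, linear trend, and 2 sine/cosine pairs —
the linear term is included because a pure Fourier set cannot remove a
ramp), re-add the temporal mean, then smooth spatially (Gaussian, 4 mm
FWHM) and temporally (Gaussian, 2 data points). The temporal kernel width
is interpreted as FWHM by default — the convention of the classic
single-subject GLM packages — with a plain-sd reading selectable.
Slice-scan-time correction is omitted: the synthetic series has no slice
timing.

Seed maps: voxelwise OLS of each time course on [intercept, seed-structure
mean course, global mean course, optional confounds], all non-intercept
regressors centered and unit-scaled (the seed t statistic is invariant to
this; it only conditions the design). Because temporal smoothing leaves the
noise autocorrelated, naive OLS t statistics would be strongly
anti-conservative (roughly a fifth of pure-noise voxels would pass FDR at
q = 0.01). The package therefore corrects the contrast variance with the
known smoothing kernel (V = KKᵀ) and uses Satterthwaite effective degrees
of freedom, tr(RV)²/tr(RVRV); on temporally smoothed null data the
resulting p-values are uniform (verified by KS test in the suite). The
correction can be disabled to reproduce the naive behaviour.

Thresholding: Benjamini–Hochberg step-up over in-mask voxels at q = 0.01,
then removal of connected components smaller than 10 voxels
(26-connectivity by default; 6/18 selectable). Structure–function
correspondence is quantified as the Dice coefficient between a pathway (or
planted) mask and the thresholded activation, restricted to a region of
interest; undefined when both masks are empty there.

## Pipeline and problem sizes

`run_connectome` chains all stages from a phantom spec (or NIfTI inputs
with an FSL-style gradient table) and writes NIfTI masks/maps, per-hemisphere
CSV matrices and a JSON report; everything derives from one integer seed.
On phantom input the tractography substrate is the ground-truth fiber field
by default; `fiber_source="estimated"` routes it through the NLLS +
bootstrap estimator instead, which is validated per-voxel in the test suite
but is orders of magnitude slower over a full corridor system and does not
change what the downstream stages test.

The validation batteries use: 1000 streamline samples per seed voxel; 20
independent tracking replicates for connectome recovery and hemispheric
symmetry; 20 simulated resting-state sessions for the structure–function
battery; 10,000 null replicates for the asymmetry type-I check; and 500
pure-noise maps for the FDR check. These sizes give Monte-Carlo error well
inside the asserted margins while keeping a full run in the minutes range.

## Known limitations

* Nearest-voxel orientation lookup; no orientation interpolation.
* No modelling of susceptibility or eddy distortions, motion, coil
  sensitivities, or slice timing — the registration/distortion pipeline of
  a real study is out of scope by design.
* The drift GLM in preprocessing and the seed GLM are run sequentially, so
  the seed-map residual df does not account for the drift projection (a
  ~5/149 effect).
* Sub-territory anatomy is never named: the package computes parcellations
  and probabilities, not anatomical interpretations.
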