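# Methods

## Phantom model

Each synthetic scan is a `(nz, ny, nx)` Hounsfield-unit grid, by default
32 × 80 × 80 voxels at 1.4 × 0.66 × 0.66 mm (z, y, x). The z grid is the
1.4 mm reconstruction increment; the 3.1 mm slice thickness is carried as
metadata and consumed only by the scoring normalisation (below).

A lesion is a sphere with a Gaussian radial attenuation profile
`HU(r) = peak · exp(−r²/2σ²)`, with σ chosen so the profile crosses the
130 HU scoring threshold exactly at the nominal radius R. Inside R the
rendered value is clamped to ≥ 130 HU so float rounding cannot drop a truth
voxel below threshold. Consequences that the tests exploit:

* the pre-noise thresholded geometry is exactly the rasterised ball of
  radius R — an analytic volume oracle (`(4/3)πR³` up to rasterisation);
* ground truth (mask, per-lesion volume and Agatston contribution,
  scan-level score) is computed from pre-noise geometry and is invariant
  under noise and motion blur, which are applied afterwards.

Background is a constant soft-tissue value (35 HU by default, optional
smooth heterogeneity field, both ≤ 60 HU); acquisition noise is additive
Gaussian; motion unsharpness is a single-parameter 1D Gaussian blur along
the anterior–posterior (y) axis. The published protocol does not state a
noise magnitude for the low-dose acquisition, so the noise sd is a free
config parameter (default 15 HU; the pipeline experiment uses 20 HU).

Anatomical territories are fixed axis-aligned boxes in fractions of the
field of view — coronary, aorta, valve, bone — a desk-scale stand-in for
anatomy. The distractor boxes are deliberately separated from the coronary
box (the aorta along x, the valve along y) so that "coronary vs not" is
decidable from spatial features, which is the property the detection
acceptance surface measures. Random phantoms draw 0–4 coronary and 0–2
distractor lesions with radii 1.5–4.5 mm and peaks 150–700 HU, spanning all
four density bands and all five risk strata.

The rater-noise model perturbs a true score table at scan level: each
lesion is dropped with probability `p_drop` (removing a binomial fraction
of the score), spurious small lesions arrive at Poisson rate `p_add`, and a
log-normal factor with sd `jitter_sd` multiplies what remains. Zero noise
reproduces the reference column exactly.

What the phantoms do **not** emulate: beam hardening, photon statistics,
ECG phase, scanner dialects, real coronary anatomy or per-artery labels.
Passing tests therefore demonstrate the correctness of the pipeline's
mechanics and its behaviour under controlled noise — not clinical
performance on patient scans.

## Extraction conventions

Thresholding is inclusive (HU ≥ 130), matching the Agatston convention.
Connected components use the 26-neighborhood by default (6 and 18
available); candidate order is deterministic by bounding-box minimum
corner. Per-slice areas are computed on the stored 1.4 mm z grid with no
interpolation. Oversize components (bone) are flagged, never dropped —
rejection is the classifier's job. The threshold is kept at 130 HU
regardless of tube voltage and is configurable.

## Scoring conventions

* **Thickness normalisation.** Agatston's definition assumes contiguous
  3 mm slices. Here every reconstructed slice on the 1.4 mm grid
  contributes (no de-overlap correction) and the sum is multiplied by
  `thickness / 3` (3.1/3 ≈ 1.033 by default, configurable).
* **Minimum lesion area** 1 mm² per slice (classic convention,
  configurable). A single 0.66 × 0.66 mm voxel therefore has calcium
  volume but zero Agatston score — an intended asymmetry.
* **Fractional scores** are kept unrounded; strata use half-open
  intervals: 0 → "0", (0, 10] → "1-10", (10, 100] → "11-100",
  (100, 400] → "101-400", (400, ∞) → ">400".
* "Number of calcifications" counts connected components labeled coronary.

Because automated scoring reads the noisy volume while ground truth uses
pre-noise intensities, the per-slice max HU — and hence the density weight
— is biased slightly upward under noise; this occasionally flips a scan one
stratum upward and is accepted as faithful to scoring on the stored
reconstruction.

## Detection

* **Spatial normalisation** is an axis-aligned affine
  `ref = (world − offset)/scale`, obtained either by moment-matching a
  cardiac-region mask (centroid and per-axis sd) or from the field of view
  (mapping the cardiac box to a centred unit frame). Full deformable
  registration is out of scope; the contract is only "a transform into the
  atlas frame".
* **Atlas** = voxelwise mean of pulled-back training masks on a reference
  grid spanning ±3 units (32 × 48 × 48), Gaussian-smoothed and clipped to
  [0, 1]. The experiment default smoothing is 0.5 reference units: with
  50 sparse training masks, less smoothing leaves the prior near zero
  almost everywhere and the spatial feature carries no signal; 0.5 spreads
  support over the coronary territory while distractor territories stay
  near zero.
* **Features** (14 by default): candidate volume; atlas probability at the
  centroid; normalised centroid coordinates (3); and per scale
  {1, 2, 4} mm the Gaussian-smoothed intensity, gradient magnitude and
  Laplacian, all computed in mm units so anisotropic voxels are handled
  correctly. The scale set spans the lesion sizes the phantoms generate.
* **Classifier**: features are z-scored with training statistics (stored on
  the model). A kNN (k = 15) posterior is computed for every candidate;
  posteriors inside the band [0.3, 0.7] are re-decided by an RBF SVM
  (C = 1, gamma = "scale") trained on the same data. Band (0.5, 0.5)
  degenerates to pure kNN (odd k never produces a 0.5 posterior), band
  (0, 1) to pure SVM. k, kernel, scales and band are config — the original
  clinical software's hyperparameters were never published, and no fidelity
  to them is claimed.
* Training labels for phantoms come from ground-truth mask overlap: a
  candidate is coronary when ≥ 50 % of its voxels lie in the mask (noise
  can append a few off-mask voxels to a true lesion).

## Agreement statistics

* **Weighted kappa**: `κ_w = 1 − Σ v_ij o_ij / Σ v_ij e_ij` with linear
  penalties `v_ij = |i−j|/(k−1)`; transpose-invariant, equals unweighted κ
  for k = 2. Point estimates only (no CIs).
* **ICC**, single-measure, from the two-way mean squares (subjects MSR,
  raters MSC, residual MSE): the two-way-*mixed* model defaults to the
  consistency form `(MSR−MSE)/(MSR+(k−1)MSE)` (reference-vs-automated
  comparison, rater bias not penalised); the two-way-*random* model
  defaults to absolute agreement
  `(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)` (multi-rater case). Either form
  is selectable by flag. Degenerate inputs (zero variance) raise.
* **Kendall's W** with mid-rank ties and the standard `Σ(t³−t)` tie
  correction. Note the chance level of W for m independent raters is 1/m,
  not 0.
* **QCD** `(Q3−Q1)/(Q3+Q1)` with linear-interpolation quartiles (the choice
  affects the second decimal at most); the limit value 1 is returned when
  Q1+Q3 = 0 with Q3 > 0.
* **Bland–Altman for non-uniform differences**: OLS of |ref − auto| on
  √(mean of the pair); 95 % limits `±(a + b√x) · 1.96·√(π/2)`, zero-centred
  (the model carries no offset term), with negative predicted absolute
  differences clipped to 0 — relevant at small x when the fitted intercept
  is negative. On data whose |Δ| is genuinely half-normal with mean
  `a + b√x`, the fitted limits cover ≈ 95 % of differences; the suite
  checks 95 ± 1 % on 10⁴ simulated pairs.

## Problem sizes and numerical choices

The synthetic pipeline experiment trains on 50 phantoms and evaluates on 50
held-out phantoms (32 × 80 × 80 voxels, 20 HU noise, no blur) — large
enough that all five strata occur and the candidate pool exceeds 150, small
enough to run in well under a minute per stage on one CPU. Texture filters
are precomputed once per volume and shared across candidates. Atlas and
texture sampling use trilinear interpolation; outside-frame atlas lookups
return 0 by contract. All randomness flows through explicit
`numpy.random.default_rng` seeds; repeated generation is bit-identical.

## Known limitations

* Territories are geometric boxes; no per-artery (LM/LAD/LCx/RCA/PDA)
  attribution, no stents, no metal artifacts.
* The reliability values reported for the original patient cohort (ICCs of
  0.90/0.88/0.64, Kendall's W 0.88) depend on unavailable clinical scans
  and are not recomputed here; the synthetic held-out properties stand in
  as the pipeline's acceptance surface.
* The Agatston thickness normalisation for overlapping reconstructions is
  a convention choice (factor 3.1/3, documented above), not a published
  calibration.
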