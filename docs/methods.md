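# Methods

## The measurement

Each imaged cervical site contributes one short fluorescence movie taken
through a coherent fiber bundle in contact with proflavine-stained
epithelium.  One representative frame is chosen, an operator region of
interest (ROI) is applied, and the frame is contrast-equalized (CLAHE),
median-filtered to suppress the bundle's honeycomb pattern, and thresholded
into a binary nuclear mask.  After removing objects smaller than 50 px or
larger than 1500 px (strict bounds; 50 px and 1500 px objects are kept), the
site's statistic is the nuclear-to-cytoplasmic area ratio

    N/C = nuclear_px / (roi_px − nuclear_px),

a ratio of totals, not a mean over nuclei — the wording "mean N/C ratio" in
clinical usage refers to this pooled quantity, and the ratio-of-totals
definition is the one implemented.  A site is called neoplastic when
N/C > 0.163 (strict inequality; a site exactly at the cutoff is negative).
High-grade dysplasia (CIN 2/CIN 3) is the positive class; HPV effect and
CIN 1 (low grade) pool with normal/benign as negatives.

## Synthetic study conditions

The generator stands in for clinical images and defines the conditions every
test runs under:

- **Geometry.** 720 µm circular FOV sampled at 1 µm/px (so the disc is
  720 px across); triangular core lattice with 4 µm nearest-neighbor spacing
  (the instrument's quoted lateral resolution) and 2.5 µm cores rendered as
  Gaussian bumps.  The pattern multiplies the scene, is normalized to unit
  mean inside the FOV, and its peak fractional modulation defaults to 0.2.
- **Nuclei.** Non-overlapping ellipses (equivalent-circle radius 5–9 px,
  eccentricity ≤ 0.4) placed by rejection sampling until the pixel-counted
  N/C is within 0.002 of the request (the API guarantees ≤ 0.005).
  Non-overlap keeps the ground truth exactly countable and the segmentation
  oracle unambiguous.  Nuclei are flat-topped (peak 0.75 vs background
  0.25 of dynamic range), which makes noiseless frames exactly
  threshold-separable — deliberate, so segmentation correctness is testable
  bit-for-bit.
- **Noise.** Poisson shot noise at 2000 photons per full-scale pixel plus
  Gaussian read noise of 0.01 of dynamic range, both optional.  No value is
  claimed for the clinical instrument; these were chosen once as plausible
  for an LED/CCD system.
- **Cohort.** Per-diagnosis analyzable-site counts default to the study
  table (Normal 5, Inflammation 7, HPV effect 11, CIN 1 7, CIN 2 2,
  CIN 3 12; 44 sites).  True N/C per site is drawn from a Beta distribution
  with per-diagnosis mean (0.06, 0.07, 0.08, 0.10, 0.19, 0.22) and sd
  (0.015–0.03).  The low-grade and high-grade anchors are the two printed
  exemplar ratios (0.08, 0.22); the remaining means and all dispersions are
  configuration, not claims — the study never prints its group means.
  `artifact_fraction` adds extra sites rendered to fail QC (defocus over
  ~72% of the FOV plus inter-frame motion) on top of the analyzable mix;
  at 8/52 this reproduces the study's 52-imaged / 44-analyzed arithmetic.
- **Movies** default to 5 frames (3-second clinical movies at video rate
  would be hundreds); the pipeline only needs enough frames to exercise
  selection and motion scoring, and several whole-cohort tests use
  single-frame movies and a 240 µm FOV to keep runtimes in seconds.

## Quality control

The discard rules are: out-of-focus fraction > 0.5, motion score > 0.3, or
debris fraction > 0.05.  The study states the 50% focus rule but no metric;
the metrics here are the package's own design:

- **Focus.** Defined by resolvability of the fiber-core lattice — the bundle
  face sits at a fixed optical conjugate, so a focused image always carries
  the honeycomb, and defocus removes it along with all other fine structure.
  The three independent reciprocal-lattice spot frequencies (fundamental at
  2/(√3·s) cycles/px for core spacing s) are located once per frame from the
  whole-field power spectrum; each 32 px tile, normalized by its own mean
  intensity, is then matched-filtered at those exact frequencies and is in
  focus when the matched power reaches 6× its high-frequency noise floor
  (with a 1e-5 absolute guard against spectral leakage in noise-free
  frames).  Tiles whose lattice carrier is swamped by strong in-focus
  nuclear edges are rescued by a second channel: noise-subtracted mid-band
  variance ≥ 1.5e-3.  Both thresholds were calibrated once on synthetic
  sharp vs. defocused frames (per-tile accuracy 99.4% / 100% in that
  calibration) and are exposed in `QCThresholds`.  Mean normalization makes
  the decision invariant to rescaling intensities by any positive constant.
- **Motion.** One minus the best normalized cross-correlation with a
  temporally adjacent frame.  The minimum over neighbors is used so a frame
  is penalized only when it matches neither neighbor; this also makes frame
  selection provably invariant to appending a fully penalized (e.g.
  all-black) frame.
- **Debris.** Connected saturated regions larger than 1500 px (the same
  bound the size filter treats as debris), as a fraction of the FOV.
- **Selection.** The representative frame maximizes (in-focus tile fraction
  − motion score − debris fraction); ties break to the lowest index.  The
  study's choice was manual and blinded; the automated score is a
  deterministic surrogate, and the CLI accepts a per-site override.

## Numerical choices

- CLAHE: 8×8 tile grid, clip limit 0.01, on intensities normalized to
  [0, 1]; pixels outside the FOV are replaced by the inside mean before any
  windowed filter so nothing inside the FOV depends on values recorded
  outside it, and are re-zeroed afterwards.
- Median filter: disc footprint, default radius ceil(0.75 × core spacing)
  = 3 px.  A radius-3 disc spans about one lattice cell and suppresses the
  periodic pattern to ~25% of its amplitude while radius-6 px nuclei retain
  ≥ 90% of their area; a radius-4 disc reaches ~10% residual but erodes the
  same nuclei below 90%.  The default favors nuclear-area fidelity (the
  quantity the statistic depends on); the radius is a parameter.
- Threshold: Otsu's between-class-variance maximizer computed within the
  ROI only, as the initializer for the study's operator-adjusted threshold;
  per-site overrides are accepted.  With a 256-bin histogram over the data
  range the suggested threshold is equivariant under affine intensity maps.
- Connectivity: 8-connected components, labels in raster order of first
  pixel; objects touching the ROI boundary are retained (no edge-exclusion
  rule is stated for the study); a flag can exclude them.
- Group tests: classical pooled-variance two-sample t, two-sided (Welch and
  Bonferroni variants behind flags, default off, matching the study's raw
  pairwise reporting).  QC-failing sites are excluded from all statistics.
- ROC: operating points at all midpoints between distinct scores plus
  sentinels; AUC by the trapezoidal rule walking the curve in decreasing
  cutoff (equals the Mann–Whitney U/(n₁n₂) with half-credit for ties);
  Q-point = closest point to (FPR 0, sensitivity 1), ties to higher
  sensitivity then lower cutoff; Youden-J selection also reported.
- Percentages are reported at full precision and rounded half-up to integer
  percent for presentation.

## What the synthetic study does and does not show

Passing tests establish that the pipeline is self-consistent: it recovers
known ground-truth N/C within ±0.02 under the default noise across
0.05–0.30, segments noiseless frames exactly, applies the stated QC
arithmetic (52 rendered → 44 analyzed at the default artifact fraction), and
separates high-grade from benign categories with p far below 0.05 at the
study's sample sizes.  The default synthetic cohort is *more* separable than
clinical data — its fixed-cutoff sensitivity/specificity and AUC come out
near-perfect, compared with the study's 86%/87% — because rendered nuclei
are clean ellipses with uniform staining and the category distributions are
well-separated Beta laws.  Crowded/overlapping nuclei, pleomorphism,
staining heterogeneity, glare, and operator ROI variability are not modeled,
so agreement on synthetic data does not by itself validate clinical
performance.  The exact per-site clinical N/C values, the study's group
means and its exact t-test p-values would require the original images and
are not claimed.

## Known limitations

- The 50/1500 px size bounds and the 0.163 cutoff are applied verbatim in
  pixel units; whether they were magnification-dependent in the original
  software is unknowable from the text.
- Focus detection presumes the honeycomb is present (pattern amplitude > 0)
  or that in-focus tissue edges carry mid-band power; a pattern-free,
  texture-free frame is reported out of focus by construction.
- Sites are treated as independent; no per-patient clustering adjustment is
  made (the study analyzed sites independently).
- Touching nuclei are not split (no watershed); the statistic is area-based
  and the study applied none.
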