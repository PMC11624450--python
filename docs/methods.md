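# Methods

This note documents the models, conventions and design choices behind
`babylength`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Scene model and synthetic generator

The generator (`babylength.synthetic`) emulates the capture protocol the
pipeline assumes: a supine child and a standard-size card
(85.6 mm × 54.0 mm) on a flat support surface, photographed from above.

**Camera.** A pinhole camera at height *h* (default drawn uniformly from
1000–1300 mm) with focal length 1280 px and a 1280×960 px sensor. The
ideal capture is perpendicular (`tilt = 0`), where the plane-to-image map
is an exact similarity with scale `s = focal/h` px/mm (≈ 1.0–1.3 px/mm).
A *tilt* defect re-positions the camera at a zenith angle drawn from
15–30° while still aiming at the scene centre — how a photographer
leaning sideways actually holds a phone — with the azimuth near one of
the four sides of the mat (±10° jitter).

**Body.** A 2-D capsule chain on the support plane. Landmarks are placed
so that the *measured* chain — crown → mid-shoulder → mid-hip plus the
left/right leg-chain means — sums exactly to the child's true length:
paired joints sit symmetrically about the body axis and along-axis gaps
are solved from the prescribed segment lengths (`Δx = √(ℓ² − Δy²)`).
True lengths are uniform on 450–850 mm (only an age range 0–18 months is
specified for the population; uniform sampling exercises the model across
the whole range rather than concentrating mass mid-range). Segment
proportions jitter around an infant-typical profile
(0.235/0.305/0.195/0.195/0.07) and body half-width is 9–13 % of length.
Recorded ("length-board") measurements add zero-mean Gaussian error of
2 mm — the scale of expert duplicate measurement — rounded to 1 mm.

**Card.** Placed beside the body, 10–100 mm from the silhouette edge,
roughly aligned with the body axis (±10°, sometimes rotated 90°). The
*card_body_overlap* defect instead centres the card on the torso's
lateral edge, resting on/against the child and drawn on top of the body:
a card slid fully *under* the torso would simply be an unsuccessful card
segmentation, not an overlap warning, because no non-learned detector can
recover an invisible quadrilateral. The *card_off_plane* defect raises
the card 20–60 mm above the surface, inflating its apparent scale — a
bias no warning can detect from a single view, deliberately left
unflagged.

**Rendering.** Flat-shaded: gray background (118), dark body (52), card
with a blue excess (B − R = 64) so a colour detector can segment it.
Scenes are rasterised at 2× and box-downsampled, giving edge pixels
fractional coverage like a real photograph; the card polygon is rasterised
with a subpixel-aware point-in-polygon fill because integer-truncating
polygon fills introduce ±0.5 px edge bias, which would drown the tilt
signature the warnings must detect. Additive Gaussian pixel noise
(σ = 2/255) is applied last. Defects: blur (Gaussian, σ 1.5–3 px),
low contrast (compression toward the mean by 0.45), baggy contour
(widened, irregular silhouette), occlusion (a cover rectangle over one
body region, whose landmarks are also withheld from providers).

The generator does **not** model: photorealistic texture and lighting,
3-D limb articulation out of the support plane, lens distortion, clothing
folds, or learned-detector failure modes. Passing tests therefore
demonstrate the internal consistency of the geometry, training protocol
and metrics — not field performance on real photographs.

## Card detection and pixel-per-metric

Detection is classical: threshold the blue-excess channel (> 20 of 64),
keep the largest connected component, fit the maximum-area quadrilateral
inscribed in its convex hull, then refine each corner by intersecting
total-least-squares lines fitted to half-contrast crossings of intensity
profiles sampled across each edge (window ±6 px, wide enough to straddle
a blurred edge). On clean scenes this yields ≈ 0.1 px RMS corner error
and < 0.2 % pixel-per-metric error. The provider is pluggable so a
learned detector/segmenter can be swapped in behind `CardDetection`.

Scales: the two longer opposite edges are averaged and divided by
85.6 mm (`scale_w`), the shorter pair by 54.0 mm (`scale_h`);
`pixel_per_metric` is their arithmetic mean. A single global scale is
used (no per-region calibration).

## Warnings and their thresholds

All four warnings are pure functions of detected geometry with strict
inequalities (an exactly-at-threshold value does not warn):

* **W0** — filled card quad intersects the body bounding box with
  positive area. The box is the landmark bounding box padded by 0.15 ×
  the shoulder span (landmarks sit inside the silhouette).
* **W1** — observed aspect ratio deviates from 85.6/54.0 by more than
  0.8 %. The observed ratio is the *worst per-corner* adjacent-edge
  ratio rather than the ratio of opposite-edge means: the per-corner form
  also reacts to keystone (opposite-edge convergence), which is the only
  signature left when the card happens to lie near the ground footprint
  of a tilted camera, where the local view is perpendicular and
  anisotropy vanishes.
* **W2** — IoU between the segmentation mask and the filled fitted quad
  below 0.90 (IoU chosen as the mask-agreement statistic).
* **W3** — |scale_w − scale_h| / mean > 0.5 %.

The W1/W3 tolerances were calibrated against the projection physics of
the generator, not chosen by convention: a 15° oblique capture produces
only ~3–6 % scale anisotropy at the image centre and ~0 % at the camera
footprint, while clean-scene detection noise after subpixel refinement is
< 0.3 %. The chosen cutoffs separate these regimes (measured: ≥ 15°
tilt flagged in > 99 % of scenes, clean false-positive rate ≈ 2 %). A
coarser, convention-style 10 % tolerance would miss essentially all
realistic tilts. All three thresholds are exposed in `WarningConfig`.

Blur and glare are *not* warned on (the warning set is exactly W0–W3);
blurred scenes may still trip W1/W3 when the smeared edges genuinely
degrade the calibration.

## Features and length model

Per image: the five segment lengths in mm (pixels / ppm), total chain
mm, ppm, scale_w/scale_h ratio, mean landmark confidence, and image
diagonal (px). Features are only produced when both extractions succeed.

The regressor is a bagging ensemble (default 30 bootstrap members) of
unlimited-depth decision trees; member type, count, depth and the
aggregation rule (mean, optionally median) are configuration. The
prediction is exactly the mean of member predictions.

**Two-step training.** Step 1 fits on all (warning-free) rows; per-row
training absolute errors are computed; rows with AE at or below the 90th
percentile (linear-interpolation percentile, boundary inclusive) are
retained; step 2 refits on the retained rows. With 10 rows at least 9
are retained. A +300 mm label outlier is removed in ≈ 100 % of seeded
runs. On clean data trimming is essentially inert.

**Fold assignment.** Children are sorted by measured length and dealt to
5 folds in snake order (participant counts within one, interleaved
length distributions), followed by a local swap pass between
length-adjacent children to balance per-fold image counts. Invariants
checked programmatically: counts within one, image totals within 20 % of
the mean, per-fold length distribution within KS distance 0.25 of the
pooled distribution. These balance bounds are properties of study-scale
cohorts; with only a handful of children per fold they can be
arithmetically unattainable (e.g. 12 children over 5 folds), so the CLI
reports rather than rejects violations on small cohorts.

**HPO.** Seeded random search; each trial samples member count, depth
and a random feature subset, scored by mean warning-free validation MAE
across the 5 folds; ties and reproducibility are governed by one seed
stream. The search is deliberately framework-free — the search space is
small and a reproducible argmin over seeded trials is the entire
requirement.

**Seeding.** One master seed derives all streams (generator,
measurement error, per-image render noise, landmark noise, fold
assignment, bagging, HPO) through `numpy` `SeedSequence` spawning; all
derived seeds stay below 2³¹.

## Evaluation conventions

Errors are computed and reported in cm (`E = measured − predicted`);
internal lengths are mm throughout. Failures are excluded from means and
counted by reason. Participant averages use the unweighted mean of a
child's successful image predictions (sorted before summation so the
result is exactly independent of processing order) and require at least
9 images by default — the protocol's choice, exposed as a flag. The
warning sweep enumerates all 16 ignore-subsets; its empty-subset row
equals the metrics restricted to warning-free images. TEM uses the
standard two-measurer form `sqrt(Σd²/2N)`; published WHO (0.48, 0.70 cm)
and clinic/community (1.41, 1.25–1.59 cm) interobserver TEMs are carried
as reporting constants only, with no pass/fail verdict.

## Problem sizes in the bundled experiments

The test-suite and acceptance-script cohorts are sized for a single CPU:
geometry oracle 100 scenes; defect→warning rates on 400 scenes;
cross-validated parameter recovery on 200 children × 6 images at 2, 4
and 6 px landmark noise (MAE ≤ 10 mm required at 2 px, monotone
degradation across the three); a mixed-defect 60 × 12 cohort for the
success-rate and sweep quantities; 50–100 seeded runs for trimming
reliability. With these sizes the cross-validated MAE at 2 px noise is
≈ 4 mm — the synthetic task is easier than real photography, and the
number demonstrates correct parameter recovery, not clinical accuracy.

## Known limitations

* Landmarks come from ground truth (plus isotropic noise) unless an
  external pose model is adapted; infant-specific pose failure modes are
  represented only by the occlusion defect.
* The card-off-plane scale bias is undetectable from a single view by
  design; a real deployment would need scene priors or depth data.
* The silhouette is schematic; the baggy-contour defect perturbs the
  rendered outline but not the landmark geometry, so it degrades nothing
  in the synthetic pipeline — it exists to exercise detectors that use
  the contour.
* Uniform length sampling and equal images per child make fold balancing
  easier than a clinical cohort with enrolment skew would be.
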