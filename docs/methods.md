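# Methods

This note documents the models and procedures implemented in `psrmorph`,
the defaults they use, and what the synthetic validation does and does not
demonstrate.

## Problem setting

Picrosirius Red stains collagen fibres red; the counterstain renders
myocytes orange/yellow; adipocyte vacuoles, vessel lumens and the slide
background are unstained (near-white). Given a calibrated RGB section image
(µm/px) and, for free-wall samples, an epicardial-surface annotation, the
pipeline measures the percentage of analyzable tissue area occupied by
collagen, fat and myocytes — total and per epicardial/endocardial half —
and models those percentages across hearts and sampling locations.

## Pixel classification

Classification operates in HSV. Defaults: near-white pixels
(saturation ≤ 0.25, value ≥ 0.72) are background; red-band pixels
(hue 0.88–1 or 0–0.055 with saturation ≥ 0.25) are collagen; orange/yellow
pixels (hue 0.055–0.30) are myocytes. Overlaps resolve in priority order
background → collagen → myocyte (low-saturation pixels have unstable hue,
so the white test runs first). Pixels in no band are assigned the nearest
class centre in the colour-cone embedding `(s·cos 2πh, s·sin 2πh, v)`,
which makes hue distance circular and hue irrelevant at zero saturation;
the label field therefore always partitions the image.

These thresholds are **not** the unpublished settings of any commercial
analysis application; they were calibrated on this package's synthetic
fixtures. Real slides require explicit user calibration via the config
file (`PipelineConfig.color_bands`). RGB banding is supported by supplying
bands in an `HSVBand`-shaped dialect after conversion, but HSV is the
default because stain hue separates red collagen from orange myocytes more
robustly than raw channels.

## Fat detection

Fat is geometrically defined: an *enclosed* unstained component is a
vacuole, while border-connected white area is slide background. A
provisional-background component is relabelled fat when it (a) does not
touch the image border, (b) has area within
[`min_area_um2`=40, `max_area_um2`=320] µm², and (c) has solidity ≥ 0.85
after a closing with radius 1 px. The areas are physical so the filter
respects calibration; the defaults bracket the synthetic vacuoles
(radius 5–9 µm) and deliberately sit below the lumen area floor (350 µm²)
so fat and lumen candidates never compete. For real adipocytes
(30–150 µm across) the area band must be raised accordingly. Whether real
tissue clefts bordering the section edge should count as fat is
unknowable from the available description; border-connectivity is this
package's convention.

## Vessel exclusion

Perivascular collagen scales with vessel caliber, which varies strongly
between samples, so it is excluded from fibrosis quantification.

**Elliptical score.** The score of a candidate region is the
intersection-over-union between the region's pixel set and its
moment-matched filled ellipse (same centroid and second-order central
moments; semi-axes `2√λ` of the coordinate covariance eigenvalues). It is
1 exactly for discretised ellipses, scale-invariant, exactly invariant
under integer translation and 90° rotation, and low for elongated or
branched shapes. This is a documented **reconstruction**: it makes the
published acceptance threshold of 0.4 operational, but it is not the
proprietary vendor formula. Degenerate (collinear) regions score 0.

**Lumen candidates.** Fat detection runs first; the remaining enclosed
background components with area ≥ `min_lumen_area_um2` (350) are scored
and accepted iff score ≥ `score_threshold` (0.4). Candidates are ordered
by centroid for reproducibility.

**Cuff reach.** Excluded perivascular collagen is the set of
collagen-labelled pixels geodesically reachable from the lumen within the
collagen class — one 8-connected dilation step per unit distance
(Chebyshev metric) — capped at `cuff_reach_factor` (2.0) × the equivalent
lumen radius `sqrt(area/π)`. The cap scales the excluded cuff with vessel
caliber; the value 2.0 is a design choice, configurable, and also a
reconstruction (no reach definition is published). Geodesic connectivity is
evaluated on the pre-exclusion collagen mask, so the reaches of nearby
vessels union independently. Myocyte and fat pixels are never relabelled.

## Epicardial/endocardial partition

The 50:50 split of total tissue area is implemented as an equal-area
distance-rank partition: every analyzable-tissue pixel gets an exact
Euclidean distance (pixel centres, `scipy` distance transform) to the
annotated epicardial surface; the cut is the whole-distance-stratum
threshold bringing the nearer half closest to 50% of tissue area. Whole
strata are never split, so the halves can differ by at most one stratum;
the equal-area reading is the only one that guarantees a 50:50 area split
on arbitrary wall shapes. Septal samples have no epicardial surface and
are quantified whole. Whether the original analysis split by area, by
wall-thickness midline or manually is unstated; equal-area is this
package's choice.

## Composition

Percentages denominate analyzable tissue: collagen + fat + myocyte pixels,
with excluded lumen and perivascular pixels removed from numerator *and*
denominator — keeping them in the denominator would silently deflate all
three percentages. Tissue area is `pixels × (µm/px)² × 10⁻⁶` mm². The
right-ventricular free-wall samples of a heart are pooled by pixel counts
before percentages are formed; the outflow tract keeps its own location
label but maps to the RV analysis group.

## Multilevel model

Per component, `log(value)` is modelled with cell-mean fixed effects for
every (location × region) cell plus optional covariates (sex coded F=1;
age and BMI centred at their sample means), and a random intercept per
heart; estimation is REML via `statsmodels MixedLM`. Conventions:

* Geometric means are `exp(estimate)`; 95% CIs are `exp(est ± 1.96·SE)`
  (Wald, z = 1.96, no small-sample df correction at ~29 clusters).
* Ratios between cells are `exp(difference)` with the difference SE taken
  from the fixed-effect covariance; two-sided Wald p-values; no
  multiplicity adjustment.
* Zero proportions (possible for septal fat) break the log transform;
  default policy replaces them with half the smallest positive observed
  value for that component and warns; `zero_policy="fail"` raises instead,
  naming the offending rows.
* Noise-free (zero-residual) input makes the mixed likelihood singular;
  the fit then returns the exact OLS projection with zero variance
  components, tagged `degenerate-zero-variance` rather than masking the
  singularity.
* Covariate predictions are evaluated at sample-average covariates
  (centring), keeping cell estimates interpretable as adjusted geometric
  means. A rank-deficient design (e.g. a constant covariate) is an
  explicit error.
* Each component and region-scope is fitted as a separate model; the
  original study's exact fixed-effect structure is unstated.

## Synthetic data

`generate_slide` draws: a tissue slab with configurable margin, epicardial
side and optional sinusoidal curvature; elliptical vessel lumens (semi-major
15–24 px by default, axis ratio 0.6–0.95) wrapped in collagen cuffs of
requested thickness; enclosed circular fat vacuoles; and interstitial
collagen obtained by thresholding a smoothed Gaussian noise field at the
exact pixel count matching the target fraction. Classes are rendered as
Gaussian RGB clouds around documented centres (collagen ≈ (178,34,48),
myocyte ≈ (235,158,58), unstained ≈ (246,244,242); SD 6). All placement
flows from one seed; identical specs are bit-identical. Unattainable
requests (vacuole packing, collagen exceeding the free interstitium) raise
`PackingError` rather than truncating silently.

Reported `true_fracs` denominate analyzable tissue (tissue minus the
perivascular cuff), i.e. exactly the quantity the pipeline is specified to
recover; the cuff itself is collagen-class in the truth mask and lumens
are background-class.

Fixture-specific choices worth knowing:

* a 2 px collagen-free moat separates cuffs from interstitial collagen so
  each cuff is a distinct structure. Real interstitial collagen can abut
  the cuff, in which case geodesic exclusion would remove some connected
  interstitial collagen within reach — the <1% collateral figure measured
  on fixtures does not transfer to such tissue;
* class boundaries are sharp (no optical blur, no stain-batch variation,
  no scanner artefacts), so near-perfect colour classification on fixtures
  is an upper bound, not a claim about real slides;
* vessels and vacuoles never touch the slide border, sidestepping
  partial-structure edge cases.

`generate_study` simulates the clustered study design: per heart one
shared log-normal random intercept (SD 0.3 by default) plus row-level
residual noise (SD 0.2), around per-cell log means defaulting to published
normal-myocardium reference geometric means (collagen 15.2/8.6/9.5%, fat
12.3/1.5/4.7%, myocytes 65.9/88.6/81.2% for RV/IVS/LV totals). The
magnitude of real within-heart correlation is not reported anywhere; the
default SDs are fixture choices, not estimates. Demographics mirror the
modelled autopsy series (≈ 4/29 female — the female count is fixed and
shuffled so the sex covariate is never accidentally constant — age
32.1 ± 9.9 y, BMI 28.7 ± 7.3).

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate on: a 12-slide grid of
1024² sections spanning collagen 5–20% × fat 0–12%; partition checks on a
401×300 slab and a 768² curved wall; and 500 simulated 29-heart studies
for ratio recovery, CI coverage and covariate type-I calibration (truth
ratios 1.77 collagen RV/IVS and 2.63 fat RV/LV). These sizes give
Monte-Carlo error well below the tolerances being checked while keeping a
full run around a minute on one CPU.

## Known limitations

* Colour thresholds, the elliptical-score formula and the cuff reach are
  reconstructions of an unpublished commercial workflow; agreement with
  that workflow on real slides is untested and untestable without its
  settings.
* No stain deconvolution, no machine-learned classification, no
  photorealistic texture in the generator.
* Wald inference without df correction is slightly anticonservative at a
  few dozen clusters (measured covariate type-I error ≈ 5–6% at nominal
  5%).
* No whole-slide pyramidal formats; images must fit in memory as RGB
  arrays.
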