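# Methods

## The counting problem

A bone-marrow aspirate (BMA) differential cell count (DCC) reports the
proportion of each nucleated cell type among counted cells on a stained
smear. On a whole-slide image (WSI) only the body–tail junction band is
countable: the smear body is too thick (cells overlap), the tail too
sparse and lytic. `marrowdcc` models the full automated workflow as five
chained stages, each behind a backend contract so that classical reference
implementations, ground-truth oracles and (externally trained) deep models
are interchangeable:

1. **ROI segmentation** — the WSI thumbnail (downscale factor 100) is
   resized longest-side to 256 px with zero padding, a backend predicts a
   binary junction mask, and the mask is restored to thumbnail shape.
2. **Tiling** — the WSI is cut into non-overlapping 1600 px grid tiles;
   a tile is retained when the area-weighted fraction of its footprint
   covered by ROI foreground (measured on the thumbnail raster) reaches
   τ = 0.5.
3. **Tile-of-interest (TOI) filtering** — retained tiles are resized to
   224 px and classified TOI / non-TOI, removing blank, over-stained and
   otherwise uncountable tiles.
4. **Cell segmentation** — each TOI is resized to 1024 px and a promptable
   segmenter is prompted at every node of a 32×32 point grid
   ("segment everything"); predictions are filtered by quality score
   (≥ 0.5) and area (80–40 000 px²) and deduplicated by greedy
   non-maximum suppression on mask-derived bounding boxes (IoU 0.7,
   ties: larger area, then prompt raster order).
5. **Cell classification and counting** — every candidate is cropped as a
   square (`max(w, h) + 2·offset`, offset 12 px, zero-padded at tile
   borders), resized to 224 px and classified over a fixed 22-class
   taxonomy; the 16 countable classes form the DCC, the other six
   (apoptotic cell, atypical lymphocyte, immature lymphocyte,
   prolymphocyte, smudge cell, others) are tallied but excluded from the
   denominator, matching manual counting practice.

Two clinical gates follow the classifier: a per-cell review flag when the
top-class probability is below 0.60, and a slide-level "automatic
rescreening" alert when more than one class shows a misclassification
rate ≥ 0.10 on a labelled validation run. The misclassification rate is
read as per-class `1 − recall` from a validation confusion matrix
(offline), and the 60% gate applies to the maximum class probability;
both phrasings admit an online/other reading, and the offline/max-probability
reading was adopted as the more testable one.

## Agreement statistics

Automated and manual DCCs are compared as 16-vectors of proportions (not
raw counts — proportions are what a manual differential reports):

* Pearson correlation (`scipy.stats.pearsonr`), undefined (flagged `None`)
  when either vector is constant;
* Lin's concordance correlation coefficient with population
  (n-denominator) moments,
  `CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`, which satisfies
  `|CCC| ≤ |r|` with equality iff the first two moments match;
* Bland–Altman limits of agreement `d̄ ± 1.96·SD(d)` with the sample
  (n−1) standard deviation of the paired differences.

## Synthetic smears

Real BMA WSIs are large and not redistributable, so the package ships a
seeded generator whose output carries exact ground truth for every stage.
The default scene is a 16 000 × 16 000 px slide (10×10 grid of 1600 px
tiles, 160 px thumbnail) — large enough for a realistic stage funnel,
small enough that a full reference run takes a couple of minutes on one
CPU.

* **Bands.** Horizontal body/junction/tail bands with fractions
  (0.40, 0.30, 0.30), aligned to tile boundaries so the ground-truth
  retained set is unambiguous. The body is rendered as coarse
  high-contrast blotches (400 px, i.e. several thumbnail pixels) — at
  thumbnail scale a fine-grained texture would average out and the body
  would look *flat*, inverting the intended texture ordering
  body > junction > tail that the reference ROI backend relies on.
* **Cells.** Non-overlapping ellipses (64-point boundary polygons,
  rasterised by polygon fill; the same polygons are serialised to
  Labelme-style JSON so re-rasterisation from disk is bit-exact).
  Class identity is encoded by radius range (28–56 px) and a
  deterministic (cytoplasm, nucleus) colour pair: 11 hues × 2 value
  rings, all well below background luminance so a global dark-object
  threshold captures whole cells. A minimum 8 px gap keeps components
  separable after the 1600→1024 resize. The default class-proportion
  vector is a hand-set marrow-like differential (granulocytic series
  dominant, erythroid ≈ 20%, lymphocytes 17%, excluded classes at
  fractions of a percent).
* **Cell load.** Poisson-distributed with mean 40 cells per good tile;
  with ~25 good junction tiles this yields roughly a thousand effective
  cells per slide, the order of magnitude of a generous manual count.
* **Bad tiles.** 15% of junction tiles are blank or over-stained
  (luminance-scaled with a purple cast); the tail carries faint red-cell
  clutter only.
* **Noise.** Luminance-only Gaussian sensor noise plus per-tile
  multiplicative brightness/contrast jitter (±5%) standing in for stain
  variability.

Deliberately **not** modelled: touching/overlapping cells, photorealistic
chromatin/cytoplasm texture, scanner artefacts, pyramidal WSI formats.
Passing tests therefore demonstrate the correctness of the orchestration,
geometry, filtering, counting and statistics — not that the shipped
classical backends would survive real Wright–Giemsa material; on real
slides the backends are expected to be replaced by trained models behind
the same contracts.

## Reference backends and their calibration

* **ROI (texture band-pass).** Local variance (15×15 uniform filter) on
  the padded 256 px thumbnail; keep pixels whose variance lies between
  the 0.30 and 0.70 distribution quantiles; largest connected component;
  morphological closing (disk 5). The quantile window is calibrated to
  the default scene geometry: the lower cut sits at the tail's pixel
  share, the upper cut at the tail+junction share — an upper cut far
  above it necessarily admits the body band, whose texture energy is
  highest. On the default scene this backend reaches IoU ≈ 0.75 against
  the ground-truth band.
* **TOI (blob count + luminance gates).** Dark-blob count in [8, 150]
  and mean luminance in [180, 252] on the 224 px tile; score is a product
  of soft sigmoid gates. Blank/tail tiles fail the lower blob bound,
  body texture explodes past the upper bound, over-stained tiles fail the
  luminance floor.
* **Promptable segmenter (Otsu + connected components).** Dark-object
  Otsu threshold on luminance; a prompt returns its connected component
  (empty on background). Quality score is the isoperimetric circularity
  `4πA/P²` clipped to [0, 1]. Component masks are cached per image so
  the 1024-prompt grid costs one labelling pass.
* **Cell classifier (nearest centroid).** Seven features per crop —
  object area fraction, mean object RGB, mean RGB of the darkest 40% of
  object pixels (nucleus proxy) — standardised by training statistics;
  per-class prototype means; probabilities are a softmax of negative
  squared distances. Prototypes are fitted at pipeline start on a
  balanced all-junction synthetic scene (uniform class proportions,
  seed derived from the run seed). The softmax temperature (0.5) is set
  so the fraction of ≥60%-confident predictions tracks accuracy on a
  balanced validation split, keeping the review gate informative.
  A featureless crop returns the uniform vector (no evidence).

## Numerical conventions

* 0-based coordinates, `(x, y) = (col, row)`, half-open boxes.
* All pixel arithmetic rounds half away from zero; one rounding rule
  everywhere.
* Longest-side resize splits the short-side padding deficit
  floor/ceil (leading/trailing). Mask restoration strips padding first,
  then nearest-neighbour rescales (preserving {0, 1}); images are
  interpolated bilinearly.
* ROI coverage of a tile is computed on the thumbnail raster with exact
  area weights for partial thumbnail pixels; it equals coverage measured
  on a full-resolution upsampled mask.
* Empty∩empty segmentation metrics are defined as 1 (nothing to
  disagree about); empty ground truth makes recall undefined and raises.
* Argmax ties in classification resolve to the lowest taxonomy index.
* Per-class misclassification rates are computed as
  `(rowsum − diagonal)/rowsum` so rates like 10/100 compare exactly
  against the 0.10 alert threshold.
* The single run seed is fanned out per stage as
  `(seed·1_000_003 + crc32(stage_name)) mod 2³¹`.

## Problem sizes used in the shipped checks

Oracle-closure runs use a 4800² scene (3×3 tiles, one band row each) with
a 64×64 prompt grid — dense enough that every cell's inscribed disc
(radius ≥ 17 px at the 1024 working scale) contains a grid point, which
guarantees full recall by construction. Reference-backend recovery runs
use the full default 16 000² scene. Statistical calibrations use 1 000
random mask/vector pairs and 10 000 Gaussian differences; brute-force
equivalence checks use 200 randomised instances of ≤ 5 candidates
(NMS) and ≤ 4 boxes (recall matching).

## Known limitations

* The generator's colour-coded classes make classification far easier
  than real morphology; accuracy numbers on synthetic scenes say nothing
  about real-slide accuracy.
* Touching cells are excluded by construction, so the NMS path is only
  exercised by duplicate prompts, not by genuinely ambiguous boundaries.
* The reference ROI backend assumes a horizontal three-band layout; on
  arbitrary smear geometries only the quantile logic, not the band
  prior, carries over.
* Partial edge tiles are dropped, so up to one tile-width of slide
  margin is never counted.
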