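# Methods

`dermatex` implements a classical multi-stage recognition pipeline for three
skin conditions — herpes, paederus dermatitis and psoriasis — from single
color photographs of an epithelium on a dark background. The pipeline has
three phases: geometric preprocessing, feature extraction (texture and
lesion area), and SVM classification. Because curated clinical photographs
cannot ship with the package, every stage is exercised on images from the
built-in synthetic generator, whose ground truth makes the stages testable.

## Preprocessing

1. **Median filtering.** A square window (default 3×3, edge-replicated
   borders) replaces each pixel by the median of its neighborhood,
   suppressing salt-and-pepper noise while preserving edges. The window is
   configurable; 3×3 removes isolated impulses without blurring the lesion
   textures the later stages measure.
2. **Binarization and orientation.** A global Otsu threshold separates the
   bright epithelium from the dark background. Only the largest connected
   component is kept and its interior holes are filled — dark lesion
   texture can dip below the global threshold, and the distance-transform
   ridge below needs a solid foreground. The long-axis angle θ is the
   principal-axis direction of the second-order central moments of the
   mask; the image is rotated by −θ (nearest-neighbor resampling onto the
   tight enlarged canvas ⌈w·|cos θ| + h·|sin θ|⌉ × ⌈h·|cos θ| + w·|sin θ|⌉)
   so the epithelium lies horizontal. Right-angle rotations are exact pixel
   bijections.
3. **Medial axis.** The Euclidean distance transform assigns every
   foreground pixel its distance to the nearest background pixel. Within
   the foreground's bounding rectangle, each occupied column contributes
   the row of maximal distance (ties resolved to the uppermost row); the
   row profile is smoothed with a 1-D median of window 5. This per-column
   ridge is the medial axis; it requires at least 10 occupied columns.
4. **Ten vertical regions.** The axis arclength is divided into ten equal
   spans. Every foreground pixel inside the bounding rectangle is
   projected onto the axis (nearest axis point); the arclength position of
   the projection selects the span, with exact boundary hits going to the
   lower-indexed span. The result is exactly ten pairwise-disjoint regions
   L1..L10 covering the boxed foreground, each intersecting the axis.

## Texture features

Gray levels are quantized uniformly from [0, 255] into L bins (default
L = 64). The co-occurrence matrix G(i, j) counts ordered pixel pairs
(p, p + offset) with both endpoints inside the region of interest,
accumulated over unit offsets at 0°, 45°, 90° and 135°, then symmetrized
and normalized to probabilities — the standard orientation-insensitive
Haralick construction. Five statistics summarize G:

* contrast Σ (i−j)² G(i,j) — depth of texture grooves;
* correlation Σ (i−x̄)(j−ȳ) G(i,j) / (σ_x σ_y) — linear dependence of
  paired levels (defined as 0, with a warning, when a marginal standard
  deviation vanishes, as happens on constant skin);
* entropy −Σ G log₂ G with 0·log 0 := 0 — information content; exactly 0
  for a texture-free region;
* uniformity (inverse difference moment) Σ G(i,j)/((i−j)²+1);
* energy Σ G², computed on the normalized table by default. A raw-count
  mode exists because energy magnitudes on unnormalized pair counts are
  orders of magnitude larger and some published feature tables are only
  consistent with that convention.

One feature record is computed per vertical region; a region too small to
form a pixel pair falls back to whole-image features with a warning.

## Lesion area

Most lesions of these three conditions are roughly circular, so the lesion
is quantified by pixel area rather than shape:

1. **Marker-controlled watershed.** The gradient magnitude (Sobel, after
   Gaussian smoothing with σ = 1.5 px) is flooded from its regional minima
   that survive h-minima suppression at depth h = 0.3 (0..255 gradient
   units). This deliberately over-segments the frame into many small
   basins; the low default keeps basins small enough that few straddle the
   lesion boundary, and the next stage merges them.
2. **Region clustering.** Each basin is summarized by mean color, mean
   intensity and log-size. Colors enter as opponent chromaticity
   (R−G, G−B) plus brightness: the diagnostic signal of erythema and scale
   is chromatic, while lesion *texture* is a brightness phenomenon, so
   chroma groups bright and dark parts of one lesion together where
   saturation-normalized hue splits them. A small deterministic k-means
   (farthest-point seeding from a seeded RNG, Lloyd iterations until the
   centers stop moving, cap 300) groups basins into k = 4 clusters with
   roles: the darkest border-touching cluster is background; among the
   rest, the cluster whose size-weighted median chroma lies farthest from
   the overall skin chroma is the lesion; the nearest is normal skin; the
   remainder is mis-segmented and rejoins lesion or skin by chroma
   distance. If the best lesion candidate sits closer than 20 chroma units
   to skin, no lesion is declared — this keeps normal skin at area ≈ 0.
3. **Morphology and area.** Regions fully enclosed by lesion are
   mistakenly-cut interior zones and are merged in (hole filling); the
   mask is then smoothed by a closing-then-opening with a disk of radius
   3 px. Closing runs first: opening first erodes around every pinhole
   before it can be filled and systematically eats lesion area. The
   statistic is the lesion pixel count and its fraction of the frame.

The lesion stage runs on the unrotated median-filtered color image: the
rotated canvas grows with θ (up to ~2× the original area), which would make
the area *fraction* depend on the incidental orientation of the epithelium
rather than on the lesion.

## Classification

Each image becomes an 11-dimensional feature vector: the (minimum, maximum)
over the ten vertical regions for each of the five texture statistics —
mirroring the minimum/maximum layout in which such features are
conventionally tabulated — plus the lesion area fraction. Features are
rescaled to [0, 1] per dimension from the training data (dimensions with no
training spread are dropped with a warning).

Binary subproblems are soft-margin RBF SVMs, f(x) = sgn(Σ aⱼ yⱼ k(xⱼ, x) + b)
with k(u, v) = exp(−‖u−v‖²/2σ²), trained one-vs-one by a deterministic
SMO solver (first multiplier scanned in index order, second chosen to
maximize |E_i − E_j|, tolerance 1e−3, convergence when a full pass changes
nothing). The penalty is C = 50, the value at which recognition peaks on
the reference data; σ defaults to the median pairwise training distance,
which is scale-free and deterministic. Multiclass decisions are majority
votes over the three pairs, ties resolved to the lowest class index
(herpes < paederus dermatitis < psoriasis). Three classifiers are trained:
SVM1 on the ten texture dimensions, SVM2 on the area fraction alone, and
the integrated SVM on all eleven; the integrated SVM produces the final
label, the others are diagnostics quantifying what each feature family
contributes.

Trained models serialize to a single versioned JSON archive (scaler,
per-pair support vectors, multipliers, bias, σ, C).

## Synthetic data

The generator emulates the structure the pipeline relies on, not
photorealism:

* an elongated bright foreground (super-ellipse, exponent 3, semi-axes
  0.44 w × 0.23 h, gray ≈ 125–200 with smooth low-frequency variation,
  slightly warm-toned) at a configurable orientation on a dark (0–20)
  background — giving the distance transform a clean ridge;
* a disk lesion of class-specific radius painted at the foreground center:
  psoriasis r = 40 px > herpes r = 30 px > paederus r = 20 px (the area
  ordering the pixel-area statistic exploits), each with a class-specific
  texture: herpes — sparse 2-px speckle at ±90 gray; paederus — dense 2-px
  grain at ±127 (the harshest fine texture); psoriasis — coarse 10-px
  patches at ±25. Each class also carries a fixed chromatic tint
  (erythema-like for herpes/paederus, scale-like for psoriasis) that the
  lesion-segmentation stage detects. Texture is additive in gray, so the
  tint — hence the chroma signal — is uniform across a lesion;
* salt-and-pepper noise (each corrupted pixel → 0 or 255 with equal
  probability) applied last, default fraction 0.02, exercising the median
  filter.

With these defaults the per-class ranges of the maximum-correlation
feature over the ten regions are pairwise disjoint, so the texture branch
alone can separate the classes, and the radii separate them by area.
Dataset generation jitters orientation (±45°), radius (±12%, preserving
the area ordering) and texture amplitude (±10%) per image, with per-image
child seeds: the same dataset seed reproduces the dataset bit for bit.

What the generator does **not** model: camera and illumination variation,
hair and specular occlusion, irregular lesion shapes, multiple lesions,
skin-tone diversity. Passing tests therefore demonstrate that the
implementation is correct and self-consistent under controlled conditions,
not that the measured recognition rates transfer to clinical photographs.

## The self-contained experiment

`end_to_end_experiment` (also `dermatex experiment`, and what
`scripts/acceptance.py` reruns) generates 30 images per class at 256×256,
uses the first 10 per class for training and the remaining 20 per class for
testing (90 images, 30 train / 60 test), and reports the per-class
recognition table plus overall accuracies of SVM1, SVM2 and the integrated
classifier. At the default configuration this completes in under a minute
on one CPU; a single 256×256 image runs through the full pipeline in well
under a second.

## Numerical choices and degenerate inputs

* Quantization floor: bin = ⌊pixel·L/256⌋; GLCM entries are exact pair
  counts before normalization.
* Canvas sizes round up with a 1e−9 guard so exact right angles do not
  inflate by one pixel.
* Medial-axis ties go to the uppermost row; segment-boundary ties to the
  lower span; SVM vote ties to the lowest class index — all deterministic.
* Constant images: binarization returns an empty mask with a warning;
  watershed returns a single region with a warning; correlation of a
  degenerate GLCM is 0 with a warning rather than an error.
* An all-foreground mask has no background set, so the distance transform
  raises; a foreground narrower than 10 columns cannot support ten
  segments and raises.
* k-means reduces k with a warning when there are fewer regions than
  clusters.

## Known limitations

* The measured lesion area is biased low by a few percent (boundary basins
  straddling the lesion edge), proportionally more for small lesions.
* The texture-only classifier (SVM1) is noticeably weaker than the
  integrated one on some dataset seeds; the min/max collapse over ten
  regions discards most of the per-region signal.
* Only the largest foreground component is analyzed; multi-lesion frames
  are quantified as one aggregate area.
* The medial axis is pixel-resolution (no sub-pixel refinement) and
  assumes the epithelium is roughly convex after rotation.
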