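# Methods

## Problem and model

Chronic venous insufficiency (CVI) is graded from leg photographs via a
two-level semantic model. Local *concepts* — normal skin (1), reticular
vein or telangiectasia (2), varicose veins (3), pigmentation or edema
(4), vein ulcers (5) — are assigned to square grid patches by a
supervised classifier; the image-level *scene* (mild / moderate /
severe) is classified from statistics of those concepts. The link
between the levels encodes two clinical facts: lesion size matters, so
patches are taken at three scales, and lesion location matters (edema,
skin changes and ulcers concentrate near the ankle), so concept
occurrences are counted separately in the upper and lower image halves.

Severity is defined from the concepts present: mild ⊂ {1, 2},
moderate ∋ 3, severe ∋ {4, 5}.

## Preprocessing

Images are resized to a canonical 250 × 700 frame (bilinear pixels,
nearest-neighbor masks; the aspect distortion encodes the typical
length-to-width ratio of a leg crop) and color-corrected by the
gray-world rule computed **over foreground pixels only**, so background
cannot bias the illuminant estimate. Intensities are floats in
[0, 255], quantized only on export. Normalization order is
mask → resize → normalize; this is a convention (the two orders differ
only through interpolation rounding). Foreground masks are inputs;
absent masks default to all-foreground.

## Patch grids

Scales 15, 25 and 50 px. 250 and 700 are not divisible by 15, so the
right/bottom remainder is cropped — no partial patches, at most 14 rows
and 10 columns of pixels discarded — giving exactly 70 / 280 / 736
patches per image at scales 50 / 25 / 15. A patch belongs to the upper
region when its center row is above row 350, else lower. Patches enter
training and representation only when at least half their pixels are
foreground (`min_foreground_fraction = 0.5`, a majority-skin rule).

## Patch features (352 dims)

| block | dims | parameters |
|---|---|---|
| uniform LBP histogram | 59 | radius 1, 8 neighbors; interior codes only (border codes depend on padding) |
| MPEG-7 edge histogram | 5 | 2×2 sub-blocks, standard five filter masks, strength threshold 11 |
| GLCM statistics | 4 | 16 gray levels, 4 symmetric unit offsets, contrast/correlation/energy/homogeneity averaged over offsets; correlation of a constant patch defined 0 |
| dense SIFT mean+variance | 256 | 4×4 cells × 8 orientations, cell = max(2, patch//5), step 4 px, SIFT-style normalize→clip 0.2→renormalize; sites fully inside the patch |
| gradient mean | 1 | central differences, one-sided at borders |
| color statistics | 18 | mean/median/variance per channel, RGB and full-range BT.601 YCbCr |
| neighbor context | 7 | mean over 4-connected, foreground-passing neighbors of (gradient mean, 3 RGB means, 3 YCbCr means); zeros when no neighbor qualifies |
| patch index | 2 | (row/n_rows, col/n_cols), scale-comparable in [0, 1] |

All choices are the standard parameterizations of descriptors that are
usually named without parameters; they are defaults, not tuned values.

## Fuzzy-information feature selection

Each feature is fuzzified into three triangular sets (low/mid/high)
anchored at the min, midpoint and max of the **training** values; the
memberships of any value sum to 1. Set probabilities are estimated as
normalized mean memberships, joints via the minimum t-norm, and all
information measures (marginal/joint/conditional entropy, MI,
conditional MI, in bits) are Shannon entropies of those probabilities.
On crisp 0/1 memberships this reduces exactly to the discrete plug-in
estimators, which is the property the tests pin down. The Luca–Termini
fuzziness measure −(1/n)Σ[μ log₂ μ + (1−μ) log₂(1−μ)] is exposed
separately; it quantifies how fuzzy an assignment is (zero for crisp
sets) and flags degenerate constant features, but set probabilities —
not per-sample fuzziness — carry the dependence structure used for
scoring.

A candidate f is scored against the selected set S and class C by
relevance I(f;C), minus mean unconditional redundancy, plus mean
class-conditional redundancy, plus a β-weighted (β = 0.5) second-order
interaction over selected pairs (active from |S| = 2). Greedy forward
search adds the argmax each step, ties to the lowest index, stopping at
`k_max` or when the best score is ≤ 0. The criterion composition and
β, the triangular three-set family, and the minimum t-norm are design
choices of this package. Class labels are fuzzified as crisp one-hot
sets. The search is vectorized across candidates with memoized pair
joints; its scores are property-tested against the direct per-candidate
scoring routine.

## Classifiers

One-vs-one SVMs (libsvm) on standardized, column-selected inputs;
standardization statistics come from training data only and are stored
in the model. Concepts: quadratic polynomial kernel (γ = 'scale',
coef0 = 1), one model per scale, never shared across scales. Scene:
linear kernel. C = 1 for both. Per-class decision scores for ROC are
one-vs-one vote counts plus a logistic squashing of the pairwise margin
sum (bounded below 1, so votes dominate and margins break ties).
Conflicting three-annotator patch labels resolve by majority, then by
nearest resolved patch (Euclidean center distance, ties toward smaller
row then column).

## Evaluation protocol

Accuracy, Cohen's kappa and macro-F1 are computed from the confusion
matrix; a class with a degenerate precision/recall denominator gets
F1 = 0, and a class neither true nor predicted is excluded from the
macro average. AUC is the tie-averaged rank statistic. The repeated
protocol draws stratified 2/3–1/3 splits (stratification keeps the
small classes represented in every split), runs feature selection *per
repeat on the training portion only*, trains, evaluates on the held-out
third, and reports per-repeat metrics with means and standard
deviations, fully reproducible from one seed.

## Synthetic study conditions

The generator emulates the geometry and the concept semantics of real
leg photographs, not their photometric realism: a tapered elliptical
silhouette on a plain dark background, skin-toned base texture with
pixel noise and smooth shading, and per-concept lesion textures — thin
dark reddish random-walk strokes (2), thick tortuous dark bluish ridges
(3), brownish diffuse blotches (4), bright irregular blobs (5).
Severe-class lesions are placed in the lower half with probability 0.9
(the ankle-region prior); mild legs carry strokes with probability 0.7,
otherwise no lesion at all. Patch ground truth is the plurality concept
among painted pixels (ties to the lower concept number; unpainted
patches are normal skin), so labels are exact by construction and the
scene label is recoverable from the painted concepts.

The default study uses 30 images per class, contrasts at which the
concepts are clearly separable, and a 20-repeat protocol. Passing tests
therefore demonstrate the pipeline's mechanics and the ordering of its
variants (combined scales vs single scales, supervised concepts vs a
k = 50 k-means codebook) under separable conditions; they say nothing
about accuracy on clinical photographs, where concept boundaries are
soft and inter-annotator disagreement is substantial.

## Problem sizes and cost choices

The end-to-end study trains each concept SVM on a class-balanced
subsample of at most 250 patches per concept (best of 3
train/validation repeats kept, mirroring best-of-repeats model
selection), then classifies all ~56 000 foreground patches; the
concept stage uses the full 352-dim feature bank (the all-features
variant) while fuzzy forward selection runs per repeat at the scene
stage on the 45-dim representation, where the average selected subset
is what the protocol reports. Forward selection over the full patch
feature bank is available through the same API but is quadratic in the
selected-set size and cubic in candidate evaluations, so it is applied
where the representation is small.

## Degenerate inputs and numerical conventions

Empty patch sets give zero COVs (no-evidence semantics, preserving the
count-weighted identity whole = mean(upper, lower)); constant features
fuzzify to the mid set and are flagged degenerate; GLCM correlation of
a zero-variance patch is 0; EHD of an edge-free patch is the zero
vector; probability vectors are renormalized before entropy (a no-op on
crisp inputs); 0·log 0 = 0 throughout. Entropies are in bits.

## Known limitations

- Masks are inputs; there is no automatic leg segmentation.
- Concept assignment is hard (argmax), not probability-weighted.
- The synthetic generator's separable contrasts upper-bound what the
  pipeline can show; no claim transfers to clinical data without a
  labeled dataset.
- The second-order interaction term makes forward selection expensive
  beyond a few hundred candidate features.
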