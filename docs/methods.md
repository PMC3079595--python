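# Methods

## Model

The detector treats RoI selection in a stained histology field as a
three-stage visual process.

**Conspicuity channels.** Three low-level channels follow the Itti-Koch
centre-surround architecture. A dyadic Gaussian pyramid (smoothing sigma 1,
decimation by 2) is built on each feature plane; feature maps are
`|centre − surround|` with the surround level upsampled to the centre level
by nearest-neighbour repetition. Each map passes through the
peak-promoting normalization N(·): rescale to `[0, 1]`, then multiply by
`(M − m̄)²` where `M = 1` is the global maximum and `m̄` the mean of all
*other* 3×3 local maxima (connected plateaus counted once, zero pixels never
maxima). Maps with one dominant peak survive; maps with many comparable
peaks are suppressed; an all-zero map stays zero. Normalized maps are
upsampled to input resolution, summed over scales, and the sum rescaled to
`[0, 1]`.

- *Intensity*: `I = (R + G + B)/3`.
- *Colour*: broadly tuned opponency planes `RG = R′ − G′`, `BY = B′ − Y′`
  (`R′ = r − (g+b)/2` etc., clipped at zero); centre-surround differencing
  of these planes implements double colour opponency.
- *Orientation*: modulus of the complex Gabor response (frequency 0.25,
  bandwidth 1) at `n_orientations = 4` stripe angles `0°, 45°, 90°, 135°`,
  computed per pyramid level and differenced across scales.

Pyramid layout: the canonical 9 levels with centres `{2, 3, 4}` and
surround offsets `{3, 4}` for images of 256 px and larger; below that a
5-level layout (centres `{1, 2}`, offset `{2}`) keeps the coarsest level a
few pixels wide. Both are exposed via `PyramidConfig`.

**Texture channel.** Tumour tissue is more cluttered than stroma, so a
fourth channel measures the Shannon entropy (bits) of the local intensity
histogram: intensities in `[0, 1]` are quantized into `n_bins = 32` equal
bins and counted in a `window = 9` square neighbourhood with reflective
padding; the map is divided by `log2(n_bins)`. Bin counts are obtained from
a uniform filter and rounded to exact integers, so analytic cases are exact
in floating point. The entropy map is single-scale and is *not* passed
through N(·) by default: N(·) suppresses maps with many comparable peaks,
which is precisely the signature of a genuine texture region, and the
channel's analytic contract (a balanced two-symbol window scores exactly
1.0) requires the raw value. Applying N(·) remains available via the
`normalize_entropy` flag. Odd windows are centred; even windows are
accepted (covering `[i − w//2, i + w − w//2)`) because balanced two-symbol
neighbourhoods only exist at even window sizes.

**Grouping.** The still-segmentation uses the Felzenszwalb-Huttenlocher
merge rule on the pixel grid (4-connectivity by default): edge weights are
absolute intensity differences in 0–255 units (optionally the Euclidean RGB
difference behind `color_edges`); edges are processed in nondecreasing
weight and components merge when
`w ≤ min(Int(c1) + k/|c1|, Int(c2) + k/|c2|)`, `Int(c)` being the largest
weight among edges already merged inside `c`. A final pass merges every
component below `min_size` into its lowest-weight neighbour; labels are
renumbered consecutively in row-major order of first occurrence. Equal
weights are ordered by (weight, first endpoint, second endpoint), making the
result platform-deterministic; adding a constant to all intensities leaves
the partition unchanged. An optional Gaussian pre-smoothing
(`smooth_sigma`, default 0.8 px) is applied before graph construction and is
itself a learned parameter.

**Integration.** Each of the four maps is averaged inside each region; the
per-region indices are combined as a weighted mean with non-negative weights
normalized to sum one, then min-max normalized across regions (an all-equal
vector maps to 0.5 — no region stands out). Regions with combined saliency
*strictly* above the unweighted mean of region saliencies form the RoI, so
degenerate all-equal fields yield an empty mask, the conservative behaviour
for a detector. Region means are taken on the raw `[0, 1]` maps and
normalization applied once, at combination, to avoid double scaling.

## Quality energy

A prediction `c` is compared with an expert mask `g` through
distance-weighted pixel counts with `w(i) = offset + slope·min(i, d_max)`
(defaults 1, 1, 20 px): missing-foreground pixels (`g ∧ ¬c`) are weighted by
their Euclidean distance to `c`, added-background pixels (`c ∧ ¬g`) by their
distance to `g` — errors far from the relevant border are perceptually worse
than border jitter. An empty mask is treated as maximally distant
(`d_max` everywhere), which keeps empty predictions well defined and makes
the penalties below saturate at `w(d_max)` per pixel. The normalized
quality divides by `area · w(d_max)`; decibel values are
`10·log10(normalized + 1e-7)`, floored at −70 dB for a perfect match.

For full partitions, each ground-truth region is matched to the predicted
region of maximal overlap, matches made unique greedily in descending
overlap (ties: lower region index). The summed pairwise quality is the
boundary inaccuracy `e_bl`; unmatched predicted regions are scored as added
background against a blank image (`e_ov`), unmatched ground-truth regions
symmetrically (`e_un`); the energy is the unweighted sum
`E = e_bl + e_ov + e_un`, zero exactly on agreement. The exact weighting
constants and the dB normalization used by the original corpus study are
not recoverable; only relative comparisons of these values are meaningful.

## Learning

Generalized pattern search minimizes an objective that is piecewise constant
in the segmentation parameters, so gradients are unavailable. From the
current iterate the search first probes long jumps on the mesh
`M(x0, Δ) = {x ± m·Δ·s_i·ê_i}` with multipliers `m ∈ {16, 4}` (the search
step), then the unit poll `m = 1`, coordinates in declared order, `+`
before `−`, accepting the first strictly better point with the mesh size
kept; when nothing improves the mesh is halved, and the search ends after
`max_refinements = 6` halvings. The search step is what lets the optimizer
cross wide plateaus of the piecewise-constant energy; with unit polls alone
the stage-1 learner stalls in a local shelf measurably worse than random
sampling of the same box. Non-finite objective values are treated as +∞;
evaluations are cached on rounded parameter tuples; integer-valued
coordinates (`min_size`, `entropy_window`) are rounded at evaluation time
while the search itself stays real-valued.

Learning is staged. Stage 1 fits `(k, smooth_sigma, min_size)` by
minimizing the summed partition energy against expert partitions, over the
box `k ∈ [10, 5000]` (start 500, scale 128), `sigma ∈ [0, 2]` (start 0.8,
scale 0.4), `min_size ∈ [1, 500]` (start 20, scale 32). Stage 2 freezes the
segmentation and fits the four channel weights in `[0, 1]^4` (start 0.25
each, scale 0.25) minimizing the summed normalized foreground-background
quality of the thresholded RoI against the expert RoI mask; an all-zero
poll is evaluated with uniform weights (the combination is undefined at the
origin) and the returned vector is renormalized to sum one. Region feature
indices are precomputed once per image since they do not depend on the
weights. A k-fold harness (`crossvalidate`, default 11 folds, seeded
permutation assignment) reports per-fold held-out scores.

## Synthetic fixtures

`generate_fixture` emulates exactly the two properties the method exploits:
islets are darker than stroma (default palette: background RGB
(230, 200, 210), islets (120, 90, 160) — eosin-pale pink vs
haematoxylin-dense violet) and internally cluttered (shared-luminance
Gaussian speckle, sd 45 vs 5 in 0–255 units, ratio comfortably above the
5× at which the entropy contrast is guaranteed by test). Islet supports are
discs deformed by low-frequency radial modes (frequencies 2–4, relative
amplitude ≤ 0.2) so contours stay smooth and closed; placement is rejection
sampling with at most 1000 attempts; a final Gaussian blur (0.8 px) softens
borders. Defaults are 128×128 fields with two islets of radius 14–24 px —
large enough for the reduced pyramid, small enough that the learning loops
run in seconds per evaluation. The suites used by tests and the acceptance
script are 20 training and 20 held-out fields with seeds derived from a
single master seed.

`channel_discriminative_fixture` realizes fields where only one channel
identifies the RoI. A single discriminative islet is not sufficient for
that purpose: with a correct segmentation any weighting already selects it
and the weight objective is flat at the uniform start. Each field therefore
plants a *target* (in the ground truth; conspicuous only in the named
channel) and a *distractor* (excluded from the ground truth; conspicuous in
the complementary channels), so mis-weighted channels select the wrong
region and carry measurable cost. For the colour variant the target has the
background's mean intensity exactly, so the intensity-edge segmentation
cannot isolate it and the RGB edge weights (`color_edges`) are used.

What the fixtures do *not* emulate: nuclei and cellular micro-structure,
stain variation and vignetting, tissue folds, magnification-dependent
texture statistics, and the contour ambiguity of real expert annotations.
Passing tests therefore demonstrate that the pipeline recovers regions
distinguished by brightness, hue or local entropy with smooth closed
contours — the method's operating assumptions — not clinical performance on
real slides, whose texture statistics are unknown here.

## Numerical choices and degenerate inputs

- Conspicuity maps and combined saliencies are rescaled only when their
  maximum is positive; constant inputs yield identically zero maps, a
  single region, and an empty RoI.
- Micro-images (≤ 8×8, catalogue in `historoi.fixtures`) carry analytic
  partitions and use 0–255 intensity units, the scale on which `k/|c|` is
  defined; RGB images in `[0, 1]` are rescaled by 255 before segmentation.
- Distance transforms use `scipy.ndimage.distance_transform_edt`; pixels at
  distance ≥ `d_max` saturate the weight.
- Masks are `{0, 255}` on disk and `{0, 1}` in memory; label maps are
  16-bit PNGs (≤ 65 535 regions) with a JSON sidecar; coordinates are
  0-based row-major.
- Determinism: every stochastic component draws from
  `numpy.random.default_rng` seeded explicitly; identical inputs and
  parameters give byte-identical masks.

## Known limitations

- The entropy channel is single-scale; a multiscale entropy pyramid is a
  plausible extension (flag-compatible, not implemented).
- Greedy maximal-overlap matching can differ from an optimal assignment
  when several regions have comparable overlaps; the uniqueness rule is
  deliberate and documented rather than claimed optimal.
- The region-selection threshold (strict mean of per-region saliencies) is
  unweighted by area; very fragmented segmentations therefore bias the
  threshold toward small regions.
- GPS converges to a mesh-local minimizer only; the search step mitigates
  but does not remove dependence on the starting point and scales.
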