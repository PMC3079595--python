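# historoi

Supervised visual-attention detection of diagnostic Regions of Interest
(RoIs) in H&E-stained histopathology fields, built for basal-cell-carcinoma
style images where tumour "islets" appear as darker, visibly cluttered
regions on pale stroma.

The detector emulates the first pass of a pathologist's slide examination as
an interaction of three visual processes:

1. **Conspicuity (V1).** Four per-pixel maps: intensity, red-green /
   blue-yellow double colour opponency and Gabor orientation energy computed
   with the classic Itti-Koch multiscale centre-surround architecture, plus
   a texture channel — the Shannon entropy of the local intensity histogram —
   which is the discriminative cue when stain colour is uninformative.
2. **Grouping (V2).** A graph-based still-segmentation with the
   Felzenszwalb-Huttenlocher merge rule: components `c1, c2` merge when the
   lightest edge between them satisfies
   `w <= min(Int(c1) + k/|c1|, Int(c2) + k/|c2|)`, where `Int(c)` is the
   internal difference and `k` a learned scale preference.
3. **Integration and selection (V4 modulation).** Each conspicuity map is
   averaged inside each region, the four per-region indices are combined
   with learned non-negative weights, and regions whose normalized saliency
   strictly exceeds the mean region saliency form the predicted RoI.

Both parameter groups are learned from expert masks by generalized pattern
search (GPS), a derivative-free optimizer suited to the piecewise-constant
objective: first the segmentation parameters `(k, smooth_sigma, min_size)`
minimizing the perceptual partition energy `E = e_bl + e_ov + e_un`
(distance-weighted missing-foreground / added-background boundary errors
plus over- and under-segmentation penalties after maximal-overlap region
matching), then the feature weights minimizing the foreground-background
quality of the thresholded RoI.

Because the expert-annotated corpus behind such studies is rarely
distributable, the package ships a first-class synthetic-fixture generator
emulating the two properties that drive the method — colour/intensity offset
and local-entropy offset of islets against stroma — with exact ground-truth
masks, so everything is testable and reproducible offline.

## Worked example

```python
from historoi import RoiDetector
from historoi.evaluation import pixel_confusion
from historoi.fixtures import fixture_suite

train = fixture_suite(20, seed=101)   # (image, mask) pairs
test = fixture_suite(3, seed=202)

det = RoiDetector().fit([img for img, _ in train], [m for _, m in train])
print("learned:", det.segmentation_params_)
for i, (img, gt) in enumerate(test):
    mask, table, labels = det.detect(img)
    conf = pixel_confusion(mask, gt)
    print(f"field {i}: {labels.max() + 1} regions, "
          f"{int(table['selected'].sum())} selected, "
          f"sensitivity {conf.sensitivity:.1f}%, specificity {conf.specificity:.1f}%")
```

Output:

```
learned: SegmentationParams(k=452.0, smooth_sigma=0.0, min_size=500, connectivity=4, color_edges=False)
field 0: 3 regions, 2 selected, sensitivity 93.8%, specificity 100.0%
field 1: 3 regions, 2 selected, sensitivity 95.7%, specificity 99.7%
field 2: 3 regions, 2 selected, sensitivity 97.3%, specificity 99.8%
```

The two-stage learner picked a segmentation scale that isolates each islet
(here three regions per field: two islets plus stroma), the two islet
regions exceed the mean region saliency and are selected, and the predicted
masks recover the planted RoIs almost pixel-perfectly — `sensitivity` is the
percentage of true RoI pixels detected, `specificity` the percentage of
stroma pixels correctly rejected.

`RoiDetector` follows the scikit-learn estimator contract
(`get_params`/`set_params`, `fit`, `predict`, `score` = mean Dice), so it
clones and composes with sklearn model-selection utilities; images are
passed as a list of `(H, W, 3)` arrays in `[0, 1]` and may differ in size.

## Command line

```
historoi fixtures  --out data --n 20 --seed 5        # synthetic fields + masks
historoi conspicuity data/img_000.png --channel all --out maps
historoi segment    data/img_000.png --k 500 --out labels.png
historoi learn      --train data --out params.json
historoi detect     data/img_000.png --params params.json --out-mask pred.png
historoi evaluate   --pred pred.png --gt data/gt_000.png
historoi crossval   --data data --folds 11 --out report.csv
```

All subcommands accept `--config config.yaml` (schema-validated; unknown
keys rejected; see `historoi.config`).

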