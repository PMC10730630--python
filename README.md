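# hcscreen

Training-free, assay-agnostic analysis for high-content screening (HCS).

An HCS campaign images cells in 384-well plates under hundreds to thousands
of perturbations (compounds, siRNAs) and must reduce millions of microscopy
images to a short list of *hits*. The conventional route — a hand-crafted,
assay-specific image-analysis workflow built on cell segmentation — is the
main bottleneck of the technology. `hcscreen` implements the alternative:
encode every image with a pretrained convolutional network and run one fixed,
fully automated statistical pipeline downstream, with no training, no
segmentation, and no per-assay tuning.

## Pipeline

1. **Encoding.** Each single-channel field is split into non-overlapping
   224×224 tiles; each tile is replicated into a fake-RGB image, normalized
   with the encoder's training-corpus constants, and passed through a
   ResNet-18 with the classification layer removed. Per-dimension medians
   aggregate tiles → field and fields → well, and the C channel blocks are
   concatenated into one 512·C profile per well.
2. **Spatial correction.** Tukey's two-way median polish on the 16×24 well
   grid removes additive row/column artifacts per plate, per feature
   (effects estimated from sample wells; corrected value = x − row − col).
3. **Plate alignment.** Robust Z-score against each plate's negative
   (vehicle-only) controls: z = (x − median(neg)) / (1.4826·MAD(neg)). Any
   per-plate affine distortion cancels exactly, so wells from different
   plates become comparable.
4. **Hit selection.**
   - *With a positive control*: a linear discriminant axis
     w ∝ S⁻¹(μ₊ − μ₋) is fitted on the two control populations; conditions
     whose projections exceed the top-1% quantile in **every** replicate are
     hits.
   - *Without a positive control*: the Mahalanobis distance
     d(x) = √((x−μ)ᵀS⁻¹(x−μ)) to the negative-control distribution (mean μ,
     Ledoit–Wolf-shrunk covariance S) flags outlier conditions, which are
     then grouped into k phenotype clusters (Ward linkage) with one
     representative per cluster for visual review.

A PCA diagnostic (mean silhouette of plate labels in the first two principal
axes) quantifies plate effects before/after alignment.

No public screen accompanies this pipeline, so `hcscreen.synthetic_data`
generates screens with known ground truth — plate gradients, affine plate
distortions, duplicate replicates, and planted hit phenotypes (cell loss,
cell-channel brightness) at 1% prevalence — at both the feature level and as
rendered TIFF trees.

## Worked example

Simulate a duplicate 4-plate screen (1280 conditions, 1% planted hits) and
run the no-positive-control branch end to end:

```sh
hcscreen simulate --out screen --seed 7
cat > pipeline.yaml <<EOF
platemap: screen/platemap.csv
features: screen/features.csv
out_dir: run
mode: negative
EOF
hcscreen run --config pipeline.yaml
```

The run directory contains every intermediate (`features_raw.csv`,
`features_corrected.csv`, `features_aligned.csv`), `hits.csv`, figures, and
`report.json`. For this seed:

```
threshold 16.408  n_hits 13  shrinkage 0.9268

              distance  score_R1  score_R2   hit  cluster  representative
cond_0226        35.43     35.48     35.37  True        5            True
cond_0344        36.84     34.35     39.33  True        3           False
...
cond_0564        23.04     24.70     21.38  True        6            True
```

13 conditions exceed the Mahalanobis threshold (the 99% quantile of
per-condition distances) in both replicates — exactly the 13 planted hits.
`distance` is the replicate-mean Mahalanobis distance to the negative-control
distribution in aligned MAD units; `cluster` is the Ward phenotype group
(here the planted brightness hits, e.g. `cond_0564`, land in clusters
disjoint from the cell-loss hits) and `representative` marks the member
closest to each cluster center. With `mode: positive` the same screen is
scored along the control LDA axis instead and `hits.csv` carries
`display_score` (replicate-mean projection) with the same all-replicates
gating.

`hcscreen encode` runs the image branch on a TIFF tree
(`<replicate>/<plate>/<well>_f<field>_ch<channel>.tif`), and
`hcscreen report run/` renders score scatter, PCA plate plots and per-plate
heatmaps as PNG.

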