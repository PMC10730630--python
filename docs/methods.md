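# Methods

## Model and assumptions

The pipeline treats a screen as a collection of well-level feature vectors
and makes three structural assumptions:

1. **A pretrained encoder is a usable phenotype sensor.** A residual network
   trained on natural images maps each 224×224 tile to a 512-vector whose
   geometry preserves morphological differences. Nothing downstream depends
   on what the individual dimensions mean — only on distances and linear
   projections in the profile space. The pipeline is therefore equally
   applicable to hand-crafted feature tables; every stage after encoding is
   dimension-agnostic.
2. **Nuisance structure is additive per plate.** Within-plate positional
   artifacts are row + column effects on each feature; between-plate
   distortions are per-plate affine maps x → a·x + b. Median polish removes
   the former, negative-control robust Z-scoring cancels the latter exactly.
3. **Negative controls define the null phenotype.** Both hit-calling
   branches are relative to the vehicle-only wells: the LDA axis starts at
   the negative-control mean, and the Mahalanobis branch models the
   negative-control distribution explicitly.

## Encoding

- Tiles are anchored top-left; the right/bottom remainder strip (width
  < 224 px) is discarded. Padding would embed artificial black borders;
  the lost strip is a thin image margin. Fields smaller than one tile are
  rejected unless `pad_to_tile` is set.
- Intensities are divided by the bit-depth maximum (65535 for 16-bit), not
  min–max rescaled per image: acquisitions use a fixed exposure, so absolute
  brightness is biological signal and per-image rescaling would erase
  brightness phenotypes.
- Each tile's single channel is replicated to three planes (fake RGB); the
  standard per-plane natural-image constants (mean 0.485/0.456/0.406, s.d.
  0.229/0.224/0.225) are then applied per plane.
- Aggregation is the per-dimension median, tiles → field and fields → well;
  both steps are invariant to tile, field and file-enumeration order, and
  results are batch-size invariant.
- The encoder is injected (`EncoderSpec`). The default is a NumPy
  implementation of ResNet-18 with the classification head removed
  (He-initialized from a fixed seed; `.npz` state-dicts loadable), which
  fixes the 512-d contract and keeps the full image path runnable offline;
  mock encoders (mean-intensity, constant) are used for pipeline tests. An
  untrained encoder is *not* a phenotype sensor — runs on real screens
  should load trained weights.

## Spatial correction

Tukey's median polish alternates row and column median sweeps (row first;
the algorithm is order-dependent at the margin, so the order is fixed for
reproducibility) with `tol = 1e-6` on the maximum effect change and
`max_iter = 20`. The decomposition `overall + row + col + residual`
reconstructs the input exactly at every iteration; on noisy plates the
effects typically keep drifting below ~1e-3 per sweep when the cap is hit,
which is far beneath the aligned-unit scale of any effect of interest.

Row/column effects are **estimated from sample wells only** (controls and
empty wells enter as gaps) and then subtracted from every well. Control
wells routinely occupy dedicated plate columns; a column filled with one
control would otherwise have its entire phenotype absorbed into the column
effect, silently deleting the positive-control signal that the LDA branch
needs. Rows/columns containing no sample wells get a zero effect. The
corrected value keeps the plate's location (`x − row − col`), leaving the
scale to the alignment step. Each plate of each replicate is corrected
independently. The bare `median_polish`/`spatial_correct(table)` operations
(no layouts) polish all wells and serve as the textbook reference.

## Plate alignment

Per plate and feature, `z = (x − median(neg)) / (1.4826·MAD(neg))`, using
only that plate's negative-control wells; 1.4826 makes the MAD estimate
Gaussian-consistent. The MAD is floored at `1e-8` with a per-feature flag so
locally constant features cannot divide by zero. A plate with no negative
controls is a hard error; fewer than 8 yields a warning (the typical number
per plate is a platform choice; the data model allows any count ≥ 1).
Alignment is exactly invariant to per-plate affine corruptions because both
the polish decomposition and the (median, MAD) pair are affine-equivariant.

The PCA diagnostic mean-centers the table, projects on the first two
principal axes and reports the mean silhouette of (plate, replicate) labels —
near 1 when plates form separate clouds, near 0 (or negative) when mixed.

## Hit selection

**Positive-control branch.** Two-class LDA in closed form:
`w ∝ S_pooled⁻¹ (μ₊ − μ₋)`, unit norm, oriented positive-control-high.
`S_pooled` is the within-class-centered covariance with shrinkage toward
`tr(S)/D · I`; the shrinkage intensity defaults to the Ledoit–Wolf analytic
value (profiles have D = 512·C dimensions but only tens to hundreds of
control wells, so regularization is required for invertibility and can be
overridden or disabled for well-conditioned data). The hit threshold is the
`1 − f` quantile (default f = 0.01, "top 1% of the screen") of per-condition
display scores — the replicate-mean projections of **sample** conditions,
controls excluded. A condition is a hit only if *every* replicate exceeds
the threshold; ties are excluded by the strict inequality, so the flagged
fraction is an upper bound under ties. The gate generalizes the duplicate
design ("both replicates above the line") to any replicate count, and can
only shrink the hit set relative to thresholding the mean.

**No-positive-control branch.** The negative model is the control mean and
shrunk covariance (as above, positive-definiteness checked via eigenvalues;
condition number recorded). Mahalanobis distances are computed for every
well via a Cholesky solve. The distance threshold defaults to the same
`1 − f` quantile construction on per-condition replicate-mean distances — an
absolute distance can be supplied instead, since no principled universal
cutoff exists for "significantly outside the null distribution". Replicate
gating is identical to the LDA branch. Hits are clustered on their
replicate-averaged aligned profiles by agglomerative Ward/Euclidean
clustering cut at k = 6 groups (k is an acknowledged arbitrary exploration
knob, exposed in the config); each cluster's representative is the member
closest to the cluster mean, intended as the image to inspect per phenotype.
Per-channel distances repeat the Mahalanobis computation on a single
channel's feature block to localize channel-specific effects such as
brightness changes in the cell channel.

## Synthetic screens

The feature-level generator is the primary test substrate. Defaults model a
duplicate compound screen: 1280 conditions (a standard repurposing-library
size) over four 384-well plates per replicate, 16 negative and 16 positive
control wells per plate in dedicated columns, surplus wells empty. Well
profiles are condition effect + i.i.d. N(0, 1) noise per feature, plus a
per-plate linear row/column gradient (amplitude 1) and a per-plate affine
distortion (scale 0.7–1.3, offset ±2). Because the noise has unit scale,
planted effects are expressed directly in aligned MAD units.

Two phenotype classes are planted at 1% prevalence: *cell loss* (all
feature blocks depressed — a proxy for the dominant toxicity axis) and
*brightness* (confined to the upper half of the cell-channel block). The two
directions have disjoint support, hence are orthogonal; effects displace
each supported feature by `effect_size` (default 5) aligned units — a
phenotype moves many deep features at once, which is what makes
population-level distances informative. Positive controls sit on the
cell-loss direction at twice the default effect. Screens for the
positive-control branch plant only the control phenotype class (that branch
by construction looks for one phenotype); no-control screens plant both
(80/20).

Profiles default to D = 64 (two channel blocks of 32) rather than 512·C.
Every statistic involved is dimension-generic, and real deep features are
strongly correlated (low effective rank), which an isotropic
full-width simulation would misrepresent: in D = 1024 independent
dimensions the χ²-type noise floor of the Mahalanobis distance would
swamp effects that correlated real features expose. The reduced width keeps
the simulated signal-to-noise in the realistic regime and whole-screen runs
in seconds.

Per-plate random streams are derived from the master seed and the
(replicate, plate) coordinates, so adding plates never perturbs existing
ones and a fixed seed reproduces tables bitwise.

The image-level generator renders Gaussian-blob cells (nuclei small/bright,
cell channel large/dim, Poisson-distributed counts), a linear background
gradient across the plate, and shot noise; cell-loss hits have 5× fewer
cells, brightness hits a 3× brighter cell channel. It exercises the
tile→encode→aggregate path end to end at small scale. It deliberately omits
PSF blur, chromatic aberration, debris and focus failures — passing tests
demonstrate the statistical machinery, not robustness to real-microscope
artifacts, and say nothing about the adequacy of an untrained encoder on
real cells.

## Numerical choices and edge cases

- Polish convergence: `tol 1e-6`, `max_iter 20`, row sweep first;
  all-missing rows/columns are errors, isolated gaps use medians over
  present cells.
- MAD floor `1e-8` (flagged); quantile thresholds use linear-interpolation
  quantiles; strict `>` at the threshold.
- Covariance regularization: `S_reg = (1−λ)S + λ·tr(S)/D·I`, λ by
  Ledoit–Wolf (`auto`), a fixed value, or `none` (refuses singular input).
- Feature tables refuse non-finite values at construction; state moves
  one-way through raw → spatially_corrected → aligned.
- CSV intermediates round-trip bit-exactly (round-trip float parsing), so
  resumed and re-run pipelines are byte-identical.
- Well names accept `A1`/`A01` dialects and canonicalize to zero-padded.

## Known limitations

- Only the 384-well geometry is supported.
- The default encoder ships untrained; trained ResNet-18 weights must be
  provided for real screens (`--encoder path/to/weights.npz`).
- No statistical error control (p-values/FDR) is attached to hit calls; the
  thresholds are quantile- or user-set, as is conventional for this style of
  screen triage.
- Hierarchical clustering of hits is exploratory; k has no optimality
  criterion.
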