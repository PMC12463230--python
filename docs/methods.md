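# Methods

## The problem

Bulk molecular traits of a biopsy (proliferation markers such as Ki67,
expression-derived subtypes such as PAM50 Luminal A/B, receptor status)
are measured once per slide, yet the tissue they summarize is spatially
heterogeneous. This package studies three linked questions on H&E-style
slide images: (i) whether tiles of a slide predict the slide's bulk
label; (ii) whether that predictability survives compression of each tile
into a low-dimensional autoencoder latent vector; and (iii) whether the
latent space is *organized* by the labels at all, measured by an inertia
statistic against a permutation null.

## Synthetic cohort

Real WSI cohorts with rich molecular annotation are generally not
redistributable, so the pipeline ships a generator whose output has the
statistical structure the analysis assumes, with ground truth retained.

Each cohort has `n_patients × timepoints_per_patient` slides (default
3 timepoints per patient, mirroring a baseline / on-treatment / surgery
sampling design; the three slides of a patient always carry distinct
timepoints). One slide is an H×W×3 8-bit image composed of:

- **Background**: a smooth random field thresholded so ≈
  `background_fraction` of the area is near-white; every background pixel
  has all channels ≥ 235, comfortably above the whiteness threshold
  (220) used downstream. Default fraction 0.25.
- **Tissue**: eosin-pink base color with Gaussian texture.
- **Nuclei**: hematoxylin-purple disks with radius 2–6 px. Local target
  coverage is `0.03 + 0.5 · clip(signal_strength · level/100 + η, 0, 1)`
  where `level` is the local trait level and `η ~ N(0, noise_sd)` is a
  per-slide noise term — so nucleus density is a monotone increasing
  function of the trait when `signal_strength > 0` and pure noise when it
  is 0.
- **Heterogeneity patches**: random disks covering
  `heterogeneity_patch_fraction` of the tissue (default 0.15) whose local
  trait level is resampled uniformly on [0, 100].

The per-pixel local level is stored as a float32 `truth_map` (sidecar
TIFF), and the slide's bulk trait value is defined as the tissue-area
mean of that map, so bulk label and spatial ground truth are consistent
by construction. The truth map is validation-only: no pipeline stage
reads it.

Only one trait can drive a single per-slide density map, so the first
entry of `trait_specs` is the driver. Additional traits are noisy
monotone transforms of the driver's bulk level: a latent
`z = signal_strength · (bulk/100) + noise_sd · ε` is rank-mapped to a
uniform grid on (0, 100) for continuous traits or thresholded at its
median for binary traits. `signal_strength = 0` therefore yields a trait
carrying no morphological information — the negative control.

What the generator does *not* emulate: realistic stain variation or
deconvolution, scanner artifacts, nucleus shape/chromatin morphology,
multi-resolution WSI pyramids. Passing tests show the pipeline recovers
planted *density* structure; they do not show that subtle morphological
signals in real H&E would be recovered.

## Tiling and labels

Tiles are 128×128×3 crops on a non-overlapping grid anchored top-left;
partial edge tiles are dropped (fixed network input shape). A pixel is
background iff all three channels are ≥ the whiteness threshold
(default 220, configurable since whiteness is not sharply defined);
tiles with more than 50% background are discarded. Positions are 0-based
row-major (row, col) indices and round-trip through the filename pattern
`{slide_id}__r{row}_c{col}.png`.

Continuous traits are binarized by empirical quantiles with inclusive
linear interpolation between order statistics (numpy's default): values
≤ q20 → 0, ≥ q80 → 1. The OOD band takes (q20, q30] → ood0 and
[q70, q80) → ood1; values exactly at a cut go to the lower bin for
determinism. Band probabilities are rounded to 12 decimals before the
quantile call so `0.2 + 0.1` cannot drift past the exact order statistic.
Slides strictly between q30 and q70 are excluded. Binarization requires
at least 5 values and errors on a constant vector. The trinary scheme for
the inertia analysis cuts at q33/q66; binary traits pass through
unchanged.

Splits are drawn at the slide level (never tile, deliberately not
patient: the three samples of a patient come from different timepoints),
stratified by bin to keep small cohorts from losing a class, with OOD
slides forming their own set. Every set containing both classes is
balanced by downsampling each label group, without replacement, to the
smallest group.

## Networks

No deep-learning framework is required: `hetile.nn` is a small NumPy
core with im2col stride-2 convolutions, 2×2-stride-2 transposed
convolutions (exact ×2 upsampling, non-overlapping output patches),
ReLU/sigmoid, dense heads, MSE and BCE-with-logits losses, and Adam. All
layer gradients are finite-difference-checked in the test suite.

**Autoencoders.** Five members with bottleneck tensors (64,16,16),
(256,4,4), (128,2,2), (64,1,1), (2,1,1) — element counts 16384, 4096,
512, 64, 2 — reached by 3, 5, 6, 7, 7 stride-2 conv layers from 128×128
(a 2→1 halving uses a 2×2 valid kernel). Hidden channel widths halve
backwards from the bottleneck channel count with a floor of 8 (giving
3→16→32→64 for the 3-layer member). Hidden activations are rectifiers;
the bottleneck is linear so latent vectors are unconstrained; the decoder
mirrors the encoder and ends in a logistic layer, so reconstructions and
inputs live on [0, 1] (pixels are scaled by 1/255). Training: MSE, Adam
lr 0.001, batch 16, default 40 epochs, returning the checkpoint with the
smallest validation MSE. Latent tensors are flattened channel-major.

**Classifiers.** Raw tiles: a 4-conv-block CNN (widths 8/16/32/64,
stride 2) with global average pooling and a single-logit head — sized so
the whole suite trains on one CPU. Latent vectors: per-feature
standardization (train statistics) then a 64/32 two-hidden-layer
perceptron. Training: BCE-with-logits, Adam lr 0.001, batch 8, 20
epochs, keeping the epoch with the best validation accuracy (ties →
earliest epoch). Scores are logistic probabilities; the decision
threshold is fixed at 0.5. ImageNet-pretrained backbones are exposed only
as an adapter interface that raises a distinct "adapter unavailable"
error (CLI exit code 42) when no weights are installed; tests never
require them.

## Metrics and heterogeneity maps

Per evaluation set: accuracy, F1 (positive class 1), rank-based AUC-ROC
(tie-corrected; computed via scikit-learn and cross-checked in the tests
against the Mann-Whitney formulation), the 2×2 confusion matrix at
threshold 0.5, and a normal-approximation 95% CI for accuracy,
p ± 1.96·√(p(1−p)/n), clipped to [0, 1]; an exact Clopper-Pearson
interval is available behind a flag. Single-class truth yields an
undefined (NaN) AUC, other metrics still computed.

Heterogeneity maps place each tile's predicted label at its (row, col);
cells without a retained tile are missing and rendered white
(yellow = 1, blue = 0 by default). Per-slide accuracy is agreement of
non-missing cells with the slide's *bulk* label — a map-level summary
only, since tile-level ground truth does not exist when labels are
inherited from the slide.

## Inertia and its permutation null

For latent vectors x_i (i = 1..m) and binning C,
J(C) = (1/m) Σ ‖x_i − μ(C(x_i))‖₂ with class centroids μ. The distance
is deliberately unsquared — this is not the squared-distance inertia
k-means minimizes (that variant is available behind a flag). The null
permutes labels among slides uniformly at random (the identity
permutation is allowed), broadcasts each slide's new label to all its
tiles — so label proportions are preserved and within-slide coherence is
never broken — and recomputes centroids per draw. The summary
`percent_above` counts null draws *strictly* greater than the actual J;
ties count as not-above. Under exchangeable labels the rank argument
makes percent_above/100 uniform on {0, 1/n, …, 1}, which the test suite
verifies by KS test.

The sampling protocol draws, per class, a fixed number of slides and a
fixed number of tiles per slide, both uniformly without replacement
(defaults 5 slides × 100 tiles per class). A study repeats sampling and
permutation over many rounds (default 100) with independent sub-seeds
derived from one master seed; both the sample and the permutations are
redrawn each round (the alternative — one fixed sample — is available by
running a single round).

## Orchestration and reproducibility

`RunConfig` is one YAML-serializable object; every stage derives its seed
as `(master_seed · 1000003 + crc32(stage_name)) mod 2³¹`, so a single
integer reproduces the whole run while stages remain independently
rerunnable. Result CSVs get a sidecar JSON with the config hash and
package version. Experiments write only inside their output directory.

## Problem sizes in the shipped analyses and tests

The shipped analyses run at desk scale, chosen so the statistical
contrasts of interest are unambiguous on one CPU: cohorts of 10–14
patients (30–42 slides) at 512×512 px (≤16 tiles/slide), classifier
training at 10 epochs on balanced sets of ~130 tiles, and a reduced
autoencoder sweep over dimensions {512, 64, 2} with 300 training tiles,
60 validation tiles and 20 epochs. The sweep uses 20 epochs rather than
fewer because the capacity ordering of validation MSE across dimensions
is only meaningful once each member has (nearly) plateaued; at very few
epochs the comparison reflects optimization speed instead of capacity.
The inertia smoke profile uses 3 slides × 6 tiles per class and 10
rounds of 100 permutations.

One calibration choice deserves emphasis: with labels shuffled at the
slide level before training, test tiles are not independent — all tiles
of a slide share whatever density the model latches onto — so the
binomial unit for the "accuracy ≈ 0.5 under the null" check is the
slide, not the tile. The acceptance test averages tile accuracy over
five independent shuffle replicates and uses the 95% binomial band with
n = total number of independent test slides.

## Known limitations

- The synthetic signal is one-dimensional (density); multi-factor
  morphology, stain variation and batch effects are out of scope.
- Quantile binarization is sensitive at exact cut values; the lower-bin
  rule is a convention, not a property of the data.
- The five-member architecture family fixes bottleneck shapes; kernel
  sizes and channel plans beyond the stated rule are conventional
  choices, not tuned.
- Per-slide map accuracy measures agreement with the bulk label, not
  spatial truth; on real data discordant cells may be either model error
  or genuine heterogeneity, and only the synthetic truth map can tell
  them apart.
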