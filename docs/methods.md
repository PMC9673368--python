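# Methods

## Problem and scope

`ovus` re-creates, at desk scale, an ensemble-CNN workflow for classifying
ovarian/adnexal tumors on B-mode ultrasound as benign or malignant:
synthetic phantom generation, training-set augmentation, a zoo of small
trainable CNN classifiers, three ensemble decision rules, Grad-CAM saliency
with ensemble averaging, repeated random-subsampling evaluation, and a
confidence-threshold triage analysis. Clinical ultrasound archives of this
kind are private, and the full-size workflow fine-tunes large ImageNet
architectures on a GPU; everything here is sized to run on one CPU in
minutes while keeping every algorithmic decision testable.

## Synthetic phantoms (`synthgen`)

Each phantom is a grayscale H x W grid in [0, 1] containing one lesion on a
speckle-textured background. The morphology encodes the ultrasound features
sonographers use (the B/M features of the IOTA Simple Rules):

* **benign** — a smooth ellipse (`boundary_irregularity = 0`), one locule,
  no papillae, no solid component: a unilocular hypoechoic cyst;
* **malignant** — an irregular boundary (radial perturbation built from
  harmonics 3-7 with seeded random amplitudes and phases, amplitude drawn
  from U(0.08, 0.22)), and at least one of: multiple locules (Voronoi
  septation walls between seeded interior points), 1-3 bright papillary
  blobs, or an echogenic solid cap covering 10-35% of the interior.

Intensity model: background level 0.55, lesion interior 0.15, solid
component 0.45, septa 0.70, papillae 0.80, then multiplicative speckle
`I * (1 + n)` with zero-mean uniform `n` (default variance 0.05, the same
convention as the augmentation noise). No wave physics — no point-spread
function, attenuation, or shadowing — is simulated; passing tests on
phantoms demonstrates that the pipeline's machinery is correct, not that it
would reach any particular accuracy on clinical images.

The default resolution is 96 x 128 (the 975 x 674 clinical aspect ratio,
scaled down); the end-to-end fixtures use 64 x 64 for speed. Sizes below
32 x 32 are rejected.

**Separability guarantee.** The class signal exists independently of any
learning: `boundary_roughness` fits the boundary radius r(theta) of the
noise-free lesion mask with harmonics {0, 1, 2, 4, 6} (a smooth, possibly
eccentric ellipse plus its even overtones) and returns the relative RMS
residual. Smooth lesions score near zero, perturbed ones clearly above; a
single threshold separates the generator's two classes with 100% accuracy,
which the test suite asserts on random draws.

**Splitting.** `split_dataset` uses a pooled, seeded shuffle with
`floor(train_fraction * N)` training items (default 0.7). Only this
convention reproduces the reference bookkeeping 2 x floor(0.7 x 1896) =
2654 augmented training images; note those published counts are internally
inconsistent by one image (a 568-image validation set vs 1896 - 1327 =
569), which this package documents rather than resolves. A `per_class` mode
(floor within each class) is available but not the default.

## Augmentation (`augment`)

The recipe doubles the training set: each original image appears once with
an in-place randomization (horizontal flip with probability 1/2; one
rotation angle drawn uniformly from {+30, -30} degrees with probability
1/2), plus exactly one speckle-noised copy of the un-noised original.
Speckle is multiplicative, `out = clip(I + n*I, 0, 1)`, with `n` i.i.d.
zero-mean uniform on [-sqrt(3v), +sqrt(3v)] so that Var(n) = v (default
v = 0.05); a Gaussian multiplier is selectable. Rotation is bilinear about
the image center on a fixed canvas with zero fill (ultrasound borders are
dark). Whether flip and rotation should be applied independently or
exclusively is not specified anywhere authoritative; the independent-
probability scheme is a documented choice, and only the noise copies add
images because nothing else accounts for the exact 2x count.

## Backbone zoo (`backbone`, `_nn`)

No deep-learning framework is used: `_nn` is a purpose-built numpy layer
library (im2col convolution, depthwise convolution, residual and
depthwise-separable blocks, global average pooling, dense head, softmax
cross-entropy, Adam). Each layer carries an analytic backward pass,
verified against central finite differences in the test suite; the same
backward machinery supplies Grad-CAM's feature-layer gradients. Everything
is float32 end to end and fully deterministic given the seeds (weight
initialization, shuffle order, and data are all driven by
`numpy.random.Generator` streams derived from explicit seeds).

Three presets mirror the structure (not the scale) of the architectures a
clinical system would choose for their accuracy/time ratio:

| preset | input | stages | ingredient |
|---|---|---|---|
| tiny-residual-18-like | 64 x 64 x 3 | widths 8-16-32 | residual blocks |
| tiny-residual-50-like | 64 x 64 x 3 | widths 8-16-24-40 | deeper residual stack |
| tiny-separable-xception-like | 96 x 96 x 3 | widths 8-16-32 | depthwise-separable convs |

Inputs are bilinearly stretched (no letterboxing) to each preset's fixed
input size, grayscale replicated across three channels, then mapped to
[-1, 1] before the stem. The training recipe is a fixed-epoch Adam run
(defaults: 30 epochs, batch 32, learning rate 1e-4) minimizing plain
cross-entropy with no weight decay, schedule, early stopping, or checkpoint
selection. The 1e-4 default matches a transfer-learning setting; the
desk-scale experiments train these tiny networks from scratch, where 1e-4
barely moves in 10 epochs, so the experiment fixtures use 1e-3 to 3e-3 —
the ordinary from-scratch range — and the choice is recorded per fixture.
There is no ImageNet pretraining anywhere.

Class order is (benign, malignant) throughout; malignant (index 1) is the
positive class.

## Ensemble rules (`ensemble`)

Given one softmax confidence vector per model:

1. **majority vote** — each model votes its argmax; the label with most
   votes wins; a tied vote falls back to the confidence sum restricted to
   the tied labels. Confidence = winning vote share.
2. **confidence sum** (soft voting) — per-class scores are summed; argmax
   wins. Confidence = winning sum / number of models.
3. **weighted confidence sum** — as (2), but the model with the best
   class-specific accuracy has its score for that class multiplied by 1.5
   before summation. Confidence = winning sum / (n - 1 + 1.5), the maximum
   attainable, so all three strategies emit confidences on one [0, 1] scale
   (no authoritative formula exists for the ensemble confidence; this
   normalized form is the package's definition).

Exact ties resolve to **malignant**: in this application a missed
malignancy is the costlier error. The best-model-per-class mapping for
rule 3 is measured on the un-augmented training fold of each repetition,
never on the validation fold. `select_backbones` ranks candidate models by
accuracy/time ratio (descending, ties toward higher accuracy) — the rule
that picks which trained models enter the ensemble.

## Grad-CAM (`gradcam`)

The canonical gradient-weighted class-activation formulation: channel
weights are the spatial mean of d(logit_c)/d(feature map) at the last
convolutional stage, the weighted channel sum is rectified, bilinearly
upsampled to the image size, and min-max normalized to [0, 1] (all-zero
maps pass through unchanged). The ensemble map is the pixel-wise mean of
the per-model maps. Each per-model map is normalized **before** averaging —
a deliberate choice (the source procedure says only "superimposed and
averaged") so that every model contributes equally regardless of raw
gradient magnitude. Consequence, asserted as a property test: a pixel only
one of n models attends to is attenuated to 1/n, which is exactly the
mechanism that suppresses spurious background attention in the ensemble
view. Overlays blend the grayscale image with the jet colormap at a given
alpha.

## Evaluation (`evaluate`)

With malignant positive:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SE  = TP / (TP + FP)          SP = TN / (TN + FN)        (as_printed)
    SE  = TP / (TP + FN)          SP = TN / (TN + FP)        (conventional)
    SD  = sqrt((1/N) * sum (x_i - mean)^2)                   (population)

The `as_printed` SE/SP follow the source formulas verbatim even though they
are algebraically precision and NPV rather than textbook
sensitivity/specificity; both modes are implemented, every report is
labeled with its mode, and zero denominators raise rather than silently
returning 0. Default mode is `as_printed` for fidelity.

`repeated_holdout` is Monte-Carlo cross-validation: repetition r re-splits,
re-augments, and re-trains the whole zoo with seed `base_seed + r`, scores
singles and all three ensembles on the held-out fold, and summarizes each
metric as mean +- population SD. `paired_t_test` is the classic paired t on
differences (df = n - 1, two-sided; all-zero differences degenerate to
p = 1). `tradeoff_curve` appends models in ascending single-image time
order and min-max scales subset accuracy and cumulative time across subsets
into [0, 1] (flat axes are flagged degenerate rather than divided by zero);
wall-clock timings are measured and reported but never asserted — they are
hardware facts, not algorithmic ones.

## Triage (`triage`)

Selective prediction over per-image records (truth, prediction, ensemble
confidence): retention is `confidence >= threshold` everywhere (the source
text mixes "more than" and ">="; `>=` is used uniformly). The sweep runs
0.80 to 1.00 in 0.01 steps (21 rows); the operating-point report counts
excluded / retained-correct / retained-incorrect (a partition of the
records, asserted at every threshold) and compares retained-set accuracy
against the no-triage baseline. Retained-count monotonicity in the
threshold is asserted; retained-accuracy monotonicity is not, because it is
not guaranteed pointwise. The threshold is an exposed parameter (default
0.86, the published operating point, which that study justified by an
~20% expert-vs-pathology inconsistency rate — an external statistic this
package does not encode).

## Pipeline and problem sizes

`pipeline.run_experiment` chains all stages and writes metrics CSVs,
decision CSVs, heat-map PNGs, the triage curve, and a structured log with
per-stage seeds and wall times; the whole bundle is a pure function of the
`ExperimentConfig`, and stage seeds derive from `base_seed` (plus the
repetition index) so stages can be re-run in isolation.

The standard desk-scale fixture is 400 phantoms (200 per class, 64 x 64),
all three presets, 10 epochs at learning rate 1e-3, and 3 repetitions of
the 70/30 subsampling — about 80 s on one CPU. On it, the confidence-sum
ensemble's mean validation accuracy sits near 90%, at or above the best
single model and far above the weakest (the separable-convolution preset is
deliberately the most data-hungry of the three). The ensemble-beats-worst
comparison is asserted; ensemble-beats-best is reported but not asserted,
since at 3 repetitions it is a statistical tendency, not a theorem.

## Numerical notes and limitations

* Bilinear rotation cannot return a binary step edge exactly after a
  +30/-30 round trip; pointwise tolerances for the rotation identity are
  checked on smooth fields, distributional ones on checkerboards.
* Softmax scores of lightly trained tiny networks are soft; on the
  desk-scale fixture the ensemble confidences rarely exceed 0.86, so the
  fixture's triage demonstration uses the start of the sweep (0.80) rather
  than the clinical operating point.
* Finite-difference gradient checks use float64 and a small epsilon, with
  randomized biases, because a pre-activation sitting exactly on the ReLU
  kink makes central differences legitimately disagree with the
  subgradient.
* The phantom generator omits acoustic shadowing, depth-dependent gain,
  probe geometry, text/caliper burn-ins, and inter-patient variability;
  results on phantoms say nothing quantitative about clinical performance.
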