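# Methods

## Problem setting

A medical image classifier is validated on samples from a source
distribution P and deployed on a target distribution Q. We test
H0: P = Q against H1: P ≠ Q from unlabelled images alone. Two shift
families matter: *subgroup shifts*, where Q re-weights a subpopulation of P
(every target image is within the source support, so outlier detection
fails by construction), and *out-of-distribution (OOD) shifts*, where
target images (here: ungradable, insufficient-quality images) lie outside
the source support.

All detectors follow the same four-fold protocol. Training folds
S_P^tr, S_Q^tr of size n_train per side fit the feature extractor; test
folds S_P^te, S_Q^te of size m per side feed the statistic; the decision is
made at significance level α = 0.05. Train/test disjointness is enforced at
the image-identifier level by partitioning each backing dataset into a
train pool and a test pool (default 50/50) before any sampling; folds are
then drawn i.i.d. with replacement from their pool according to the shift's
weighting rule. Disjointness is per-image because synthetic patients carry
one image each; for real data with repeated patients the same partition
mechanism applies to whatever identifier the attribute sheet provides.

## Permutation testing

Statistics are calibrated by re-partitioning the pooled test folds B times
(default B = 100, giving p-value resolution 1/(B+1) = 0.0099, sufficient
for decisions at α = 0.05) and using the add-one estimator

    p = (1 + #{permuted t at least as extreme}) / (1 + B),

which guarantees p ≥ 1/(1+B) and validity P(p ≤ α) ≤ α under
exchangeability. The boundary p = α rejects. C2ST uses the signed
two-sided criterion |t| ≥ |t_obs| (the logit-difference statistic is
signed); MMDD uses the upper tail t ≥ t_obs (a discrepancy has no
meaningful lower tail). Permutations re-partition *precomputed* per-image
quantities — logits for C2ST, rows of the joint (2m)×(2m) kernel matrix for
MMDD — and never retrain the detector. Permuted values that equal the
observed statistic up to floating-point summation order are counted as
extreme (this can only increase p, preserving validity). MUKS does not use
the permutation engine: its per-class KS p-values come from the exact
two-sample distribution when both sizes are ≤ 25 and from the asymptotic
distribution with the standard effective-size correction otherwise
(delegated to scipy), combined with a Bonferroni rule,
reject iff min_c p_c ≤ α/C, with the overall p reported as the Bonferroni
bound min(1, C·min_c p_c). The KS statistic itself is evaluated at pooled
unique data points with right-continuous EDFs and no randomised
tie-breaking, so results are deterministic under ties.

The MMD estimator is the pairwise U-statistic that excludes i = j in all
four kernel blocks, including the cross terms. A consequence worth noting:
its value depends on the (arbitrary) pairing of x_i with y_i, so permuted
re-partitions are enumerated as *ordered* partitions; under H0 all
orderings are exchangeable and the test remains exact.

## Neural components

There is no deep-learning framework in the dependency footprint. All
learned components are small multilayer perceptrons over flattened pixels,
implemented in numpy with hand-derived backpropagation and verified against
finite differences in the test suite. At the 32–64 pixel scale this package
targets, the synthetic appearance effects are global and low-frequency, so
dense layers capture them well; convolutional or residual backbones buy
little here while costing an order of magnitude in training time. The
backbone knob required to study detector capacity survives as
{shallow, small, large} = {linear, one hidden layer of 32, two hidden
layers 128/64} for the domain classifier.

The training recipe is shared by the task classifier, the domain classifier
and the kernel feature net: cross-entropy (or the MMD objective), SGD with
Nesterov momentum 0.9, multiplicative learning-rate decay 0.9 per epoch,
light augmentation, and selection of the epoch with the lowest validation
loss (a 10% slice of the training fold, or an explicit validation fold for
the task model). The default initial learning rate is 0.01: the 0.001
conventionally used for full-scale residual networks underfits these small
dense nets within the epoch budget — at 0.001 the grading model collapses
to the majority grade (held-out 5-acc 0.79 = the grade-0 prevalence), while
at 0.01 it reaches ≈ 0.89 on the default synthetic population. Epoch
defaults: 25 for the task model, 20 for the domain classifier and the
kernel (each with early selection), batch 64 (32 for kernel training,
which pairs equal-size minibatches from both folds).

The deep kernel k(x,y) = ((1−δ)·g_a(f(x),f(y)) + δ)·g_b(x,y) is trained by
maximising the unbiased MMD estimate itself — deliberately *not* the
power-normalised objective, whose variance correction was not found
beneficial in this setting. Constraints are enforced by parameterisation:
σ² = exp(s) and δ = sigmoid(c) keep length scales positive and the mixing
weight strictly inside (0,1). Length scales initialise from the median
heuristic (2σ² = median pairwise squared distance on a warm-up batch of up
to 64 images per side); δ initialises at 0.5 (uninformative mixing). The
feature net maps pixels through one hidden layer of 64 units to a
128-dimensional embedding.

## Synthetic data generator

The generator emulates the population structure of a large multi-hospital
diabetic-retinopathy screening cohort. Default marginals (each normalised
to sum to 1): sex 60/39.7/0.3 female/male/other; ethnicity
8/6/11/5/69/1/1 african/asian/white/indian/latin-american/multiracial/
native-american; image quality 40/41/18 adequate/good/excellent with
"insufficient" at probability zero in the source (it exists only in the
OOD fold); co-morbidities 10%; DR grades 79/7/13/1/1. Attributes are
sampled independently of each other — the simplest model that supports
every simulated shift; correlation structure can be injected by editing
the marginals per use.

Rendering composes, deterministically given (attributes, spec, seed): a
circular bright fundus field on a dark background; a global pigmentation
offset per ethnicity (amplitude 0.10); a low-amplitude sinusoidal texture
whose phase encodes sex (amplitude 0.005 — calibrated so that a pixel-space
linear classifier reaches only ≈ 0.75 held-out accuracy on female-vs-male
in the mixed population, i.e. the effect is real but near the detection
threshold, the hardest of the simulated shifts); a diffuse off-centre haze
patch for co-morbidities (amplitude 0.18); grade-dependent lesion-like
spots (5 per grade, Gaussian radius 0.06 of the half-width, contrast
growing with grade) whose positions are per-image random — sized so that
grade leaves a learnable signature at 32 px rather than sub-pixel dots
invisible to dense nets; quality-dependent Gaussian blur (σ = 0, 0.5, 1.1,
3.0 px at the 64-px reference size for excellent/good/adequate/
insufficient, scaled linearly with image size) plus quality-dependent
extra noise; and for insufficient quality an additional heavy corner
occlusion. Pixels are clipped to [0,1] and quantised to the 8-bit grid at
render time, so the PNG + CSV on-disk format round-trips bit-exactly.

This produces the intended difficulty ordering — OOD quality shifts are
easiest to detect, co-morbidity shifts intermediate, sex shifts hardest —
which the test suite asserts. What the generator does *not* reproduce:
retinal anatomy (no vessel trees), realistic camera physics, attribute
correlations (e.g. grade–quality), patient-level repeated imaging, or any
claim that sex or ethnicity have these particular image-level signatures
in real fundus photographs (those mappings are stand-ins chosen for their
statistical detectability profile). Passing tests therefore demonstrate
correctness and calibration of the testing machinery and qualitative
orderings, not quantitative detection rates on real retinal data.

## Task model and subgroup report

The monitored algorithm is a 5-grade classifier (referable DR = grade ≥ 2).
The subgroup report gives, per level of a grouping attribute, the 5-class
accuracy and, after binarisation, binary accuracy, sensitivity and
specificity, with raw confusion counts stored so every metric is
recomputable; subgroups without referable cases report sensitivity as NaN,
and the "All" row equals the count-weighted pooling of subgroup confusion
matrices (asserted in tests). Training requires all five grades present
and fails with the missing grades named otherwise.

## Power evaluation

Detection rate = fraction of repetitions in which H0 is rejected, each
repetition drawing a fresh four-fold split (so C2ST/MMDD retrain every
time — the honest power estimate) with a child seed spawned from the master
seed; rates carry 95% Wilson intervals (well-behaved at the 0/1
boundaries). Type-I error is the same procedure with target = source.
Repetition errors are recorded and a cell is marked failed above a 10%
error fraction. The sweep axes default to m ∈ {10, 30, 50, 100, 200, 500}
and w ∈ {1, 5, 10, 100}.

## Desk-scale problem sizes

The package's study conditions are 32×32 images, backing pools of 2000
in-distribution images, a task model trained on 1500 + 300 images,
n_train = 200 and m = 100 for calibration runs (500 repetitions per
detector), and n_train = m = 500 for power runs (100 repetitions per
cell). These sizes make a full calibration-plus-power study a
minutes-scale computation on one CPU while leaving every statistical
property visible; the image-size and backbone knobs exist precisely so the
resolution and capacity dependence of test power can be explored upward.

## Known limitations

- The acceptance-style checks are property-based (calibration bounds,
  monotonicity, oracle equivalence) rather than reproductions of detection
  rates measured on restricted-access clinical data.
- MUKS power is tied to the task model: shifts that leave softmax outputs
  unchanged are invisible to it by design.
- The permutation engine assumes equal fold sizes; unequal folds are
  down-sampled with a warning rather than supported natively.
- Sex/ethnicity renderers are statistical stand-ins (see above); absolute
  power numbers for those shifts characterise the generator, not retinas.
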