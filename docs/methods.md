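# Methods

This note records the models, the defaults and the design choices behind
`antcad`, in the order the pipeline runs them.

## Information-theoretic relevance

All entropies are Shannon entropies in bits (base-2 logarithms) over
maximum-likelihood cell probabilities — raw counts divided by n, with no
smoothing. Mutual information is computed as I = H(X) − H(X|Y) with the
conditional entropy obtained through the chain rule H(X|Y) = H(X,Y) − H(Y);
the identity I = H(X) + H(Y) − H(X,Y) is enforced by tests to 1e-12.
Symmetrical uncertainty SU = 2I/(H(X)+H(Y)) is clipped into [0, 1] against
floating-point drift. Two degenerate cases need conventions:

* both variables constant ⇒ SU := 0 (a constant carries no information);
* the heuristic maps η_FC = 1/(1 − SU_FC) and η_FF = 1/SU_FF diverge at
  SU → 1 and SU → 0 respectively; both are clamped with ε = 1e-6
  (configurable), so a perfectly class-determined feature gets desirability
  1e6 rather than ∞.

Continuous features must be discretized before any of this. The package
defaults to **equal-width binning with 10 bins** per feature (equal-frequency
available), which is deterministic, monotone and standard practice for
SU-based feature ranking. A constant feature collapses to a single bin
without error. The bin count matters mostly through the SU bias floor:
independent variables have positive expected empirical SU of order
(bins_x−1)(bins_y−1)/(2n ln2 · H̄); at the default n = 300 this floor is
visible (~0.02) but two orders below planted-signal SU values.

## The selector

The feature graph is complete; state is a strictly positive per-feature
pheromone vector τ, initialized to all ones. Tour construction follows the
pseudo-random proportional rule with weight τᵅηᵝ. The printed form of the
rule puts the greedy branch at q < q₀; the canonical ant-colony-system
convention is the opposite, and since the toolkit cannot know which was
intended it implements the printed form and exposes `acs_convention=True`
to flip it. Greedy ties break to the lowest index; all randomness flows
through one `numpy` generator seeded from the config.

Numeric defaults (α = β = 1, ρ = 0.1, q₀ = 0.8, 20 ants, 50 iterations) are
conventional ant-colony-system values; none were stated by the method's
description, and all are config fields. The subset size k is fixed per run
(default ⌈F/10⌉) so deposits are comparable across ants and runs.

Subset scoring:

* **wrapper** — stratified 5-fold cross-validated misclassification error
  of a pluggable classifier (default 1-nearest-neighbor: fast and
  parameterless) on the restricted table; deposit = 1/max(error, 1e-3), so
  a perfectly separable subset deposits 1000. The CV fold seed is derived
  once per run, making scores deterministic within a run and cacheable by
  subset.
* **filter** — the mean static heuristic desirability of the subset's
  nodes. The description of filter deposits as an "average number of nodes"
  is dimensionally constant for fixed-length tours, so the toolkit
  interprets it as mean node desirability; this interpretation is flagged
  here deliberately.

Per-step heuristics: `fc` uses η_FC alone; `ff` uses η_FF of each candidate
relative to the last visited node; `combined` uses η_FC(j)/(1 + SU_FF(last, j)),
trading relevance against redundancy — the two criteria are named by the
method but no combination rule is given, so this is the package's choice.
Every ant deposits on every feature of its tour (the update formula sums
over all ants, not best-ant-only).

## Auto-encoder

One hidden layer each way: z = h⁽¹⁾(W₁x + b₁), x̂ = h⁽²⁾(W₂z + b₂).
Transfers default to logistic sigmoids (linear option provided for analytic
tests); the cost is the mean squared error over all samples and dimensions;
pixels are normalized to [0, 1] beforehand so the logistic output range can
cover them. Training is full-batch gradient descent from a seeded
Glorot-uniform initialization with backtracking: a step that raises the
cost is reverted and the learning rate halved, a successful step grows it
by 20%. This makes the cost sequence monotone non-increasing, adapts the
step to the gradient scale (gradients are tiny when averaged over 4096
pixel dimensions), and rules out divergence by construction. Analytic
gradients are verified against central finite differences (norm-relative
error < 1e-5 required). Hidden sizes are free; 256 is the default for
4096-pixel inputs, and the bundled experiments use 32 — enough capacity for
the synthetic classes at a fraction of the cost.

## Image pre-processing and splits

Grayscale conversion uses ITU-R BT.601 luma (0.299, 0.587, 0.114), with
integer inputs rounded back to integers. Resizing is bilinear with
anti-aliasing when shrinking; aspect ratio is not preserved (images are
stretched to the target square, the simplest reading of resizing to a fixed
resolution). Flattening is row-major, stated so feature indices are
interpretable.

The stratified split shuffles within each class with a seeded generator and
takes `round_rule(train_fraction · n_class)` training members. Published
per-class 80-20 counts for the two reference datasets are inconsistent
under any single rounding rule — flooring matches the chest X-ray counts
(e.g. 460.8 → 460) while nearest matches the brain-MRI counts
(1140.8 → 1141) — so the rule is a config enum, defaulting to
`nearest_train`.

CNN feature extraction is an adapter contract only: a backbone registered
under a known name must produce the published feature width (alexnet 4096,
googlenet 1000, resnet50 2048, densenet201 1920). Tests exercise the
contract with mock backbones; no pre-trained weights ship with the package.

## Metrics

A C-class confusion matrix is reduced one-vs-rest to per-class TP/TN/FP/FN;
per-class rates follow the standard formulas (ACC, TPR, TNR, PPV, NPV, F1,
MR, MCC) and are macro-averaged without class weights — published multiclass
tables give single values with no aggregation rule, and macro-OVR is the
reproducible default. The overall ACC comes from the matrix trace and
MR := 1 − ACC, so the pair sums to one exactly. Any 0/0 rate is defined as
0 and flagged on the report instead of propagating NaN. The algebra is
verified against an exact-rational re-derivation on random count vectors.

## Synthetic data

The table generator plants three column types: informative columns whose
class-conditional means sit `effect_size` noise-SDs apart (each feature uses
its own random permutation of the class offsets, so signal columns are not
mutual copies), redundant columns equal to an informative column plus
N(0, 0.1) jitter, and independent N(0, 1) noise columns. Defaults — 300
samples, 60 features, 8 informative, 4 redundant, 3 balanced classes,
effect size 1.5 — are sized so selection is non-trivial (a random subset
classifies near chance) yet minute-scale. The recovery experiment runs with
`n_redundant = 0`: a redundant copy carries the same class signal as its
source, so under a pure feature-class heuristic copies and sources are
interchangeable in the top-k and "informative columns recovered" would be
ill-posed; the redundant construction is instead validated through the
SU_FF matrix, where planted copies rank in the top 5% of pairs.

The image generator emulates class-structured inputs only: deterministic
per-class patterns (horizontal gratings, vertical gratings, centered
Gaussian blob) plus i.i.d. Gaussian pixel noise. It reproduces none of the
statistics of real radiographs — no anatomy, no acquisition artifacts, no
intra-class deformation — so passing end-to-end tests demonstrates that the
pipeline's machinery is correct and deterministic, not that its accuracy
transfers to clinical data.

## Problem sizes and determinism

The bundled experiments use the generator defaults above; the end-to-end
run uses 30 images per class at 64×64, a 32-unit auto-encoder trained for
60 epochs, and wrapper-mode selection of 20 latent features with 15 ants ×
10 iterations — sizes chosen to keep the full suite in the minutes range on
one CPU while leaving every effect measured comfortably above its
threshold. A single master seed derives per-stage seeds via
`SeedSequence([master, stage_index])`; reruns reproduce selected indices
and metric reports bit-for-bit (timings excluded).

## Known limitations

* SU estimation uses ML counts; with many bins and few samples the
  independence floor rises, and no bias correction is applied.
* The O(F²) SU_FF matrix is skipped unless a redundancy-aware heuristic
  mode requests it, but when computed it is quadratic in features.
* The auto-encoder is strictly one hidden layer, full-batch, CPU-only; it
  is a feature compressor, not a state-of-the-art representation learner.
* Wrapper scoring refits the evaluation classifier per candidate subset;
  with slow classifier families, filter mode is the practical default.
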