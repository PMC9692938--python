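# antcad

Ant-colony feature selection for image-based computer-aided diagnosis.

Medical image classifiers (COVID-19 from chest X-rays, brain-tumor typing
from MRI slices) work on feature vectors extracted by deep networks — and
most of those features are redundant or irrelevant. `antcad` implements a
pipeline whose core is an **ant colony optimization (ACO) feature selector**
guided by entropy-based relevance heuristics, together with everything
needed around it: a single-hidden-layer auto-encoder feature extractor, an
image pre-processing stage, a pluggable classifier/metric harness, and
synthetic generators with planted ground truth so every stage is testable
without downloading any dataset.

## The method

**Relevance heuristics.** Features are discretized (equal-width, 10 bins by
default) and scored with symmetrical uncertainty, the normalized mutual
information

SU(X, Y) = 2 I(X; Y) / (H(X) + H(Y)) ∈ [0, 1],

computed in bits from empirical counts. SU_FC (feature–class) measures
relevance, SU_FF (feature–feature) redundancy. These map to heuristic
desirabilities η = 1/(1 − SU_FC) and η = 1/SU_FF (ε-clamped where the maps
diverge).

**The selector.** Features are nodes of a complete graph with pheromone
trail τ (initialized to 1). Each of *m* ants starts on a random node and
grows a k-subset by the pseudo-random proportional rule: with probability
q₀ it takes the unvisited node maximizing τᵅ·ηᵝ, otherwise it samples
proportionally to those weights. After each iteration every ant deposits on
its subset following

τᵢ(t+1) = (1 − ρ)·τᵢ(t) + Σₖ Δτᵢᵏ,

where Δτ is the inverse cross-validated classifier error of the subset
(wrapper mode) or its mean heuristic desirability (filter mode). Defaults:
α = β = 1, ρ = 0.1, q₀ = 0.8, 20 ants, 50 iterations.

**Extraction and evaluation.** Images are converted to grayscale (BT.601),
resized to 64×64, flattened and normalized; a logistic auto-encoder
z = h(W₁x + b₁), x̂ = h(W₂z + b₂) trained by full-batch descent on the
mean squared reconstruction error supplies the latent feature table.
Adapters for pre-trained CNN backbones (AlexNet 4096, GoogLeNet 1000,
ResNet-50 2048, DenseNet-201 1920 features) are supported as registered
callables — no weights are bundled. Classification runs through a roster of
scikit-learn families (decision tree, SVM, KNN, ensemble, naive Bayes,
discriminant analysis) and is scored with macro-averaged one-vs-rest
ACC/TPR/TNR/PPV/NPV/F1/MR/MCC from the confusion matrix.

## Worked example

```bash
python examples/02_aco_selection.py
```

```
selected subset: [0, 1, 2, 3, 4, 5, 6, 7]
planted informative features recovered: 8/8
1-NN cross-val accuracy: selected 1.000 vs random subset 0.867
```

The planted table has 300 samples and 60 features of which only 8 carry
class signal (class means 1.5 noise-SDs apart). The selector recovers all 8
from SU-guided pheromone search alone; a random 8-subset, which mostly
picks noise columns, classifies far worse. The other examples walk through
relevance ranking (`01`), auto-encoder compression (`03`), the metric
bundle (`04`) and the full image pipeline with a with/without-selection
comparison (`05`).

The same stages are scriptable from the shell:

```bash
antcad synth table --n 300 --features 60 --out table.csv --truth truth.json
antcad select --input table.csv --mode filter --k 8 --seed 1 --out selection.json
```

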