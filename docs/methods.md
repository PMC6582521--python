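# Methods

`imgqsar` predicts compound potency (pIC50) from 2D structure depictions and
benchmarks that image route against fingerprint-based baselines under a
controlled experimental design. This note documents the models, the data
conventions, the synthetic-data generator that defines the package's study
conditions, and the numerical choices made where the design was open.

## Data curation

Input is a ChEMBL-style activity table (compound structure, `standard_value`,
`standard_units`, `standard_relation`, target). Curation applies, in order:

1. **Stringent activity filter.** A row survives iff `standard_units == "nM"`
   and `standard_relation == "="` (exact string equality after whitespace
   trimming) and the value is positive and finite. No unit conversion is
   attempted; an audit log counts drops per rule.
2. **Structure standardization.** The fragment with the most heavy atoms is
   kept, removing counterions and solvents. Ties break by molecular weight,
   then by lexicographically smallest canonical SMILES, so the choice is
   deterministic. A molecule whose surviving fragment contains an element
   outside the organic whitelist {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}
   is rejected (recorded, not raised). Charged organic species are kept as-is;
   no neutralization or tautomer canonicalization is performed.
3. **Log-scale conversion and aggregation.** IC50 [nM] becomes
   pIC50 = 9 − log10(IC50); replicate measurements for the same
   (compound, target) pair are averaged **on the pIC50 scale**, not on the
   IC50 scale (the two differ; the log-scale mean is the contract).

Curation is idempotent: re-curating its own output reproduces it.

## Molecular representations

* **Images.** Standardized molecules are depicted with kekulized (explicit
  alternating) bonds, element-coloured heteroatom labels and dark bond lines
  on a white background, rasterized directly at 224 × 224 × 3 (the input size
  the backbone families expect). Rendering is deterministic: identical
  structure and settings give byte-identical PNGs; a provenance hash of the
  renderer settings is attached to every image and used as the disk-cache key,
  so images are comparable only within one depiction style. Raster fidelity
  (fonts, antialiasing) is a property of the renderer version; only the size
  and the Kekulé style are contractual.
* **Fingerprints.** Hashed circular (Morgan) fingerprints of radius 2 folded
  to one of {128, 256, 512, 1024, 2048} bits, cached per record.

Before entering a network, images are scaled to [0, 1] and normalized with
the fixed per-channel constants mean (0.485, 0.456, 0.406) and
SD (0.229, 0.224, 0.225) per RGB channel.

## Model families

* **ConvNet regressors.** A convolutional feature extractor from one of four
  classic families — AlexNet, VGG-19-bn, ResNet-152, DenseNet-201 — with the
  classification layers replaced by a regression head with **no output
  nonlinearity**: either a single linear layer ("standard") or five
  fully-connected layers of widths 4096, 1000, 200, 100 and `n_tasks`
  ("extended") with ReLU activations and 50% dropout after each hidden layer.
  "Five fully-connected layers" counts the four hidden widths plus the linear
  output layer. Whether a ReLU follows the last hidden layer is a config
  switch (`final_hidden_relu`, default on). Multi-task heads end in one
  output per task. The feature extractor is identical between the standard
  and extended variants of one backbone seed.

  The networks are implemented in a compact NumPy engine written for this
  package (dense/conv/pool/batch-norm layers with explicit forward/backward
  passes; convolution via im2col). Backbones are **randomly initialized**
  (He): no pretrained-weight source ships with the package, and
  `pretrained=True` raises. The frozen-random-backbone configuration treats
  the convolutional stack as a fixed random feature extractor — a legitimate
  and well-studied regime (random-feature regression) that keeps the whole
  pipeline runnable on one CPU.
* **Fingerprint DNN.** input → 60 → 20 → 10 → 1 with ReLU and 10% dropout on
  the three hidden layers.
* **Random Forest.** 100 trees, otherwise library defaults (scikit-learn),
  seeded. The validation split is deliberately unused by the forest (nothing
  is tuned); it stays in the split so all families share one test set.

## Training

All records are split 70/15/15 into train/validation/test
(train = ⌊0.70 n⌋, validation = ⌊0.15 n⌋, test = remainder) uniformly at
random; **the same split is reused by every model family**.

Networks minimize per-mini-batch mean squared error with SGD + Nesterov
momentum 0.9 (MSE has the same argmin as the monitored RMSE; a per-batch RMSE
objective would only rescale gradients). Validation RMSE is computed every
epoch; the parameters of the best-validation epoch are kept, and training
stops early when validation RMSE has not improved for the patience window.
The learning rate follows a cyclical step-decay schedule:

    lr(e) = lr0 · decay^⌊(e mod 200) / step⌋

with decay ∈ {0.1, 0.6}, step ∈ {10, 25}; the rate resets to `lr0` at each
200-epoch cycle boundary. Momentum buffers are carried across cycle
boundaries. ConvNets default to 600 epochs with patience 250 (patience is
evaluated on the global best, so it spans cycle boundaries); the DNN runs up
to 2000 epochs with patience 200 and batches of ⌈0.15 · n_train⌉. Grid search
enumerates lr0 ∈ {0.1, 0.01, 0.005, 0.001, 0.0001} × decay × step ×
augmentation × batch ∈ {4, 16, 32} (120 points) and selects minimal
validation RMSE, ties broken by enumeration order.

Training-time **augmentation** applies, independently with 50% probability
per image per epoch: a horizontal flip, a vertical flip, and a ±90° rotation
(direction uniform). These are label-preserving dihedral transforms; any
composition stays in the 8-element dihedral orbit of the image.

Two further training details are the package's own choices:

* The output layer is initialized at the mean-predictor solution (zero
  weights, bias = mean training label per task), so the network starts from
  the null model and spends its epochs learning signal rather than the label
  offset. Disable with `OptimSpec(init_output_bias=False)`.
* With a frozen backbone and augmentation off, backbone features are computed
  once and cached for the whole run; `standardize_features` additionally
  z-scores them on the training split. This is the `ci` preset's path.

**Presets.** `full` mirrors the publication-scale schedule (600 epochs,
patience 250). `ci` is the desk-scale profile used throughout the test suite
and the acceptance script: frozen random AlexNet backbone, standard head on
standardized cached features, lr0 = 1e-4 (chosen as ~1/feature-dim for the
9216-dimensional standardized features), batch 16, ≤30 epochs, patience 10,
no augmentation. It completes in minutes on one CPU. Problem sizes in the
shipped analyses (600 compounds for fingerprint models, 200 for image models,
4×4×3×2 factorial designs with 10 replicates) were chosen to keep a full
from-scratch rerun at this scale.

**Multi-task training** masks the loss to observed (compound, task) pairs:
the mean of squared errors is taken over observed entries only, so a task
with no labels in a batch contributes exactly zero gradient. Per-task test
RMSEs are reported separately.

## Evaluation

* RMSE in pIC50 units throughout; Pearson's r; R² defaults to squared
  Pearson correlation (the convention under which Y-scrambling collapse is
  judged), with the coefficient-of-determination variant available.
* **Mean-predictor baseline:** the constant model predicting the training-set
  mean, evaluated on the test split. With imbalanced pIC50 distributions this
  null already achieves deceptively low RMSE, so every learned model is
  reported against it.
* **Ensembling:** per-compound arithmetic mean of two models' predictions
  (by default the best ConvNet and the 2048-bit RF). By convexity of the
  Euclidean norm the ensemble RMSE never exceeds the mean of the component
  RMSEs.
* **Y-scrambling:** labels of train+validation compounds are permuted
  uniformly; test labels and all structures are untouched. A sound pipeline
  collapses to R² ≈ 0 on the test set.
* **Residual diagnostics:** residual mean/SD, normal Q–Q pairs, and a
  quantified heteroscedasticity check — the slope of |residual| on predicted
  value, flagged at p < 0.01 — instead of a visual judgement.

## Factorial comparison of runs

Per-run performance (test RMSE; any per-run scalar can be supplied) is
modelled by treatment-coded OLS. The main-effects model is

    response = Dataset_i + Model_j + Batch_k + Augmentation_l + μ0 + ε

and the cross-family comparison adds the full Dataset × Model interaction.
Reference levels are absorbed into μ0, which on a balanced design equals the
reference cell's mean response; each coefficient is the offset of its level
from the reference. Per-factor p-values use a Type-II ANOVA (for the balanced
designs targeted here Type I and II coincide). Defaults pick the
lexicographically smallest level as reference so fits are invariant to row
order; references are configurable. Balance checking reports replicate counts
per design cell. `select_best_per_cell` keeps, per (dataset, replicate), the
architecture with the lowest test RMSE, ties broken by a configurable
architecture order.

## Synthetic structure-activity generator

The generator defines the package's study conditions: 6 drug-like scaffolds
(benzanilide, sulfonanilide, diphenylmethane, 2-arylbenzimidazole,
aryloxypyridine, arylpiperazine) with two substitution sites and 12
substituents give an enumerable space of 864 compounds. True activity is
additive:

    pIC50 = 4.5 + scaffold offset + contribution(R1) + contribution(R2)

with i.i.d. normal noise (SD 0.3) per emitted measurement. Most substituent
contributions are ≈0 and three are large (0.9–1.7), so the activity
distribution is imbalanced with its mode in the 4–5 band, as in IC50 sets
curated from public databases, while still carrying a substructure signal
strong enough for fingerprint models to recover (the defaults were set so
that a 100-tree RF reaches ≤0.6× the mean-predictor RMSE). Emission mimics
database records: IC50 in nM rounded to 3 significant figures (pIC50
round-trip tolerance 0.01), unit "nM", relation "=", a counterion fragment
appended with probability 0.1, and a second replicate row with probability
0.1. A ground-truth table records each compound's noiseless activity. An
optional second task blends the primary contribution map with an alternative
map for multi-task experiments.

What the generator does **not** emulate: realistic chemical-space diversity
(2 sites × 12 fragments is a toy lattice), assay-dependent noise structure,
activity cliffs, or inter-target correlations beyond the simple blend.
Passing tests therefore demonstrate pipeline correctness and recoverability
of a planted additive signal — not real-data predictive performance, which
requires the original database extracts and full-scale training.

## Numerical choices and degenerate inputs

* Filter predicates are exact string matches after trimming; curation rejects
  rather than repairs.
* `to_pic50` raises on non-positive or non-finite input; correlation metrics
  raise on constant input; residual diagnostics require ≥20 points.
* Non-finite training loss aborts with the epoch and learning rate in the
  message rather than continuing silently.
* Grid-search and best-per-cell ties break by enumeration order;
  largest-fragment ties by the deterministic key above.
* All randomness flows through explicit seeds (`numpy.random.default_rng`);
  fixed seeds reproduce split membership, rendered bytes, augmentation draws,
  and model predictions exactly.

## Known limitations

* No pretrained weights: transfer learning proper (fine-tuning ImageNet
  features) is out of reach offline; the frozen-random-feature regime is the
  supported desk-scale configuration, and full backbone training, while
  implemented, is impractically slow on CPU for the deep backbones.
* The curation whitelist definition of "organic" is a documented convention,
  not a universal standard.
* Aggregating replicates by the mean ignores measurement-quality weights.
* The DNN's learning-rate schedule reuses the cyclical step-decay mechanics
  with lr0 = 0.01 by default; no separate schedule was tuned for it.
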