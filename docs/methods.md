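# Methods

## Problem and model

`pairdx` implements a diagnostic classifier for thyroid-nodule expression
profiles that must pool samples from heterogeneous platforms (RNA-seq FPKM,
several microarray generations) without cross-platform normalisation or batch
correction. The device that makes this possible is a within-sample rank
feature in the top-scoring-pair family: for every unordered pair of roster
genes (gene I, gene II), a sample scores 1 iff its expression of gene I
strictly exceeds that of gene II, else 0 (ties score 0). Because the score
depends only on the ordering of two measurements *within one sample*, it is
invariant to any strictly increasing transform applied uniformly to that
sample — which covers scaling, offset and log transforms that differ between
platforms. A 923-gene roster yields C(923, 2) = 425,503 binary features per
sample.

Feature selection correlates each binary pair feature with the binary
malignant/benign label. For two binaries, the Pearson correlation is the phi
coefficient, equal to sqrt(chi²/n) of the 2×2 table in magnitude; the P value
comes from the two-sided t statistic r·sqrt((n−2)/(1−r²)) on n−2 degrees of
freedom. Pairs with |r| ≥ 0.4 and P < 0.05 are retained. The threshold is
applied to |r| because an anti-correlated pair is exactly as informative as a
correlated one (its indicator is the complement up to ties); `signed=True`
restores the literal signed reading. No multiple-testing correction is
applied — the raw P < 0.05 convention is deliberately preserved. Selection is
computed on training samples only and the retained vocabulary is frozen for
held-out data; recomputing it on test data would leak labels. Zero-variance
features are assigned r = 0, p = 1 and can never be retained.

## Classifier

The classifier is a stacked denoising sparse autoencoder (SDSAE) with a
softmax head, implemented from scratch in numpy:

* **One layer (DSAE).** Sigmoid encoder and (untied, by default) sigmoid
  decoder. During pretraining, each input vector has exactly floor(q·d)
  coordinates set to zero (q = 0.5 by default), chosen uniformly per sample;
  the layer reconstructs the *clean* vector from the corrupted one. The
  deterministic per-sample count, rather than i.i.d. Bernoulli masking, makes
  the corruption level exactly testable. Reconstruction loss is binary
  cross-entropy summed over features and averaged over the batch — the inputs
  are {0,1} pair scores, for which BCE is the natural likelihood; squared
  error is available via `recon_loss="mse"`. A KL-divergence penalty
  sum_j [ρ·log(ρ/ρ̂_j) + (1−ρ)·log((1−ρ)/(1−ρ̂_j))] on the batch-mean hidden
  activations ρ̂ pushes each hidden unit toward the sparsity target ρ = 0.1.
* **Stack.** Three hidden layers of 20 units. Greedy layerwise pretraining:
  layer 1 trains on the features, layer 2 on layer 1's clean (uncorrupted)
  hidden activations, likewise layer 3.
* **Fine-tuning.** The three encoders plus a softmax head are trained end to
  end on cross-entropy, with no corruption. Samples are split 80/20 into
  training and validation parts, stratified by class (at 14.2% benign an
  unstratified split easily goes single-class at small n); training stops when
  validation loss has not improved for `patience` = 10 epochs and the
  best-validation parameters are restored. The validation size is
  round(0.2·n) with per-class largest-remainder allocation.

All optimisation is plain mini-batch gradient descent with hand-derived
backpropagation. Defaults: learning rate 0.1, batch size 32, 100 pretraining
epochs per layer, up to 200 fine-tuning epochs. Initial weights are uniform in
±sqrt(6/(fan_in+fan_out)); all randomness (initialisation, shuffling,
corruption masks, the split) descends from one seed through independent
`numpy` substreams, so training is bit-reproducible and saved models reload to
bit-identical predictions.

### Sparsity-penalty weight

The weight β of the KL penalty is a genuinely open choice. The default is
**β = 0.1**. With β = 1.0 the deeper 20-unit layers reach the degenerate
optimum in which every hidden unit outputs the constant ρ: the KL term is
exactly zero there, the representation carries no sample information
(per-unit activation standard deviation collapses to ~0), and fine-tuning
cannot recover — the classifier degrades to the majority class. This happens
because the reconstruction term of a 20-input layer is of the same order as
the penalty, unlike the first layer whose reconstruction is summed over
thousands of pair features. At β = 0.1 the constraint is still clearly
active (mean hidden activation is pulled to ≈0.17 against an unconstrained
≈0.46) while the representation stays informative. β is configurable
everywhere and is recorded in the training log.

### Decision rule

A sample is called malignant iff its softmax malignancy probability is
≥ 0.5; the boundary is inclusive by documented convention. The threshold is
configurable on the model.

## Comparators

Four standard families are fitted to the same retained-pair features through
scikit-learn: MLPClassifier(hidden_layer_sizes=(200, 100), solver="sgd",
early_stopping=True, alpha=0.1, validation_fraction=0.20),
LogisticRegression(solver="lbfgs"), RandomForestClassifier(n_estimators=200,
max_depth=7, max_features=10), SVC(kernel="linear", C=0.1). They are
benchmarks, not the contribution, so delegation is appropriate; every
effective hyperparameter, including library defaults, is recoverable via
`baseline_provenance` for the run log.

## Diagnostic metrics

From a 2×2 confusion table (positive = malignant): sensitivity tp/(tp+fn),
specificity tn/(tn+fp), accuracy, PLR = sens/(1−spec), NLR = (1−sens)/spec,
PPV, NPV, prevalence. Conventions chosen to match clinical
diagnostic-accuracy reporting:

* **Proportion CIs** are Wald intervals p ± 1.96·sqrt(p(1−p)/n), deliberately
  *not* clipped to [0,1]: at extreme proportions and small n the printed
  bounds legitimately cross 100% or 0% (e.g. sensitivity 71/72 on 72
  positives gives 95.9–101.3%). `clip=True` truncates on request.
* **Likelihood-ratio CIs** use the log method: ln(LR) ± 1.96·SE with
  SE²(ln PLR) = (1−sens)/(sens·n_pos) + spec/((1−spec)·n_neg) and the
  analogous form for the NLR, exponentiated back. All four cells must be
  positive; a zero cell is flagged, not silently propagated.
* **Accuracy CI**: reported as a Wald interval on (tp+tn)/n. Published
  accuracy intervals for this problem are sometimes far narrower than any
  binomial interval at the printed n and cannot be reproduced from counts;
  this package documents the divergence rather than imitating an
  unidentifiable convention.
* **AUC** is the Mann–Whitney statistic with half credit for ties, identical
  to the trapezoidal ROC area, computed from the softmax probabilities. No
  AUC CI is reported (DeLong/bootstrap are out of scope).
* **Predictive values at arbitrary prevalence** follow Bayes' rule, which at
  the cohort's own prevalence reproduces the count-based PPV/NPV exactly.
  This powers the 20–40% prevalence sweep relevant to cytologically
  indeterminate nodules, where the malignancy rate is far below the ~86% of
  surgical cohorts.
* z = 1.96 is fixed; metrics with zero denominators are reported as
  undefined, never as silent NaN. Display rounding is 1 decimal for
  percentages and 3 for ratios.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
microarray chemistry or RNA-seq count distributions:

* Labels are i.i.d. Bernoulli(prevalence); default prevalence 0.858
  (malignant), the imbalance of the pooled surgical cohorts being emulated.
* Each of `n_informative_pairs` planted pairs (a, b) occupies two genes used
  by no other pair; latent means satisfy mean(a) − mean(b) = +δ in class 1
  and −δ in class 0, centred on the genes' baseline. All other genes get
  class-independent baseline means drawn once per roster (uniform 4–8,
  arbitrary expression-like units) so accidental orderings cannot correlate
  with class. Latent expression adds Gaussian noise with s.d. σ.
* Each sample is assigned a platform uniformly at random; the platform
  applies x → scale·x + shift (then log1p for log-scale platforms) uniformly
  to the whole sample. Such transforms are strictly increasing, so pair
  scores from observed data equal those from latent data — the batch
  invariance the featurization claims. `gene_distortion > 0` adds gene-wise
  multiplicative jitter per platform, an explicit stress knob that *breaks*
  the invariance; default 0.
* One seed spawns independent substreams for labels, means, pair placement,
  noise, platform assignment and distortion, so changing σ does not reshuffle
  labels.

Defaults n_genes = 200, 30 informative pairs, δ = 3, σ = 1 (so δ = 3σ: a
planted pair flips orientation with probability Φ(3/√2) ≈ 0.983 per sample,
giving |phi| comfortably above the 0.4 selection threshold at n in the
hundreds). These are chosen for testability: strong planted signal, realistic
imbalance. What passing tests show is that the pipeline recovers planted
orderings and classifies near-perfectly when its assumptions hold; they say
nothing about effect sizes in real cohorts, where signal strength, probe
noise, within-class heterogeneity (multiple pathologies per class) and
platform intersection artefacts are unknown and unmodelled.

Train and held-out data must come from **one** simulated process (one seed):
a different seed plants different informative pairs and different baseline
means, i.e. a different population, on which no classifier trained on the
first can work.

## Study-scale evaluation

The end-to-end evaluation simulates 800 samples at the defaults above, trains
on the first 600 (featurize → filter → pretrain → fine-tune) and evaluates on
the remaining 200. Problem sizes were chosen so the whole run completes in a
few minutes on one CPU while leaving the filter ~20,000 candidate pairs and
the network several thousand retained features. With δ = 3σ the correlation
filter typically recovers all 30 planted pairs (the acceptance bar is ≥ 80%)
and held-out accuracy is ≥ 0.95.

## Numerical choices and degenerate inputs

* Sigmoid computed in the numerically stable split form; BCE and KL logs are
  clamped at 1e−7.
* Gradients of every parameter block (encoder/decoder weights and biases, all
  stacked layers, softmax head) are validated against central finite
  differences at rel. error < 1e−5 in the test suite.
* Ties in pair scoring go to 0 (the "otherwise" branch); discretised arrays
  tie often, so this is explicit, and it preserves monotone invariance.
* |r| exactly 1 gets P = 0 (the t statistic is infinite).
* Single-class labels, empty retained-pair sets, NaN expression, duplicate
  gene symbols and shape mismatches are hard errors with contextual messages,
  never silent coercions.
* Divergent training (non-finite loss) raises an error naming the epoch.

## Known limitations

* The generator's platform model is sample-uniform monotone by construction;
  real probe-level gene-specific distortions are only reachable through the
  `gene_distortion` stress knob, under which the invariance guarantee is
  void.
* No GPU path and no optimiser beyond plain SGD; the architecture is fixed to
  sigmoid activations.
* Real-cohort performance figures are not reproducible here by design: they
  require the original public accessions and unpublished training details.
  What this package reproduces exactly is the evaluation arithmetic
  (point estimates, Wald and log-method CIs, Bayes prevalence sweeps) from
  count-level inputs, and the pipeline's qualitative behaviour on data whose
  generating process is known.
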