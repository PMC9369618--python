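# Methods

## The problem and the model

`dsscreen` predicts which of c therapeutic categories (by default seven:
analgesic, antineoplastic, antibacterial, antiviral, antifungal,
antidiabetic, antiarrhythmic) a drug molecule belongs to, from structure
alone. Instead of trusting a single classifier, it treats each classifier's
predicted class-probability vector as a piece of *evidence* and combines
the evidences with Dempster's rule.

Formally, the class labels form a discrimination frame
Θ = {θ₁, …, θ_c}. A classifier's probability vector is read as a basic
probability assignment (BPA) m with mass only on the singleton hypotheses:
m(∅) = 0 and Σᵢ m(θᵢ) = 1. For two BPAs the conflict coefficient is

    Kc = Σ_{i≠j} m₁(θᵢ) m₂(θⱼ) = 1 − Σᵢ m₁(θᵢ) m₂(θᵢ),

and Dempster's rule fuses them by the normalized elementwise product

    (m₁ ⊕ m₂)(θᵢ) = m₁(θᵢ) m₂(θᵢ) / (1 − Kc).

Restricted to singleton BPAs the rule is commutative and associative, so a
set of classifiers fuses by a simple left fold. The restriction is
deliberate: the BPAs here *are* classifier probability vectors, which never
place mass on composite subsets. A general power-set implementation exists
only as a test oracle.

**High conflict.** When a pairwise step's Kc exceeds 0.95 (or equals 1,
where the rule is undefined), Dempster's rule is replaced for that step by
the arithmetic mean of the two masses and the row is flagged. The mean is a
conservative, order-symmetric stand-in chosen by this package; the
literature offers several specialised high-conflict rules, and the slot is
pluggable (`FusionSpec.fallback`). Masses of exactly 0 are floored at 1e-12
(configurable) and renormalized before combination, so calibrated
classifiers emitting hard zeros cannot manufacture spurious total conflict.

**Fusion sets.** A fusion spec is named by the ascending indices of its
member classifiers — 1 = RF, 2 = SVM, 3 = LR, 4 = LDA, 5 = ABT — so DS12
fuses the random forest and the SVM, DS1235 everything but LDA.

## Base classifiers

All five classifiers use a one-vs-rest (OvR) decomposition so that every
class receives a positive-class score; the scores are renormalized to a
probability vector (an all-zero row maps to the uniform vector).
Hyper-parameters are chosen per training set by exhaustive grid search
scored by mean stratified five-fold CV accuracy, ties to the earlier grid
point:

| classifier | grid |
| --- | --- |
| RF  | trees 10–100 step 10 × criterion {gini, entropy} |
| ABT | base learners 10–100 step 10 |
| SVM | C = 1…10 × kernel {polynomial (degree 3), RBF} |
| LR  | liblinear solver, C ∈ {1e-4, 1e-3, 1e-2, 0.1, 1, 10} |
| LDA | defaults, no grid |

Implementation note: both tree-ensemble grids nest in the ensemble size, so
the searches are run incrementally — a warm-started forest grown to 10, 20,
…, 100 trees consumes the same RNG stream as fresh fits at each size, and
the first k stages of a 100-stage AdaBoost equal the k-stage fit. The CV
scores, and therefore the chosen parameters, are exactly those of the
naive exhaustive search at roughly a fifth of the cost.

SVM scores become probabilities through libsvm's built-in sigmoid
calibration fitted inside cross-validation (`probability_mode =
"calibrated"`); a softmax over raw decision values is available as a
configuration alternative, since whether calibration or normalized decision
values feed the fusion is an open modelling choice.

## Data division and the repeated protocol

Samples are divided by the Kennard–Stone maximin rule on the standardized
feature matrix (z-score per column; distances are Euclidean, which is why
standardization precedes division). The rule seeds the training set with
the two most distant samples, then repeatedly adds the unselected sample
whose minimum distance to the training set is largest. Ties break to the
lowest row index, so every split is bit-reproducible.

KS is deterministic, but the evaluation protocol needs split-to-split
variability. The `random_start` policy draws the seed pair uniformly from
the top decile of most-distant pairs using the repeat's seed; everything
afterwards is the plain greedy rule. This is the smallest perturbation that
varies the split while preserving the maximin character; it is this
package's choice of randomization, not a canonical one.

The train fraction defaults to 0.75 (common chemometrics practice; the
protocol is fraction-agnostic and the value is configurable). The repeated
protocol runs 100 splits by default, fitting every base classifier per
split and reporting mean ± sd of prediction accuracy Q = n_correct/n and
Cohen's kappa K = (Q − p_e)/(1 − p_e) with
p_e = Σ_k n_true,k · n_pred,k / n². Kappa is the primary model-selection
criterion (it discounts the chance agreement inflated by uneven classes),
Q the tie-break.

Two protocol edge rules keep long sweeps well-posed:

* a split that leaves any class with fewer than 2 training members cannot
  be stratified for CV; such a split is rejected and redrawn
  deterministically from a derived seed (logged). At study scale (smallest
  class ≳ 40) this never fires; it matters only for scaled-down data.
* a test set may miss a class entirely; kappa is then computed from the
  observed marginals (logged), and in the measure-zero case of both label
  vectors being constant the repeat records kappa = 0 rather than aborting
  the sweep.

## External validation

The validation flow draws, per run, a fixed per-class number of molecules
out of the training pool (redrawn each run from the run's seed; run r uses
base_seed + 1000·r), fits on the remainder, and predicts the holdout plus
every multi-role molecule. Predicted probabilities are averaged per
molecule over the runs in which it was predicted; multi-role molecules
appear in every run. Default 3 runs.

A single-role molecule counts as correct when the averaged top-1 class is
its label. A multi-role molecule counts as correct when the top-1 class is
*any* of its 2–3 roles; the number of molecules whose role set intersects
the top-2 classes is reported alongside, because a multi-role drug's
secondary activity often surfaces as the second-ranked class. The top-1
membership rule is this package's operationalization of "correctly
predicted" for multi-label molecules.

## Molecule handling and features

Curation removes, in order: unparseable SMILES; multi-fragment structures
(salts, mixtures); molecules with molar mass above 1800 g/mol (default,
configurable — heavier molecules sit so far out in descriptor space that
they distort standardization); duplicate canonical structures (first kept);
and, opt-in, stereoisomer pairs (groups sharing a stereo-stripped canonical
form). Every removal is tallied; curation never raises on a bad molecule.

The tier system S1 ⊇ S2 ⊇ S3 ⊇ S4 encodes increasing curation strictness.
The original tier judgments are literature calls (is the drug an adjuvant?
is the indication a side use? is the mechanism known?), which are not
algorithmic; here they are driven by explicit per-record annotation flags
so the peeling logic itself is testable.

Five feature families are computed from SMILES with RDKit:

* **F1_combinatorial** — RDKit's scalar 2-D descriptor block merged with
  the 42 MQN counts and 192 2-D autocorrelations, de-duplicated by name
  (~444 descriptors before cleaning): a combinatorial block mixing
  count-based, constitutional, topological and autocorrelation information.
* **F2_descriptors** — the scalar 2-D descriptor block alone (~210); the
  surviving count after cleaning is data-dependent.
* **F3_maccs** — 167 MACCS structural keys.
* **F4_topological** — RDKit path-based fingerprint, 2048 bits (a common
  default; the width is configurable).
* **F5_morgan** — circular Morgan fingerprint, radius 4, 1024 bits.

Cleaning drops any column containing a missing/non-finite value, then any
zero-variance column. Binary fingerprints are standardized exactly like
real descriptors (after zero-variance bits are dropped), so the KS distance
computation treats all families uniformly.

## Synthetic data: what it does and does not show

The generators reproduce the three statistical properties the method must
cope with, and nothing else:

* class imbalance — default sizes 228/211/296/108/64/70/42, the shape of a
  curated seven-class drug collection, scalable by a factor;
* real-valued blocks — spherical Gaussians whose class means differ by
  `separation` within-class sd units on class-specific coordinates;
* binary blocks — Bernoulli bits whose rate rises by `bit_contrast` on a
  class-specific block of informative bits (default 64 per class over a
  background rate of 0.2).

`make_complementary_predictors` bypasses featurization and emits two
probability matrices with controlled argmax accuracies and a controlled
overlap between their error sets. An erring predictor keeps the true class
as a strong runner-up — the behaviour of real confusable classifiers, and
the regime in which product-style fusion recovers the truth from one
confidently-correct partner. This is the minimal scenario exhibiting the
fusion gain of two complementary classifiers.

None of the generators simulate chemistry: no scaffolds, no activity
cliffs, no descriptor correlation structure. A passing synthetic run shows
the machinery is correct (splits, fits, fusion algebra, metrics), not that
any particular accuracy will transfer to real molecules. The toy SMILES
fixture (28 well-known drugs, two multi-role, one deliberately oversized
synthetic chain, one salt) exercises the real featurization path end to
end, but is far too small to support statistical claims.

## Numerical choices and scales

* Mass-vector sanity tolerance 1e-9; fused rows renormalized after every
  pairwise step; zero-mass floor 1e-12.
* KS ties (equal distances) break to the lowest row index; the
  deterministic policy takes the first flat argmax of the distance matrix,
  i.e. the lexicographically smallest max pair.
* Train size = round(fraction · n), with explicit guards for train < 2 or
  test < 1.
* z-scores use the population sd (ddof 0); summary stds over repeats
  likewise, so a single repeat reports sd 0.
* Test-scale defaults used by the test suite and the acceptance script:
  Gaussian protocol at 10 % of the study class sizes (n ≈ 103; 10 repeats
  for the separated case, 20 for the null), complementary predictors at
  n = 500, smoke runs at 2 repeats / 2 validation runs. These sizes are the
  package's choice of a desk-scale experiment; all protocol parameters
  (grids, folds, thresholds) stay at their study values.

## Known limitations

* Composite focal elements carry no mass; evidence like "one of classes
  {2, 5}" cannot be expressed.
* The high-conflict fallback is a package choice, not an established rule;
  conclusions drawn from heavily-flagged fusions deserve scepticism.
* Molecules are 2-D here: stereoisomers with identical connectivity get
  identical fingerprints in most families, so enantiomeric drug pairs are
  not discriminated (the opt-in isomer-pair curation rule exists for this
  reason).
* Multi-role molecules are never trained on; the pipeline cannot emit
  genuinely multi-label predictions, only ranked class probabilities.
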