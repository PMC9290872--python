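# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `rerx`, in the order the pipeline runs.

## Data model

A cohort is an *(n, p)* matrix bound to a schema that declares each
predictor *discrete* (finite integer codes; tested with `=`) or
*continuous* (interval domain; tested with `<=`/`>`). Validation is total:
every out-of-domain cell is an error with row/column coordinates, and
missing values are rejected rather than imputed — imputation is a modelling
decision this package refuses to make silently. CSV output prints
continuous values with `repr` (shortest round-tripping decimal) and is read
back with Python's correctly rounded `float()`, so write→read is bit-exact;
pandas' fast CSV float path is deliberately bypassed because it can be one
ulp off.

The packaged 52-variable perinatal schema records count-valued obstetric
history (parity, gravida, prior cesareans, prior preterm births,
spontaneous abortions) as *continuous*. Published rule sets in this domain
threshold these counts at fractional values such as 0.32 and 0.13, implying
a continuous treatment (likely scaling) upstream of tree induction; an
integer declaration would make those rules untypable. Two prior-delivery
history frequencies are unpublished for the emergency class and are set by
assumption (45% prior vaginal delivery, 10% prior vacuum delivery),
consistent in direction with the published parity shift.

## Network stage

Architecture: *p* inputs → H tanh units → 1 logistic output (default H = 4;
small single-hidden-layer networks are the norm for rule extraction because
the network is a scaffold, not the deliverable). Continuous inputs are
z-scored on the training data; the constants are stored in the network so
later predictions reuse them. Training is deterministic full-batch gradient
descent with classical momentum (defaults: learning rate 0.2, momentum 0.9,
L2 10⁻⁴, 400 epochs, seeded Gaussian init). Momentum was chosen over plain
fixed-step descent because it reaches the same fit in roughly a tenth of the
epochs without sacrificing seed-determinism; there is no minibatching, so
runs are exactly reproducible.

Pruning is greedy backward elimination at the *attribute* level, since the
downstream algorithm consumes attribute sets (D′, C′), not sparse weights.
Each step ranks all retained attributes by the training accuracy obtained
when that attribute's inputs are zeroed (computed with rank-1 corrections
to one shared forward pass), picks the least damaging, and accepts it
outright if accuracy stays within `prune_tolerance` (default 0.01) of the
current value; otherwise the network is briefly retrained without the
attribute (default 100 epochs) and the tolerance re-checked. The loop stops
at the first rejection and never empties the input layer. The per-step
invariant — accuracy after an accepted step ≥ accuracy before it minus the
tolerance — is what the tests assert; tolerances compound across steps by
design, which is what lets pure-noise attributes be swept out one at a
time. Retraining every *candidate* (rather than only the chosen one) would
square the cost for identical selections in all but adversarial cases.

## Tree stage

C4.5-style binary-outcome induction. Candidate splits at a node are every
midpoint between consecutive distinct values of each continuous attribute
(binary `<= t` / `> t`; attributes reusable down the path) and one multiway
split per not-yet-used discrete attribute (one branch per declared domain
code). A split is valid when at least two branches hold `min_leaf` samples
(default 2). Selection follows the C4.5 convention: among candidates with
positive information gain at least the mean gain of all candidates,
maximize gain ratio (gain / split information, bits). Ties are broken by
lowest schema index then smallest threshold, making induction reproducible
enough to verify against brute-force enumeration on small cohorts.

Pruning is pessimistic-error pruning: a subtree is replaced by a leaf when
the upper binomial confidence limit (confidence 0.25, normal-approximation
form) on the leaf's training errors does not exceed the sum over the
subtree's leaves plus 0.1. Subtree *raising* is not implemented.

Grafting (default on) is this package's own conservative variant of
post-hoc leaf refinement: each impure leaf with at least `2 * min_leaf`
local samples may be re-split — same candidate grammar as induction — when
the split strictly reduces the sum of Laplace-corrected branch errors
((e+1)/(n+2) per branch). Children predict their own majority class, so
training accuracy never decreases and the leaf count never decreases;
disabling the flag is an exact identity. Variants that import evidence from
sibling regions can relabel sample-free subregions; the in-region form was
chosen because its guarantees are provable and testable.

Rule conversion emits one rule per leaf in left-to-right order, merging
same-attribute interval tests (keep the tightest `<=` and `>`); the
resulting rules are mutually exclusive and exhaustive, which the tests
check by exhaustive matching rather than first-match shortcut.

## Recursion and the hyperplane fallback

Defaults δ₁ = δ₂ = 0.10 (support and error thresholds for refinement);
these are conventional values in the rule-extraction literature and are the
most consequential knobs in the configuration. Support and error of every
*emitted* rule are recomputed on the original input cohort, not on S′ or an
intermediate subset, so the printed statistics describe the population a
reader cares about.

The recursion as classically stated assumes each refined rule consumes at
least one discrete attribute. With continuous-mode trees (or an empty
antecedent) that assumption fails and the subproblem may be identical to
its parent, so the driver refines a rule only when the subproblem strictly
shrinks — fewer samples or a strictly smaller discrete pool — and keeps the
rule as a leaf otherwise. `max_recursion_depth` (default 10) remains a hard
error, not a silent truncation, because hitting it indicates a degenerate
configuration worth surfacing.

When D′ is empty the driver fits one separating hyperplane over the
surviving continuous attributes on S′ (falling back to the current sample
set if S′ is single-class) and stops on that branch. The hyperplane is a
logistic fit (L-BFGS on standardized attributes, tiny L2 of 10⁻⁶ for
identifiability) re-expressed in original units as ∑ WᵢCᵢ = W₀, and is
emitted as two half-space rules flagged `hyperplane` so interpretability
reports can count them separately.

## Rule engine and auditor

Classification is first-match-wins over the ordered rule list with a
default class. This makes printed order operative: published rule tables
can contain antecedent-identical rules with opposite conclusions, and the
engine must behave deterministically in their presence. The auditor makes
such anomalies visible instead of fixing them: it reports
antecedent-identical conflicting pairs, rules whose merged region is empty,
and rules shadowed by a single earlier rule whose region contains theirs.
Shadowing by a *union* of earlier rules is deliberately not detected; the
check is syntactic, sound and complete only for single-rule containment.
Thresholds are stored at full precision with exactly `<= t` closed /` > t`
open boundary semantics.

The packaged 15-rule perinatal fixture encodes each published rule row
verbatim (exactly its non-blank cells, original order, class 1 = emergency
cesarean). Its ninth/tenth rules are antecedent-identical with opposite
classes — presumed a transcription artifact in the source — and are
preserved, not repaired; the packaged default class is the majority
(non-emergency) class.

## Evaluation

Stratified k-fold assignment is drawn per run from a seed derived as
`(seed * 100003 + run * 101) mod 2^31`; folds partition each class
separately so the ~15% minority is present in every fold (unstratified
assignment is available by flag). Within each fold the entire pipeline —
network, pruning, tree, recursion — runs on the training split only.
Aggregates are means over all run × fold cells.

AUC is the tie-aware Mann–Whitney estimate (midranks). Rule classifiers
emit few distinct scores, so a documented convention maps rules to scores:
a sample's score is `1 − error` of the rule that fires for it when that
rule predicts the positive class, `error` when it predicts the negative
class, and 0.5 for default-class fall-through (rule errors estimated on the
training split). Any strictly monotone transform of scores leaves the AUC
unchanged, which the tests assert.

## Synthetic cohorts

The generator emulates a perinatal delivery cohort: 1513 rows, 228
positives (15.1%), continuous variables as truncated normals centred on
per-class published means with spread = published range / 4, binary
indicators as per-class Bernoulli draws at the published percentages.
Within a class, variables are independent — real risk factors are
correlated, and no correlation structure is published — so planted rules
are the mechanism for injecting dependence with known ground truth. Drawn
rows matching a planted rule have their labels overwritten by the rule's
consequent; buckets per class are filled by rejection so the requested
counts are *exact*, with a 50× oversampling budget before a hard error.
Label noise (default 5%) is applied as symmetric swaps — k positive and k
negative rows exchange labels, 2k ≈ noise · n — preserving exact class
counts at the cost of a higher effective flip rate in the minority class.

The planted-recovery benchmark (`planted_recovery_spec`) shifts the two
planted attributes (birth weight ~N(2000, 200) vs ~N(3000, 350) g; prior
cesareans ~N(1.0, 0.3) vs ~N(0.1, 0.15)) so the planted rule is the Bayes
classifier up to label noise. Consequences worth knowing: passing recovery
and CV checks on these cohorts demonstrates that the pipeline finds planted
low-dimensional structure under mild noise; it does *not* demonstrate
performance on real perinatal data, where predictors are correlated,
effects are weaker, and no two-condition rule is close to Bayes-optimal.

## Problem sizes and determinism

All shipped benchmarks run at the study scale the generator emulates
(n = 1513, p = 52); a full extraction takes well under a second on one
core, and 10×5-fold cross-validation of the pipeline completes in seconds,
so no test or script subsamples. Every stochastic component — network
initialization, fold assignment, the generator — is driven by explicit
seeds, and identical (cohort, config, seed) triples reproduce identical
networks, rule sets and CV reports bit-for-bit.

## Known limitations

* Binary outcomes only; multi-class extraction is out of scope.
* No missing-data handling by design (reject, never impute).
* The grafting variant is local to each leaf; it will not discover
  relabelings supported only by evidence outside the leaf's region.
* The auditor's unreachability check is syntactic (single-rule
  containment), not a full coverage analysis.
* The generator's independence-within-class assumption understates the
  difficulty of real cohorts; its anchors describe one hospital's
  population and are an emulation, not a reproduction.
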