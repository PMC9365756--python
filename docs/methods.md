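# Methods

This note documents the models and procedures implemented in `neurostack`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A `Dataset` couples a feature table with per-column kinds — `numeric`,
`nominal`, `region_count` — and one class token per row. Region-count
columns hold nonnegative integers (hypometabolic voxel counts per brain
atlas region; 47 columns for the Brodmann atlas, 90 for AAL) or the missing
sentinel. Missingness uses a single internal sentinel (NaN); the CSV reader
maps the input spellings `""` and `"NA"` onto it (extendable). Class order
is first-appearance order unless configured, which fixes the enumeration
order of one-vs-one tasks and makes tie-breaks reproducible. Every result
file embeds the run configuration, including the seed.

## Cleaning

`clean` removes explicitly listed columns and *flags* — never silently
deletes — rows violating a consistency rule. The default rule flags rows
whose region counts are all zero yet carry a disease label (a patient with
entirely normal brain metabolism labelled as demented is either a data
error or an interesting case; either way the decision belongs to the
analyst). Flagged rows are kept, with a warning, by default.

## Iterative forest imputation

The imputer follows the MissForest scheme:

1. initial fill: column mean (numeric, region-count) or mode (nominal);
2. visit variables in ascending order of missing count (ties by column
   order), each time fitting a forest of randomized trees on the currently
   completed table restricted to observed rows and predicting the missing
   entries; nominal predictions are the forest's majority vote;
3. stop when the combined change statistic — the sum of squared changes of
   the imputed numeric values normalized by their sum of squares, plus the
   fraction of changed nominal imputations — first *increases* (the
   previous sweep's values are kept) or drops below the tolerance, or when
   `max_iterations` is reached.

Defaults: 50 trees, squared-error split criterion with random split
selection (`ExtraTrees` learners), tolerance 1e-3, at most 100 iterations.
Integer-kind (region-count) imputations are rounded half-away-from-zero and
clipped at 0. Observed cells are never modified, and the whole procedure is
a deterministic function of (data, config, seed).

Assumption: missingness is (approximately) MCAR/MAR; the forests can
exploit nonlinear relations between columns, which is what the acceptance
experiment measures (NRMSE on a planted quadratic relation vs. plain mean
imputation).

## Encoding and binarization

One-hot encoding maps a nominal column with *n* observed levels to *n*
binary indicator columns `col=value` (exactly one is 1 per row). No level
is dropped: downstream feature selection treats each indicator as a
candidate feature in its own right, and collinearity is harmless to the
wrapper search.

Qualitative hypometabolism: region count *v* becomes 1 iff
*v ≥ threshold_voxels*. The default threshold of 1 voxel is deliberately
permissive and is an expert-facing parameter, not a constant. Binarization
is idempotent.

## Wrapper feature selection

Genotypes are variable-length, duplicate-free integer arrays over feature
indices (a duplicate index is meaningless for subset selection, so
crossover deduplicates and may shrink a child). Initial lengths are uniform
on [1, L_max] (default: half the feature count) with genes sampled without
replacement.

Fitness 1 is the mean held-out metric (accuracy or macro-F1) of the chosen
classifier over `cv_repeats` repetitions of stratified `cv_folds`-fold CV
(full-study protocol: 5 repetitions of 5-CV), with split seeds derived
deterministically from the run seed so fitness is a pure function of
(genotype, data, seed). Scores are cached per feature *set*. Fitness 2 is
the parsimony objective `1 − len/num_features`, exact up to floating
representation.

The mono-objective GA uses tournament selection (k = 2, 1 winner, drawn
without replacement), one-point crossover on variable-length genotypes,
random-resetting mutation (each gene replaced with probability 1/length by
a uniformly drawn unused index — the per-gene rate is a config knob, not a
fixed constant of the method), and elitism or annihilation survivor
selection. With elitism the best fitness is non-decreasing by construction.

NSGA-II uses binary tournaments on (non-domination rank, crowding
distance), the same variation operators, and (μ+λ) truncation by fronts
and crowding. The engine supports independent restarts with distinct seeds
(default 2), merging final fronts by non-domination. Population size and
generation count default to 100/200 as tool defaults.

The hypervolume indicator is computed by inclusion–exclusion over point
subsets: the dominated region is the union of boxes [reference, point] and
the intersection of any subset of boxes is the box of the componentwise
minima. This is exponential in front size and capped at 20 points — ample
for bi-objective fronts here; a sweep algorithm is the optimization hook if
larger fronts are ever needed. The reference point defaults to (0, 0)
because both objectives live in [0, 1].

## Classifiers and metrics

Seven classical families (Bernoulli naive Bayes, RBF-kernel SVM, k-NN,
decision tree, random forest, AdaBoost, gradient boosting) sit behind one
spec object that validates hyperparameter names and pins the seed; the
learners themselves are scikit-learn's. Multiclass precision, recall
(= sensitivity), specificity and F1 are macro-averaged over one-vs-rest
reductions; a class absent from the evaluation labels is excluded from the
macro mean with a warning. ROC curves are per class (one-vs-rest) by
threshold sweep. Since `SVC(probability=True)` is deprecated in current
scikit-learn, SVM scores are logistic-squashed decision margins
1/(1 + e^(−d)): monotone in the margin, per-sample, batch-independent —
properties a min–max rescale over a prediction batch would lack. Grid
search runs the same CV protocol as the wrapper fitness; ties break by
first-in-grid order.

## Grammatical evolution

Grammars are BNF tuples {N, T, P, S}; alternatives keep their textual
order because that order defines codon semantics. Parsing rejects
references to undefined non-terminals and dead ends (non-terminals that
cannot derive a terminal-only string, detected by a min-depth fixpoint).

Genotype→phenotype mapping is the leftmost codon-modulo rule: at a
non-terminal whose depth-feasible alternative set has k > 1 members, the
next codon c selects member `c mod k`; single-alternative choices consume
no codon (this includes the case where the depth budget leaves only one
feasible alternative of a larger rule). Exhausted codons wrap to the start
at most `max_wraps` times (default 2); beyond that the individual is
invalid and receives the worst fitness (F1 = 0 and a size penalty) rather
than raising.

The evolutionary loop operates on derivation trees directly:

- **PI-grow initialization** (position-independent grow): open
  non-terminals expand in random order; while no branch has reached the
  depth target, the deepest growth-capable open node (one that can still
  derive unboundedly deep, i.e. reaches a recursive cycle) is forced to
  pick a growth-capable alternative. Trees therefore reach, and never
  exceed, the target depth; initial targets are ramped uniformly between
  the grammar's minimum depth and `max_init_depth` for diversity.
- **Subtree crossover**: swap subtrees at a uniformly chosen pair of
  same-label non-terminals; children exceeding `max_depth` are resampled
  (bounded retries, then the parents are returned unchanged).
- **Subtree mutation**: regrow the subtree under one randomly chosen
  non-terminal within the remaining depth budget; applied (with
  `mutation events = 1`) to the population resulting from crossover.

The bi-objective NSGA-II maximizes the F1 of the thresholded expression
(threshold 0.5, configurable) and minimizes tree size. Tree size counts
*derivation* (non-terminal) nodes — expansion steps — not terminal leaves,
so a bare slot reference `x[i]` has size 3 under the default grammar.
Defaults: population 300, elite 30, generations 1500, crossover probability
0.9, selection proportion 0.5 (the fraction of the population entering the
mating pool each generation), `max_init_depth` 10, `max_depth` 15. The
"best" front member for reporting is the highest-F1, then smallest, then
lexicographically first phenotype.

Expressions are evaluated with protected operators — pdiv(a, b) = 1 where
|b| ≈ 0, plog(a) = log(1 + |a|), pexp with a clipped exponent — so no
phenotype can produce NaN/inf; evaluation is vectorized over meta-feature
matrices and cached per phenotype string.

The default combiner grammar is

```
<expr>  ::= (<expr> <op> <expr>) | <pre>(<expr>) | <var> | <const>
<op>    ::= + | - | *
<pre>   ::= tanh | plog | pexp
<var>   ::= x[<idx>]
<idx>   ::= 0 | ... | K-1
<const> ::= 0.1 | 0.5 | 1.0 | 2.0
```

with K the meta-feature slot count; enabling demographics extends `<idx>`
with the gender and age positions appended after the task outputs. Any
user grammar can be loaded from a BNF file instead.

## Discrete Bayesian networks

Layer-1 outputs are binarized by half-up rounding. Structure learning is
exact and score-based: per-node family scores (decomposable) are
precomputed for every candidate parent set up to `max_parents` (default 3),
best-parent-set tables are built per candidate node subset, and a dynamic
program over node subsets (sink decomposition) returns the globally
score-optimal DAG — the same optimum an A* search over orderings with an
admissible heuristic reaches; the subset DP is the simpler exact
realization at ≤ 12 nodes. Ties break toward lexicographically smaller
parent sets, so learning is deterministic and invariant to row order.

The default score is BIC (log-likelihood − ½·log n · #parameters): raw
maximum likelihood provably prefers maximally connected DAGs and defeats
structure discovery, so plain log-likelihood is selectable but not the
default. CPTs are maximum-likelihood with additive smoothing α = 1 by
default — an unseen parent configuration yields a uniform row instead of a
zero that would break the argmax over class networks.

One network is learned per class from that class's meta rows; all networks
share the full task-output node set so their joint probabilities are
comparable. A sample is assigned the class whose network gives its
evidence vector the highest joint probability; exact ties go to the first
class in order, with a warning. Partial-evidence inference is out of scope.

## The stacking meta-model

For classes {A, B, C}: three pairwise tasks, each with its own feature
subset (from the feature-selection stage) and classifier (RBF SVM by
default), trained only on examples of its two classes. Layer-1 outputs are
class-probabilities when available, else logistic-squashed decision scores.
Samples outside a task's pair still receive that task's score.

Development/validation protocol (per outer fold):

1. outer stratified 5-fold split; one fold held out end-to-end;
2. on the remaining folds, 10 iterations of stratified 5-CV produce
   out-of-fold layer-1 scores; the 10 repetitions are *stacked* as
   separate meta rows (averaging is available), each tagged with
   (outer fold, inner iteration) provenance;
3. majority classes are randomly down-sampled to the minority count
   (only when imbalance exists; no synthetic rows);
4. per class, a combiner is trained: GE mode splits the meta rows 50/50
   with class stratification, evolves on the training half and reads the
   reported F1 off the held-out half; BN mode learns the class's network
   from the class's rows;
5. layer-1 tasks are refit on the full outer-training data and the
   held-out fold is predicted by argmax over combiner values.

GE combiners read the tasks involving their class by default (class A ←
C_AvsB, C_AvsC); a `combiner_scope="all_tasks"` switch feeds every task's
output to every combiner, and BN combiners always use the full vector so
the per-class joints share a node set. The reference model is the same
machinery with one-vs-rest tasks and the identity (mean) combiner.

Demographic columns (e.g. a one-hot gender indicator and age) can be
appended as extra x slots after the task outputs, min-max scaled to [0, 1]
with bounds learned on the training data; the combiner grammar's index
rule then covers the appended positions. This is off by default — letting
the combiner read demographics directly can bias the diagnosis — and
exists to let users measure exactly that effect. `compare_strategies`
validates the GE and BN combiners and the one-vs-rest reference under the
same outer folds for side-by-side reporting.

## Synthetic data

The generator emulates the shape of the clinical cohorts this tool
targets: three classes with a 171/72/87 imbalance by default, age/gender demographics, standard-normal
cognitive scores with planted per-class mean shifts (in within-class SD
units), and zero-inflated Poisson region counts — controls almost all-zero
(p = 0.01), diseased classes with low background hypometabolism (p = 0.05)
unless a region carries a planted (probability, intensity) effect — so
qualitative binarization is meaningful. MCAR missingness is applied at a
configurable rate. The ground-truth object records every planted quantity.
What it does **not** emulate: realistic covariance between cognitive tests,
MNAR missingness, atlas spatial structure, or site/scanner effects —
passing tests demonstrate the machinery recovers *planted* structure, not
that it will perform identically on clinical data.

Direct meta-feature fixtures (per-class Beta-distributed slots, plus a
deterministic class-encoding mode) exercise the combiner layers without
running layer 1. A pairwise-separable generator plants a disjoint,
well-separated feature pair per class pair, the regime the pairwise
stacking design targets.

## Problem sizes used by the tests and acceptance script

Chosen as desk-scale versions of the study conditions: wrapper-selection
recovery uses 40 features / 5 planted effects at 1.5–2 SD, 125 samples,
NSGA-II population 50 for 30 generations with Bernoulli-NB 5-fold-CV
fitness (1 repetition), 5 seeds; GE combiner recovery uses population 50
for 100 generations (scaled from the 300/1500 defaults), 5 seeds; the
meta-model comparison runs the full nested protocol (outer 5-fold, inner
10×5-CV, balancing, 50/50 grammar split) on 105 samples with GE population
50 for 60 generations; imputation uses n = 150 with 15% MCAR over 10
seeds; Bayesian-network oracle checks enumerate all DAGs at 3–4 nodes and
all evidence vectors at ≤ 6 nodes.

## Known limitations

- Inclusion–exclusion hypervolume is exponential (capped at 20 points);
  only bi-objective problems are supported.
- Exact Bayesian-network search is limited to 12 nodes; no approximate
  fallback is provided, by design.
- The GE engine evolves trees, not codon arrays; genotype-level operators
  exist only in the mapping entry point used for validation.
- No probability calibration of layer-1 scores; the 0.5 GE threshold
  assumes roughly calibrated task outputs.
- Grid search is exhaustive only; no randomized/Bayesian search.
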