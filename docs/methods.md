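# Methods

`parsiopt` implements a parsimonious hyperparameter-optimization study for
multitask QSAR classification networks: a discrete architecture space,
four search strategies with a shared 100-evaluation budget, a pooled
non-error-rate score, a D-optimal main-effects analysis, and synthetic
data so the whole pipeline runs on a desktop in minutes.

## The architecture space

Nine factors are tuned, each at a small number of discrete levels:

| factor           | kind         | levels                               |
|------------------|--------------|--------------------------------------|
| neurons_layer1   | quantitative | 10, 100, 500, 1000                   |
| neurons_layer2   | quantitative | 0, 100, 500, 1000                    |
| neurons_layer3   | quantitative | 0, 100, 500, 1000                    |
| dropout          | quantitative | 0, 0.1, 0.25, 0.5                    |
| learning_rate    | quantitative | 1e-2, 1e-3, 1e-4, 1e-5               |
| epochs           | quantitative | 5, 50, 200, 500                      |
| activation       | qualitative  | sigmoid, relu, tanh, elu             |
| optimizer        | qualitative  | sgd, adam, rmsprop, adagrad          |
| penalty          | qualitative  | none, L1, L2                         |

The grid therefore has 4^8 x 3 = 196,608 points.  A zero neuron count
means the layer is absent; combinations with `neurons_layer2 = 0` but
`neurons_layer3 > 0` are kept as distinct grid points (so the cardinality
above is exact) and the gap is resolved when a network is realised:
`ArchitectureConfig.effective_hidden_layers()` truncates the hidden stack
at the first empty layer.  We deliberately do *not* repair such
combinations inside `decode`, because the chromosome coding must be a
bijection on the grid (`decode(encode(c)) == c` everywhere); a
`repair_gaps` flag offers the alternative behaviour.

Chromosomes use 2 bits per factor, big-endian level index.  The 3-level
penalty factor decodes its 2-bit code modulo 3, so pattern `11` wraps to
level 0; every 18-bit string is therefore decodable, at the price of a
slight sampling bias toward `penalty=none` under uniform random bits.

## The network and its score

The multitask model is a fully connected net, 1024 binary inputs, up to
three shared hidden layers, and one sigmoid output per task.  Training
minimises binary cross-entropy averaged over *observed* (sample, task)
cells only — a compound annotated for 3 of 30 tasks contributes exactly 3
terms — plus an optional L1/L2 penalty on the weight matrices (coefficient
1e-4; biases unpenalised).  Weights start from a truncated normal (mean 0,
std 0.05, cut at 2 std); batch size is fixed at 128; dropout is inverted
(surviving activations scaled by 1/(1-rate)) and active only during
training.  SGD, Adam (0.9/0.999), RMSprop (rho 0.9) and Adagrad update
rules are implemented directly; everything is deterministic under a seed.
Batch size, the penalty coefficient and the truncation bounds are fixed
choices, not tuned factors.

Performance is scored by pooling confusion counts over tasks:

    SN_T  = 100 * sum_t TP_t / (sum_t TP_t + sum_t FN_t)
    SP_T  = 100 * sum_t TN_t / (sum_t TN_t + sum_t FP_t)
    NER_T = (SN_T + SP_T) / 2

NER_T is computed as the plain mean of the two percentages (a version of
the formula that re-multiplies by 100 would leave the percentage scale and
contradict the property that NER always lies between SN and SP).  A
compound is called active when its output probability strictly exceeds the
per-task threshold; equality means inactive.  Thresholds are chosen per
task by scanning all midpoints of consecutive distinct scores (plus 0 and
1) and maximising per-task balanced accuracy, ties to the smallest
threshold.  Thresholds are fitted on the scores of the evaluation fold;
this is simple and self-contained but mildly optimistic — on label-permuted
data the 3-fold CV NER_T settles near 52 rather than exactly 50 with
~650-sample folds.  Users who prefer unbiased fold estimates can fit
thresholds on training scores via `pipeline.external_test_eval`, which
does exactly that for external-set evaluation.

The fitness of an architecture is its 3-fold cross-validated NER_T with
stratified folds, confusion counts pooled across folds before computing
the metrics.  Stratification uses greedy iterative multilabel
stratification (scarcest annotation first, each sample to the fold with
the greatest remaining need); exact multilabel stratification is NP-hard
and the greedy scheme keeps per-task prevalences within a fraction of a
percentage point at the sizes used here.

## Search strategies

All strategies see the same interface: a space and a fitness callable.
Grid search enumerates everything; random search draws 100 distinct
configurations uniformly.  The genetic algorithm evolves 10 binary
chromosomes for 42 generations: two roulette-selected parents (selection
probability proportional to raw fitness), one-point crossover, independent
10% per-bit mutation, children evaluated and inserted, the two worst
culled; at generation 21 the worst half of the population is replaced by
fresh random chromosomes (cataclysm).  This accounting gives 10 + 84 + 5 =
99 evaluations; the run is topped up with uniform random probes to exactly
100 so every strategy consumes the same budget.  The TPE starts with 10
random trials, then repeatedly splits the observations into the best
ceil(0.25 n) and the rest, models each group with per-factor categorical
densities (+1 pseudo-count), draws 24 candidates factor-wise from the good
density and evaluates the one maximising l(x)/g(x).  Duplicate
configurations are re-scored from a cache but still consume budget — the
budget counts trials, matching a deterministic per-run CV fitness.  One
consequence worth knowing: once the TPE densities concentrate, it can
propose the same configuration repeatedly and effectively stop exploring;
this is faithful to categorical TPE with a deterministic objective.

## Synthetic data

The generator emulates the shape of the three public benchmarks rather
than their chemistry: features are iid Bernoulli bits (density 0.05,
length 1024, mimicking sparse ECFP fingerprints); each task's latent score
mixes a shared component (weight sqrt(rho)) and a task-specific component,
both linear in a 25-feature sparse random projection; a per-task intercept
found by bisection matches the expected prevalence; missingness is
independent per cell (MCAR) with a repair pass so every sample keeps at
least one annotation.  Presets: `nura` (30 tasks, 50% missing), `tox21`
(12 tasks, 8% actives, 20% missing), `clintox` (2 tasks, 94.1%/7.1%
actives, fully annotated, n = 1472).  The `nura`/`tox21` missing fractions
and prevalences are plausible placeholders, not published values, and the
reduced default size is n = 2000 (`full_scale=True` restores the full
sample counts).

Two signal variants exist.  `signal_kind="weighted"` (default) draws
standard-normal projection weights — a realistic graded signal that is
only partially learnable at small n, because most of the class boundary's
margin is tiny.  `signal_kind="count"` uses unit weights, so the latent
score is the number of active signal bits — a structural-alert-style rule
with feature-space margin 1 that a sparsity-inducing learner can recover
essentially perfectly.  The learnability checks use the count variant with
noise-free labels (`signal_scale=inf`, threshold at the prevalence
quantile); an L1-penalized single-hidden-layer net then reaches CV NER_T
above 90 at n = 2000, while the same net without the penalty overfits the
999 irrelevant bits.  What passing these checks shows is that the trainer,
metrics and CV plumbing are correct — not that real fingerprint data is
this clean: real tasks have correlated features, activity cliffs and
label noise that the generator does not model.

Two surrogate fitness landscapes stand in for CV-trained networks when
testing the optimizers (milliseconds per evaluation).  Both are additive:
per-factor, per-level utilities plus a baseline plus Gaussian noise,
clipped to [0, 100].  `planted_landscape()` encodes the effect structure
the DoE analysis should find — high learning rate good, many epochs good,
L2 good and L1 clearly bad, few third-layer neurons good, everything else
flat (baseline 55, noise std 2).  `strong_landscape()` gives every factor
one strongly superior level (+5, baseline 40, noise std 1, unique optimum
at 85); its noise level matches the replica-to-replica spread observed for
best-of-100 searches.  The planted landscape is the reference for the
effect-sign analysis; the strong landscape is the reference terrain for
comparing strategies, because a landscape in which near-optimal
configurations are abundant lets random search saturate and washes out
the differences between informed and uninformed search.

## D-optimal effect analysis

The model is intercept + main effects, one coefficient per quantitative
factor and effects-coded columns (reference = first level) per qualitative
factor — matching a display of one coefficient per hyperparameter level.
Quantitative factors are coded by level rank mapped to [-1, 1], ranks
taken by increasing numeric value so the highest learning rate codes to
+1; rank coding rather than raw values because levels span decades.
Designs are selected by Fedorov exchange (random nonsingular start, swap a
design row for any candidate row that increases det(X'X), stop when a
sweep finds no improvement or after 100 sweeps; up to 50 restarts if the
start is singular).  Default run count is 3x the number of model terms.
Effects are fitted by ordinary least squares with 95% confidence intervals
from the t distribution on (runs - terms) degrees of freedom; a
coefficient is flagged positive/negative when its interval excludes zero,
otherwise inconclusive.

## Study orchestration

`run_study` repeats each stochastic strategy over replicas (seeds =
master seed + replica index), collects best-per-replica NER_T, and
compares methods with two-sided Welch t-tests (unequal variances,
Welch–Satterthwaite degrees of freedom, alpha 0.05); replica variances
differ across methods, so the pooled-variance test would be wrong.  Wall
clock per method is logged but never tested — it is hardware-dependent.
Grid search is refused above a configurable space-size cap (default
10,000 points).

## Problem sizes and known limitations

The shipped checks use: the full 196,608-point space for enumeration and
budget accounting; 10 replicas x 100 evaluations for method comparisons;
n = 2000, single-task, count-signal data for learnability; n = 1472
two-task data for the imbalance checks; 400-candidate subsets for the
D-optimal analysis on the full space.  Known limitations: the GA with the
prescribed operators (population 10, roulette on raw fitness, 10% per-bit
mutation, 100-trial budget) is a weak finisher on needle-like objectives —
on an 18-bit bit-counting task it reliably climbs to 16–17 ones but finds
the exact all-ones optimum in only ~5% of runs, because 10% mutation
flips 1.8 bits per child in expectation and drifts away from near-optimal
chromosomes; the cataclysm restores diversity but does not change this.
Real-data absolute scores (and the published per-dataset tables) are out
of scope: they require the external fingerprint datasets and
cluster-scale compute.
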