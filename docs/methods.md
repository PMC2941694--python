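# Methods

`nutrinet` implements two hybrid wrapper methods for analysing a
multifactorial binary trait (here: normal vs overweight BMI status) from
categorical genetic, nutritional and demographic factors, together with
the encoding, evaluation and simulation machinery they require.  This
note records the models, the defaults and why, and the design choices
made where the design was genuinely open.

## The classifier

A three-layer feed-forward perceptron: `n_inputs` input units, one
hidden layer of `n_hidden` hyperbolic-tangent units, and a single
log-sigmoid output unit producing a value in (0, 1).  An output ≥ 0.5
predicts the positive class C2 (overweight, BMI > 25); the tie at
exactly 0.5 goes to C2.  Because the hidden layer is tanh, categorical
inputs are encoded into [-1, +1]: class *j* of a *k*-class factor maps
to −1 + 2(j−1)/(k−1), so a 4-class factor maps to
[−1.000, −0.333, +0.333, +1.000], a 3-class genotype to {−1, 0, +1}
and gender to {−1, +1}.

**Training** is full-batch gradient descent on mean-squared error with a
momentum term (default `mc = 0.9`) and an adaptive learning rate
(initial `lr0 = 0.01`).  After each candidate step: if the epoch error
grew by more than `err_ratio = 1.04`, the step is discarded, the rate is
multiplied by `lr_dec = 0.7` and the momentum memory is zeroed;
otherwise the step is accepted, and if the error decreased the rate is
multiplied by `lr_inc = 1.05`.  These three constants are the canonical
defaults of this classical scheme and are exposed in `NetworkConfig`.
Batch (rather than online) updates and the MSE loss are this package's
choices — both fit the adaptive-rate scheme naturally and keep the
wrapper loops fast and deterministic.  Default stopping: `max_epochs =
300`, or earlier when the best error has improved by less than `tol =
1e-6` over `patience = 20` epochs.  Weights initialise i.i.d. uniform on
[−w, +w]; all training is bit-reproducible given (seed, config, data).
The analytic back-propagation gradient is verified against central
finite differences to 1e-6 relative error in the test suite.

## The fitness

Candidate factor subsets are scored by 3-fold cross-validation: one
network per fold, trained on the other two folds (~67 % of subjects) and
tested on the held-out fold (~33 %).  Each fold contributes the average
of its training and testing accuracy, and the fitness **F** (percent) is
the mean of the three fold averages — algebraically also
(mean train accuracy + mean test accuracy) / 2.  Note F deliberately
mixes training accuracy in, so it rewards capacity as well as
generalisation; parsimony comes from the wrappers (the elimination
trajectory, the GA's dimensionality penalty), not from F itself.

Folds are stratified by class by default (a per-class round-robin deal
that keeps every fold's class ratio within one subject of the overall
ratio while fold sizes differ by at most one); unstratified splitting is
available behind a flag.  Stratification is this package's default
because it stabilises small-fold class ratios; the plain random variant
matches a literal "randomly chosen" split.

## Backward elimination (PDM)

From the full factor set, every single-factor removal is scored by the
3-CV fitness; the removal with the highest fitness is committed (ties
break to the lowest factor index), and the loop repeats down to one
factor.  The full trajectory N → 1 is always emitted.  The search costs
N(N+1)/2 network-triple evaluations for N factors, so candidate scoring
optionally runs with a reduced epoch budget while each committed subset
is re-scored at the full budget (`scoring_config`).

Subset selection from the trajectory uses a plateau rule: the smallest N
whose fitness is within ε (default 2.0 percentage points) of the
trajectory's peak.  The rule formalises "keep factors while the fitness
plateau lasts"; the full trace supports selection by inspection instead.

The hidden-layer size grid {1, 2, 4, 6, 8} can interact with the
elimination in two ways, both provided because the coupling is not
uniquely determined: `outer` (default at small scale) runs the complete
elimination once per hidden size and keeps the best-peak trajectory;
`fixed` chooses the grid winner on the full factor set and eliminates
once.  Each candidate evaluation uses a fresh deterministic seed derived
from (run seed, hidden size, dimensionality, candidate) — independent
reconstruction, not warm starts.

## Genetic-algorithm search (GA)

Chromosomes are binary strings: a factor mask (63 bits at study scale,
adapting to the cohort), then 4 bits for the hidden-neuron count, 3 for
the initial-weight range, 4 for momentum and 2 for the learning rate —
76 bits in total at 63 factors.  The value tables are configuration,
since only the segment widths are fixed by the design:

| segment | decode | default values |
|---|---|---|
| hidden (4 bits) | 1 + binary value | 1 … 16 |
| weight range (3 bits) | table lookup | 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 2.0 |
| momentum (4 bits) | table lookup | 16 equispaced values 0 … 0.9 |
| learning rate (2 bits) | table lookup | 0.001, 0.005, 0.01, 0.05 |

The momentum grid tops out at 0.9 (step 0.06) so that the
backward-elimination configuration (lr = 0.01, mc = 0.9) is exactly
reachable by the codec — a constraint we prioritised over any particular
upper end of the grid.

One generation: evaluate all M chromosomes (3-CV fitness; results cached
by bit pattern so a duplicated chromosome never retrains — trainings are
bounded by 3 × unique chromosomes); apply the dimensionality penalty —
chromosomes whose mask exceeds the threshold T, or is empty, are
reassigned 50 % of the mean fitness of the generation's *unpenalized*
members (the restriction avoids a circular definition; if every member
is penalized the overall mean is used, with a warning); elitist
fitness-proportionate (roulette) selection of the mating pool, with the
single best chromosome copied unchanged into the next generation
(tournament selection is available behind a flag); two-point crossover
with probability Pc = 0.7; per-bit mutation with probability Pm = 0.01;
and the election operator, which keeps the two fittest members of each
2-parents + 2-offspring family, so an offspring worse than both parents
never enters the population (a per-offspring-vs-parent variant is
selectable).  Defaults: M = 100, 50 generations, run at thresholds such
as T = 30 or unbounded.

Offspring produced mid-generation are compared in the election on raw
fitness, with infeasible offspring assigned the penalty value computed
from the parent generation's feasible mean — the penalty is relative to
the population the offspring compete in.  Per-chromosome evaluation
seeds derive from (global seed, chromosome bits), making fitness a pure
function of the chromosome, which the cache requires for coherence.
Elitism plus election make the best-so-far fitness monotone
non-decreasing, an invariant asserted on every run; the reported optimum
is the best *feasible* chromosome ever evaluated, so a penalized
chromosome can never be reported while a feasible one exists.

## Evaluation metrics and significance

Sensitivity is the true-positive rate on C2 (overweight), specificity
the true-negative rate on C1; a rate whose denominator is empty reports
NaN, never a silent zero.  ROC curves threshold the output neuron over
[0, 1] in steps of 0.02 (51 thresholds, predict positive when output ≥
threshold); AUC is the trapezoidal area with (0, 0) and (1, 1) anchored.
The fixed grid is the evaluation procedure itself, which is why it is
implemented here rather than delegated to a generic ROC routine.

Permutation significance: the testing-fold labels are permuted S = 1000
times with the model outputs fixed (retraining under permutation would
be computationally implausible and is not done); R counts permuted
statistic values **strictly** exceeding the observed one, and
p = (R + 1)/(S + 1), so p ∈ [1/(S+1), 1] and R = 0 gives
p = 1/1001 < 0.001.  Counting ties into R (more conservative) is an
option.  Per-fold p-values are averaged for the reported mean p.  Under
exchangeable null labels with a continuous statistic the p-values are
uniform on the attainable grid, which the suite verifies with a
Kolmogorov–Smirnov test over 200 replicate nulls.

## Encoding rules and degenerate inputs

Food and total nutrition intakes are binned at their sample quartiles;
supplement intakes put exact zeros into class 1 and split non-zero
values at their tertiles into classes 2–4.  Quantiles are
linear-interpolation sample quantiles, and a value equal to a cut point
goes to the **lower** class (half-open, upper-closed intervals) — fixed
for determinism since either convention is defensible.  All-identical
quartile input is an error (degenerate quantiles); all-zero supplement
input maps everyone to class 1; fewer than three distinct non-zero
supplement values is an error rather than a silent guess.  Genotype
class order defaults to the metadata's order (no canonical ordering of
homozygote/heterozygote forms is assumed) and is configurable.  Missing
cells are rejected by default, with an opt-in drop-subject policy.  BMI
dichotomises at 25 kg/m², boundary inclusive into C1.

## The synthetic cohort generator

The real cohort is proprietary, so the generator emulates its structure
with known ground truth: per-variant Hardy–Weinberg genotypes (allele
frequencies default to U(0.2, 0.8) draws), log-normal intakes with
zero-inflated supplements (default zero mass 0.4) and total = food +
supplement, the same binning as real data, gender at the study's 38.9 %
male fraction, and a logistic outcome on the *encoded* values with
planted main effects and pairwise product interactions (an MDR-style
penetrance-table term is available for epistasis without main effects).
Defaults reproduce the study scale: 2341 subjects, 24 genotypes, 38
nutrition variables, and the 877:1464 class balance; the default planted
set qualitatively mirrors the study's findings (gender + genotypes +
nutrition factors).

The intercept is calibrated by bisection against the realized draw
(outcome C2 iff p_i > u_i for a fixed per-seed uniform vector), which is
monotone in the intercept and hits the target class count within one
subject — deterministic where calibrating the expected probability would
leave ~1 % binomial noise at study scale.  The generator's own
correctness gate, `logistic_recovery_check`, refits the generating model
and reports coefficient bias/RMSE (shrinking ~1/√n) and deviance.

What the generator does **not** emulate: correlation structure among
nutrients from food-frequency questionnaires (beyond the mechanical
total = food + supplement identity), linkage disequilibrium between
variants, measurement error, or missing data.  Passing recovery tests
therefore show that the wrappers find planted signal under clean,
independent factors — not that they would resolve the collinear,
confounded structure of real dietary data.

## Problem sizes in the test suite

The released suite exercises the methods at desk scale, chosen as the
smallest sizes at which the planted signal is comfortably learnable:
recovery properties use 300-subject cohorts with 15–20 factors and three
strong planted SNPs, 10 seeded replicates each (the thresholds — at
least k−1 of k planted factors recovered in ≥ 80 % of replicates — are
test-suite parameters); the GA invariants run at M = 10–20 over 10–15
generations; networks in wrapper loops train for 60–100 epochs.  The
planted effects in recovery tests sit on SNPs only, because nutrition
factors have built-in collinear proxies (total = food + supplement) that
make "which factor carries the signal" non-identifiable.

## Known limitations

* The fitness's training-accuracy component means F is not an unbiased
  generalisation estimate; compare test-set metrics when model
  selection matters.
* Backward elimination is greedy: a factor informative only jointly
  with an already-removed partner cannot return (no floating search).
* Roulette selection degenerates when all adjusted fitnesses are equal
  (uniform sampling); tournament selection avoids this.
* No class-imbalance handling: with imbalanced cohorts the classifier
  drifts toward the majority class, visible as sensitivity >
  specificity when C2 is the majority — qualitatively the asymmetry
  expected on real BMI cohorts.
* The permutation test fixes the trained model; it tests association
  between outputs and labels, not the full training pipeline.
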