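# Methods

## Population model and synthetic cohort

The cohort generator emulates a health-surveillance population of
administrative VDT users described by (i) a disorder-class prior and (ii)
class-conditional marginal frequencies of seven dichotomized clinical
attributes.  Classes are `none, musculoskeletal, ophthalmological, nervous,
cardiovascular, other`; attributes and their tracked states are sex (man),
age ≥ 39 years (the population mean age, used as the cutoff), BMI
(overweight), sleep quality (variable), physical activity (yes), smoking
(yes, frequent or sporadic) and alcohol use (yes, habitual or
sporadic/weekend).

Each record draws its class from the prior, then each attribute
independently from a class-conditional Bernoulli.  Conditional independence
given the class is a modelling choice, not an observation: only
class-conditional *marginals* are available, and the independent completion
is the maximum-entropy distribution consistent with them.  It is also
exactly the family a naive/augmented-naive classifier targets, which makes
the generator the natural ground truth for structure-learning tests.  A
`coupling=(a, b)` hook overrides attribute `b` with a copy of `a`'s
tracked-state indicator, planting a single feature–feature dependency for
augmentation-recovery tests.

Calibration (`data/paper_spec.json`): P(none) = 1942/2453 ≈ 0.7917; within
the disordered fraction the shares are 29.08% musculoskeletal, 14.66%
ophthalmological, 10.92% nervous, 9.97% cardiovascular, remainder pooled as
"other".  The "other" pool has no published attribute breakdown and inherits
the no-disorder column.  The source tabulation contains internal
inconsistencies (an age row summing to 99.82%, an activity row to 103%,
per-class counts that do not sum to the disordered total); printed
percentages are taken at face value and counts are not reconciled.

What the generator does **not** emulate: continuous age and BMI,
longitudinal repeat examinations, employment-sector structure, missing
values, and any attribute–attribute dependence beyond the optional planted
coupling.  Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative family, not robustness to real-world
dependence or measurement error.

Default cohort size is 2453 (the study's sample size); class counts are
multinomial, not fixed, so per-class n varies between seeds.

## Bayesian network engine

Networks are the triplet (variables, DAG, CPTs); the joint factorizes over
parents.  Design choices:

* **Structure learning.** Augmented naive Bayes: the target is made parent
  of every feature; for every feature pair the empirical
  CMI(Xᵢ; Xⱼ | target) is computed in bits; pairs above `cmi_threshold`
  (default 0.01 bits — a pragmatic noise floor, flagged in configuration)
  enter a Kruskal maximum-weight spanning forest, with weight ties broken by
  lexicographic pair order; each tree is directed away from its
  lexicographically smallest member.  Every feature thus has at most one
  feature parent, the augmentation subgraph is acyclic by construction, and
  the output is deterministic.  With an infinite threshold the learner
  degenerates to the naive star.
* **Estimation.** CPT rows are (count + s)/(total + s·k) with smoothing s
  (default 0, the plain frequency/maximum-likelihood estimator).  An
  unobserved parent combination with s = 0 yields a uniform row — an
  explicit, documented fallback rather than NaNs.
* **Inference.** Exact variable elimination with a min-degree elimination
  order and variable-name tie-breaks; networks here have ≤ 10 nodes, so
  exactness is cheap.  Evidence of probability zero raises an error rather
  than returning NaN.  A full-enumeration oracle (tests/oracles.py) checks
  posteriors to 1e-12 on random networks.
* **Classification.** MAP over the target posterior; exact ties resolve to
  the earlier state in declared order.
* **Sensitivity.** One-way: the prior row of a *root* node is shifted by δ
  on one state, the other states are renormalized proportionally, and the
  signed change in a target posterior is returned.  The perturbation is only
  well-defined as a CPT edit for parentless nodes; the intended use (the
  disorder class, which is always a root here) satisfies that, and non-root
  sources raise an error.

## Proportion screening

Pooled two-sample z-test, two-sided, no continuity correction — the standard
choice for comparing a disorder class against the no-disorder reference on
one dichotomous attribute.  When the pooled proportion is 0 or 1 the two
groups are necessarily identical and the result is defined as (z = 0,
p = 1).  No multiple-testing correction is applied by default (mirroring the
source analysis); a Bonferroni option divides alpha by the number of
attributes.  The published per-class test statistics cannot be regenerated
from the published group sizes and percentages under this (or any standard)
two-sample test; they are treated as unverifiable and excluded, and the
test's behaviour is validated instead by a type-I-error simulation
(rejection rate at α = 0.05 within [0.035, 0.065] over 2000 null
replicates).

## Protocol cost-utility model

Ten diagnostic tests, each with a specialist (doctor or nurse), a time cost
in minutes and a money cost in USD per employee (salary rates already folded
into the printed costs; no currency handling).  The influence diagram has a
decision node over strategies, a probabilistic node per test with a
`perform_probability`, two utility nodes per test (time, money) and two
additive aggregates, so every expected utility is a probability-weighted
sum and, with all probabilities 1, reduces to the plain set sum.

Total utility adds dollars and minutes: the published totals equal
money + minutes numerically, i.e. 1 USD per minute.  `minute_value` exposes
that valuation (total is affine in it with slope equal to the time
utility).  Reductions versus the extensive reference are reported on **both**
axes because the published reduction row mixes them: the flexible-strategy
figures (11/23/31/41%) are time-axis reductions, while the optimized
headline (54%) is a total-utility reduction.  Display values are rounded to
whole percent; raw values are retained.  Strategy B's printed total
(32.4933) is inconsistent with its own money and time cells (sum 42.4933);
the replica computes the consistent value and carries a flag row.

## Pipeline and reproducibility

All randomness flows from one integer seed, fanned out to per-stage child
seeds through `numpy.random.SeedSequence(seed, spawn_key=(stage,))`, so a
stage re-run standalone reproduces the pipeline's artifact byte-for-byte.
The summary log records, per stage, the parameters and a SHA-256 prefix of
the artifact.

Problem sizes used by the test suite and drivers: 2453 records for the
narrative pipeline (the study size), 20,000 for calibration-recovery checks
(3 binomial standard errors ≈ ±1.5 percentage points on the spotlighted
71.81% cell), 50,000 for the strictest parameter-recovery properties, 200
random ≤ 6-node networks for the elimination-vs-enumeration equivalence and
2000 replicates for the z-test calibration — sizes at which every
Monte-Carlo band is a 3-standard-error bound computed from the binomial
sampling distribution, not a tuned tolerance.

## Known limitations

* The augmentation algorithm is one member of the ABN family; the original
  analysis used proprietary software whose exact scoring is unpublished, so
  the learned arc set is validated on synthetic ground truth, not against
  the published figure.
* Attribute dependence beyond one planted coupling is not modelled, so the
  learner's behaviour under dense real-world dependence is untested here.
* Sensitivity analysis covers root-prior perturbations only.
* The cost model is linear and per-employee; scheduling effects (a team
  performs up to 15 examinations daily) are out of scope.
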