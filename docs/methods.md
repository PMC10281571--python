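# Methods

## Course labels and data model

Disease course is dichotomised from the Age-Related MS Severity score
at last follow-up: unfavourable iff ARMSS ≥ 5 (the boundary is
unfavourable), favourable otherwise. ARMSS is consumed as an input
column and never recomputed from EDSS and age: the reference matrix
behind the score is an external resource, and recomputing it is out of
scope. Clinical covariates (EDSS on the half-point 0–10 grid,
lesion-localisation and onset-symptom flags, oligoclonal-band status,
IgG index, treatment initiation) are carried as typed fields with
validated enumerations.

Feature matrices are patients × proteins on a fold-change-like scale.
Missing cells are first-class: a patient missing any protein referenced
by a rule *abstains* from that rule and is reported in an `excluded`
count rather than entering the confusion table. Exclusion is the most
conservative treatment of missingness for a conjunctive predicate (no
imputation is smuggled in) and keeps the arithmetic of the remaining
counts exact.

## Rules and their evaluation

A rule is a conjunction of threshold predicates, each `protein <= t` or
`protein > t`, predicting one course class. The two comparators tile
the real line, so together with per-protein repetition they express any
axis-aligned interval; conjunctions whose satisfiable set is provably
empty (e.g. `> 3 AND <= 2` on the same protein) are rejected at
construction. The text dialect

```
ARMSS>=5.0 IF { A2M<=2.5 AND Haptoglobin<=1.0 }
```

is normalised to `<=`/`>` with an `AND`-joined body; typeset variants
(split comparators `< =`, stray italics markers) are accepted on input
only.

A rule defines a single operating point of a binary classifier with the
rule's predicted class as the positive class. Metrics follow the
standard 2×2 definitions; Cohen's kappa uses chance agreement computed
from the marginal prediction and label frequencies; the ROC AUC of a
single operating point is the two-point trapezoid
(sensitivity + specificity)/2. Any metric whose denominator is zero is
*undefined* (`None`), never 0 or 1 — this matters in the search, where
degenerate candidates (the always-true rule has undefined NPV-side
behaviour and specificity 0) must not be rewarded. Metrics are carried
at full precision; 2-decimal percent rounding happens only in the
report layer.

## Discretisation and the threshold vocabulary

The search does not invent thresholds: candidate thresholds per protein
come either from equal-frequency binning (default k = 4 categories) or
from user-supplied cut-offs. Equal-frequency cutpoints are midpoints
between the adjacent order statistics at the ideal bin edges
(ranks n·i/k); when the values at an edge are tied, the edge moves to
the nearest rank where adjacent values differ — a cutpoint never
separates equal values, and occupancy balance is best effort under
ties. A value equal to a cutpoint falls in the lower bin, consistent
with the `<=` predicate family. k = 4 is the default because it yields
the graduated 1.0 / 2.5-style thresholds seen in published rules of
this kind; user cut-offs override equal-frequency ones per protein.

## The genetic algorithm

The search maintains `population_size` candidate rules for a fixed
target class. Each generation: evaluate all rules, keep the top
`survivors` *distinct* rules unchanged (truncation selection with
elitism — deduplication keeps the breeding pool diverse without
weakening elitism), and refill by single-point crossover of random
survivor pairs (probability `crossover_rate`, otherwise cloning)
followed by mutation. Mutation resamples each condition's threshold,
comparator or protein independently with probability `mutation_rate`,
then adds or drops a condition with the same probability. Crossover
uses a shared cut position, so crossing a rule with itself is the
identity; contradictions introduced by mixing are repaired by dropping
the later condition, keeping offspring conditions inside the parents'
union. All randomness flows from a single seeded generator; identical
config, data and seed give bit-identical results, and elitism makes the
best fitness non-decreasing (asserted on every run).

Fitness functions: weighted sensitivity/specificity
(w_s·sens + w_sp·spec)/(w_s + w_sp) — the balanced case equals the
two-point ROC AUC — plus accuracy, kappa and Youden's J. A rule with
any required metric undefined scores 0. Tilting the weights is how
high-sensitivity versus high-specificity rules are obtained from the
same cohort.

Defaults (population 200, survivors 20, mutation 0.1, crossover 0.7,
100 generations, at most 7 conditions — the longest published rule has
seven) are starting points, not statements about the original software,
which documents the knobs but not their values. Selection is plain
truncation because the mechanism described for the original tool is
"hypotheses that survive"; roulette or tournament selection would be
speculation. Genetic operators act on symbolic conditions rather than a
bit-string encoding; the original encoding is not described, and
condition-level operators are the natural choice when thresholds live
in a per-protein vocabulary.

`exhaustive_search` enumerates every rule up to `max_conditions` (guard:
one million rules) with a deterministic lexicographic tie-break and
serves as the ground-truth oracle: on instances with 6 proteins, 2
thresholds and rules of ≤ 2 conditions, the GA reaches the exhaustive
optimum in ≥ 95% of runs (it reached it in 50/50 in the released test
configuration).

## Cohort statistics

Two-sided tests throughout, following the analysis this package
reproduces: pooled-variance Student's t (not Welch) with
df = n₁+n₂−2, available in raw and summary (mean, sd, n) forms that
agree to 1e−12 when the summaries come from the raw sample; and
Fisher's exact test with the conventional probability-mass two-sided
definition (sum of hypergeometric probabilities of same-margin tables
no more probable than the observed one). The Fisher implementation
works in exact integer arithmetic — weights comb(r₁,a)·comb(r₂,c₁−a)
— so the "no more probable" comparison needs no floating tolerance and
the result matches a rational-arithmetic enumeration bit for bit (the
test suite verifies this for every table with total ≤ 60; mid-p and
doubling variants are deliberately not offered). Zero pooled variance
with equal means gives t = 0, p = 1 by convention; with unequal means
it is an error rather than an infinite statistic.

No multiple-testing correction is applied anywhere; p-values are raw
with the α = 0.05 convention of the original analysis. This is a
documented limitation, not an endorsement.

Outlier exclusion offers the Tukey fence (default k = 1.5, quartiles by
linear interpolation) and the z-score rule (default |z| > 3, sample
sd). The method and threshold are explicit parameters and are always
reported alongside the excluded indices — the source analysis mentions
excluded outliers without defining "outlier", so the choice is
surfaced rather than hidden. Note that the z-score rule suffers
masking: two opposite 8-sd outliers in one n = 20 sample inflate the
sd enough that neither exceeds |z| = 3, while the Tukey fence still
catches both.

The verification-stage comparison runs the raw pooled t-test on
measured concentrations per protein, optionally after per-group outlier
exclusion, and always reports both the with- and without-exclusion
p-values.

## The synthetic-cohort generator

No patient-level data accompany the published analysis, so the
generator emulates its statistical shape and is itself first-class,
tested code.

**Discovery cohort.** Defaults: 20 unfavourable / 43 favourable
patients — the group totals that enter the published rules' confusion
arithmetic — and 151 protein features. ARMSS is uniform on [5, 10] and
[0, 5) in the two groups, so labels match the configured sizes exactly.
Clinical covariates are drawn at the published group rates (e.g. optic
nerve involvement 39.4% vs 7.4%, gait disturbance 4.5% vs 17.1%).
Non-planted features are group-independent log-normal noise with median
1 and log-scale 0.4, a generic fold-change-like null; the published
analysis gives no distributional information about the 151 proteins, so
log-normality is a recorded assumption, not a claim.

**Planted rules.** A planted rule forces `round(penetrance·T)`
target-class and `round(background_rate·F)` other-class patients to
satisfy every condition; every other patient fails a uniformly chosen
non-empty subset of the conditions (so no single condition separates on
its own and multi-protein structure is genuinely required). Values are
placed deterministically on the correct side of each threshold within
wide relative bands (below: 0.20–0.55·t; above: 1.15–2.5·t), which
makes planted effects large and leaves a broad gap around each
threshold — any candidate threshold inside the gap classifies the
cohort identically, and the planted confusion counts are exact by
construction rather than emergent. Penetrance below background is
rejected as an anti-predictive plant, and planted rules may not share
proteins. Stored ground truth (per-patient satisfaction, outlier
positions) is verifiable from the emitted tables alone via
`ground_truth_check`.

**Verification cohort.** 20 + 20 patients; per protein and group,
concentrations are zero-truncated normal with configurable means and
sds. Defaults give standardised group differences of ≈ 1.1 for the two
markers reported as significant at this sample size (two-sample power
≈ 0.92 at α = 0.05), zero for the null marker, and a real shift for the
haptoglobin analogue that planted outliers are intended to mask. Each
measurement is displaced upward by `outlier_magnitude` (default 8)
group sds with probability `outlier_rate` (default 0.05, ≈ 2 of 40
measurements per protein).

**What passing tests do and do not show.** The generator plants clean,
box-shaped signals in otherwise independent features; real CSF
proteomics has correlated proteins, batch effects, heavier tails and
signals that are not axis-aligned. Recovery of planted markers
therefore demonstrates correctness of the search machinery under the
model's own assumptions, not expected sensitivity on real cohorts.
Likewise the published verification-stage p-values cannot be reproduced
without the unpublished raw concentrations; the powered-simulation
properties stand in for them.

## Numerical and test-scale choices

- Rule evaluation is vectorised with cached per-condition satisfaction
  vectors; fitness values are memoised per canonical rule, making GA
  runs cheap and exactly repeatable.
- Ranking ties (equal fitness) break on the canonical rule key, so
  results are independent of population order.
- The released test configuration uses 50-seed batches for the
  stochastic search properties, a 40-patient instance family for the
  oracle comparison, and a 200/40/100-generation GA for marker
  recovery; these sizes give stable pass/fail behaviour at interactive
  runtimes.
- The planted-marker recovery tests supply a graduated user cut-off
  grid (0.5 … 2.5) as the threshold vocabulary — the same style of
  fold-change cut-offs the published rules use. Equal-frequency
  cutpoints at k = 4 sit at cohort quantiles, which need not fall in a
  planted gap; with a quantile vocabulary the best expressible rule can
  sit close to the noise ceiling, and failures to recover would then
  reflect vocabulary granularity rather than search quality, which is
  not what that test measures.

## Known limitations

- Single conjunctive rules only: no rule lists, decision trees or
  Pareto fronts over sensitivity/specificity.
- No ROC curves — a conjunctive rule has one operating point.
- No multiple-testing correction; see above.
- ARMSS computation, ELISA mechanics, imaging and upstream proteomics
  are out of scope; their outputs are consumed as inputs.
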