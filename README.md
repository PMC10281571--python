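# garules

Genetic-algorithm mining of conjunctive threshold rules for prognostic
biomarker discovery in multiple sclerosis (MS).

## The problem

Predicting which newly diagnosed MS patients will accumulate serious
disability is hard. One line of attack measures cerebrospinal-fluid
(CSF) protein levels at diagnosis, follows patients for years, and asks
which initial protein profiles separate patients who later did well
from those who did not. Disease course is summarised by the Age-Related
MS Severity (ARMSS) score at last follow-up, dichotomised at 5:

- **favourable course**: ARMSS < 5
- **unfavourable course**: ARMSS ≥ 5

`garules` implements this analysis as a tested pipeline for researchers
working with case/control-style proteomic cohorts:

- **conjunctive rules** over protein fold-change features, e.g.

  ```
  ARMSS<5.0 IF { CD36<=1.0 AND A2M>2.5 AND ApoA1<=1.0 }
  ```

  A patient satisfying every condition is predicted into the rule's
  class, everyone else into the complement;
- a **genetic algorithm** that evolves a population of such rules
  (truncation selection with elitism, single-point crossover,
  per-condition mutation) against a configurable fitness function, with
  candidate thresholds drawn from equal-frequency discretisation or
  user-supplied cut-offs, plus an **exhaustive-search oracle** for small
  instances;
- the full set of single-operating-point classifier metrics:
  sensitivity TP/(TP+FN), specificity TN/(FP+TN), accuracy, PPV, NPV,
  Cohen's kappa (P₀−Pₑ)/(1−Pₑ), and the two-point ROC AUC
  (sensitivity+specificity)/2;
- **cohort statistics**: pooled-variance Student's t-tests (raw or
  summary form), exact two-sided Fisher tests on 2×2 tables (integer
  arithmetic, no floating-point tie ambiguity), Tukey-fence / z-score
  outlier exclusion, and grouped clinical summary tables;
- a **synthetic-cohort generator** that plants rules with chosen
  penetrance and background rate into simulated discovery cohorts and
  generates verification-stage concentration tables with group shifts
  and extreme outliers, so the whole pipeline is testable without any
  patient-level data.

## Worked example

```python
from garules import (
    CourseLabel, GAConfig, SimConfig, confusion, evaluate_rule,
    parse_rule_text, run_ga, simulate_discovery, threshold_vocabulary,
)

# a synthetic discovery cohort: 20 unfavourable / 43 favourable patients,
# 151 proteins, with the high-specificity rule planted at 20/43 coverage
bundle = simulate_discovery(SimConfig(seed=7))
labels = {p: CourseLabel(v) for p, v in bundle.truth["labels"].items()}

rule = parse_rule_text("ARMSS<5.0 IF { CD36<=1.0 AND A2M>2.5 AND ApoA1<=1.0 }")
print(evaluate_rule(rule, bundle.features, labels).as_percent_dict())
```

prints

```
{'TP': 20, 'T': 43, 'FP': 0, 'F': 20, 'excluded': 0,
 'sensitivity': 46.51, 'specificity': 100.0, 'accuracy': 63.49,
 'PPV': 100.0, 'NPV': 46.51, 'kappa': 35.57, 'ROC AUC': 73.26}
```

i.e. the rule covers 20 of the 43 favourable-course patients
(sensitivity 46.51%) and misclassifies none of the 20
unfavourable-course patients (specificity 100%); kappa 35.57% reflects
the modest chance-corrected agreement of such a high-specificity,
low-sensitivity operating point. Mining rules from the same cohort:

```python
vocab = threshold_vocabulary(bundle.features, k=4)
result = run_ga(bundle.features, labels, vocab,
                GAConfig(target_class=CourseLabel.FAVOURABLE, seed=1))
best_rule, best_perf, best_fitness = result.best
```

The same workflows are available from a shell:

```sh
garules simulate --seed 7 --out study/
garules mine --features study/features.tsv --cohort study/cohort.tsv \
        --bins 4 --pop 200 --survivors 20 --gens 100 --seed 17 --out rules.json
garules evaluate --rules rules.json --features study/features.tsv --cohort study/cohort.tsv
garules stats --cohort study/cohort.tsv
garules verify --elisa study/elisa.tsv --protein A2M --exclude-outliers tukey:1.5
```

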