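# parsiopt

Parsimonious hyperparameter optimization for multitask QSAR neural
networks.

Multitask classification networks — one model, shared hidden layers, one
output per biological endpoint — are standard in computational toxicology
and drug discovery, but their performance hinges on hyperparameters whose
exhaustive tuning is prohibitively expensive: the full grid considered
here has 196,608 architectures.  `parsiopt` implements and compares four
tuning strategies under a common small budget of 100 fitness evaluations:

* **grid search (GS)** — exhaustive enumeration (the reference optimum);
* **random search (RS)** — 100 uniform draws from the grid;
* **genetic algorithm (GA)** — 10 binary chromosomes, 42 generations,
  roulette-wheel selection, one-point crossover, 10% per-bit mutation,
  culling of the two worst, and a mid-run cataclysm;
* **tree-structured Parzen estimator (TPE)** — sequential model-based
  optimization with categorical Parzen densities over the good and bad
  halves of the history, proposing points maximising l(x)/g(x).

The score of an architecture is the overall non-error rate of a 3-fold
cross-validated network, with confusion counts pooled over all T tasks:

    SN_T  = 100 · Σt TP_t / (Σt TP_t + Σt FN_t)
    SP_T  = 100 · Σt TN_t / (Σt TN_t + Σt FP_t)
    NER_T = (SN_T + SP_T) / 2

The package also ships a D-optimal design-of-experiments analysis
(Fedorov exchange + main-effects OLS) that explains *which*
hyperparameters drive NER_T, a self-contained numpy trainer for the
multitask nets (masked binary cross-entropy for missing labels, four
optimizer update rules, inverted dropout, L1/L2 penalties), and a
synthetic-data generator that emulates the shape of the NURA / Tox21 /
ClinTox benchmarks — class imbalance up to 94%/7%, missing annotations,
correlated tasks — so every stage runs in minutes without downloads.

## Worked example

Compare the three stochastic strategies, ten replicas each, on the
built-in surrogate landscape (an additive stand-in for cross-validated
NER_T with one strongly superior level per hyperparameter and a unique
optimum at 85):

```python
import parsiopt as po

land = po.strong_landscape()
report = po.run_study(lambda s: po.SurrogateFitness(land, s),
                      po.default_space(), replicas=10, seed=0)
print(report.summary.round(3).to_string(index=False))
print(report.pairwise.round(4).to_string(index=False))
```

```
method  mean_best_NER_T  ci_half_width  n_replicas  seconds
    rs           70.357          2.286          10    0.018
    ga           78.375          2.811          10    0.060
   tpe           75.604          2.383          10    1.676

method_a method_b  statistic  p_value
      rs       ga    -5.0065   0.0001
      rs      tpe    -3.5943   0.0021
      ga      tpe     1.7009   0.1066
```

Read: the best-of-100 NER_T found by random search averages 70.4 (95% CI
half-width 2.3) over ten replicas, while the genetic algorithm and the
TPE average 78.4 and 75.6 on identical budgets; Welch t-tests call both
improvements significant (p = 0.0001 and 0.0021), and GA vs TPE is not
significantly different — the qualitative picture expected of informed
versus uninformed search.  The same comparison can be driven by real
cross-validated fitness on a synthetic dataset via
`po.CrossValidationFitness(X, labels)`.

The same workflow is available from a shell:

```bash
parsiopt study --methods rs,ga,tpe --replicas 10 --seed 0 --out out/
parsiopt optimize --method tpe --dataset clintox --seed 1 --out tpe_run.csv
```

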