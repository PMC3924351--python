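# cbcpref

Choice-based conjoint (CBC) analysis for health-preference studies:
randomized minimal-overlap designs with embedded holdout tasks,
hierarchical-Bayes (HB) estimation of individual part-worth utilities, and
the validity and stability diagnostics a repeated-measures preference study
needs — Root Likelihood (RLH), holdout Mean Absolute Error (MAE) with
logit-exponent tuning, lexicographic-behavior flags, and test-retest
agreement (Cohen's kappa, Spearman, strong-preference persistence).

The package grew out of a study of preferences for analgesic treatment of
cancer pain, where two patient groups completed a CBC exercise twice, three
months apart.  Patient-level data from such studies are rarely shareable,
so the package ships a synthetic-panel generator that reproduces the study's
*structure* — two groups (139 + 102 respondents), two waves with 17%
attrition, a lexicographic minority, and group-specific dominant attributes
— with known ground truth, making every stage of the pipeline testable end
to end.

## The model

Each treatment profile is a combination of attribute levels (here: % pain
relief, side-effect type, side-effect severity, analgesic class,
out-of-pocket cost).  Choices follow a random-utility model

```
V_i = x_i' beta + e
```

with `x_i` the effects-coded profile (sum-to-zero within attribute) and `e`
extreme-value noise, giving logit choice probabilities
`P(i) = exp(s x_i' beta) / sum_j exp(s x_j' beta)` with scale (logit
exponent) `s`.  HB places a population distribution `beta_r ~ N(alpha, D)`
over respondents and samples the posterior by Gibbs (conjugate draws for
`alpha` and `D`, per-respondent Metropolis-Hastings for `beta_r`), so
individual utilities are estimable from a dozen choices each.  Derived
quantities:

* **relative importance** — an attribute's utility range as a percentage of
  the summed ranges; sums to 100 per respondent;
* **RLH** — geometric mean of the predicted probabilities of the choices a
  respondent made (1/k at chance, 1 when perfect);
* **MAE** — mean absolute difference, in share points, between predicted
  and observed aggregate holdout shares, after tuning `s` per group;
* **lexicographic flag** — RLH > 1.5/k and one attribute's importance > 50%;
* **stability** — kappa/Spearman agreement of attribute ranks across waves,
  and whether attributes with ≥ 50% baseline importance stay in the top two.

## Worked example

```
$ cbc run --seed 7 --out demo
completed stages ['simulate', 'fit', 'validate', 'stability']; outputs in demo
```

This simulates the default two-group, two-wave panel (241 respondents, 12
random + 2 holdout tasks at positions 5 and 10, 29% planted lexicographic
respondents), fits HB per group and wave, and writes `validity.json`,
`stability.json`, per-respondent utilities and a reproducibility manifest.
With seed 7 the validity table reads:

| group@wave | n   | mean RLH (95% CI)    | MAE (pts) | scale | lex. rate |
|------------|-----|----------------------|-----------|-------|-----------|
| W@T1       | 139 | 0.810 (0.792–0.827)  | 1.91      | 0.46  | 0.35      |
| A@T1       | 102 | 0.816 (0.797–0.835)  | 2.36      | 0.83  | 0.32      |
| W@T2       | 115 | 0.816 (0.798–0.834)  | 1.52      | 0.38  | 0.17      |
| A@T2       | 95  | 0.812 (0.796–0.828)  | 2.62      | 1.00  | 0.21      |

RLH ≈ 0.81 means the fitted utilities predict the average made choice with
probability 0.81 per task (chance is 0.5); an MAE of ~2 share points means
predicted holdout shares track observed shares closely after per-group
scale tuning.  The stability report gives a pooled rank kappa of 0.38
("fair" on the conventional guideline bands; the between-wave preference
drift in the generator is what degrades it), Spearman 0.71, and every
attribute that was strong (≥ 50% importance) at baseline stayed in the top
two at follow-up.

Sample-size planning, without simulating respondents:

```
$ cbc samplesize --grid 100:275:25 --seed 1
  n  mean_max_se ...
200     0.048251 ...
smallest n with mean max SE <= 0.05: 200
Johnson's rule minimum: 125
```

## Layout

```
src/cbcpref/
  schema.py      attribute/level schemas, effects coding
  design.py      task generation, diagnostics, holdouts, sample size
  simulate.py    synthetic respondent panels with ground truth
  models.py      AggregateChoiceLogit, HierarchicalBayesLogit (sklearn-style)
  validity.py    RLH, importance, lexicographic flags, MAE, scale tuning
  stability.py   ranks, kappa, Spearman, strong-preference persistence
  io.py          long-format CSV dialect, utilities export
  pipeline.py    one-command run with reproducibility manifest
  cli.py         the `cbc` command
```

See `docs/methods.md` for modeling assumptions, priors, and the design of
the synthetic population.
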