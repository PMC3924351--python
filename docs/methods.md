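# Methods

This note documents the statistical procedures implemented in `cbcpref`,
the choices made where the methodology left room, and what the synthetic
panel does and does not establish about real data.

## Design generation

Each respondent answers `t` random tasks (default 12) plus `h` fixed
holdout tasks (default 2, at positions 5 and 10 of 14) with `a = 2`
full-profile alternatives per task.  Random tasks are built greedily, one
attribute at a time: a task takes the `a` least-used levels of each
attribute so far, with uniformly random tie-breaking, and assigns them to
alternatives in random order.  This construction guarantees two properties
exactly:

* **minimal overlap** — within a task, alternatives never share a level of
  an attribute that has at least `a` levels;
* **level balance** — over a respondent's random tasks, every level of
  every attribute appears either floor or ceil of `t*a / m` times.

Orthogonality (independence of attribute-level pairings) is not enforced
explicitly; the random tie-breaks and random alternative assignment leave
pairwise joint level frequencies within ~0.5% of the independence
expectation at study scale, which `check_design` measures.  A commercial
implementation would search explicitly over a penalty; the greedy rule
reproduces the stated design properties without one.

Holdout tasks should present "a clearly preferred, but not overly dominant
alternative".  `construct_holdout` operationalizes this as a predicted
preferred share strictly inside (0.60, 0.80) under a set of reference
utilities at scale 1 — the midpoint band between chance (0.5) and dominance
(1.0) — found by random search over minimal-overlap profile pairs.
Holdouts are identical across respondents and waves; random tasks are
regenerated fresh per respondent per wave (a panelist never answers the
same random question set twice).

## Sample size

Two procedures, both in `design.py`:

* **Johnson's rule of thumb**: `n >= 500 c / (t a)` with `c` the maximum
  level count.  For the study design (`c` capped at 6, `t = 12`, `a = 2`)
  this gives 125.
* **Simulation**: for each candidate `n`, dummy respondents choose
  uniformly at random on freshly generated questionnaires; an aggregate
  effects-coded logit is fit and the maximum standard error over coded
  parameters recorded, averaged over replicates (default 20).  The
  criterion is applied to the *maximum* over parameters — the conservative
  reading — and the simulated questionnaire is the full 14-task design:
  at the design stage holdout tasks look exactly like any other task and
  inform the dummy-data fit.  The binding parameters are the two 5-level
  attributes; analytically their SE at `n` respondents is
  `sqrt(6.4 / (14 n))`, crossing 0.05 between 175 and 200, so a step-25
  grid selects n = 200.  With 12 tasks instead, the SE at n = 200 is
  ~0.052 and the criterion is not attainable at 200; the `t` argument
  exposes both conventions.  Uniform-random dummy choosers are a modeling
  choice worth stating: informative dummy preferences would change the
  information matrix and hence the SEs.

## Estimation

Profiles are effects-coded with the last level of each attribute as the
omitted reference (codes -1), so per-level utilities are zero-centered
within attribute — the convention in which conjoint utilities are reported.
The analgesic schema (4/5/3/2/5 levels) yields p = 14 coded parameters.

**Aggregate logit** pools all respondents: Newton-Raphson on the
conditional multinomial-logit likelihood with analytic gradient and
Hessian, SEs from the observed information, convergence by gradient
sup-norm.  Runaway coefficients (|beta| > 20) are treated as separation:
capped, with a warning.

**Hierarchical Bayes** is a Gibbs sampler over (`alpha`, `D`,
`beta_1..beta_n`): a conjugate Normal draw for the population mean
(prior `N(0, 100 I)`), a conjugate inverse-Wishart draw for the population
covariance (prior df `p + 5`, scale `I` — weakly informative conventions in
the conjoint tradition, all exposed in `FitConfig`), and one random-walk
Metropolis-Hastings update per respondent with proposal covariance
`step^2 D`.  `step` adapts toward 30% acceptance during burn-in only, so
the post-burn kernel is fixed.  Chains initialize at the pooled MLE: a
cold start at zero mixes pathologically slowly, because the covariance
draw collapses before individuals can move.  Default chain lengths are
10,000 burn-in + 10,000 saved draws thinned by 10; the test suite and the
shipped pipeline default to shorter chains (2,000 + 2,000), which on the
241-respondent panel reproduce the same summaries to well within posterior
uncertainty — individual posterior means stabilize much faster than the
population-mean chain's split R-hat (reported as `rhat_`, warning
threshold 1.2).  Estimation always excludes holdout tasks; waves and
groups are fit separately, matching a study design in which the respondent
pool differs across waves.

A property worth knowing: with only 12 binary tasks per respondent the
population covariance is weakly identified, so under the default priors it
does not collapse even when the data are generated with zero
heterogeneity, and the population mean then exceeds the attenuated pooled
MLE by ~20% (classic mixed-logit attenuation).  The pooling limit — HB
collapsing onto the aggregate logit — is exact only under a covariance
prior concentrated at zero (`iw_scale=0.01, iw_df_extra=300` in the tests,
agreement to ~0.02).

## Validity metrics

* **RLH** is computed in log space over the respondent's 12 estimation
  tasks at scale 1 (holdouts excluded, keeping fit and validation
  disjoint; an option includes them).
* **Relative importance** is the range of per-level utilities divided by
  the summed ranges, per respondent; group tables average per-respondent
  importances.  Note this differs from applying the range method to
  aggregate utilities — both are computed in the tests to document the
  discrepancy.
* **Holdout prediction** uses each respondent's posterior-mean utilities
  (not draws: deterministic given the chain, and the conventional
  reporting choice), averaged into aggregate shares.
* **MAE** is reported in share percentage points.  The logit exponent is
  tuned per group and wave on a default grid of 25 log-spaced points in
  [0.1, 10], ties to the smallest scale; the grid covers the 0.3–2.5 range
  that scale heterogeneity between patient groups can produce.
* **Lexicographic flag**: RLH strictly above 1.5x chance (0.750 for paired
  tasks) and maximum importance strictly above 50%.

## Stability metrics

Importances are ranked per respondent and wave (ties broken by schema
order, deterministically).  Cohen's kappa is computed on the pooled
respondent-by-attribute rank pairs, and per attribute on that attribute's
rank pairs; the unit of analysis is stated because a kappa "overall and
within each attribute" admits several tables.  The CI uses the
Fleiss-Cohen-Everitt large-sample variance.  Magnitude labels follow the
conventional bands (0–.20 slight, .21–.40 fair, .41–.60 moderate, .61–.80
substantial, .81–1 almost perfect), upper edges inclusive, negative values
labelled "no agreement".  A *strong* preference is an attribute with
baseline importance of 50% or more (inclusive); it is *stable* when that
attribute ranks first or second at the second wave.  Per-attribute
sensitivity/specificity come from the strong-at-T1 x top-2-at-T2
cross-table: sensitivity is the stable fraction among strong baselines,
specificity the non-top-2 fraction among non-strong baselines — an
interpretation, since the cross-table is not uniquely determined by the
verbal definition.  Respondents lost to follow-up are excluded pairwise.
Change scores are actual (T2 - T1) and absolute importance differences;
actual changes sum to zero per respondent because importances sum to 100.

## The synthetic population

The generator emulates the *structure* of a two-group repeated-measures
patient study, not any particular cohort's numbers.  Defaults: 241
respondents in groups W (139) and A (102); two waves with independent 17%
dropout; segment part-worths Normal around segment means with
per-parameter SD 0.25; wave-2 part-worths are wave-1 plus N(0, 0.25^2)
drift (drift is plain noise: the study found changes in patients'
information sets uncorrelated with importance changes, so no
covariate-driven drift is modeled).

Trader (non-lexicographic) segment means are the published group-level
aggregate utilities divided by 50 to land on a logit scale that yields
realistic choice consistency (RLH ~ 0.8), with two structural adjustments:
group A's side-effect-type block is scaled so side-effect type and pain
relief are its top two attributes (the qualitative group contrast), and
group W's pain-relief block is scaled so trader dominant shares sit near
39% — clearly below the 50% lexicographic threshold, which is what makes a
planted lexicographic fraction identifiable at all.

Lexicographic segments (29% of each group by default) are derived from the
trader mean by muting non-dominant attributes (x0.3) and scaling the
dominant one to 80% of the total utility range, with response scale 1.5
and heterogeneity SD 0.15.  These values were calibrated once, against the
end-to-end criterion that the planted fraction be recoverable by the
RLH/importance flag through HB estimation: muting (rather than amplifying)
keeps the group mean below the flag threshold, so shrinkage does not
manufacture false positives, and the higher response scale separates
lexicographic respondents through the RLH gate.  Across seeds the
recovered rate falls within ~4 points of the planted 29%, with false
positives 2–10% and detection 80–93%.

What passing tests on this panel do **not** show: that real patients'
heterogeneity is Normal or diagonal-dominant, that real lexicographic
behavior is a discrete segment rather than a continuum, that real drift is
isotropic noise, or that the calibrated effect sizes match any clinical
population.  The generator validates the *pipeline* — coding, sampler,
metrics, reports — under a known truth; substantive conclusions still
require real choice data.

## Numerical details

* Logit probabilities and RLH go through `log_softmax` / log-sum-exp; a
  non-finite utility raises immediately rather than propagating NaNs.
* The MNL Newton step adds a 1e-10 ridge before solving and backtracks on
  the log-likelihood.
* Inverse-Wishart draws are PD by construction; the sampler records the
  minimum covariance eigenvalue seen (`min_cov_eigenvalue_`) as an
  invariant check.
* Rank ties (exactly equal importances) break by schema order; strong
  preference uses an inclusive >= 50; the lexicographic flag uses strict
  inequalities — both boundaries are tested.
* All randomness flows from `numpy.random.default_rng(seed)`; seeded runs
  are bit-reproducible, and the pipeline manifest (config, seeds, SHA-256
  checksums) makes that checkable; wall-clock timings live outside the
  reproducibility contract.

## Problem sizes in the shipped checks

The test suite and acceptance script run at the study's own scale where
that is cheap (241 respondents, 12 + 2 tasks; sample-size grids of 4–8
points at 20 replicates) and use 2,000 + 2,000 HB chains, which for these
data sizes reproduce the longer default chains' summaries.  The zero-drift
stability and recovery checks share one simulated panel and four group-wave
fits.
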