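# greedymatch

**How much does a propensity-score-matched treatment effect depend on the
random ordering inside the matching algorithm?**

Greedy 1:1 propensity-score (PS) matching — the workhorse of observational
pharmacoepidemiology — processes treated subjects one at a time, in an order
that is usually randomised, and never revisits a match. Two popular variants
are *caliper-random* matching (pick a random unmatched control within the
caliper) and *nearest-neighbor (NN) caliper* matching (pick the closest
unmatched control, if within the caliper). Both are order-dependent: rerun
the same analysis on the same cohort with a different random seed and you
get a different matched set, a different odds ratio, and sometimes a
different answer to "is the effect significant?".

`greedymatch` quantifies that instability by Monte-Carlo experiment:

1. **Simulate a cohort** with eight independent baseline covariates
   (six Bernoulli(0.2), two Normal(0, 0.5)), a logistic treatment model and
   a logistic outcome model,

   p(T = 1 | X) = expit(α₀ + Σₖ αₖ Xₖ),
   p(Y = 1 | T, X) = expit(β₀ + Σₖ βₖ Xₖ + β_T T),

   where the αₖ, βₖ are log odds ratios (defaults: OR_T =
   2, 1, 0.5, 2, 1, 0.5, 1.5, 0.5 and OR_Y = 1, 2, 0.5, 0.5, 1, 2, 0.5, 1.5)
   and the intercepts α₀, β₀ are calibrated numerically so the marginal
   treatment and outcome prevalences hit their targets. The covariates
   confound: the crude OR is biased away from exp(β_T).
2. **Fit the PS** by logistic regression of T on X₁…X₈, once per cohort.
3. **Repeat the matching** R times (default 1000) with a fresh random
   treated-subject ordering each time, caliper width 0.2 (or 0.01) times the
   SD of the estimated PS.
4. **Estimate the OR in each matched set** by conditional logistic
   regression for 1:1 pairs — for a treatment-only model the MLE is the
   discordant-pair ratio n₁₀/n₀₁ with Wald 95% CI
   exp(ln(n₁₀/n₀₁) ± 1.96·√(1/n₁₀ + 1/n₀₁)) — and check covariate balance
   (all standardized mean differences ≤ 0.1).
5. **Summarise across repetitions**: median, IQR and full range of the OR,
   % of repetitions significant in either direction, mean matched subjects,
   % unsuccessfully balanced, plus a successful-only sensitivity analysis.

The study grid crosses cohort size {500, 2500, 10000}, treatment prevalence
{20%, 50%}, outcome prevalence {10%, 50%} and true OR {0.75, 1.0, 1.5}
(36 scenarios) × 2 algorithms × 2 caliper widths.

## Worked example

```python
from greedymatch import Scenario, RepeatedMatching

scenario = Scenario(n=10_000, p_treat=0.5, p_outcome=0.5, true_or=0.75, seed=1)
model = RepeatedMatching.from_scenario(
    scenario, algorithm="caliper_random", caliper_multiplier=0.2)
res = model.fit(reps=250, base_seed=1)
print(res.summary())
```

```
     Repeated greedy PS matching
======================================
                            value
--------------------------------------
algorithm               caliper_random
caliper multiplier        0.2 x SD(ps)
repetitions                        250
median OR                        0.725
IQR of OR               (0.715, 0.734)
full range of OR        (0.670, 0.762)
crude (unadjusted) OR            0.557
% significant low risk          100.0%
% significant high risk           0.0%
mean matched subjects             7287
% unsuccessful matches            0.0%
undefined ORs                        0
--------------------------------------
```

Reading this: the simulated conditional treatment OR is 0.75, but the crude
cohort OR is 0.56 — the covariates confound the association downward.
Matching removes essentially all of that bias (median matched OR 0.725, with
this cohort's own sampling noise), yet rerunning the *identical* matching
with different seeds moves the estimate across a 0.67–0.76 range. At this
cohort size every reordering still yields a significantly protective effect;
at n = 500 the same experiment produces ranges wide enough to cross 1, so
significance itself becomes seed-dependent. `res.per_repetition` holds the
seed-by-seed results, `res.successful_only()` the balance-restricted
sensitivity summary.

The full experiment is available from the shell:

```sh
greedymatch run-grid --reps 1000 --seed 1 --out grid.csv        # all 36 scenarios
greedymatch run-scenario --n 2500 --p-treat 0.2 --p-outcome 0.5 \
    --true-or 0.75 --reps 1000 --seed 1 --out cell              # one cell
greedymatch simulate --n 10000 --seed 1 --out cohort.csv        # just a cohort
```

`run-grid` accepts a YAML config (`--config`) with `reps`, `base_seed`,
`algorithms`, `caliper_multipliers` and either a `grid:` block or an explicit
`scenarios:` list; a JSON manifest (seeds, grid digest, quantile convention)
is written next to every output.

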