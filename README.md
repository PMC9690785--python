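# riaft-bart

Bayesian causal survival analysis for **clustered, right-censored,
multi-treatment** data — and data-driven discovery of treatment-effect
heterogeneity.

Large registry datasets (think: cancer patients treated at hundreds of
hospitals, choosing among several guideline-accepted treatments) pose three
problems at once: survival outcomes are right-censored, patients are clustered
within institutions whose quality varies, and treatment choice is confounded
by patient characteristics.  This package implements **riAFT-BART**, a
random-intercept accelerated failure time model whose regression function is a
sum of Bayesian regression trees (BART):

```
log T_ij = f(A_ij, x_ij) + b_j + eps_ij,
eps_ij ~ N(0, sigma^2),   b_j ~ N(0, tau^2)
```

* `f` — a regularized sum of trees over covariates `x` and treatment `A`,
  capturing nonlinearities and treatment–covariate interactions without
  pre-specification;
* `b_j` — institution-level random intercepts on log survival time;
* censored log times are imputed by truncated-normal data augmentation inside
  a fully conjugate Gibbs sampler.

From the posterior draws the package computes **counterfactual** quantities
for every unit under every arm: survival-time ratios `exp(f(a,x) − f(a',x))`,
5-year survival-probability differences `S(t*|a,x) − S(t*|a',x)`, population
average effects with credible intervals, and mean counterfactual survival
curves.  A "fit-the-fit" layer then regresses the individual effects on the
covariates with stepwise random forests (out-of-bag R², 1% improvement
stopping rule), extracts interpretable subgroup rules from the final forest
(inTrees-style harvest–prune–rank), and reports each subgroup's effect with a
credible interval — hypothesis-free heterogeneity discovery.

A clustered-survival simulator with closed-form counterfactual truths
(proportional- and nonproportional-hazards Weibull families, confounded
3-arm assignment, calibrated censoring) and a replicated PEHE benchmark
harness round out the package.

## Worked example

```python
import riaft_bart as rb

cfg = rb.ScenarioConfig(n=600, n_clusters=15, family="ph", seed=20)
dataset, truth = rb.simulate(cfg)

draws = rb.fit_riaft(dataset, rb.McmcConfig(n_trees=50, n_burn=500,
                                            n_keep=500, seed=1))

ite = rb.individual_effects(draws, dataset, pair=(1, 3), t_star=60.0)
ratio = rb.average_effect(ite, "ratio")
diff = rb.average_effect(ite, "diff")

trace, rules = rb.discover_teh(ite, dataset.covariates,
                               dataset.covariate_names,
                               n_estimators=200, seed=0)
```

Output of this exact script:

```
simulated 600 units, 15 clusters, 80.0% events
posterior sigma 1.089, tau 0.223 (log-time scale)
arm 1 vs 3 survival-time ratio: 0.78 (0.58, 1.02)
arm 1 vs 3 5-year survival difference: -0.067 (-0.148, +0.005)
true average difference in this draw of the generator: -0.045
selected effect modifiers: ['x6', 'x4', 'x1', 'x9'] (improvement-below-threshold)
  rule x6 > 0.5 AND x1 <= -0.1677: support 0.23, effect -0.017 (-0.113, +0.090)
```

Reading it: patients on arm 1 are estimated to live 0.78 times as long as
they would on arm 3 (interval touching 1 — borderline), equivalently a 6.7
percentage-point lower 5-year survival probability, close to the generator's
true −4.5 points for this draw.  The heterogeneity layer correctly surfaces
`x6` and `x1` — the two covariates whose interaction with treatment the
generator planted — and its top rule (binary `x6` positive, low `x1`)
identifies a subgroup whose effect is near zero, i.e. patients for whom arm 3
offers no advantage.

The same pipeline is available from the shell:

```bash
riaft-bart simulate --scenario ph --n 600 --seed 20 --out data.csv
riaft-bart fit --data data.csv --trees 50 --burn 500 --keep 500 --out draws.npz
riaft-bart effects --draws draws.npz --data data.csv --horizon 60 --out effects.csv
riaft-bart teh --draws draws.npz --data data.csv --contrast 1,3 --out rules.json
riaft-bart evaluate --scenario nph --reps 10 --out metrics.csv   # PEHE benchmark
```

Every output directory gains a `manifest.json` recording the stage settings
and seeds, so runs are regenerable from their artifacts.

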