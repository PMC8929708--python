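# ophs — interpretable demand modelling for online psychological help-seeking

During a large epidemic, online mental-health platforms become the main
channel for psychological support, and the platforms' operators need to know
— days to weeks in advance — how many people will ask for help each day.
`ophs` implements an interpretable machine-learning pipeline for exactly
that problem: it predicts the daily number of online psychological
help-seeking (OPHS) posts from four predictor families and then explains
every prediction with Shapley attributions.

The package is aimed at computational researchers in public mental health
and digital epidemiology who want a fully tested, fully synthetic-checkable
version of this analysis: every stage can be run against a generator that
plants known structure (topics, platform coupling, epidemic effects) so the
pipeline's recovery properties are measurable.

## What it computes

Given a stream of help-seeking posts, a daily epidemic case table, and the
daily count series of two platforms, the pipeline builds four feature
blocks aligned on the calendar:

* **topic** — seed lexicons are expanded in embedding space (PPMI-SVD word
  vectors; a word joins the lexicon when its cosine similarity to a seed
  exceeds a threshold, 0.3260 for problem words and 0.3556 for
  influential-factor words), posts are reduced to in-lexicon tokens,
  embedded by average word vectors, and clustered with k-means; k is chosen
  by the silhouette coefficient over a 4–20 scan (each semantic family is
  clustered separately). Daily post counts per cluster are the features.
* **liwc** — daily token proportions per category of a LIWC-style
  dictionary (terminal wildcards, multi-membership).
* **temporal** — an additive decomposition y(t) ≈ g(t) + s₇(t) + s₃₆₅(t)
  (piecewise-linear trend with changepoints, Fourier seasonality,
  ridge-penalised least squares) supplying trend, weekly, yearly,
  additive_terms and yhat columns, plus a forecast baseline.
* **covid** — cumulative/new confirmed cases and deaths.

Features at day *t* are paired with the count at day *t + L* for horizons
L ∈ {1, 3, 7, 14}; five regressors (LR, ridge, lasso, linear SVR, random
forest) are compared by out-of-fold 10-fold MAE and Pearson r, over all 15
feature-block combinations. The fitted model is interpreted with
interventional Shapley values (exact 2^P enumeration, a per-tree route, and
permutation sampling), aggregated into the cumulative set-level statistic

    SHAP_F(+) = Σ_{i,j : j ∈ F, SHAP_ij > 0} SHAP_ij

(and its negative counterpart), per-feature positive-entry counts X_i,
top-k rankings by mean |SHAP|, and single-day force-plot decompositions.
Lead-lag Pearson correlation between the two platforms' series estimates
the coupling delay between them.

## Worked example

```python
import ophs

# synthetic study: epidemic curve, coupled platform counts, planted topics
epi = ophs.generate_epidemic_series(365, seed=41)
dem = ophs.generate_ophs_series(365, epi, ophs.DemandModelParams(seed=42))
problems = ophs.default_topic_specs("problems")
factors = ophs.default_topic_specs("factors")
posts = ophs.generate_post_corpus(dem.primary, problems, seed=43,
                                  companion_topics=factors)

# which platform leads, and by how many days?
lag = ophs.lead_lag_correlation(dem.primary, dem.secondary)
print(lag.best_lag)                    # 13

# full feature pipeline and a 3-day-ahead random-forest model
res = ophs.run_feature_pipeline(
    posts, epi, dem.primary.astype(float),
    problem_seeds=[w for s in problems for w in s.seed_words],
    factor_seeds=[w for s in factors for w in s.seed_words],
    seed=0)
print(res.problems.clustering.k)       # 7  (silhouette-selected)

fit = ophs.DemandModel.from_bundle(
    res.bundle, dem.primary.astype(float), horizon=3, algorithm="rf"
).fit(seed=0)
print(fit.summary())
```

The summary printed by the last call:

```
Demand regression results
==============================================
algorithm             rf
horizon (days)        3
rows                  362
features              47
split                 kfold10 (seed 0)
MAE (out-of-fold)     2.868
Pearson r             0.816
MAE / mean (%)        5.97
==============================================
```

i.e. predicting three days ahead, the model's out-of-fold error is about
2.9 posts/day against a mean of ~48 posts/day (≈6% relative error), and
out-of-fold predictions correlate with the truth at r ≈ 0.82. Attributions
then identify what drives the forecast:

```python
attr = fit.shap_values(method="sampling", seed=0, n_permutations=10,
                       max_background=40)
print(ophs.top_k_features(attr, 5).table)
#                 feature  mean_abs_shap  cumulative_share
# 0      temporal__weekly       2.061641          0.243478
# 1        temporal__yhat       1.278346          0.394449
# 2  covid__cum_confirmed       1.049824          0.518432
# 3       temporal__trend       0.938697          0.629291
# 4     covid__cum_deaths       0.920649          0.738019
```

The temporal features dominate, and the two epidemic covariates with
planted nonzero effects (cumulative confirmed cases and cumulative deaths)
rank inside the top five — the generator's injected drivers, recovered.

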