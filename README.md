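# sentirisk

Spatiotemporal Poisson relative-risk modelling of negative-sentiment
counts against weekly climate covariates.

## The problem

Social-media posts give a fast, spatially resolved signal of how people
react to climatic stress. Given a panel of geotagged documents (e.g.
tweets) assigned to regions, the question is whether the weekly share
of *negative* documents co-varies with temperature, precipitation and
extreme events such as the July 2021 flood in western Germany — and by
how much, region by region.

`sentirisk` implements the full analysis chain for this question:

* a **text pipeline** that cleans and tokenizes raw documents, labels
  them negative/positive/neutral with a transparent, pluggable lexicon
  scorer, and aggregates them into weekly region-level counts;
* **covariate preparation**: weekly regional temperature and
  precipitation, categorized into ordered levels (precipitation: below
  0.01 / 0.01–0.035 / 0.035 and higher; temperature: below 15 °C /
  15–19 / 19–23 / 23 °C and above), plus the three 28-day
  before/during/after event windows around 2021-06-22…2021-07-19;
* the **risk model** itself with an in-repo Laplace (Gaussian
  approximation) fitter and optional empirical-Bayes hyperparameter
  selection;
* a **synthetic-data generator** that emulates the whole study with
  known ground truth, so every stage is testable without any download;
* a **CLI** (`sentirisk run`) orchestrating simulate → build-panel →
  covariates → fit → report.

## The model

Weekly negative counts `NTw(i,t)` in region `i` and week `t` are

```
NTw(i,t) ~ Poisson( μ(i,t) ),      μ(i,t) = θ_tot · TTW(i,t) · relrisk(i,t)
```

where `TTW(i,t)` is the total number of documents (the exposure),
`θ_tot = Σ NTw / Σ TTW` is the dataset-wide negative share, and the
log relative risk is additive in a latent spatiotemporal field and
categorized covariate effects:

```
log relrisk(i,t) = b0 + field(i,t) + f_temp[cat_T(i,t)] + f_precip[cat_P(i,t)]
```

The field is a Gaussian Markov random field: an intrinsic CAR (Besag)
structure `Q = τ (D − A)` on the region-adjacency graph, combined with
a stationary AR(1) process over weeks as a Kronecker (separable)
product; independent alternatives for either factor are available. The
category effects `f_h ~ N(0, C)` carry chain priors (independent or
AR(1) over adjacent levels), and a temperature × precipitation
interaction with a two-dimensional ICAR prior can be switched on. A
global intercept plus sum-to-zero constraints (per week for the field,
per block for the effects) make the decomposition identifiable, so
effects are reported relative to their own mean.

Fitting is deterministic: Newton ascent of the joint log posterior
over all latents (equality constraints handled exactly by a kriging
correction) gives the posterior mode, and the negative Hessian
restricted to the constraint subspace gives posterior standard
deviations and covariances of arbitrary contrasts. 95% bounds are
`mean ± 1.96 sd` on the log scale, transformed monotonically to the
percent relative-risk scale `100·(exp(·) − 1)`.

## Worked example

The default configuration simulates the reference study — the 13
merged German federal states (Hamburg, Bremen, Berlin joined with
neighbours), 187 weeks from 2019-01-01, ~6000 tweets per region-week,
a planted ×1.10 relative-risk event in the contiguous western block
(NW, RP, SL, HE) during the flood window — and fits it:

```
sentirisk run --out runs/demo --seed 1
cat runs/demo/report.txt
```

which prints (abridged):

```
theta_tot (baseline negative share): 0.1000
converged in 4 Newton iterations

temperature effect (percent RR change vs block mean):
       low:  -0.37% [ -0.64,  -0.10]*
       mid:  -1.26% [ -1.71,  -0.81]*
   average:  -0.35% [ -0.77,  +0.07]
      high:  +2.00% [ +1.50,  +2.51]*

precipitation effect (percent RR change vs block mean):
       low:  -1.01% [ -1.45,  -0.57]*
       mid:  -0.82% [ -1.26,  -0.38]*
      high:  +1.85% [ +1.08,  +2.64]*

before -> during RR change by region (* = 95% significant):
      HE:  +8.84% [ +4.63, +13.22]*
      NW:  +8.96% [ +4.19, +13.94]*
      RP: +10.79% [ +6.25, +15.53]*
      SL: +11.57% [ +6.23, +17.17]*
      ...
```

Reading this: negative-sentiment risk rises about +2% in the hottest
temperature band and about +1.1% (here +1.85% including the event's
contribution to high-precipitation weeks) in the wettest band, both
significantly, while the flood regions show a significant ~+9…12%
increase in relative risk from the before-window to the during-window
— the same qualitative and quantitative picture the generator planted.

The same estimator is available as a library object:

```python
import sentirisk as sr

bundle = sr.default_bundle(seed=1)          # known-truth synthetic study
est = sr.NegativeSentimentRiskModel().fit(bundle.panel, bundle.climate,
                                          bundle.graph)
est.effect_summary("temperature").to_frame()
est.rr_difference().to_frame()
```

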