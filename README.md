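# sealdisp

Detection-corrected estimation of natal dispersal between two breeding
colonies from tag–resight records, with a hierarchical Bayesian model fit by a
bespoke Metropolis sampler and an individual-based simulator for end-to-end
validation.

## The problem

Colonial breeders such as northern elephant seals (*Mirounga angustirostris*)
are tagged as pups at their birth colony and resighted as breeding adults.
Natal dispersal — breeding for the first time at a colony other than the birth
colony — is a binomial event per female, so with two colonies the observed
dispersal rate from colony *i* to *j* is

    μ_ij = b_ij / (b_ij + b_ii)

where `b_ij` counts females born at *i* first seen breeding at *j*.  But if
lifetime detection differs between colonies, this ratio is biased: dispersal
toward the well-observed colony is overestimated.  `sealdisp` estimates the
per-colony detection chain from the resight data themselves and corrects the
dispersal rates, propagating all uncertainty.  It is aimed at mark–recapture
studies with discrete breeding sites and imperfect, site-specific detection.

## The method

Per colony, from resight summaries alone:

* **Reappearance** `π = D_{t+1} / D_t`: the probability a female observed
  breeding in one year is observed at the same colony the next year
  (Beta posterior from the two counts).
* **Return rate** `τ = σρ` (survival × tag retention; only the product is
  identifiable): the decay rate of the pooled age distribution of breeding
  females, estimated by log-linear regression (Normal posterior).
* **Annual detection** `δ = π / τ`.
* **Lifetime detection** `Δ = δ / (1 − τ(1 − δ))`: the probability a female
  who ever breeds is ever observed — annual detection times the expected
  number of seasons until first detection.

The corrected dispersal rate needs only the ratio `Δ_ji = Δ_j / Δ_i`:

    μ̂_ij = b_ij / (b_ij + b_ii Δ_ji)

Monte-Carlo draws of `Δ_ji` form the prior for a hierarchical model in which
the observed disperser count of each annual cohort is Poisson with mean

    b_ij = B_i μ̂_ij Δ_ji / (1 − μ̂_ij (1 − Δ_ji))

and the 17 annual rates share a Normal hyper-distribution on the log-odds
scale, `logit(μ̂_ij) ~ Normal(θ, Σ)` (optionally with a linear year trend
`ν·t + η`).  A one-parameter-at-a-time random-walk Metropolis sampler (6000
steps, 2000 burn-in by default) draws the joint posterior; at every sweep the
detection ratio is refreshed from its stored prior sample, so detection
uncertainty flows into the dispersal posterior but is never informed by the
dispersal counts.

The complete count data of the published two-colony study (17 cohorts,
1994–2010, Año Nuevo and Piedras Blancas) are bundled in
`sealdisp.datasets`.

## Worked example

```python
import sealdisp as sd
from sealdisp import datasets

det = datasets.study_detection_posterior(M=100_000, seed=1)
print(det.summary().round(3).to_string(index=False))

table = datasets.study_cohort_table()
an, pb = datasets.COLONIES
cfg = sd.DispersalModelConfig(seed=1)
post = sd.fit_dispersal(table, pb, det.ratio_draws(an, pb), cfg, n_chains=4)
print(sd.summarize(post).table.round(3).loc[["theta", "sigma", "mu_2000", "mu_2004"]])
```

prints

```
                 colony quantity  mean  ci_low  ci_high
               AnoNuevo       pi 0.563   0.543    0.583
               AnoNuevo      tau 0.799   0.789    0.809
               AnoNuevo    delta 0.705   0.678    0.731
               AnoNuevo    Delta 0.922   0.913    0.931
         PiedrasBlancas       pi 0.165   0.138    0.194
         PiedrasBlancas      tau 0.783   0.753    0.813
         PiedrasBlancas    delta 0.211   0.176    0.249
         PiedrasBlancas    Delta 0.551   0.493    0.608
AnoNuevo/PiedrasBlancas    ratio 1.678   1.517    1.872
PiedrasBlancas/AnoNuevo    ratio 0.598   0.534    0.659
            mean  ci_low  ci_high
parameter
theta      0.161   0.097    0.238
sigma      0.773   0.300    1.470
mu_2000    0.343   0.189    0.585
mu_2004    0.060   0.009    0.155
```

Reading the output: a female breeding at Piedras Blancas had a 55% chance of
ever being recorded versus 92% at Año Nuevo, so raw counts overstate
northward dispersal.  After correction, a mean 16% of Piedras Blancas-born
females per cohort still dispersed north to breed (`theta`, 95% CI
0.10–0.24), with strong year-to-year variation (`mu_2000` vs `mu_2004`).
Fitting the opposite direction the same way gives a southward mean near 8%.

A command-line layer wraps the same functions:

```sh
sealdisp simulate --seed 1 --out sim/        # synthetic two-colony data
sealdisp tally --sightings sim/sightings.csv --tagged sim/tagged_totals.csv \
    --final-year 2018 --out tables/
sealdisp detection --study --out det/        # bundled study counts
sealdisp fit --study --direction PiedrasBlancas --out fit/
sealdisp report --out report/                # tables, figure, manifest
```

## Simulator

`sealdisp.simulate` builds individual females with known survival × retention,
colony-specific detection, cohort dispersal probabilities, and rare adult
movement, then emits exactly the sighting records the ingest layer reads.
`recovery_experiment` runs the whole pipeline over replicate simulations and
reports bias and credible-interval coverage of the dispersal hyper-mean.  See
`docs/methods.md` for model assumptions, parameter choices, and limitations.
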