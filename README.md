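# tziprisk

Temporal zero-inflated Poisson (tZIP) modelling of all-cause
rehospitalisation risk among elderly inpatients, with a time-indexed joint
risk estimator, comparator models, monthly validation harnesses, and a
conditional-inference tree for ranking the estimator against post-discharge
service features.

## The problem

Rehospitalisation models for older patients are typically built for a fixed
28- or 30-day window and degrade rapidly at longer horizons. `tziprisk`
implements a mixture-model alternative in which the *window length itself*
is a model input, so one fit yields a risk trajectory from 28 to 365 days
post-discharge. It is aimed at biostatisticians and health-services
researchers who work with episode-level EHR extracts; because such extracts
cannot be shared, the package ships a calibrated synthetic cohort generator
so every stage is runnable and testable end to end.

## The model

For a patient with LACE covariates
x = (**L**ength of stay, **A**cuity of admission, **C**harlson index,
**E**R visits in the prior 6 months) observed for t days after discharge,
the rehospitalisation count Y(t) follows a zero-inflated Poisson mixture
whose both parameters carry fixed temporal offsets in standardised time
t* = t / t_scale ∈ (0, 1]:

    logit p(t) = β_p · [1, x] + f_p(t*)          (structural-zero part)
    λ(t)       = exp(β_λ · [1, x]) · f_λ(t*)     (Poisson count part)

    P(Y = 0) = p + (1 − p) e^{−λ},   P(Y = y) = (1 − p) e^{−λ} λ^y / y!

p(t) is the probability of being "inactive" (not at risk within the
window); it is convexly decreasing in t. λ(t) is the expected cumulative
count of an at-risk patient; it is concavely increasing. The offset shapes
are chosen from a small candidate library by training log-likelihood
(`families="auto"`), subject to a numeric audit of those shape constraints.

The **joint estimator** combines both components into the probability of at
least one rehospitalisation by horizon t:

    JE(t) = (1 − p(t)) · (1 − e^{−λ(t)}),    S(t) = 1 − JE(t)

JE(t) is both a per-patient risk trajectory and the scalar ranking score
used in the discrimination analyses. Observed zeros decompose, via the
posterior p / (p + (1 − p) e^{−λ}), into structural ("inactive") versus
at-risk ("active") zeros.

Comparators sharing the same four predictors: the additive van Walraven
LACE point score (0–19) and a Cox proportional-hazards model on time to
first rehospitalisation. The hybrid stage grows an unbiased
recursive-partitioning tree with surrogate splits (URPSS): permutation-test
feature selection with Bonferroni adjustment, rank-based statistics, and
surrogate routing for logically missing service features.

## Worked example

```
tziprisk simulate --n 20000 --seed 7 --out train.csv
tziprisk simulate --n 10000 --seed 8 --out valid.csv --services 6 --residential-fraction 0.4
tziprisk fit --episodes train.csv --out fit.json --family "p:linear|lam:sqrt"
tziprisk report --fit fit.json --episodes train.csv --out coefs.csv
tziprisk tree --episodes valid.csv --fit fit.json --out tree.json
```

prints (abridged):

```
fitted family p:linear|lam:sqrt (loglik=-31109.82, converged=True)
component                       term    ratio  coefficient       se          z
 logistic            Acute Admission 0.736322    -0.306087 0.117619  -2.602353
 logistic       ER Visits (6 months) 0.657174    -0.419807 0.052019  -8.070213
  poisson            Acute Admission 0.821015    -0.197214 0.017908 -11.012622
  poisson       ER Visits (6 months) 1.164361     0.152172 0.003850  39.523469
zero decomposition: 59.1% active / 40.9% structural
root feature: je_28d
```

Reading the output: in the logistic component the `ratio` column is an
odds ratio on being *inactive* — each prior ER visit multiplies the odds of
being out of rehospitalisation risk by 0.657, i.e. it raises risk. In the
Poisson component the ratio is a rate ratio on the expected count — each ER
visit multiplies expected rehospitalisations by 1.164. About 59% of the
observed zero counts are attributed to at-risk patients who simply had no
event yet ("active zeros"). In the hybrid tree the tZIP-based 28-day risk
estimate (`je_28d`) is selected as the root ("mother node"), i.e. its
marginal contribution to the 28-day outcome exceeds that of every clinical
and service-utilisation feature in the pool.

A per-patient risk trajectory from the same fit (LOS 5 d, acute admission,
Charlson 2, one ER visit):

```python
>>> from tziprisk import risk_curve
>>> from tziprisk.io import read_fit
>>> fit = read_fit("fit.json")
>>> x = {"los_days": 5.0, "acute_admission": 1, "charlson_index": 2, "er_visits_6m": 1}
>>> risk_curve(fit, x, [28, 90, 180, 365]).to_frame().round(3)
 horizon_days    je  survival
         28.0 0.220     0.780
         90.0 0.381     0.619
        180.0 0.536     0.464
        365.0 0.739     0.261
```

The monthly validation harnesses are available as
`tziprisk evaluate --mode retrospective --train train.csv --valid valid.csv --out eval.csv`
(12 monthly subsets × horizons × {JE, Cox, Linear}, ROC-AUC and PR-AUC per
cell) and `--mode prospective` (score first, reveal outcomes afterwards,
with an audit log).

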