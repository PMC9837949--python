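# Methods

## Model

`tziprisk` models the rehospitalisation count of an elderly patient over a
post-discharge window of length t days as a zero-inflated Poisson mixture
whose both parameters are functions of the window length. The logistic
component gives the probability p(t) that the episode is a *structural*
zero — a patient not at risk of rehospitalisation within the window; the
Poisson component gives the expected cumulative count λ(t) of an at-risk
patient. Both linear predictors use the four unstandardised LACE
covariates (length of stay in days, acute-admission indicator, Charlson
comorbidity index, ER visits in the prior six months); LACE is kept on its
natural scale so ratios are directly interpretable per unit.

Time enters through two fixed offsets in standardised exposure
t* = t / t_scale, where t_scale is the maximum in-sample exposure (728.2
days under the default study window — two years):

    logit p(t) = β_p · [1, x] + c_p · h(t*)
    log  λ(t)  = β_λ · [1, x] + log(c_λ · g(t*))

h is a unit-normalised decreasing shape (h(1) = −1), g a unit-normalised
increasing shape with g(0) = 0 and g(1) = 1. The offsets carry fixed
loading 1 — they are true offsets, not estimated slopes — which keeps both
intercepts identifiable. The candidate shape library is
h ∈ {−t, −√t, ln(1 − t/2)/ln 2} and g ∈ {t, √t, ln(1 + t)/ln 2}; with
`families="auto"` all nine pairs are fitted and the highest training
log-likelihood wins, subject to a numeric audit (100-point grid at the
training covariate means) that p(t) is decreasing and convex and λ(t)
increasing and concave. Ties break toward lower AIC, then lexicographic
family id. The audit matters: a concave logit offset (the log shape)
produces a locally concave p near t = 0 when p ≈ 1/2 there, and such
families are excluded from selection rather than silently accepted.

### Offset scale constants

The two scale constants are part of the default family definition:
c_p = 4.0710 and c_λ = 2.2042. They were calibrated once, before any model
fitting, by solving two moment equations at the reference coefficient
values and the default covariate margins: the generated cohort must
reproduce (i) a mean two-year rehospitalisation count of 1.6 and (ii) a
59.3% / 40.7% split of observed zeros into active versus structural zeros.
The implied zero fraction (~0.29) is consistent with a first-quartile of 0
and a median of 1 rehospitalisation. These constants are deliberately not
free parameters of the fit.

## Joint estimator and zero decomposition

The joint estimator at horizon t is the mixture probability of at least
one rehospitalisation by t:

    JE(t) = (1 − p(t)) (1 − e^{−λ(t)})

It is the unique probability statement using both components at a horizon,
nondecreasing in t for every admissible family (a decrease is treated as a
hard error indicating an invalid family, not a warning). S(t) = 1 − JE(t)
is the model survival curve, comparable to a Kaplan–Meier estimate of time
to first rehospitalisation. For an observed zero count at exposure t, the
posterior probability of being structural is p / (p + (1 − p) e^{−λ});
cohort shares of active/structural zeros are averages of these posteriors
over zero-count records and sum to one exactly.

## Estimation

Both coefficient vectors are estimated jointly by direct maximum
likelihood: BFGS on the mean negative log-likelihood with an analytic
gradient, from a deterministic start (logistic intercept at the logit of
the observed zero excess, Poisson intercept at the log mean positive count
net of the mean offset, all slopes zero). Convergence requires a gradient
sup-norm below 1e−8 (mean scale; accepted down to 1e−5 with the norm
reported); non-convergence is flagged, never silently returned. Standard
errors come from the inverse observed information (numerical Hessian at
the optimum); a singular information matrix yields a fit with absent SEs,
flagged. An EM implementation (posterior-weighted offset logistic and
Poisson IRLS steps) is provided purely as a cross-check and agrees with
the direct MLE to ~1e−3 on test cohorts. AIC is 2k − 2ℓ with k the free
coefficients. The model collapses to a plain zero-inflated Poisson
regression under the constant family (f_p ≡ 0, f_λ ≡ 1) and to a Poisson
GLM when the inflation component is disabled; both reductions are verified
against independent implementations (statsmodels) in the test suite.

## Synthetic cohort generator

The generator emulates an episode-level EHR extract. Covariate margins
(defaults): lognormal length of stay moment-matched to mean 6.4 / SD 7.4;
Bernoulli acute admission at prevalence 0.877; negative-binomial Charlson
index (mean 1.0, SD 1.4) and ER visits (mean 0.8, SD 1.2, median 0);
exposure from a truncated normal on (0, 728.2] whose *truncated* moments
match mean 448.7 / SD 186.5 (the parent location/scale are solved
numerically). Margins are independent by default with an optional
Gaussian-copula correlation knob — real EHR covariates are correlated, so
passing tests under independence does not establish robustness to
confounded covariates. Clinical-profile flags (cancer 7.1%, COPD 21.5%,
stroke 26.4%, diabetes 26.2%, ICU admission 0.304%, surgical events 8%)
are weakly tied to the Charlson index. Service-utilisation features are
*logically* missing: each is defined only where an eligibility predicate
holds (e.g. residential-care days exist only for residential-care
residents), mirroring how service timing/duration fields are coded in
post-acute records.

Outcomes: a mixture whose p and λ both move with the window length admits
no single counting process with the ZIP marginal at *every* horizon, so
the generator enforces exactness where the model is used.

1. A latent structural flag Z ~ Bernoulli(p(t_i)) at the episode's own
   exposure t_i; structural episodes have no events.
2. The first-event time of an at-risk episode is drawn by inverse
   transform on the model's conditional zero-probability curve, so that
   marginally P(any event by h) = JE(h) exactly for every h ≤ t_i. In
   particular the active-zero rate over the full window is e^{−λ(t_i)}
   exactly, which makes the posterior zero decomposition perfectly
   calibrated against the latent flags.
3. The total count is zero-truncated Poisson at λ(t_i) — the full-window
   count therefore has the exact ZIP(p(t_i), λ(t_i)) marginal used by the
   fitter — and the remaining events fall by inverse transform on the
   normalised cumulative mean function restricted to (T1, t_i].

The price of this construction is that intermediate-horizon *count*
distributions (beyond the zero/nonzero split) are only approximately
Poisson; nothing in the package consumes them. Two calls with the same
seed produce identical cohorts.

## Comparators

The "Linear model" is the canonical van Walraven LACE point table
(L: <1 d→0, 1→1, 2→2, 3→3, 4–6→4, 7–13→5, ≥14→7; acute→3; Charlson 0–3
as-is, ≥4→5; ER visits capped at 4), an integer score 0–19 used as a
horizon-invariant ranking score; the table is an overridable constant.
The Cox model uses time to first rehospitalisation, censored at the end of
each episode's observation window (first-event formulation), fitted with
lifelines (Efron ties, Breslow baseline); horizon risk is
1 − exp(−H₀(h) e^{xβ}). Zero-variance covariates are excluded from the
partial likelihood with coefficient 0.

## Evaluation harnesses

ROC-AUC is the Mann–Whitney concordance with ties counted half; PR-AUC is
the area under the step precision–recall curve from a descending-score
sweep with equal scores grouped and no linear interpolation (the
conservative convention for imbalanced outcomes). Both are delegated to
scikit-learn and verified against brute-force hand oracles in the tests.
Kaplan–Meier survival uses lifelines.

The retrospective harness fits tZIP and Cox on a training cohort, splits
an out-of-sample cohort into 12 subsets by admission month, and reports
AUC/PR-AUC per model × horizon × month. Labels are per-record: an episode
is positive at horizon h if any event falls within h days of *its own*
discharge; episodes observed for less than h days are unlabellable and
excluded at that horizon (months left with fewer than two outcome classes
are skipped with a warning). The prospective harness scores each monthly
cohort from covariates alone, then reveals outcomes and verifies, one
month at a time, with an audit log proving scoring preceded every reveal;
degenerate months produce explicit skip records.

## Hybrid conditional-inference tree (URPSS)

At each node every candidate feature is tested for association with the
binary outcome using a standardised linear statistic on *midrank* scores —
T = Σ rank(x_i) y_i, standardised by its exact permutation mean and
variance — so p-values are invariant under strictly monotone feature
transforms and ties are handled. Rows missing a feature are excluded from
that feature's test. The minimum Bonferroni-adjusted p decides whether to
split (stop above α, default 0.05), separating variable selection from
cut-point search to avoid the bias toward many-valued features; the cut
maximises the standardised two-sample statistic over observed cut
midpoints, breaking ties toward the smaller cut. Surrogate splits are
ranked by agreement with the primary routing on co-observed rows (better
of the two orientations); rows missing the primary feature follow the
first observed surrogate, then the majority direction. P-values are
asymptotically normal by default; a seeded Monte-Carlo permutation option
(add-one smoothing, hence finite-sample valid) and an exact enumeration
over label placements for small binary-outcome instances exist for
inference-critical use and verification. Defaults: α = 0.05, minimum node
size 20, minimum leaf 7, at most 5 surrogates; the tree, its surrogate
lists, adjusted p-values and a root-ward variable ranking serialise to
JSON.

The hybrid feature matrix pairs the 28-day joint estimate (`je_28d`) with
the clinical profile (comorbidity, diagnosis flags, ICU/surgical events),
the discharge destination, and the service features. The LACE inputs are
deliberately not competing features: they enter only through the risk
estimator whose marginal contribution the tree ranks.

## Problem sizes and numerical choices

The recovery experiment uses 50,000 episodes (fit in ~3 s); the
discrimination comparison 30,000 training / 15,000 validation episodes per
seed over 5 seeds; the root-selection experiment 3,000 episodes per seed
over 20 seeds; type-I control 150–200 null cohorts of 300 rows with
199-permutation p-values. Exposure standardisation clips t* to (0, 1] and
warns when scoring beyond t_scale; linear predictors are clipped at ±700
before exponentiation; the zero-count likelihood uses log-sum-exp
throughout. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fits, trees and cohorts are bit-reproducible.

## Limitations

* The generator reproduces published *margins* and the model's own
  outcome law; it does not emulate covariate correlation (by default),
  informative censoring, seasonal admission patterns, competing risk of
  death, or coding noise. Passing tests demonstrates internal consistency
  and correct inference under the stated DGP, not real-world performance.
* Under the reference coefficients the two components' effects nearly
  cancel for acute admission and length of stay inside JE, so the JE
  ranking is dominated by ER visits; JE's advantage over a well-fitted Cox
  model on such data is real but small (~+0.002 AUC), while the additive
  LACE score trails by ~0.06.
* The logistic component of the mixture is weakly identified when active
  zeros are common: at the calibrated study conditions the acute-admission
  odds ratio carries a Monte-Carlo standard error of ~0.045 at n = 50,000.
* Bayesian estimation, zero-inflated negative binomial, recurrent-event
  Cox, calibration metrics and tree pruning are out of scope.
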