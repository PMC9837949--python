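"""Synthetic episode-level EHR cohort generator.

Real rehospitalisation extracts from hospital EHR systems cannot be shared,
so every downstream stage of this package is exercised on synthetic cohorts.
The generator draws the four LACE predictors and the exposure time from
distributions moment-matched to the published descriptive margins of a large
elderly inpatient cohort, then draws rehospitalisation outcomes
from the temporal zero-inflated Poisson process itself:

* a latent structural-zero indicator ``Z_i ~ Bernoulli(p_i(t_i))`` marks
  episodes that cannot rehospitalise within their window ("inactive");
* at-risk episodes receive a full-window count with the zero-inflated
  Poisson marginal and event times anchored to the model's zero-probability
  curve, so the probability of any event within a horizon equals the joint
  estimator JE(h) exactly, at every horizon (details in the outcome-
  generation section below).

Covariate distribution choices (all right-skewed margins have medians below
their means): lognormal length of stay, Bernoulli acute admission,
negative-binomial Charlson index and ER visits, truncated-normal exposure
capped at the two-year study window.  Margins are independent by default;
a Gaussian-copula correlation knob is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .tzip import (
    DEFAULT_FAMILY,
    LACE_COLUMNS,
    TZIPParams,
    linear_predictors,
    standardise_time,
)

__all__ = [
    "CovariateSpec",
    "reference_params",
    "generate_cohort",
    "label_horizon",
    "attach_service_features",
    "SERVICE_FEATURES",
]

#: logistic (structural-zero) coefficients (intercept, L, A, C, E) reported
#: for the reference elderly cohort; exp() gives the published odds ratios.
REFERENCE_BETA_P = np.array([0.869, -0.012, -0.467, -0.029, -0.467])

#: Poisson-component coefficients; exp() gives the published rate ratios.
REFERENCE_BETA_LAMBDA = np.array([0.059, -0.005, -0.208, 0.053, 0.149])

#: two-year study window in days (maximum observed exposure).
STUDY_HORIZON_DAYS = 728.2


def reference_params(family=DEFAULT_FAMILY, t_scale: float = STUDY_HORIZON_DAYS) -> TZIPParams:
    """tZIP parameters at the published reference coefficient values."""
    return TZIPParams(
        beta_p=REFERENCE_BETA_P.copy(),
        beta_lambda=REFERENCE_BETA_LAMBDA.copy(),
        family=family,
        t_scale=t_scale,
    )


@dataclass
class CovariateSpec:
    """Marginal moments of the covariates and exposure to emulate.

    Defaults reproduce the reference cohort's descriptive statistics:
    length of stay 6.4 (SD 7.4) days, acute-admission prevalence 87.7%,
    Charlson index 1.0 (SD 1.4), ER visits 0.8 (SD 1.2) with median zero,
    exposure 448.7 (SD 186.5) days capped at 728.2.
    """

    los_mean: float = 6.4
    los_sd: float = 7.4
    acute_prevalence: float = 0.877
    charlson_mean: float = 1.0
    charlson_sd: float = 1.4
    er_mean: float = 0.8
    er_sd: float = 1.2
    exposure_mean: float = 448.7
    exposure_sd: float = 186.5
    exposure_max: float = STUDY_HORIZON_DAYS
    residential_fraction: float = 0.0
    n_service_features: int = 0
    #: optional per-feature eligibility predicate: (feature_name, episodes
    #: DataFrame, rng) -> boolean eligibility mask; None -> default rule.
    missingness_rule: Callable | None = None
    #: optional Gaussian-copula correlation among (LOS, acute, Charlson, ER,
    #: exposure); None -> independent margins.
    copula_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("acute_prevalence", "residential_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in (
            "los_mean", "los_sd", "charlson_mean", "charlson_sd",
            "er_mean", "er_sd", "exposure_mean", "exposure_sd", "exposure_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Moment-matched marginal draws
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _negbin_params(mean: float, sd: float) -> tuple[float, float]:
    """(r, p) of a negative binomial matched to mean/SD (Poisson fallback
    when the variance does not exceed the mean)."""
    var = sd**2
    if var <= mean:
        return np.inf, float("nan")  # signal Poisson
    r = mean**2 / (var - mean)
    return r, r / (r + mean)


def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (loc, scale) such that the normal truncated to (lo, hi] has the
    requested mean and SD."""

    def moments(x):
        loc, log_scale = x
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], tol=1e-10)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError("could not match truncated-normal moments")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _copula_uniforms(n: int, corr: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
    """(n, 5) uniforms, correlated through a Gaussian copula when requested."""
    if corr is None:
        return rng.uniform(size=(n, 5))
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (5, 5):
        raise ValueError("copula_corr must be 5x5 (LOS, acute, Charlson, ER, exposure)")
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal(size=(n, 5)) @ chol.T
    return stats.norm.cdf(z)


def _draw_covariates(n: int, spec: CovariateSpec, rng: np.random.Generator) -> pd.DataFrame:
    u = _copula_uniforms(n, spec.copula_corr, rng)
    mu, sigma = _lognormal_params(spec.los_mean, spec.los_sd)
    los = stats.lognorm.ppf(u[:, 0], s=sigma, scale=np.exp(mu))
    acute = (u[:, 1] < spec.acute_prevalence).astype(int)

    def _count(ucol, mean, sd):
        r, p = _negbin_params(mean, sd)
        if np.isinf(r):
            return stats.poisson.ppf(ucol, mean).astype(int)
        return stats.nbinom.ppf(ucol, r, p).astype(int)

    charlson = _count(u[:, 2], spec.charlson_mean, spec.charlson_sd)
    er = _count(u[:, 3], spec.er_mean, spec.er_sd)
    loc, scale = _truncnorm_parent(
        spec.exposure_mean, spec.exposure_sd, 0.0, spec.exposure_max
    )
    a, b = (0.0 - loc) / scale, (spec.exposure_max - loc) / scale
    exposure = stats.truncnorm.ppf(u[:, 4], a, b, loc=loc, scale=scale)
    exposure = np.clip(exposure, np.finfo(float).tiny, spec.exposure_max)
    return pd.DataFrame(
        {
            "los_days": los,
            "acute_admission": acute,
            "charlson_index": charlson,
            "er_visits_6m": er,
            "exposure_days": exposure,
        }
    )


# ---------------------------------------------------------------------------
# Outcome generation
# ---------------------------------------------------------------------------
#
# The mixture's two temporal parameters describe, for every window length h,
# the count distribution ZIP(p(h), lambda(h)).  Because p itself moves with
# h, no single counting process has that marginal at *every* horizon, so the
# generator enforces exactness where the model is used:
#
# * the full-window count Y_i ~ ZIP(p_i(t_i), lambda_i(t_i)) — a latent
#   Z_i ~ Bernoulli(p_i(t_i)) and, for at-risk episodes with an event, a
#   zero-truncated Poisson total;
# * the first-event time T1 is drawn from the model's own zero-probability
#   curve q_i(h) = p_i(h) + (1-p_i(h)) e^{-lambda_i(h)} (conditional on
#   Z_i = 0), so P(any event by h) equals the joint estimator JE_i(h)
#   exactly, at every horizon;
# * the remaining events fall by inverse transform on the normalised
#   cumulative mean function lambda_i(.) restricted to (T1, t_i].


def _bisect_time(q_of_h, targets: np.ndarray, upper: np.ndarray, iters: int = 60) -> np.ndarray:
    """Vectorised bisection: smallest h in (0, upper] with q(h) <= target
    for a decreasing q; converges to 0 when q starts below the target."""
    lo = np.zeros_like(upper)
    hi = upper.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        too_high = q_of_h(mid) > targets
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    return hi


def _draw_outcomes(
    params: TZIPParams,
    p_end: np.ndarray,
    lam_end: np.ndarray,
    eta_p: np.ndarray | None,
    eta_lam: np.ndarray,
    t: np.ndarray,
    rng: np.random.Generator,
):
    """(structural flags, counts, event-time lists) for all episodes."""
    fam = params.family
    n = t.size
    t_std = standardise_time(t, params.t_scale)

    z = rng.uniform(size=n) < p_end
    v = rng.uniform(size=n)
    surv_end = np.exp(-lam_end)  # P(no event | at risk) over the full window
    has_event = (~z) & (v > surv_end)

    counts = np.zeros(n, dtype=int)
    events: list[np.ndarray] = [np.empty(0)] * n
    idx = np.flatnonzero(has_event)
    if idx.size == 0:
        return z, counts, events

    # first-event time: solve q(h) = p_end + (1 - p_end) * v on (0, t_i]
    target = p_end[idx] + (1.0 - p_end[idx]) * v[idx]

    def q_of(h):
        h_std = np.clip(h / params.t_scale, 1e-12, 1.0)
        lam_h = np.exp(eta_lam[idx]) * fam.f_lam(h_std)
        if eta_p is None:
            return np.exp(-lam_h)
        p_h = special.expit(eta_p[idx] + fam.f_p(h_std))
        return p_h + (1.0 - p_h) * np.exp(-lam_h)

    t1 = _bisect_time(q_of, target, t[idx].astype(float))
    t1 = np.clip(t1, np.finfo(float).tiny, t[idx])

    # total count: zero-truncated Poisson at the full-window mean
    u = rng.uniform(size=idx.size)
    k = stats.poisson.ppf(
        surv_end[idx] + u * (1.0 - surv_end[idx]), lam_end[idx]
    ).astype(int)
    k = np.maximum(k, 1)
    counts[idx] = k

    # remaining events: iid on (T1, t_i] under the cumulative mean function
    f_end = fam.f_lam(t_std)
    f_t1 = fam.f_lam(np.clip(t1 / params.t_scale, 1e-12, 1.0))
    if fam.f_lam_inv is not None:
        inv = fam.f_lam_inv
    else:
        def inv(vals):
            vals = np.atleast_1d(np.asarray(vals, dtype=float))
            return _bisect_time(
                lambda s: -fam.f_lam(np.clip(s, 1e-12, 1.0)),
                -vals,
                np.ones_like(vals),
            )
    for j, i in enumerate(idx):
        if k[j] == 1:
            events[i] = np.array([t1[j]])
            continue
        uu = rng.uniform(f_t1[j], f_end[i], size=k[j] - 1)
        extra = np.asarray(inv(uu), dtype=float) * params.t_scale
        extra = np.clip(extra, t1[j], t[i])
        events[i] = np.sort(np.concatenate([[t1[j]], extra]))
    return z, counts, events


def generate_cohort(
    n: int,
    params: TZIPParams | None = None,
    spec: CovariateSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate ``n`` synthetic episodes from the tZIP data-generating process.

    Returns one row per index hospitalisation with the LACE covariates,
    exposure, the latent structural-zero indicator, the rehospitalisation
    count and the sorted event times (as a list column).  Two calls with the
    same seed produce identical cohorts.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    params = params if params is not None else reference_params()
    spec = spec if spec is not None else CovariateSpec()
    rng = np.random.default_rng(seed)

    cov = _draw_covariates(n, spec, rng)
    t = cov["exposure_days"].to_numpy()
    p, lam = linear_predictors(params, cov, t)
    if np.any(~np.isfinite(p)) or np.any(~np.isfinite(lam)):
        raise ValueError("non-finite linear predictors from the supplied coefficients")
    X1 = np.column_stack([np.ones(n)] + [cov[c].to_numpy(dtype=float) for c in LACE_COLUMNS])
    eta_p = None if params.beta_p is None else X1 @ params.beta_p
    eta_lam = X1 @ params.beta_lambda
    z, counts, events = _draw_outcomes(params, p, lam, eta_p, eta_lam, t, rng)

    episodes = cov.copy()
    episodes.insert(0, "episode_id", [f"E{seed}-{i:07d}" for i in range(n)])
    episodes.insert(1, "patient_id", [f"P{seed}-{i:07d}" for i in range(n)])
    episodes.insert(2, "discharge_day", rng.integers(0, 365, size=n))
    episodes["rehosp_count"] = counts
    episodes["event_days"] = events
    episodes["structural_zero"] = z
    episodes["residence"] = np.where(
        rng.uniform(size=n) < spec.residential_fraction, "residential_care", "community"
    )
    episodes = attach_clinical_features(episodes, rng)
    if spec.n_service_features > 0:
        episodes = attach_service_features(episodes, spec, rng)
    return episodes


#: chronic-condition and acute-event flags of the emulated clinical profile,
#: with their cohort prevalences.
CLINICAL_FLAGS = {
    "diag_cancer": 0.071,
    "diag_copd": 0.215,
    "diag_stroke": 0.264,
    "diag_diabetes": 0.262,
    "icu_admission": 0.00304,
    "surgical_event": 0.08,
}


def attach_clinical_features(
    episodes: pd.DataFrame, rng: np.random.Generator | int = 0
) -> pd.DataFrame:
    """Append diagnosis/ICU/surgical flags of the clinical profile.

    Flags are weakly tied to the Charlson index (sicker patients carry more
    chronic diagnoses) but have no direct outcome effect beyond that, so in
    the hybrid stage they compete with the risk estimator only through the
    comorbidity channel.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    episodes = episodes.copy()
    charlson = episodes["charlson_index"].to_numpy(dtype=float)
    for name, prevalence in CLINICAL_FLAGS.items():
        eta = special.logit(prevalence) + 0.25 * (charlson - charlson.mean())
        episodes[name] = (rng.uniform(size=len(episodes)) < special.expit(eta)).astype(int)
    return episodes


#: default post-discharge service-utilisation features for the hybrid stage.
#: Each is observed only for eligible episodes; ineligibility is systematic
#: (logically missing), mirroring how service timing/duration fields are
#: coded in real post-acute records.
SERVICE_FEATURES = [
    "svc_post_acute_days",
    "svc_ambulatory_visits",
    "svc_residential_days",
    "svc_rehab_sessions",
    "svc_home_care_hours",
    "svc_day_hospital_visits",
]


def _default_eligibility(name: str, episodes: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    n = len(episodes)
    if name == "svc_residential_days":
        return (episodes["residence"] == "residential_care").to_numpy()
    return rng.uniform(size=n) < 0.7


def attach_service_features(
    episodes: pd.DataFrame,
    spec: CovariateSpec,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Append service-utilisation columns with logically missing values.

    A feature is defined only where its eligibility predicate holds; other
    rows are NaN ("MISSING" in the CSV interchange format).  Values are
    weakly related to comorbidity so they carry some—but little—outcome
    signal of their own.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    episodes = episodes.copy()
    names = SERVICE_FEATURES[: spec.n_service_features]
    extra = max(0, spec.n_service_features - len(SERVICE_FEATURES))
    names = names + [f"svc_extra_{j}" for j in range(extra)]
    rule = spec.missingness_rule or _default_eligibility
    n = len(episodes)
    charlson = episodes["charlson_index"].to_numpy(dtype=float)
    for name in names:
        eligible = np.asarray(rule(name, episodes, rng), dtype=bool)
        base = rng.gamma(shape=2.0, scale=1.0 + 0.2 * charlson, size=n)
        vals = np.where(eligible, np.round(base, 2), np.nan)
        episodes[name] = vals
    return episodes


def label_horizon(episodes: pd.DataFrame, horizon_days: float) -> pd.Series:
    """Binary 28-day-style labels: 1 iff any event occurs by the horizon.

    Episodes whose exposure is shorter than the horizon cannot be labelled
    (their window closed early) and come back as missing (<NA>).
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    exposure = episodes["exposure_days"].to_numpy(dtype=float)
    labels = np.array(
        [
            1 if (len(ev) > 0 and np.min(ev) <= horizon_days) else 0
            for ev in episodes["event_days"]
        ],
        dtype=object,
    )
    out = pd.Series(labels, index=episodes.index, dtype="Int64", name=f"rehosp_{int(horizon_days)}d")
    out[exposure < horizon_days] = pd.NA
    return out
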