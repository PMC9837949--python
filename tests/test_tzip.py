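"""Temporal mixture model: likelihood oracles, fitting, inference tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from tziprisk import CovariateSpec, generate_cohort
from tziprisk.tzip import (
    CONSTANT_FAMILY,
    LACE_COLUMNS,
    OffsetFamily,
    TZIPParams,
    candidate_families,
    coefficient_table,
    fit_tzip,
    fit_tzip_em,
    linear_predictors,
    offset_family,
    shape_audit,
    standardise_time,
    total_loglik,
    zip_logpmf,
)

REFERENCE_MEANS = {"los_days": 6.4, "acute_admission": 0.877, "charlson_index": 1.0, "er_visits_6m": 0.8}


def test_standardise_time():
    assert standardise_time(728.2, 728.2) == pytest.approx(1.0)
    assert standardise_time(364.1, 728.2) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        standardise_time(0.0, 728.2)
    # beyond-scale values clip to 1 (scoring longer-observed episodes)
    assert standardise_time(800.0, 728.2) == pytest.approx(1.0)


def test_offsets_vanish_at_full_exposure(ref_params):
    """With f_p(1) = 0 and f_lam(1) = 1 the intercepts alone set p and lambda."""
    fam = OffsetFamily(
        id="unit",
        f_p=lambda t: np.zeros_like(np.asarray(t, float)),
        f_lam=lambda t: np.ones_like(np.asarray(t, float)),
    )
    params = TZIPParams(
        beta_p=np.array([0.8, 0, 0, 0, 0]),
        beta_lambda=np.array([-0.3, 0, 0, 0, 0]),
        family=fam,
        t_scale=728.2,
    )
    x = {"los_days": 0.0, "acute_admission": 0, "charlson_index": 0, "er_visits_6m": 0}
    p, lam = linear_predictors(params, x, 728.2)
    assert p[0] == pytest.approx(special.expit(0.8))
    assert lam[0] == pytest.approx(math.exp(-0.3))


def test_temporal_monotonicity(ref_params):
    """p falls and lambda rises as post-discharge time accrues."""
    x = REFERENCE_MEANS
    t_grid = np.array([30.0, 90.0, 200.0, 400.0, 728.0])
    ps, lams = zip(*(linear_predictors(ref_params, x, t) for t in t_grid))
    ps = np.array([v[0] for v in ps])
    lams = np.array([v[0] for v in lams])
    assert np.all(np.diff(ps) < 0)
    assert np.all(np.diff(lams) > 0)


def test_linear_predictors_hand_evaluation(ref_params):
    """Both linear predictors agree with an explicit by-hand evaluation."""
    x = REFERENCE_MEANS
    t = 364.1
    t_std = t / ref_params.t_scale
    vec = np.array([1.0, 6.4, 0.877, 1.0, 0.8])
    eta_p = float(vec @ ref_params.beta_p) + ref_params.family.f_p(np.array(t_std))
    eta_l = float(vec @ ref_params.beta_lambda)
    expect_p = 1.0 / (1.0 + math.exp(-eta_p))
    expect_lam = math.exp(eta_l) * float(ref_params.family.f_lam(np.array(t_std)))
    p, lam = linear_predictors(ref_params, x, t)
    assert p[0] == pytest.approx(expect_p, abs=1e-12)
    assert lam[0] == pytest.approx(expect_lam, rel=1e-12)
    with pytest.raises(ValueError):
        linear_predictors(ref_params, {**x, "los_days": float("nan")}, t)


def test_zip_logpmf_closed_forms():
    assert zip_logpmf(0, 0.3, 0.0) == pytest.approx(0.0)
    assert zip_logpmf(2, 0.0, 1.0) == pytest.approx(-1.0 - math.log(2.0))
    # normalisation over the support
    y = np.arange(0, 201)
    total = np.sum(np.exp(zip_logpmf(y, 0.4, 1.6)))
    assert total == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        zip_logpmf(-1, 0.4, 1.6)
    with pytest.raises(ValueError):
        zip_logpmf(1.5, 0.4, 1.6)


def test_loglik_matches_naive_enumeration(ref_params):
    """Total log-likelihood equals a per-record sum of explicitly enumerated
    mixture probabilities on a 20-record instance."""
    eps = generate_cohort(20, ref_params, CovariateSpec(), seed=21)
    naive = 0.0
    for _, row in eps.iterrows():
        p, lam = linear_predictors(ref_params, dict(row[LACE_COLUMNS]), row["exposure_days"])
        p, lam = float(p[0]), float(lam[0])
        y = int(row["rehosp_count"])
        if y == 0:
            prob = p + (1 - p) * math.exp(-lam)
        else:
            prob = (1 - p) * math.exp(-lam) * lam**y / math.factorial(y)
        naive += math.log(prob)
    assert total_loglik(ref_params, eps) == pytest.approx(naive, abs=1e-10)


def test_fit_improves_on_start_and_converges(small_fit, small_cohort, ref_params):
    assert small_fit.converged
    # optimum must beat the generating parameters on this sample
    assert small_fit.loglik >= total_loglik(ref_params, small_cohort) - 1e-6
    # ascent property: optimum beats a zero-slope start configuration
    start = TZIPParams(
        beta_p=np.array([small_fit.params.beta_p[0], 0, 0, 0, 0]),
        beta_lambda=np.array([small_fit.params.beta_lambda[0], 0, 0, 0, 0]),
        family=small_fit.params.family,
        t_scale=small_fit.params.t_scale,
    )
    assert small_fit.loglik >= total_loglik(start, small_cohort)
    assert small_fit.aic == pytest.approx(2 * 10 - 2 * small_fit.loglik)
    assert np.all(small_fit.se_p > 0) and np.all(small_fit.se_lambda > 0)


def test_poisson_reduction_matches_glm(ref_params):
    """With p = 0 the fit agrees with an independent Poisson GLM."""
    import statsmodels.api as sm

    gen = TZIPParams(
        beta_p=None,
        beta_lambda=np.array([0.1, -0.005, -0.2, 0.05, 0.15]),
        family=ref_params.family,
    )
    eps = generate_cohort(5_000, gen, CovariateSpec(), seed=31)
    ours = fit_tzip(eps, families=gen.family, inflate=False)
    X = sm.add_constant(eps[LACE_COLUMNS].to_numpy(float))
    t_std = eps["exposure_days"].to_numpy() / ours.params.t_scale
    offset = np.log(gen.family.f_lam(np.clip(t_std, None, 1.0)))
    ref = sm.GLM(
        eps["rehosp_count"].to_numpy(), X, family=sm.families.Poisson(), offset=offset
    ).fit()
    np.testing.assert_allclose(ours.params.beta_lambda, ref.params, atol=1e-5)
    np.testing.assert_allclose(ours.se_lambda, ref.bse, rtol=1e-3)


def test_constant_offset_reduction_matches_plain_zip(ref_params):
    """With constant offsets the fit matches statsmodels' zero-inflated
    Poisson regression on the same data (an independent implementation)."""
    from statsmodels.discrete.count_model import ZeroInflatedPoisson

    gen = TZIPParams(
        beta_p=np.array([-0.3, 0.0, -0.4, 0.0, -0.4]),
        beta_lambda=np.array([0.3, -0.005, -0.2, 0.05, 0.15]),
        family=CONSTANT_FAMILY,
    )
    eps = generate_cohort(8_000, gen, CovariateSpec(), seed=32)
    ours = fit_tzip(eps, families=CONSTANT_FAMILY)
    X = np.column_stack([np.ones(len(eps)), eps[LACE_COLUMNS].to_numpy(float)])
    ref = ZeroInflatedPoisson(
        eps["rehosp_count"].to_numpy(), X, exog_infl=X, inflation="logit"
    ).fit(disp=0, maxiter=500)
    ref_infl, ref_count = ref.params[:5], ref.params[5:]
    np.testing.assert_allclose(ours.params.beta_p, ref_infl, atol=2e-3)
    np.testing.assert_allclose(ours.params.beta_lambda, ref_count, atol=2e-3)
    assert ours.loglik == pytest.approx(ref.llf, abs=0.01)


def test_em_cross_check_agrees_with_direct_mle(small_cohort, small_fit, ref_params):
    em = fit_tzip_em(small_cohort, family=ref_params.family)
    np.testing.assert_allclose(em.params.beta_p, small_fit.params.beta_p, atol=2e-3)
    np.testing.assert_allclose(em.params.beta_lambda, small_fit.params.beta_lambda, atol=2e-3)
    assert em.loglik == pytest.approx(small_fit.loglik, abs=0.01)


def test_shape_audit_separates_valid_from_invalid_families(ref_params):
    """Linear and sqrt logit-offsets give convex-decreasing p at the
    reference covariates (p starts below 1/2 there); the log shape is
    concave near t = 0 where p ~ 1/2 carries no logistic curvature, and the
    audit must reject it so AUTO never selects a shape-violating family."""
    x_ref = pd.DataFrame([REFERENCE_MEANS])
    for fam in candidate_families():
        params = TZIPParams(
            beta_p=ref_params.beta_p,
            beta_lambda=ref_params.beta_lambda,
            family=fam,
            t_scale=ref_params.t_scale,
        )
        expected = not fam.id.startswith("p:log")
        assert shape_audit(params, x_ref) == expected, fam.id


def test_auto_selection_prefers_generating_family(ref_params):
    """AUTO search recovers the generating nonlinearity on a large cohort
    and records every candidate's log-likelihood."""
    eps = generate_cohort(20_000, ref_params, CovariateSpec(), seed=41)
    fit = fit_tzip(eps, families="auto")
    assert len(fit.selection_trace) == 9
    assert fit.params.family.id == ref_params.family.id
    best = max(fit.selection_trace.values())
    assert fit.loglik == pytest.approx(best)


def test_fit_rejects_degenerate_counts(ref_params):
    eps = generate_cohort(100, ref_params, CovariateSpec(), seed=51)
    eps["rehosp_count"] = 0
    eps["event_days"] = [np.empty(0)] * len(eps)
    with pytest.raises(ValueError, match="distinct count"):
        fit_tzip(eps, families=ref_params.family)


def test_coefficient_table_layout_and_math(small_fit):
    tab = coefficient_table(small_fit)
    assert list(tab["component"].unique()) == ["logistic", "poisson"]
    assert list(tab["term"][:5]) == [
        "Intercept",
        "Length of Stay",
        "Acute Admission",
        "Charlson Comorbidity Index",
        "ER Visits (6 months)",
    ]
    np.testing.assert_allclose(tab["ratio"], np.exp(tab["coefficient"]))
    np.testing.assert_allclose(tab["z"], tab["coefficient"] / tab["se"])
    # z = coefficient / SE at reported precision: -0.467 / 0.018 ~ -25.9
    assert -0.467 / 0.018 == pytest.approx(-25.9, abs=0.1)
    # a null coefficient maps to a unit ratio and p-value 1
    row = tab.iloc[0]
    assert np.exp(0.0) == 1.0
    assert math.exp(0.149) == pytest.approx(1.161, abs=5e-4)
    assert row["p_value"] <= 1.0


def test_offset_family_ids_roundtrip():
    fam = offset_family("log", "linear")
    assert fam.id == "p:log|lam:linear"
    t = np.linspace(0.01, 1, 50)
    assert np.all(np.diff(fam.f_p(t)) < 0)
    assert np.all(np.diff(fam.f_lam(t)) > 0)
    np.testing.assert_allclose(fam.f_lam_inv(fam.f_lam(t)), t, atol=1e-10)
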