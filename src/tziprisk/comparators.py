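"""Comparator models sharing the four LACE predictors.

Two references against which the temporal mixture model is benchmarked:

* the additive LACE point score (the "Linear model"): the canonical
  van Walraven point table mapping length of stay, acuity, Charlson index
  and ER visits onto an integer score 0-19, used directly as a ranking
  score at every horizon;
* a Cox proportional-hazards model on time to first rehospitalisation,
  censored at the end of each episode's observation window, with horizon
  risk ``1 - exp(-H0(h) * exp(x.beta))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .tzip import LACE_COLUMNS

__all__ = ["LACE_POINTS", "lace_score", "CoxFit", "fit_cox", "cox_risk"]

#: canonical LACE point table; overridable by passing a modified copy.
LACE_POINTS = {
    "los_bins": [(1, 0), (2, 1), (3, 2), (4, 3), (7, 4), (14, 5)],  # (upper, pts)
    "los_max_points": 7,
    "acute_points": 3,
    "charlson_cap": 4,  # >= cap -> 5 points
    "charlson_max_points": 5,
    "er_max_points": 4,
}


def _los_points(los: np.ndarray, table: dict) -> np.ndarray:
    pts = np.full(los.shape, table["los_max_points"], dtype=int)
    for upper, p in reversed(table["los_bins"]):
        pts[los < upper] = p
    return pts


def lace_score(x, table: dict = LACE_POINTS) -> pd.DataFrame:
    """Additive LACE score, one row per episode.

    Point mapping: L (<1d:0, 1d:1, 2d:2, 3d:3, 4-6d:4, 7-13d:5, >=14d:7),
    A (acute admission: 3), C (0..3 as-is, >=4: 5), E (min(visits, 4)).
    Returns columns ``points_l/a/c/e`` and ``total`` (0-19).
    """
    if isinstance(x, dict):
        x = pd.DataFrame([x])
    los = x["los_days"].to_numpy(dtype=float)
    acute = x["acute_admission"].to_numpy(dtype=float)
    charlson = x["charlson_index"].to_numpy(dtype=float)
    er = x["er_visits_6m"].to_numpy(dtype=float)
    for name, arr in (("los_days", los), ("charlson_index", charlson), ("er_visits_6m", er)):
        if np.any(arr < 0):
            raise ValueError(f"negative {name}")
    pts_l = _los_points(los, table)
    pts_a = np.where(acute > 0, table["acute_points"], 0)
    pts_c = np.where(
        charlson >= table["charlson_cap"],
        table["charlson_max_points"],
        charlson.astype(int),
    )
    pts_e = np.minimum(er.astype(int), table["er_max_points"])
    out = pd.DataFrame(
        {
            "points_l": pts_l,
            "points_a": pts_a,
            "points_c": pts_c,
            "points_e": pts_e,
        },
        index=x.index if hasattr(x, "index") else None,
    )
    out["total"] = out.sum(axis=1)
    return out


@dataclass
class CoxFit:
    """Cox proportional-hazards fit on time to first rehospitalisation."""

    coefficients: pd.Series
    baseline_cumhaz: pd.DataFrame  # step function: index = time, one column
    loglik: float
    model: CoxPHFitter

    def cumhaz_at(self, horizon: float) -> float:
        """Breslow baseline cumulative hazard evaluated at a horizon."""
        ch = self.baseline_cumhaz
        idx = ch.index.to_numpy(dtype=float)
        vals = ch.iloc[:, 0].to_numpy(dtype=float)
        pos = np.searchsorted(idx, horizon, side="right") - 1
        return 0.0 if pos < 0 else float(vals[pos])


def first_event_table(episodes: pd.DataFrame) -> pd.DataFrame:
    """Time-to-first-event view: duration = first event time, else censored
    at the end of exposure."""
    durations = []
    observed = []
    for ev, exp_t in zip(episodes["event_days"], episodes["exposure_days"]):
        if len(ev) > 0:
            durations.append(float(np.min(ev)))
            observed.append(1)
        else:
            durations.append(float(exp_t))
            observed.append(0)
    tab = episodes[LACE_COLUMNS].copy()
    tab["duration"] = durations
    tab["observed"] = observed
    return tab


def fit_cox(episodes: pd.DataFrame) -> CoxFit:
    """Fit the Cox model (Efron tie handling, Breslow baseline hazard).

    Zero-variance covariates are excluded from estimation (their
    coefficient is reported as 0): the partial likelihood carries no
    information about them.
    """
    tab = first_event_table(episodes)
    if tab["observed"].sum() == 0:
        raise ValueError("cannot fit a Cox model: no rehospitalisation events")
    keep = [c for c in LACE_COLUMNS if tab[c].nunique() > 1]
    cph = CoxPHFitter()
    cph.fit(tab[keep + ["duration", "observed"]], duration_col="duration", event_col="observed")
    coefs = pd.Series(0.0, index=LACE_COLUMNS)
    coefs[keep] = cph.params_
    return CoxFit(
        coefficients=coefs,
        baseline_cumhaz=cph.baseline_cumulative_hazard_.copy(),
        loglik=float(cph.log_likelihood_),
        model=cph,
    )


def cox_risk(fit: CoxFit, x, horizon: float) -> np.ndarray:
    """Predicted probability of rehospitalisation by ``horizon``:
    ``1 - exp(-H0(h) * exp(x.beta))``; monotone in the linear predictor.

    Evaluated through the fitted model so the Breslow baseline hazard and
    the linear predictor use a consistent covariate centering.
    """
    if isinstance(x, dict):
        x = pd.DataFrame([x])
    ch = fit.model.predict_cumulative_hazard(x[LACE_COLUMNS], times=[horizon])
    return -np.expm1(-ch.iloc[0].to_numpy(dtype=float))
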