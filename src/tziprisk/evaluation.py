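"""Discrimination metrics, observed survival, and the validation harnesses.

The retrospective harness mirrors a monthly-subset external validation: the
model is trained on one year's cohort, and an out-of-sample year is divided
into 12 subsets by month of admission; each subset is scored with the three
competing scores (JE, Cox horizon risk, LACE total) and discrimination is
summarised per model x horizon x month as ROC-AUC and PR-AUC.

The prospective harness emulates a monthly deployment: each monthly cohort
is scored at discharge *before* its outcomes are revealed; the predictions
are then verified against the accrued 28-day outcomes, one month at a time,
with an audit log recording that scoring preceded every reveal.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import label_horizon
from .comparators import cox_risk, fit_cox, lace_score
from .risk import joint_estimator
from .tzip import TZIPFit, fit_tzip, linear_predictors

__all__ = [
    "roc_auc",
    "pr_auc",
    "kaplan_meier",
    "score_models",
    "retrospective_harness",
    "prospective_harness",
]

logger = logging.getLogger("tziprisk")

DEFAULT_HORIZONS = [28, 60, 90, 120, 150, 180, 210, 240, 270, 300, 330, 365]


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d and aligned")
    if np.any(~np.isfinite(scores)):
        raise ValueError("non-finite scores")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """ROC area = Mann-Whitney concordance with ties counted half."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("ROC-AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))

def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve.

    Descending-score sweep with equal scores grouped; no linear
    interpolation between operating points (the step-curve/average-precision
    convention, conservative for imbalanced outcomes).
    """
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("PR-AUC undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def kaplan_meier(times, events, horizons: Sequence[float]) -> np.ndarray:
    """Product-limit survival estimates evaluated at the horizons."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    h = np.asarray(horizons, dtype=float)
    return km.survival_function_at_times(h).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Scoring the three competing models
# ---------------------------------------------------------------------------

def score_models(
    tzip_fit: TZIPFit,
    cox_fit,
    episodes: pd.DataFrame,
    horizon: float,
) -> pd.DataFrame:
    """Per-episode risk scores of the three models at one horizon.

    JE uses both mixture components at the horizon; the Cox score is the
    predicted risk by the horizon; the Linear model is the additive LACE
    total (horizon-invariant by construction).
    """
    p, lam = linear_predictors(tzip_fit.params, episodes, float(horizon))
    return pd.DataFrame(
        {
            "JE": joint_estimator(p, lam),
            "Cox": cox_risk(cox_fit, episodes, float(horizon)),
            "Linear": lace_score(episodes)["total"].to_numpy(dtype=float),
        },
        index=episodes.index,
    )


def _month_of(episodes: pd.DataFrame) -> pd.Series:
    return (episodes["discharge_day"] // 30).clip(upper=11).astype(int) + 1


def _evaluate_subset(scores: pd.DataFrame, labels: np.ndarray, horizon, month) -> list[dict]:
    rows = []
    for model in scores.columns:
        rows.append(
            {
                "cohort_month": month,
                "horizon_days": horizon,
                "model": model,
                "auc": roc_auc(scores[model].to_numpy(), labels),
                "auprc": pr_auc(scores[model].to_numpy(), labels),
                "n": int(labels.size),
                "positives": int(labels.sum()),
            }
        )
    return rows


def retrospective_harness(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    families="auto",
) -> pd.DataFrame:
    """Train tZIP and Cox on ``train``; evaluate JE/Cox/Linear per month.

    The validation cohort is split into 12 monthly subsets by admission
    month.  A month is skipped (with a warning) at a horizon where fewer
    than two outcome classes are labellable.  Returns a tidy report with
    one row per model x horizon x month.
    """
    tzip_fit = fit_tzip(train, families=families)
    cox = fit_cox(train)
    months = _month_of(validation)
    rows: list[dict] = []
    for h in horizons:
        labels_all = label_horizon(validation, float(h))
        for month in range(1, 13):
            in_month = (months == month).to_numpy()
            lab = labels_all[in_month]
            usable = lab.notna().to_numpy()
            if usable.sum() == 0 or lab.dropna().nunique() < 2:
                logger.warning(
                    "month %d at horizon %s skipped: fewer than two outcome classes",
                    month, h,
                )
                continue
            subset = validation.loc[in_month].loc[usable]
            scores = score_models(tzip_fit, cox, subset, h)
            rows.extend(
                _evaluate_subset(scores, lab.dropna().to_numpy(dtype=float), h, month)
            )
    return pd.DataFrame(rows)


def prospective_harness(
    fit: TZIPFit,
    monthly_cohorts: Sequence[pd.DataFrame],
    horizon: float = 28.0,
):
    """Score each monthly cohort, then reveal outcomes and verify.

    Outcomes are withheld at scoring time: JE is computed from covariates
    and the horizon only, and the label columns are only touched afterwards.
    Returns ``(report, audit_log)``; the audit log records a ``scored``
    entry before the ``revealed`` entry for every month.  Months with a
    degenerate outcome (a single class) yield an explicit skip record
    rather than being dropped silently.
    """
    rows: list[dict] = []
    audit: list[dict] = []
    for month, cohort in enumerate(monthly_cohorts, start=1):
        p, lam = linear_predictors(fit.params, cohort, float(horizon))
        je = joint_estimator(p, lam)
        audit.append({"month": month, "action": "scored", "n": len(cohort)})
        labels = label_horizon(cohort, float(horizon))
        audit.append({"month": month, "action": "revealed", "n": len(cohort)})
        usable = labels.notna().to_numpy()
        lab = labels.dropna().to_numpy(dtype=float)
        row = {
            "cohort_month": month,
            "horizon_days": horizon,
            "model": "JE",
            "n": int(usable.sum()),
            "positives": int(lab.sum()) if lab.size else 0,
        }
        if lab.size == 0 or lab.min() == lab.max():
            row.update({"auc": np.nan, "auprc": np.nan, "skipped": True})
            logger.warning("prospective month %d skipped: single outcome class", month)
        else:
            row.update(
                {
                    "auc": roc_auc(je[usable], lab),
                    "auprc": pr_auc(je[usable], lab),
                    "skipped": False,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows), audit
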