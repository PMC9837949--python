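"""Joint risk estimator JE(t), risk/survival curves and zero decomposition.

The joint estimator is the mixture probability of at least one
rehospitalisation by a horizon ``t``:

    JE(t) = (1 - p(t)) * (1 - exp(-lambda(t)))

i.e. the patient must be at risk (not a structural zero) *and* the Poisson
component must produce at least one event within the window.  JE is both a
visualisable risk trajectory (28 to 365 days) and the scalar ranking score
used in the discrimination analyses.  Its complement ``S(t) = 1 - JE(t)`` is
the model's survival (not-yet-rehospitalised) curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tzip import TZIPFit, linear_predictors

__all__ = [
    "RiskCurve",
    "joint_estimator",
    "risk_curve",
    "survival_curve",
    "decompose_zeros",
]

logger = logging.getLogger("tziprisk")


@dataclass
class RiskCurve:
    """JE(t) and S(t) = 1 - JE(t) over a set of horizons."""

    horizons: np.ndarray
    je: np.ndarray
    survival: np.ndarray
    scope: str  # "individual" or "cohort-mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"horizon_days": self.horizons, "je": self.je, "survival": self.survival}
        )


def joint_estimator(p, lam):
    """Probability of >= 1 rehospitalisation by the horizon under the mixture."""
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p must lie in [0, 1]")
    if np.any((lam < 0) | ~np.isfinite(lam)):
        raise ValueError("lambda must be nonnegative and finite")
    je = (1.0 - p) * (-np.expm1(-lam))
    return je if je.shape else float(je)


def _check_horizons(horizons) -> np.ndarray:
    h = np.asarray(horizons, dtype=float)
    if h.ndim != 1 or h.size == 0:
        raise ValueError("horizons must be a non-empty 1-d sequence")
    if np.any(h <= 0):
        raise ValueError("horizons must be positive")
    if np.any(np.diff(h) <= 0):
        raise ValueError("horizons must be strictly increasing")
    return h


def _je_matrix(fit: TZIPFit, x, horizons: np.ndarray) -> np.ndarray:
    """(n_rows, n_horizons) matrix of JE values."""
    cols = []
    for h in horizons:
        p, lam = linear_predictors(fit.params, x, h)
        cols.append(joint_estimator(p, lam))
    return np.column_stack(cols)


def risk_curve(fit: TZIPFit, x, horizons: Sequence[float]) -> RiskCurve:
    """JE trajectory for a single patient's LACE covariates.

    Monotone nondecreasing in the horizon by construction for any admissible
    offset family; a violation indicates an invalid family and is a hard
    error, not a warning.
    """
    h = _check_horizons(horizons)
    je = _je_matrix(fit, x, h)
    if je.shape[0] != 1:
        raise ValueError("risk_curve expects a single patient; see survival_curve")
    je = je[0]
    if np.any(np.diff(je) < -1e-12):
        raise RuntimeError(
            "JE decreased with horizon: offset family violates the shape constraints"
        )
    return RiskCurve(horizons=h, je=je, survival=1.0 - je, scope="individual")


def survival_curve(fit: TZIPFit, episodes: pd.DataFrame, horizons: Sequence[float]) -> RiskCurve:
    """Cohort-mean survival curve: S(t) = 1 - mean_i JE_i(t)."""
    if len(episodes) == 0:
        raise ValueError("empty cohort")
    h = _check_horizons(horizons)
    je = _je_matrix(fit, episodes, h).mean(axis=0)
    if np.any(np.diff(je) < -1e-12):
        raise RuntimeError(
            "cohort JE decreased with horizon: offset family violates the shape constraints"
        )
    return RiskCurve(horizons=h, je=je, survival=1.0 - je, scope="cohort-mean")


def decompose_zeros(fit: TZIPFit, episodes: pd.DataFrame):
    """Split the observed zero counts into structural versus at-risk zeros.

    For each zero-count episode the posterior probability that the zero is
    structural, at that episode's own exposure, is

        P(Z = 1 | Y = 0) = p / (p + (1 - p) e^{-lambda}).

    Returns ``(share_active, share_structural, posteriors)`` where the
    shares are cohort averages over zero-count records (summing to 1) and
    ``posteriors`` is a Series of structural-zero posteriors indexed by the
    zero-count rows.
    """
    zeros = episodes[episodes["rehosp_count"] == 0]
    if len(zeros) == 0:
        logger.warning("no zero-count records: zero decomposition is empty")
        return float("nan"), float("nan"), pd.Series(dtype=float)
    p, lam = linear_predictors(
        fit.params, zeros, zeros["exposure_days"].to_numpy(dtype=float)
    )
    post = p / (p + (1.0 - p) * np.exp(-lam))
    share_structural = float(np.mean(post))
    return 1.0 - share_structural, share_structural, pd.Series(post, index=zeros.index)
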