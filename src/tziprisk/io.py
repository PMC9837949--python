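"""CSV/JSON interchange for episode tables, fits and trees.

Episode tables travel as CSV with a documented header (one row per index
hospitalisation), a leading schema comment line, event times as a
semicolon-delimited sub-field, and an explicit ``MISSING`` token for
logically missing service features.  Fitted models and trees serialise to
JSON with a schema-version field; serialisation is deterministic (sorted
keys), so identical fits produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tzip import (
    CONSTANT_FAMILY,
    OffsetFamily,
    TZIPFit,
    TZIPParams,
    offset_family,
)

__all__ = [
    "write_episodes",
    "read_episodes",
    "fit_to_json",
    "fit_from_json",
    "write_fit",
    "read_fit",
    "write_tree",
]

EPISODE_SCHEMA = "tziprisk-episodes-v1"
FIT_SCHEMA = "tziprisk-fit-v1"
TREE_SCHEMA = "tziprisk-tree-v1"
MISSING_TOKEN = "MISSING"

REQUIRED_EPISODE_COLUMNS = [
    "episode_id",
    "patient_id",
    "discharge_day",
    "los_days",
    "acute_admission",
    "charlson_index",
    "er_visits_6m",
    "exposure_days",
    "rehosp_count",
    "event_days",
    "residence",
]


def write_episodes(episodes: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write an episode table as CSV under the documented schema."""
    df = episodes.copy()
    df["event_days"] = [
        ";".join(f"{t:.6f}" for t in ev) for ev in df["event_days"]
    ]
    if "structural_zero" in df.columns:
        df["structural_zero"] = df["structural_zero"].astype(int)
    svc = [c for c in df.columns if c.startswith("svc_")]
    for c in svc:
        df[c] = df[c].map(lambda v: MISSING_TOKEN if pd.isna(v) else f"{v}")
    path = Path(path)
    with path.open("w") as fh:
        header = f"# schema={EPISODE_SCHEMA}"
        if seed is not None:
            header += f" seed={seed}"
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_episodes(path) -> pd.DataFrame:
    """Read an episode CSV back, reconstructing event-time lists and NaNs.

    Refuses files with a different schema version and names any missing
    required columns in the error.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# schema="):
            raise ValueError(f"{path}: missing schema header line")
        schema = first.split("schema=", 1)[1].split()[0].strip()
        if schema != EPISODE_SCHEMA:
            raise ValueError(
                f"{path}: schema version mismatch: found {schema!r}, expected {EPISODE_SCHEMA!r}"
            )
        df = pd.read_csv(fh, dtype={"event_days": str}, keep_default_na=True)
    missing = [c for c in REQUIRED_EPISODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed episode CSV, missing column(s): {missing}")
    df["event_days"] = [
        np.array([float(v) for v in s.split(";")]) if isinstance(s, str) and s else np.empty(0)
        for s in df["event_days"].fillna("")
    ]
    if "structural_zero" in df.columns:
        df["structural_zero"] = df["structural_zero"].astype(bool)
    for c in [c for c in df.columns if c.startswith("svc_")]:
        df[c] = pd.to_numeric(df[c].mask(df[c].astype(str) == MISSING_TOKEN), errors="coerce")
    return df


# ---------------------------------------------------------------------------
# Fit serialisation
# ---------------------------------------------------------------------------

def _family_from_id(fam_id: str) -> OffsetFamily:
    if fam_id == "constant":
        return CONSTANT_FAMILY
    try:
        p_part, lam_part = fam_id.split("|")
        return offset_family(p_part.removeprefix("p:"), lam_part.removeprefix("lam:"))
    except Exception:
        raise ValueError(f"cannot reconstruct offset family from id {fam_id!r}") from None


def fit_to_json(fit: TZIPFit, seed: int | None = None) -> str:
    """Deterministic JSON text for a fit (sorted keys, fixed float repr)."""
    payload = {
        "schema": FIT_SCHEMA,
        "seed": seed,
        "family": fit.params.family.id,
        "t_scale": fit.params.t_scale,
        "beta_p": None if fit.params.beta_p is None else fit.params.beta_p.tolist(),
        "beta_lambda": fit.params.beta_lambda.tolist(),
        "se_p": None if fit.se_p is None else fit.se_p.tolist(),
        "se_lambda": None if fit.se_lambda is None else fit.se_lambda.tolist(),
        "vcov": None if fit.vcov is None else fit.vcov.tolist(),
        "loglik": fit.loglik,
        "aic": fit.aic,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "grad_norm": fit.grad_norm,
        "selection_trace": fit.selection_trace,
    }
    return json.dumps(payload, sort_keys=True, indent=2)


def fit_from_json(text: str) -> TZIPFit:
    d = json.loads(text)
    if d.get("schema") != FIT_SCHEMA:
        raise ValueError(
            f"fit schema mismatch: found {d.get('schema')!r}, expected {FIT_SCHEMA!r}"
        )
    params = TZIPParams(
        beta_p=None if d["beta_p"] is None else np.array(d["beta_p"]),
        beta_lambda=np.array(d["beta_lambda"]),
        family=_family_from_id(d["family"]),
        t_scale=d["t_scale"],
    )
    return TZIPFit(
        params=params,
        loglik=d["loglik"],
        aic=d["aic"],
        se_p=None if d["se_p"] is None else np.array(d["se_p"]),
        se_lambda=None if d["se_lambda"] is None else np.array(d["se_lambda"]),
        vcov=None if d["vcov"] is None else np.array(d["vcov"]),
        converged=d["converged"],
        n_obs=d["n_obs"],
        grad_norm=d["grad_norm"],
        selection_trace=d["selection_trace"],
    )


def write_fit(fit: TZIPFit, path, seed: int | None = None) -> None:
    Path(path).write_text(fit_to_json(fit, seed=seed) + "\n")


def read_fit(path) -> TZIPFit:
    return fit_from_json(Path(path).read_text())


def write_tree(tree, path, seed: int | None = None) -> None:
    payload = {"schema": TREE_SCHEMA, "seed": seed, **tree.to_dict()}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
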