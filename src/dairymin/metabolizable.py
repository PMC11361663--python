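"""Metabolizable coefficient (MC) of dietary P and Ca.

The MC is the fraction of the ingested mineral available to meet net
requirements once fecal and urinary losses of dietary origin are
discounted::

    MC = (intake - fecal - urinary + endogenous) / intake

where the endogenous term is the animal's own (maintenance) fecal + urinary
loss estimated from the excretion meta-regression. With urinary excretion
at zero, MC coincides with the classical true absorption coefficient; the
name changes because urine is included here.

Two conventions for the endogenous term are exposed:

* ``mode="intercept"`` (default): endogenous = beta1 * BW^0.75 -- the
  regression intercept scaled to the animal, i.e. the maintenance
  definition of the factorial system;
* ``mode="curve"``: the full exponential curve evaluated at the record's
  scaled intake.

Per-observation MCs outside [0, 1] are flagged but retained; the overall
mean is the intercept of a weighted random-study-intercept model after
studentized-residual screening, so it is study-adjusted rather than a raw
arithmetic mean.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import _engine
from .balance_data import metabolic_weight, validate_dataset
from .meta_regression import NLMMFit, predict_excretion

logger = logging.getLogger(__name__)

#: Diet covariates screened for effects on MC.
DIET_COVARIATES = ("forage", "cp", "ee", "ndf", "starch")


@dataclasses.dataclass
class MCResult:
    mineral: str
    overall_mean: float
    se: float
    n_used: int
    n_studies: int
    removed_ids: list
    covariate_pvalues: dict


def compute_mc(records: pd.DataFrame, endogenous_fit: NLMMFit,
               mode: str = "intercept") -> pd.DataFrame:
    """Per-observation metabolizable coefficients.

    Records missing any of intake, fecal, urinary or bw are skipped with a
    log entry. Returns a frame with ``mc``, ``endogenous_used`` (g/d), an
    ``out_of_range`` flag for MC outside [0, 1], and the diet covariates
    carried through for screening.
    """
    records = validate_dataset(records)
    if mode not in ("intercept", "curve"):
        raise ValueError(f"unknown endogenous mode {mode!r}")
    complete = records[["intake", "fecal", "urinary", "bw"]].notna().all(axis=1)
    n_skipped = int((~complete).sum())
    if n_skipped:
        logger.info("compute_mc: skipped %d of %d records with missing "
                    "intake/fecal/urinary/bw", n_skipped, len(records))
    kept = records.loc[complete]
    mbw = metabolic_weight(kept["bw"].to_numpy(float))
    if mode == "intercept":
        endogenous = endogenous_fit.beta1 * mbw
    else:
        intake_mbw = kept["intake"].to_numpy(float) / mbw
        endogenous = predict_excretion(endogenous_fit, intake_mbw) * mbw
    intake = kept["intake"].to_numpy(float)
    mc = (intake - kept["fecal"].to_numpy(float)
          - kept["urinary"].to_numpy(float) + endogenous) / intake
    out = pd.DataFrame({
        "record_id": kept["record_id"].to_numpy(),
        "study_id": kept["study_id"].to_numpy(),
        "mc": mc,
        "endogenous_used": endogenous,
        "out_of_range": (mc < 0) | (mc > 1),
    })
    for cov in DIET_COVARIATES:
        out[cov] = kept[cov].to_numpy(float)
    out.attrs["n_skipped"] = n_skipped
    return out


def mc_from_flows(intake, fecal, urinary, endogenous):
    """Scalar/vector MC from explicit mass flows (g/d)."""
    intake = np.asarray(intake, float)
    if np.any(intake <= 0):
        raise ValueError("intake must be > 0")
    out = (intake - np.asarray(fecal, float) - np.asarray(urinary, float)
           + np.asarray(endogenous, float)) / intake
    return float(out) if out.ndim == 0 else out


def _merge_weights(mc_obs: pd.DataFrame, weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(mc_obs))
    if isinstance(weights, pd.DataFrame):
        merged = mc_obs[["record_id"]].merge(
            weights[["record_id", "weight"]], on="record_id", how="left")
        w = merged["weight"].to_numpy(float)
    else:
        w = np.asarray(weights, float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive for every MC observation")
    return w


def screen_diet_covariates(mc_obs: pd.DataFrame, covariate: str,
                           weights=None) -> float:
    """Wald p-value for a diet covariate's slope on MC.

    Bivariable weighted linear mixed model ``mc ~ covariate`` with a random
    study intercept, on the records with the covariate reported. Returns
    NaN when the covariate is constant (undefined slope).
    """
    if covariate not in DIET_COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}; "
                         f"expected one of {DIET_COVARIATES}")
    w_all = _merge_weights(mc_obs, weights)
    ok = mc_obs[covariate].notna().to_numpy()
    sub = mc_obs.loc[ok]
    if sub["study_id"].nunique() < 3:
        raise ValueError("need >= 3 studies with the covariate reported")
    x = sub[covariate].to_numpy(float)
    if np.ptp(x) == 0:
        return float("nan")
    y = sub["mc"].to_numpy(float)
    w = w_all[ok]
    xc = x - x.mean()  # center for a stable intercept

    def mean_fn(theta):
        return theta[0] + theta[1] * xc

    slope0, icpt0 = np.polyfit(xc, y, 1)
    fit = _engine.fit_random_intercept(
        mean_fn, [np.array([icpt0, slope0])], y, w, sub["study_id"].to_numpy(),
        df=max(sub["study_id"].nunique() - 2, 1))
    return float(fit.p_theta[1])


def overall_mc(mc_obs: pd.DataFrame, weights=None, mineral: str = "P",
               threshold: float = 2.0, max_iter: int = 10,
               covariate_pvalues=None) -> MCResult:
    """Study-adjusted overall MC with its standard error.

    Intercept-only weighted mixed model with a random study effect;
    observations with \\|studentized residual\\| > ``threshold`` are removed
    iteratively before the final estimate, mirroring the screening used for
    the excretion curve.
    """
    if mc_obs["study_id"].nunique() < 2:
        raise ValueError("overall MC needs >= 2 studies (SE undefined)")
    w = _merge_weights(mc_obs, weights)
    current = mc_obs.reset_index(drop=True)
    removed: list = []
    n_total = len(current)

    def fit_const(sub, w_sub):
        y = sub["mc"].to_numpy(float)

        def mean_fn(theta):
            return np.full(y.size, theta[0])

        return _engine.fit_random_intercept(
            mean_fn, [np.array([float(np.mean(y))])], y, w_sub,
            sub["study_id"].to_numpy())

    fit = fit_const(current, w)
    for _ in range(max_iter):
        y = current["mc"].to_numpy(float)
        resid = y - fit.theta[0]
        codes, n_groups = _engine.group_codes(current["study_id"].to_numpy())
        d = fit.var_resid / w
        u_hat = _engine.blup_intercepts(resid, d, codes, n_groups, fit.var_study)
        sd = _engine.conditional_residual_sd(d, codes, n_groups, fit.var_study)
        stud = (resid - u_hat[codes]) / sd
        bad = np.abs(stud) > threshold
        if not bad.any():
            break
        removed.extend(current.loc[bad, "record_id"].tolist())
        if len(removed) > 0.5 * n_total:
            raise RuntimeError("MC screening would remove > 50% of records")
        current = current.loc[~bad].reset_index(drop=True)
        w = w[~bad]
        fit = fit_const(current, w)

    return MCResult(
        mineral=mineral,
        overall_mean=float(fit.theta[0]),
        se=float(fit.se_theta[0]),
        n_used=len(current),
        n_studies=int(current["study_id"].nunique()),
        removed_ids=removed,
        covariate_pvalues=dict(covariate_pvalues or {}),
    )


def screen_all_covariates(mc_obs: pd.DataFrame, weights=None,
                          min_studies: int = 3) -> dict:
    """p-values for every screenable diet covariate (NaN when constant,
    omitted when too few studies report it)."""
    pvals = {}
    for cov in DIET_COVARIATES:
        sub_studies = mc_obs.loc[mc_obs[cov].notna(), "study_id"].nunique()
        if sub_studies < min_studies:
            logger.info("skipping covariate %s: only %d studies report it",
                        cov, sub_studies)
            continue
        pvals[cov] = screen_diet_covariates(mc_obs, cov, weights)
    return pvals
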