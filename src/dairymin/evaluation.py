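"""Model evaluation: study-grouped cross-validation and concordance metrics.

Predictive adequacy of the excretion curves is judged externally: studies
(balance trials) are dealt into k folds, the model -- including its
outlier-screening loop -- is refitted on k-1 folds, and population-level
predictions are made for the held-out studies, so a record is never
predicted by a model that saw its own trial.

Observed-vs-predicted agreement is summarized with Lin's concordance
statistics (r for precision, C_b for accuracy, CCC = r * C_b) and the root
mean square prediction error as % of the observed mean, plus mean/linear
bias t-tests from the regression of observed on predicted values. Breed
differences in milk mineral concentration are compared through
non-overlapping 95% confidence intervals.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .meta_regression import predict_excretion, remove_outliers_and_refit, FitError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EvaluationMetrics:
    r: float              # Pearson correlation (precision)
    cb: float             # bias correction factor (accuracy), in (0, 1]
    ccc: float            # Lin's concordance correlation = r * cb
    rmspe_pct: float      # RMSPE as % of the observed mean
    intercept_bias_p: float
    slope_bias_p: float
    n: int
    mean_bias: float = np.nan        # mean(pred) - mean(obs)
    msep_decomposition: tuple = ()   # (mean bias^2, slope bias, random) -> MSEP


def assign_folds_by_study(obs: pd.DataFrame, k: int = 5, seed: int = 0) -> dict:
    """Deal studies into k folds: seeded shuffle then round-robin.

    Every study lands in exactly one fold (1..k); fold sizes in studies
    differ by at most 1. Deterministic given the seed.
    """
    studies = sorted(obs["study_id"].unique())
    if len(studies) < k:
        raise ValueError(f"{len(studies)} studies cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(len(studies))
    return {studies[idx]: (pos % k) + 1 for pos, idx in enumerate(order)}


def cross_validate(obs: pd.DataFrame, k: int = 5, seed: int = 0,
                   threshold: float = 2.0, max_iter: int = 10,
                   folds: dict | None = None) -> pd.DataFrame:
    """Held-out (observed, predicted) pairs from study-grouped k-fold CV.

    Each training split runs the full outlier-screened fit; held-out
    records are predicted at the population level (random study effect
    zero) and are never screened themselves. A training split that fails
    to converge drops its fold with a warning. A precomputed study->fold
    mapping can be passed as ``folds`` (labels 1..k).
    """
    if folds is None:
        folds = assign_folds_by_study(obs, k=k, seed=seed)
    fold_of = obs["study_id"].map(folds)
    frames = []
    for fold in range(1, k + 1):
        test = obs.loc[fold_of == fold]
        train = obs.loc[fold_of != fold]
        try:
            fit = remove_outliers_and_refit(train, threshold=threshold,
                                            max_iter=max_iter)
        except (FitError, ValueError) as exc:
            logger.warning("fold %d training fit failed (%s); fold skipped",
                           fold, exc)
            continue
        frames.append(pd.DataFrame({
            "record_id": test["record_id"].to_numpy(),
            "study_id": test["study_id"].to_numpy(),
            "fold": fold,
            "observed": test["excretion_mbw"].to_numpy(float),
            "predicted": predict_excretion(
                fit, test["intake_mbw"].to_numpy(float)),
        }))
    if not frames:
        raise FitError("every cross-validation fold failed to fit")
    return pd.concat(frames, ignore_index=True)


def obs_vs_pred_metrics(pairs) -> EvaluationMetrics:
    """Concordance and error metrics for observed/predicted pairs.

    Accepts a DataFrame with ``observed``/``predicted`` columns or a pair
    of arrays. Moments are population (n-denominator) as in Lin's CCC:
    u = (mean_p - mean_o)/sqrt(sd_o * sd_p), v = sd_p/sd_o,
    C_b = 2 / (v + 1/v + u^2), CCC = r * C_b. Bias p-values come from the
    regression of observed on predicted (intercept = 0 and slope = 1
    t-tests).
    """
    if isinstance(pairs, pd.DataFrame):
        obs = pairs["observed"].to_numpy(float)
        pred = pairs["predicted"].to_numpy(float)
    else:
        obs, pred = (np.asarray(v, float) for v in pairs)
    if obs.size != pred.size or obs.size < 3:
        raise ValueError("need >= 3 observed/predicted pairs")
    sd_o = float(np.std(obs))
    sd_p = float(np.std(pred))
    if sd_o == 0 or sd_p == 0:
        raise ValueError("zero variance in observed or predicted values")

    r = float(np.corrcoef(obs, pred)[0, 1])
    u = (float(np.mean(pred)) - float(np.mean(obs))) / np.sqrt(sd_o * sd_p)
    v = sd_p / sd_o
    cb = 2.0 / (v + 1.0 / v + u * u)
    ccc = r * cb
    msep = float(np.mean((obs - pred) ** 2))
    rmspe_pct = 100.0 * np.sqrt(msep) / float(np.mean(obs))

    # MSEP decomposition: mean bias^2 + slope bias + random component
    mean_bias_sq = (float(np.mean(obs)) - float(np.mean(pred))) ** 2
    slope_bias = (sd_p - r * sd_o) ** 2
    random_part = (1.0 - r * r) * sd_o ** 2
    # observed-on-predicted regression for the bias t-tests; a perfect fit
    # has zero standard errors and trivially no bias
    reg = stats.linregress(pred, obs)
    df = obs.size - 2

    def _bias_p(estimate, null, stderr):
        if stderr == 0:
            return 1.0 if estimate == null else 0.0
        return float(2.0 * stats.t.sf(abs((estimate - null) / stderr), df))

    p_slope = _bias_p(reg.slope, 1.0, reg.stderr)
    p_icpt = _bias_p(reg.intercept, 0.0, reg.intercept_stderr)

    return EvaluationMetrics(
        r=r, cb=cb, ccc=ccc, rmspe_pct=float(rmspe_pct),
        intercept_bias_p=float(p_icpt), slope_bias_p=float(p_slope),
        n=int(obs.size), mean_bias=float(np.mean(pred) - np.mean(obs)),
        msep_decomposition=(mean_bias_sq, slope_bias, random_part))


def compare_breed_milk_concentration(records: pd.DataFrame,
                                     mineral: str | None = None,
                                     breeds=("Holstein", "Jersey"),
                                     alpha: float = 0.05) -> dict:
    """Per-breed mean milk mineral concentration with t-based 95% CIs.

    Returns ``{"per_breed": DataFrame, "verdict": str | None}``; the
    verdict is "different" iff the two requested breeds' CIs do not
    overlap, and None when fewer than two breeds have >= 2 observations.
    """
    df = records
    if mineral is not None and "mineral" in df.columns:
        df = df.loc[df["mineral"] == mineral]
    rows = []
    for breed in breeds:
        vals = df.loc[df["breed"] == breed, "milk_conc"].dropna().to_numpy(float)
        if vals.size == 0:
            continue
        mean = float(np.mean(vals))
        if vals.size >= 2:
            half = stats.t.ppf(1 - alpha / 2, vals.size - 1) * np.std(vals, ddof=1) / np.sqrt(vals.size)
        else:
            half = np.nan
        rows.append({"breed": breed, "n": int(vals.size), "mean": mean,
                     "ci_low": mean - half, "ci_high": mean + half})
    per_breed = pd.DataFrame(rows)
    verdict = None
    usable = per_breed.loc[per_breed["n"] >= 2]
    if len(usable) >= 2:
        a, b = usable.iloc[0], usable.iloc[1]
        overlap = a["ci_low"] <= b["ci_high"] and b["ci_low"] <= a["ci_high"]
        verdict = "not different" if overlap else "different"
    return {"per_breed": per_breed, "verdict": verdict}


def plot_obs_vs_pred(pairs: pd.DataFrame, path, title: str = "") -> None:
    """Observed-vs-predicted scatter with the identity line (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs["predicted"], pairs["observed"], s=18, alpha=0.7,
               edgecolor="none")
    lim = [0, float(max(pairs["predicted"].max(), pairs["observed"].max())) * 1.05]
    ax.plot(lim, lim, "k--", lw=1, label="y = x")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("Predicted excretion (g/kg BW$^{0.75}$/d)")
    ax.set_ylabel("Observed excretion (g/kg BW$^{0.75}$/d)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
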