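"""Balance-trial treatment-mean records: schema, I/O, scaling and weighting.

The unit of observation throughout the package is a *treatment mean* from a
mineral (P or Ca) balance trial with lactating dairy cows: per-day mineral
intake, fecal and urinary excretion and milk secretion, together with the
animal description (body weight, milk yield, DMI, breed) and diet
composition. A dataset is a flat table, one row per treatment mean, with a
``study_id`` identifying the balance trial the mean comes from.

Scaled observations express intake and total (fecal + urinary) excretion per
unit metabolic body weight (g/kg BW^0.75/d), the conventional scaler for
maintenance requirements. Observation weights are normalized inverse SEMs of
fecal excretion, trimmed below to avoid overweighting studies with
implausibly small SEMs, computed separately for studies analyzed with fixed
and with mixed statistical models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the on-disk CSV dialect; one row per treatment mean.
COLUMNS = (
    "record_id", "study_id", "article_id", "mineral", "breed", "model_type",
    "bw", "milk_yield", "dmi", "forage", "cp", "ee", "ndf", "starch",
    "intake", "fecal", "urinary", "milk_secretion", "milk_conc",
    "sem_fecal", "sed_fecal",
)

STRING_COLUMNS = ("record_id", "study_id", "article_id", "mineral", "breed",
                  "model_type")
MINERALS = ("P", "Ca")
BREEDS = ("Holstein", "Jersey", "other", "unknown")
MODEL_TYPES = ("fixed", "mixed", "unknown")
#: Columns that must be non-negative when present.
MASS_FLOW_COLUMNS = ("intake", "fecal", "urinary", "milk_secretion",
                     "milk_conc", "sem_fecal", "sed_fecal")

#: Exponent of the metabolic body weight scaler (kg^0.75).
METABOLIC_EXPONENT = 0.75


def validate_dataset(records: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants; return the frame with canonical dtypes.

    Raises ``ValueError`` naming the offending row for: missing columns,
    unknown mineral/breed/model codes, negative mass flows, non-positive
    intake, duplicate record ids, empty study ids.
    """
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    df = records.loc[:, list(COLUMNS)].copy()
    for col in STRING_COLUMNS:
        df[col] = df[col].astype("string")
    for col in COLUMNS:
        if col not in STRING_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise")

    # categorical codes: missing breed/model_type fall back to "unknown"
    df["breed"] = df["breed"].fillna("unknown")
    df["model_type"] = df["model_type"].fillna("unknown")

    def _bad_rows(mask):
        return ", ".join(df.loc[mask, "record_id"].fillna("<row %d>").astype(str))

    bad = ~df["mineral"].isin(MINERALS)
    if bad.any():
        raise ValueError(f"unknown mineral code in records: {_bad_rows(bad)}")
    bad = ~df["breed"].isin(BREEDS)
    if bad.any():
        raise ValueError(f"unknown breed code in records: {_bad_rows(bad)}")
    bad = ~df["model_type"].isin(MODEL_TYPES)
    if bad.any():
        raise ValueError(f"unknown model_type code in records: {_bad_rows(bad)}")
    for col in MASS_FLOW_COLUMNS:
        bad = df[col].notna() & (df[col] < 0)
        if bad.any():
            raise ValueError(f"negative {col} in records: {_bad_rows(bad)}")
    bad = df["intake"].notna() & (df["intake"] <= 0)
    if bad.any():
        raise ValueError(f"non-positive intake in records: {_bad_rows(bad)}")
    bad = df["bw"].notna() & (df["bw"] <= 0)
    if bad.any():
        raise ValueError(f"non-positive bw in records: {_bad_rows(bad)}")
    if df["record_id"].isna().any() or (df["record_id"] == "").any():
        raise ValueError("every record needs a non-empty record_id")
    if df["record_id"].duplicated().any():
        dupes = df.loc[df["record_id"].duplicated(), "record_id"].tolist()
        raise ValueError(f"duplicate record_id values: {dupes}")
    if df["study_id"].isna().any() or (df["study_id"] == "").any():
        raise ValueError("every record needs a non-empty study_id")
    return df


def read_dataset(path) -> pd.DataFrame:
    """Read a balance-trial CSV into a validated treatment-mean table.

    Missing cells (empty or NA) become missing values, never zeros; row
    order is preserved.
    """
    raw = pd.read_csv(path, dtype={c: "string" for c in STRING_COLUMNS},
                      na_values=["", "NA"], keep_default_na=True)
    return validate_dataset(raw)


def write_dataset(records: pd.DataFrame, path) -> None:
    """Write a treatment-mean table in the package CSV dialect."""
    validate_dataset(records).to_csv(path, index=False, na_rep="")


def sem_from_sed(sed, divisor: str = "half"):
    """SEM of a treatment mean from a reported SED between treatment means.

    ``divisor="half"`` applies SEM = SED/2 (the rule printed in the source
    convention this package follows); ``divisor="sqrt2"`` applies the
    conventional identity SEM = SED/sqrt(2) for equal replication.
    """
    sed = np.asarray(sed, float)
    if np.any(sed[np.isfinite(sed)] < 0):
        raise ValueError("sed must be >= 0")
    if divisor == "half":
        out = sed / 2.0
    elif divisor == "sqrt2":
        out = sed / np.sqrt(2.0)
    else:
        raise ValueError(f"unknown divisor option {divisor!r}")
    return float(out) if out.ndim == 0 else out


def metabolic_weight(bw):
    """Metabolic body weight, BW^0.75 (kg^0.75)."""
    bw = np.asarray(bw, float)
    if np.any(bw[np.isfinite(bw)] <= 0):
        raise ValueError("bw must be > 0")
    out = bw ** METABOLIC_EXPONENT
    return float(out) if out.ndim == 0 else out


def _single_mineral(records):
    minerals = records["mineral"].dropna().unique()
    if len(minerals) != 1:
        raise ValueError(f"records must share one mineral, got {list(minerals)}")
    return minerals[0]


def scale_observations(records: pd.DataFrame) -> pd.DataFrame:
    """Intake and total excretion per unit metabolic body weight.

    Only rows with ``bw``, ``intake``, ``fecal`` and ``urinary`` all present
    are emitted -- incomplete treatment means are dropped from the excretion
    model, and the count dropped is logged. Row order is preserved.
    """
    records = validate_dataset(records)
    _single_mineral(records)
    complete = records[["bw", "intake", "fecal", "urinary"]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("scale_observations: dropped %d of %d records with "
                    "incomplete bw/intake/fecal/urinary", n_dropped, len(records))
    kept = records.loc[complete]
    mbw = metabolic_weight(kept["bw"].to_numpy(float))
    out = pd.DataFrame({
        "record_id": kept["record_id"].to_numpy(),
        "study_id": kept["study_id"].to_numpy(),
        "intake_mbw": kept["intake"].to_numpy(float) / mbw,
        "excretion_mbw": (kept["fecal"].to_numpy(float)
                          + kept["urinary"].to_numpy(float)) / mbw,
        "milk_yield": kept["milk_yield"].to_numpy(float),
    })
    out.attrs["n_dropped"] = n_dropped
    return out


def compute_weights(records: pd.DataFrame, trim_factor: float = 0.35,
                    sed_divisor: str = "half") -> pd.DataFrame:
    """Normalized inverse-SEM observation weights with trimming.

    Within each statistical-model group (``fixed`` vs ``mixed``; records with
    unknown model type are pooled with ``mixed``):

    1. where ``sem_fecal`` is missing but ``sed_fecal`` is reported, SEM is
       derived via `sem_from_sed`;
    2. still-missing SEMs are imputed with the group mean of reported SEMs
       and flagged ``imputed_sem``;
    3. SEMs below ``trim_factor x group-mean SEM`` are raised to that floor
       and flagged ``trimmed``;
    4. ``w1 = 1/SEM`` and ``weight = w1 / mean(w1)`` within the group, so
       group mean weight is exactly 1.

    Raises ``ValueError`` if a group contains no reported SEM at all.
    """
    records = validate_dataset(records)
    _single_mineral(records)
    if not 0 <= trim_factor:
        raise ValueError("trim_factor must be >= 0")

    sem = records["sem_fecal"].to_numpy(float).copy()
    sed = records["sed_fecal"].to_numpy(float)
    from_sed = np.isnan(sem) & ~np.isnan(sed)
    sem[from_sed] = sem_from_sed(sed[from_sed], divisor=sed_divisor)

    group = np.where(records["model_type"].to_numpy() == "fixed",
                     "fixed", "mixed")
    w1 = np.empty(len(records))
    weight = np.empty(len(records))
    trimmed = np.zeros(len(records), bool)
    imputed = np.zeros(len(records), bool)
    for g in np.unique(group):
        idx = group == g
        sem_g = sem[idx].copy()
        reported = ~np.isnan(sem_g)
        if not reported.any():
            raise ValueError(f"cannot impute SEM: no reported SEM in "
                             f"model-type group {g!r}")
        mean_sem = sem_g[reported].mean()
        imputed_g = ~reported
        sem_g[imputed_g] = mean_sem
        floor = trim_factor * mean_sem
        trimmed_g = sem_g < floor
        sem_g[trimmed_g] = floor
        if np.any(sem_g <= 0):
            raise ValueError(f"non-positive SEM after trimming in group {g!r}; "
                             "use a positive trim_factor")
        w1_g = 1.0 / sem_g
        w1[idx] = w1_g
        weight[idx] = w1_g / w1_g.mean()
        trimmed[idx] = trimmed_g
        imputed[idx] = imputed_g
        logger.info("compute_weights[%s]: n=%d, imputed=%d, trimmed=%d, "
                    "mean SEM=%.4g", g, idx.sum(), imputed_g.sum(),
                    trimmed_g.sum(), mean_sem)

    return pd.DataFrame({
        "record_id": records["record_id"].to_numpy(),
        "model_group": group,
        "w1": w1,
        "trimmed": trimmed,
        "imputed_sem": imputed,
        "weight": weight,
    })


def weighted_observations(records: pd.DataFrame, trim_factor: float = 0.35,
                          sed_divisor: str = "half") -> pd.DataFrame:
    """Scaled observations joined with their weights (fit-ready table)."""
    obs = scale_observations(records)
    wts = compute_weights(records, trim_factor=trim_factor,
                          sed_divisor=sed_divisor)
    out = obs.merge(wts[["record_id", "weight"]], on="record_id", how="left")
    out.attrs.update(obs.attrs)
    return out
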