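"""Synthetic balance-trial datasets with the structure the analysis assumes.

The generator mirrors the statistical model fitted downstream: scaled total
excretion follows ``beta1 * exp(beta2 * intake) + u_j + e_ij`` with Gaussian
random study intercepts ``u_j`` and Gaussian residuals, and the bookkeeping
around it (SEM values with missingness, fixed/mixed statistical-model
labels, breed-specific milk mineral concentrations, null-effect diet
covariates) reproduces the descriptive statistics of published P and Ca
balance-trial compilations. It emulates only this statistical structure --
no digesta kinetics, saliva recycling or bone mobilization.

Everything is reproducible from a single integer seed, expanded into
independent substreams per study.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .balance_data import COLUMNS, validate_dataset

#: Dataset-level descriptive constants used for realistic covariate draws:
#: (mean, sd, low, high) on the observed scales.
_ANIMAL_DISTS = {
    "bw": (564.0, 100.0, 316.0, 754.0),        # kg
    "milk_yield": (28.3, 11.0, 4.5, 52.8),     # kg/d
    "dmi": (19.2, 4.8, 8.7, 29.0),             # kg DM/d
}
_DIET_DISTS = {
    "forage": (586.0, 155.0, 258.0, 1000.0),   # g/kg DM
    "cp": (168.0, 17.9, 121.0, 258.0),
    "ee": (32.3, 8.18, 17.4, 47.0),
    "ndf": (338.0, 49.0, 260.0, 496.0),
    "starch": (250.0, 60.0, 50.0, 400.0),      # not tabulated; typical TMR range
}

#: Per-mineral defaults: exponential-curve coefficients, observed intake
#: range (g/kg BW^0.75/d), fecal share of total excretion, SEM moments
#: (g/d), and breed milk concentrations (g/kg).
_MINERAL_DEFAULTS = {
    "P": dict(beta1=0.1352, beta2=1.4010, intake_range=(0.18, 1.48),
              sigma_study=0.09, sigma_resid=0.07,
              fecal_fraction=0.98, fecal_fraction_range=(0.89, 0.999),
              sem_mean=2.78, sem_sd=1.57, n_studies=39,
              milk_conc_means={"Holstein": 0.90, "Jersey": 1.00, "other": 0.95},
              milk_conc_sds={"Holstein": 0.09, "Jersey": 0.13, "other": 0.13}),
    "Ca": dict(beta1=0.3604, beta2=0.5925, intake_range=(0.38, 3.68),
               sigma_study=0.30, sigma_resid=0.18,
               fecal_fraction=0.97, fecal_fraction_range=(0.76, 0.999),
               sem_mean=8.28, sem_sd=6.60, n_studies=23,
               milk_conc_means={"Holstein": 1.18, "Jersey": 1.38, "other": 1.28},
               milk_conc_sds={"Holstein": 0.21, "Jersey": 0.33, "other": 0.33}),
}

#: Breed mix (Holstein predominates in the published compilations).
_BREED_PROBS = {"Holstein": 0.68, "Jersey": 0.17, "other": 0.15}

#: Sample sizes of treatment-mean milk concentrations per breed.
MILK_CONC_N = {"P": {"Holstein": 135, "Jersey": 41},
               "Ca": {"Holstein": 56, "Jersey": 47}}

#: Floor for simulated scaled excretion (g/kg BW^0.75/d); mass flows must
#: stay positive, and the truncation count is reported in ``attrs``.
EXCRETION_FLOOR = 0.01


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclasses.dataclass
class SimulationParams:
    """Conditions for one simulated balance-trial dataset.

    Defaults (via `SimulationParams.for_mineral`) reproduce the published
    study conditions: exponential-curve coefficients and observed intake
    ranges per mineral, between-study and residual SDs on the scaled
    excretion axis, lognormal fecal-SEM moments, and breed-specific milk
    mineral concentrations.
    """

    mineral: str = "P"
    n_studies: int = 39
    treatments_per_study: tuple[int, int] = (3, 4)
    beta1: float = 0.1352          # g/kg BW^0.75 (endogenous excretion)
    beta2: float = 1.4010          # per (g/kg BW^0.75)
    sigma_study: float = 0.09      # SD of random study intercepts
    sigma_resid: float = 0.07      # residual SD
    intake_range: tuple[float, float] = (0.18, 1.48)
    sem_lognormal_params: tuple[float, float] = lognormal_params_from_moments(2.78, 1.57)
    frac_missing_sem: float = 0.05
    frac_sed_only: float = 0.05
    frac_fixed_model: float = 0.5
    fecal_fraction: float = 0.98
    fecal_fraction_range: tuple[float, float] = (0.89, 0.999)
    milk_conc_means: dict = dataclasses.field(
        default_factory=lambda: dict(_MINERAL_DEFAULTS["P"]["milk_conc_means"]))
    milk_conc_sd: dict = dataclasses.field(
        default_factory=lambda: dict(_MINERAL_DEFAULTS["P"]["milk_conc_sds"]))
    frac_missing_diet: float = 0.2
    seed: int = 0

    @classmethod
    def for_mineral(cls, mineral: str, **overrides) -> "SimulationParams":
        """Defaults matching the published dataset conditions for P or Ca."""
        if mineral not in _MINERAL_DEFAULTS:
            raise ValueError(f"unknown mineral {mineral!r}")
        d = _MINERAL_DEFAULTS[mineral]
        params = dict(
            mineral=mineral,
            n_studies=d["n_studies"],
            beta1=d["beta1"], beta2=d["beta2"],
            sigma_study=d["sigma_study"], sigma_resid=d["sigma_resid"],
            intake_range=d["intake_range"],
            sem_lognormal_params=lognormal_params_from_moments(d["sem_mean"], d["sem_sd"]),
            fecal_fraction=d["fecal_fraction"],
            fecal_fraction_range=d["fecal_fraction_range"],
            milk_conc_means=dict(d["milk_conc_means"]),
            milk_conc_sd=dict(d["milk_conc_sds"]),
        )
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        if self.mineral not in _MINERAL_DEFAULTS:
            raise ValueError(f"unknown mineral {self.mineral!r}")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        lo, hi = (self.treatments_per_study
                  if isinstance(self.treatments_per_study, tuple)
                  else (self.treatments_per_study, self.treatments_per_study))
        if not (1 <= lo <= hi):
            raise ValueError("treatments_per_study must be positive and increasing")
        if self.sigma_study < 0 or self.sigma_resid < 0:
            raise ValueError("SDs must be >= 0")
        for frac in (self.frac_missing_sem, self.frac_sed_only,
                     self.frac_fixed_model, self.frac_missing_diet):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if not (0 < self.intake_range[0] < self.intake_range[1]):
            raise ValueError("intake_range must be positive and increasing")
        if self.beta1 <= 0:
            raise ValueError("beta1 must be > 0")


def _truncated_normal(rng, mean, sd, low, high, size):
    """Normal draws clipped to the observed range (simple, adequate here)."""
    return np.clip(rng.normal(mean, sd, size), low, high)


def simulate_balance_trials(params: SimulationParams) -> pd.DataFrame:
    """Draw one dataset of treatment means under the generative model.

    For each study j: ``u_j ~ N(0, sigma_study^2)``; for each treatment an
    intake (g/kg BW^0.75/d) uniform over ``intake_range`` and

        ``excretion_mbw = beta1 * exp(beta2 * intake) + u_j + e_ij``

    truncated below at `EXCRETION_FLOOR`. Scaled quantities are
    back-transformed to g/d with the study's drawn body weight, and total
    excretion is split into fecal and urinary parts. SEMs, missingness,
    model-type labels, breed, milk yield/concentration and null-effect diet
    covariates are drawn to mimic the descriptive statistics of the
    published compilations. Fully reproducible from ``params.seed``.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    study_streams = ss.spawn(params.n_studies)
    rng = np.random.default_rng(ss.spawn(1)[0])

    tps = params.treatments_per_study
    lo, hi = tps if isinstance(tps, tuple) else (tps, tps)
    mu_sem, sig_sem = params.sem_lognormal_params

    rows = []
    n_truncated = 0
    for j in range(params.n_studies):
        srng = np.random.default_rng(study_streams[j])
        study_id = f"S{j + 1:03d}"
        article_id = f"A{1 + (3 * j) // 4}"  # ~4 studies per 3 articles
        n_t = int(srng.integers(lo, hi + 1))
        u_j = srng.normal(0.0, params.sigma_study)
        bw = float(_truncated_normal(srng, *_ANIMAL_DISTS["bw"], None))
        study_my = float(_truncated_normal(srng, *_ANIMAL_DISTS["milk_yield"], None))
        breed = srng.choice(list(_BREED_PROBS), p=list(_BREED_PROBS.values()))
        model_type = "fixed" if srng.random() < params.frac_fixed_model else "mixed"
        sed_only = model_type == "fixed" and srng.random() < params.frac_sed_only

        mbw = bw ** 0.75
        intake_mbw = srng.uniform(*params.intake_range, n_t)
        e_ij = srng.normal(0.0, params.sigma_resid, n_t)
        excretion_mbw = params.beta1 * np.exp(params.beta2 * intake_mbw) + u_j + e_ij
        n_truncated += int((excretion_mbw < EXCRETION_FLOOR).sum())
        excretion_mbw = np.maximum(excretion_mbw, EXCRETION_FLOOR)

        fecal_frac = np.clip(
            srng.normal(params.fecal_fraction, 0.015, n_t),
            *params.fecal_fraction_range)
        total_gd = excretion_mbw * mbw
        milk_yield = np.clip(study_my + srng.normal(0.0, 1.5, n_t),
                             _ANIMAL_DISTS["milk_yield"][2],
                             _ANIMAL_DISTS["milk_yield"][3])
        milk_conc = srng.normal(params.milk_conc_means[breed],
                                params.milk_conc_sd[breed], n_t)
        milk_conc = np.maximum(milk_conc, 0.1)
        sem = np.exp(srng.normal(mu_sem, sig_sem, n_t))
        sem_missing = srng.random(n_t) < params.frac_missing_sem
        dmi = _truncated_normal(srng, *_ANIMAL_DISTS["dmi"], n_t)
        diet = {name: _truncated_normal(srng, *_DIET_DISTS[name], n_t)
                for name in _DIET_DISTS}
        diet_missing = {name: srng.random(n_t) < params.frac_missing_diet
                        for name in _DIET_DISTS}

        for t in range(n_t):
            row = {
                "record_id": f"{study_id}-t{t + 1}",
                "study_id": study_id,
                "article_id": article_id,
                "mineral": params.mineral,
                "breed": breed,
                "model_type": model_type,
                "bw": bw,
                "milk_yield": milk_yield[t],
                "dmi": dmi[t],
                "intake": intake_mbw[t] * mbw,
                "fecal": total_gd[t] * fecal_frac[t],
                "urinary": total_gd[t] * (1.0 - fecal_frac[t]),
                "milk_secretion": milk_conc[t] * milk_yield[t],
                "milk_conc": milk_conc[t],
                "sem_fecal": np.nan if (sem_missing[t] or sed_only) else sem[t],
                "sed_fecal": 2.0 * sem[t] if sed_only else np.nan,
            }
            for name in _DIET_DISTS:
                row[name] = np.nan if diet_missing[name][t] else diet[name][t]
            rows.append(row)

    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df = validate_dataset(df)
    df.attrs["n_truncated"] = n_truncated
    df.attrs["seed"] = params.seed
    return df


def simulate_milk_concentrations(mineral: str = "P", n_by_breed=None,
                                 mean_by_breed=None, sd_by_breed=None,
                                 seed: int = 0) -> pd.DataFrame:
    """Treatment-mean milk mineral concentrations per breed.

    Defaults reproduce the published per-breed sample sizes (`MILK_CONC_N`)
    and mean concentrations; Normal draws, seeded.
    """
    if mineral not in _MINERAL_DEFAULTS:
        raise ValueError(f"unknown mineral {mineral!r}")
    d = _MINERAL_DEFAULTS[mineral]
    n_by_breed = dict(MILK_CONC_N[mineral]) if n_by_breed is None else n_by_breed
    mean_by_breed = dict(d["milk_conc_means"]) if mean_by_breed is None else mean_by_breed
    sd_by_breed = dict(d["milk_conc_sds"]) if sd_by_breed is None else sd_by_breed
    rng = np.random.default_rng(seed)
    frames = []
    for breed, n in n_by_breed.items():
        if n < 0 or sd_by_breed[breed] < 0:
            raise ValueError("sample sizes and SDs must be >= 0")
        vals = rng.normal(mean_by_breed[breed], sd_by_breed[breed], int(n))
        frames.append(pd.DataFrame({"breed": breed, "milk_conc": vals}))
    return pd.concat(frames, ignore_index=True)
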