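"""Factorial P and Ca requirement calculators for lactating dairy cows.

Three systems are implemented over a common scenario description:

* the **proposed** system: net maintenance = intercept coefficient x
  BW^0.75 (endogenous fecal + urinary loss), net lactation = breed milk
  mineral concentration x milk yield, and dietary intake requirement
  DIR = (NR_M + NR_L) / MC with fixed metabolizable coefficients;
* the **NASEM-2021** comparator (DMI-driven P and Ca maintenance, fixed P
  absorption coefficient, forage/concentrate-specific Ca coefficients);
* the **NRC-2001** comparator (DMI- and BW-driven maintenance,
  forage/concentrate-specific absorption coefficients for both minerals).

Forage- and concentrate-specific absorption coefficients are combined by
linear mass-fraction blending over the diet's forage fraction. Scenario
presets reproduce the standard comparison grid: milk yields 10-50 kg/d with
forage fractions 0.80/0.60/0.50/0.45/0.40, body weight interpolated from
500 kg at 10 kg/d to 700 kg at 50 kg/d.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .balance_data import metabolic_weight

#: Proposed-system coefficients: maintenance (g/kg BW^0.75), breed milk
#: concentrations (g/kg) and metabolizable coefficients.
PROPOSED_COEFFICIENTS = {
    "P": {"maintenance": 0.1352,
          "milk_conc": {"Holstein": 0.90, "Jersey": 1.00},
          "mc": 0.69},
    "Ca": {"maintenance": 0.3604,
           "milk_conc": {"Holstein": 1.18, "Jersey": 1.38},
           "mc": 0.65},
}

#: NASEM-2021 comparator: maintenance g/d = a*DMI + b*BW; lactation g/d per
#: kg milk; absorption coefficients (P overall; Ca by diet fraction).
NASEM2021 = {
    "P": {"maint_dmi": 1.0, "maint_bw": 0.0006, "milk": 0.90, "ac": 0.72},
    "Ca": {"maint_dmi": 0.9, "maint_bw": 0.0, "milk": 1.03,
           "ac_concentrate": 0.60, "ac_forage": 0.40},
}

#: NRC-2001 comparator.
NRC2001 = {
    "P": {"maint_dmi": 1.0, "maint_bw": 0.0002, "milk": 0.90,
          "ac_concentrate": 0.70, "ac_forage": 0.64},
    "Ca": {"maint_dmi": 0.0, "maint_bw": 0.031, "milk": 1.22,
           "ac_concentrate": 0.60, "ac_forage": 0.30},
}

#: Comparison-grid presets: forage fraction by milk yield (kg/d).
FORAGE_SCHEDULE = {10: 0.80, 20: 0.60, 30: 0.50, 40: 0.45, 50: 0.40}
#: BW anchors for the preset grid: 500 kg at 10 kg/d, 700 kg at 50 kg/d.
_BW_ANCHORS = ((10.0, 500.0), (50.0, 700.0))
#: DMI anchors (kg/d) at 30 and 50 kg/d milk for the preset grid.
_DMI_ANCHORS = ((30.0, 20.7), (50.0, 27.0))


@dataclasses.dataclass
class Scenario:
    """One cow x diet scenario to evaluate under a requirement system."""

    mineral: str                      # "P" or "Ca"
    bw: float                         # kg
    milk_yield: float                 # kg/d
    breed: str = "Holstein"
    dmi: float | None = None          # kg DM/d
    forage_frac: float | None = None  # g/g DM
    milk_conc_override: float | None = None  # g/kg milk

    def validate(self) -> None:
        if self.mineral not in PROPOSED_COEFFICIENTS:
            raise ValueError(f"unknown mineral {self.mineral!r}")
        if self.bw <= 0:
            raise ValueError("bw must be > 0")
        if self.milk_yield < 0:
            raise ValueError("milk_yield must be >= 0")
        if self.dmi is not None and self.dmi <= 0:
            raise ValueError("dmi must be > 0 when given")
        if self.forage_frac is not None and not 0 <= self.forage_frac <= 1:
            raise ValueError("forage_frac must lie in [0, 1]")


@dataclasses.dataclass
class RequirementResult:
    """Requirement components (g/d) for one scenario under one system."""

    system: str
    mineral: str
    nrm: float                 # net maintenance, g/d
    nrl: float                 # net lactation, g/d
    net_total: float           # g/d
    mc_or_ac: float            # efficiency divisor
    dir: float                 # dietary intake requirement, g/d
    dietary_conc: float | None = None  # g/kg DM, when DMI given

    def rounded(self) -> dict:
        """Reporting precision: g/d to integers, g/kg DM to one decimal."""
        return {
            "system": self.system, "mineral": self.mineral,
            "nrm": round(self.nrm), "nrl": round(self.nrl),
            "net_total": round(self.net_total),
            "mc_or_ac": round(self.mc_or_ac, 2),
            "dir": round(self.dir),
            "dietary_conc": (None if self.dietary_conc is None
                             else round(self.dietary_conc, 1)),
        }


def net_maintenance(mineral: str, bw: float, coefficient: float | None = None) -> float:
    """Net maintenance requirement (g/d): coefficient x BW^0.75."""
    if coefficient is None:
        coefficient = PROPOSED_COEFFICIENTS[mineral]["maintenance"]
    return coefficient * metabolic_weight(bw)


def net_lactation(mineral: str, breed: str, milk_yield: float,
                  milk_conc_override: float | None = None) -> float:
    """Net lactation requirement (g/d): milk concentration x milk yield."""
    if milk_yield < 0:
        raise ValueError("milk_yield must be >= 0")
    if milk_conc_override is not None:
        conc = milk_conc_override
    else:
        milk = PROPOSED_COEFFICIENTS[mineral]["milk_conc"]
        if breed not in milk:
            raise ValueError(f"no default milk {mineral} concentration for "
                             f"breed {breed!r}; pass milk_conc_override")
        conc = milk[breed]
    return conc * milk_yield


def blended_ac(forage_frac: float, ac_forage: float, ac_concentrate: float) -> float:
    """Diet absorption coefficient: linear blend by forage mass fraction."""
    if not 0 <= forage_frac <= 1:
        raise ValueError("forage_frac must lie in [0, 1]")
    return forage_frac * ac_forage + (1.0 - forage_frac) * ac_concentrate


def _finish(system, scenario, nrm, nrl, efficiency) -> RequirementResult:
    net = nrm + nrl
    dir_ = net / efficiency
    conc = dir_ / scenario.dmi if scenario.dmi is not None else None
    return RequirementResult(system=system, mineral=scenario.mineral,
                             nrm=nrm, nrl=nrl, net_total=net,
                             mc_or_ac=efficiency, dir=dir_, dietary_conc=conc)


def proposed_requirement(scenario: Scenario, mc: float | None = None,
                         maintenance_coefficient: float | None = None) -> RequirementResult:
    """Proposed factorial system: DIR = (NR_M + NR_L) / MC."""
    scenario.validate()
    if mc is None:
        mc = PROPOSED_COEFFICIENTS[scenario.mineral]["mc"]
    nrm = net_maintenance(scenario.mineral, scenario.bw, maintenance_coefficient)
    nrl = net_lactation(scenario.mineral, scenario.breed, scenario.milk_yield,
                        scenario.milk_conc_override)
    return _finish("proposed", scenario, nrm, nrl, mc)


def nasem2021_requirement(scenario: Scenario) -> RequirementResult:
    """NASEM-2021 comparator (requires DMI; forage fraction for Ca)."""
    scenario.validate()
    coef = NASEM2021[scenario.mineral]
    if scenario.dmi is None:
        raise ValueError("NASEM-2021 maintenance needs scenario.dmi")
    nrm = coef["maint_dmi"] * scenario.dmi + coef["maint_bw"] * scenario.bw
    nrl = coef["milk"] * scenario.milk_yield
    if scenario.mineral == "P":
        ac = coef["ac"]
    else:
        if scenario.forage_frac is None:
            raise ValueError("NASEM-2021 Ca needs scenario.forage_frac")
        ac = blended_ac(scenario.forage_frac, coef["ac_forage"],
                        coef["ac_concentrate"])
    return _finish("NASEM2021", scenario, nrm, nrl, ac)


def nrc2001_requirement(scenario: Scenario) -> RequirementResult:
    """NRC-2001 comparator (requires forage fraction; DMI for P)."""
    scenario.validate()
    coef = NRC2001[scenario.mineral]
    if scenario.mineral == "P" and scenario.dmi is None:
        raise ValueError("NRC-2001 P maintenance needs scenario.dmi")
    if scenario.forage_frac is None:
        raise ValueError("NRC-2001 needs scenario.forage_frac")
    dmi = scenario.dmi if scenario.dmi is not None else 0.0
    nrm = coef["maint_dmi"] * dmi + coef["maint_bw"] * scenario.bw
    nrl = coef["milk"] * scenario.milk_yield
    ac = blended_ac(scenario.forage_frac, coef["ac_forage"],
                    coef["ac_concentrate"])
    return _finish("NRC2001", scenario, nrm, nrl, ac)


_SYSTEMS = {
    "proposed": proposed_requirement,
    "NASEM2021": nasem2021_requirement,
    "NRC2001": nrc2001_requirement,
}


def compare_systems(scenario: Scenario) -> dict:
    """All three systems on one scenario plus percent differences.

    Percent difference = 100 * (proposed - comparator) / comparator, for
    net total and dietary intake requirement.
    """
    results = {name: fn(scenario) for name, fn in _SYSTEMS.items()}
    prop = results["proposed"]
    pct = {}
    for name in ("NASEM2021", "NRC2001"):
        comp = results[name]
        pct[name] = {
            "net_total": 100.0 * (prop.net_total - comp.net_total) / comp.net_total,
            "dir": 100.0 * (prop.dir - comp.dir) / comp.dir,
        }
    return {"results": results, "pct_difference_vs": pct}


def preset_bw(milk_yield: float) -> float:
    """BW (kg) linearly interpolated between the 10 and 50 kg/d anchors."""
    (m0, b0), (m1, b1) = _BW_ANCHORS
    return float(np.clip(b0 + (milk_yield - m0) * (b1 - b0) / (m1 - m0), b0, b1))


def preset_dmi(milk_yield: float) -> float:
    """DMI (kg/d) linearly interpolated between the 30 and 50 kg/d anchors."""
    (m0, d0), (m1, d1) = _DMI_ANCHORS
    return float(d0 + (milk_yield - m0) * (d1 - d0) / (m1 - m0))


def reference_scenarios(mineral: str, breed: str = "Holstein") -> list[Scenario]:
    """The comparison-grid presets: MY 10-50 kg/d with the forage schedule,
    interpolated BW and DMI."""
    return [Scenario(mineral=mineral, bw=preset_bw(my), milk_yield=float(my),
                     breed=breed, dmi=preset_dmi(my),
                     forage_frac=FORAGE_SCHEDULE[my])
            for my in sorted(FORAGE_SCHEDULE)]


def load_preset_scenarios(mineral: str = "P") -> dict:
    """Scenario presets shipped with the package (``scenarios.yaml``)."""
    from importlib import resources

    import yaml

    raw = yaml.safe_load(
        resources.files(__package__).joinpath("scenarios.yaml").read_text())
    grid = [Scenario(mineral=mineral, bw=preset_bw(s["milk_yield"]),
                     milk_yield=float(s["milk_yield"]),
                     dmi=preset_dmi(s["milk_yield"]),
                     forage_frac=s["forage_frac"])
            for s in raw["comparison_grid"]]
    worked = [Scenario(**s) for s in raw["worked_examples"]]
    return {"comparison_grid": grid, "worked_examples": worked}
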