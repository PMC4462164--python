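"""Fermentation stoichiometry, electron equivalents, glucose balance, flavins.

Mixed-acid fermentation of glucose by *E. coli* yields formate, acetate,
lactate (and unmeasured CO2/ethanol); the metal reducer oxidises formate
(2 e- per molecule, formate -> CO2) and lactate (4 e- per molecule for
the incomplete lactate -> acetate + CO2 route) at the anode.  Degree-of-
reduction bookkeeping closes carbon and electron balances; a linear
fluorescence standard curve quantifies extracellular flavins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import constants

from .config import InputError

AVOGADRO = constants.Avogadro
GLUCOSE_MOLAR_MASS = 180.16          # g/mol
#: generic biomass CH1.8O0.5N0.2: grams per C-mol
BIOMASS_G_PER_CMOL = 12.011 + 1.8 * 1.008 + 0.5 * 15.999 + 0.2 * 14.007
#: electrons per biomass C-mol by the degree-of-reduction formula
BIOMASS_E_PER_CMOL = 4.0 + 1.8 - 2 * 0.5 - 3 * 0.2   # = 4.2


@dataclass
class MetaboliteSeries:
    """Concentration time courses (mM) in a known liquid volume."""

    time_h: np.ndarray
    conc_mM: pd.DataFrame        # one column per metabolite
    volume_L: float

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        if not np.all(np.diff(self.time_h) > 0):
            raise InputError("times must be strictly increasing")
        if len(self.conc_mM) != self.time_h.size:
            raise InputError("concentration table length mismatch")
        if (self.conc_mM.to_numpy() < 0).any():
            raise InputError("concentrations must be >= 0")
        if self.volume_L <= 0:
            raise InputError("volume must be > 0")

    @property
    def metabolites(self) -> list[str]:
        return list(self.conc_mM.columns)


@dataclass
class StoichiometrySpec:
    """Electron equivalents, carbon counts and yield caps per metabolite.

    ``electron_equivalents`` are electrons released per molecule fully
    transferred to the anode; lactate uses the incomplete-oxidation value
    (4) consistent with acetate accumulation in the anolyte.
    """

    electron_equivalents: Mapping[str, float] = field(default_factory=lambda: {
        "formate": 2.0, "lactate": 4.0, "acetate": 0.0})
    carbon_atoms: Mapping[str, int] = field(default_factory=lambda: {
        "glucose": 6, "formate": 1, "acetate": 2, "lactate": 3})
    max_yield_per_glucose: Mapping[str, float] = field(default_factory=lambda: {
        "formate": 2.0, "acetate": 2.0, "lactate": 2.0})
    #: degree of reduction per C-mol (electrons available per carbon)
    gamma_per_cmol: Mapping[str, float] = field(default_factory=lambda: {
        "glucose": 4.0, "formate": 2.0, "acetate": 4.0, "lactate": 4.0})

    def validate(self) -> "StoichiometrySpec":
        for m in (self.electron_equivalents, self.carbon_atoms,
                  self.max_yield_per_glucose, self.gamma_per_cmol):
            if any(v < 0 for v in m.values()):
                raise InputError("stoichiometry values must be >= 0")
        return self


@dataclass
class BiomassRecord:
    """Planktonic cell density with the CFU-to-dry-weight conversion."""

    time_h: float
    cfu_per_ml: float
    volume_L: float
    cfu_to_gram: float = 3e-13   # g dry weight per CFU (~0.3 pg/cell)

    def __post_init__(self) -> None:
        if self.cfu_per_ml < 0 or self.volume_L < 0:
            raise InputError("CFU density and volume must be >= 0")
        if self.cfu_to_gram <= 0:
            raise InputError("cfu_to_gram factor must be > 0")


@dataclass
class StandardCurve:
    """Linear fluorescence response: reading = intercept + blank + slope*conc."""

    slope: float        # RFU per nM
    intercept: float = 0.0
    blank: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InputError("standard-curve slope must be > 0")


def metabolite_delta(series: MetaboliteSeries, metabolite: str,
                     t0_h: float, t1_h: float, direction: str) -> float:
    """Moles of a metabolite produced or consumed on [t0, t1].

    Concentrations are linearly interpolated; the result is
    |c(t1) - c(t0)| * V / 1000 when the change matches ``direction``
    ("produced" or "consumed"), else 0.
    """
    if metabolite not in series.conc_mM.columns:
        raise InputError(f"metabolite {metabolite!r} absent from series")
    if direction not in ("produced", "consumed"):
        raise InputError("direction must be 'produced' or 'consumed'")
    t = series.time_h
    if not (t[0] <= t0_h < t1_h <= t[-1]):
        raise InputError("window outside series support")
    c = series.conc_mM[metabolite].to_numpy()
    c0, c1 = np.interp([t0_h, t1_h], t, c)
    diff = c1 - c0
    if (direction == "produced") != (diff > 0):
        return 0.0
    return abs(diff) * series.volume_L / 1000.0


def electrons_from_metabolites(delta_formate_mol: float, delta_lactate_mol: float,
                               spec: StoichiometrySpec | None = None) -> float:
    """Electrons released by anodic oxidation of the given mol amounts."""
    spec = (spec or StoichiometrySpec()).validate()
    if delta_formate_mol < 0 or delta_lactate_mol < 0:
        raise InputError("mol deltas must be >= 0")
    z = spec.electron_equivalents
    return (z["formate"] * delta_formate_mol
            + z["lactate"] * delta_lactate_mol) * AVOGADRO


def degree_of_reduction(C: int, H: int, O: int, N: int = 0) -> float:
    """Available electrons per molecule of C_c H_h O_o N_n: 4C + H - 2O - 3N."""
    if C < 0:
        raise InputError("carbon count must be >= 0")
    return 4.0 * C + H - 2.0 * O - 3.0 * N


@dataclass
class BalanceReport:
    """Carbon and electron recovery of a fermentation interval."""

    glucose_mol: float
    carbon_recovery: float
    electron_recovery: float
    product_mol: dict[str, float]
    yield_cap_violations: dict[str, bool]
    zero_glucose_with_products: bool


def fermentation_balance(glucose_consumed_mM: float, products_mM: Mapping[str, float],
                         biomass_g: float = 0.0,
                         spec: StoichiometrySpec | None = None,
                         volume_L: float = 0.02) -> BalanceReport:
    """Material balance on glucose fermentation.

    Carbon recovery = (product C-mol + biomass C-mol) / glucose C-mol;
    electron recovery analogously via degrees of reduction (biomass at
    4.2 e-eq per C-mol).  Each product is checked against its maximum
    molar yield per glucose; exceeding it raises a flag, not an error —
    measured pools can over-run the fermentative cap when a product is
    also formed by other routes or carried over.
    """
    spec = (spec or StoichiometrySpec()).validate()
    if glucose_consumed_mM < 0:
        raise InputError("glucose consumed must be >= 0")
    mmol = {m: c * volume_L for m, c in products_mM.items()}   # mmol
    glucose_mmol = glucose_consumed_mM * volume_L
    product_mol = {m: v / 1000.0 for m, v in mmol.items()}
    glucose_mol = glucose_mmol / 1000.0

    biomass_cmol = biomass_g / BIOMASS_G_PER_CMOL
    product_c = sum(spec.carbon_atoms.get(m, 0) * v for m, v in product_mol.items())
    product_e = sum(spec.gamma_per_cmol.get(m, 0.0) * spec.carbon_atoms.get(m, 0) * v
                    for m, v in product_mol.items())
    glucose_c = spec.carbon_atoms["glucose"] * glucose_mol
    glucose_e = spec.gamma_per_cmol["glucose"] * spec.carbon_atoms["glucose"] * glucose_mol

    zero_flag = glucose_mol == 0 and any(v > 0 for v in product_mol.values())
    if glucose_c > 0:
        carbon_recovery = (product_c + biomass_cmol) / glucose_c
        electron_recovery = (product_e + BIOMASS_E_PER_CMOL * biomass_cmol) / glucose_e
    else:
        carbon_recovery = electron_recovery = 0.0

    violations = {}
    for m, v in product_mol.items():
        cap = spec.max_yield_per_glucose.get(m)
        violations[m] = bool(cap is not None and glucose_mol >= 0
                             and v > cap * glucose_mol + 1e-15)
    return BalanceReport(glucose_mol=glucose_mol, carbon_recovery=carbon_recovery,
                         electron_recovery=electron_recovery, product_mol=product_mol,
                         yield_cap_violations=violations,
                         zero_glucose_with_products=zero_flag)


def cfu_to_dry_weight(record: BiomassRecord) -> float:
    """Total dry biomass (g) in the chamber from a CFU density."""
    return record.cfu_per_ml * record.volume_L * 1000.0 * record.cfu_to_gram


def glucose_consumed_fraction(biomass_dry_g: float, y_glucose: float = 0.524,
                              glucose0_mM: float = 20.0,
                              volume_L: float = 0.02) -> tuple[float, bool]:
    """Fraction of the initial glucose consumed, inferred from biomass.

    Glucose consumed = biomass / Y_glucose (g/g, default 0.524 for the
    growth phase); the fraction is that mass over the initial glucose
    mass.  Returns (fraction capped at 1, flag set when the cap bit).
    """
    if y_glucose <= 0 or glucose0_mM <= 0 or volume_L <= 0:
        raise InputError("yield, initial glucose and volume must be > 0")
    if biomass_dry_g < 0:
        raise InputError("biomass must be >= 0")
    glucose_mass_g = glucose0_mM * volume_L * (GLUCOSE_MOLAR_MASS / 1000.0)
    frac = (biomass_dry_g / y_glucose) / glucose_mass_g
    return (min(frac, 1.0), frac > 1.0)


def fluorescence_to_concentration(readings, curve: StandardCurve) -> tuple[float, float]:
    """Invert the standard curve on a set of well readings -> (mean, sd) nM.

    Per well: conc = (reading - blank - intercept) / slope; negative
    inversions (readings below background) are clipped to 0 with a
    warning.  SD is the sample SD over wells (0 for a single well).
    """
    r = np.asarray(list(readings), dtype=float)
    if r.size == 0:
        raise InputError("need at least one reading")
    conc = (r - curve.blank - curve.intercept) / curve.slope
    if (conc < 0).any():
        warnings.warn("readings below background; clipping to 0 nM", stacklevel=2)
        conc = np.clip(conc, 0.0, None)
    sd = float(np.std(conc, ddof=1)) if conc.size > 1 else 0.0
    return float(np.mean(conc)), sd
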