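"""Steady-state charge-balance speciation for dilute boreal lake water.

The model solves the proton balance of a lake-water sample whose composition
is given as charge equivalents of the major sea-salt and acid ions, total
organic carbon, and an equilibrium description of three pH-coupled
subsystems:

* **Aluminum** in equilibrium with a gibbsite-like Al(OH)3 solid phase,
  ``pAl = S_Al * pH - log K_Al``, hydrolysed to AlOH2+, Al(OH)2+ and
  Al(OH)4- through cumulative hydrolysis constants.  Fluoride and organic
  Al complexes are deliberately not speciated: fluoride counts as a strong
  acid anion only.
* **Carbonate** as bicarbonate in equilibrium with a fixed CO2 partial
  pressure (open system, supersaturated relative to the atmosphere as is
  typical for boreal lakes).
* **Organic acids** as an Oliver-style triprotic analogue whose total site
  density scales with TOC.

All charge quantities are handled internally in μeq/L; aluminum mass is
reported in μg/L.  Activity is equated with concentration (dilute waters,
no ionic-strength correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AL_MOLAR_MASS",
    "IonComposition",
    "EquilibriumConstants",
    "SpeciationResult",
    "AluminumSpecies",
    "SpeciationError",
    "UnsolvableCompositionError",
    "aluminum_speciation",
    "carbonate_charge",
    "organic_acid_charge",
    "charge_balance_residual",
    "solve_pH",
]

#: Molar mass of aluminum, g/mol (used for the μeq/L -> μg/L conversion).
AL_MOLAR_MASS = 26.98

#: pH search bracket for the charge-balance root.
PH_BRACKET = (3.0, 10.0)

#: Default tolerance on the absolute charge imbalance at the root, μeq/L
#: (1e-10 eq/L; corresponds to roughly 1e-4 pH units in poorly buffered water).
DEFAULT_TOLERANCE = 1e-4


class SpeciationError(ValueError):
    """Invalid input to the speciation engine."""


class UnsolvableCompositionError(SpeciationError):
    """The charge-balance residual has no sign change on the search bracket."""

    def __init__(self, message: str, lake_id: str | None = None):
        self.lake_id = lake_id
        if lake_id is not None:
            message = f"lake {lake_id!r}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class IonComposition:
    """One lake-year's major-ion makeup.

    Cations and anions are charge equivalents (μeq/L); ``toc`` is mg C/L.
    ``temperature`` is carried as metadata only — equilibrium constants are
    fixed and not temperature corrected.
    """

    ca: float = 0.0
    mg: float = 0.0
    na: float = 0.0
    k: float = 0.0
    nh4: float = 0.0
    so4: float = 0.0
    cl: float = 0.0
    no3: float = 0.0
    f: float = 0.0
    toc: float = 0.0
    temperature: float | None = None

    def __post_init__(self):
        for name in ("ca", "mg", "na", "k", "nh4", "so4", "cl", "no3", "f", "toc"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise SpeciationError(
                    f"{name} must be a finite nonnegative concentration, got {value!r}"
                )

    @property
    def base_cations(self) -> float:
        """BC: summed base-cation charge, μeq/L (inputs are already equivalents)."""
        return self.ca + self.mg + self.na + self.k + self.nh4

    @property
    def strong_acid_anions(self) -> float:
        """SAA: summed strong-acid-anion charge, μeq/L."""
        return self.so4 + self.cl + self.no3 + self.f


@dataclass(frozen=True)
class EquilibriumConstants:
    """Equilibrium description of the pH-coupled subsystems.

    Defaults follow the conventional values used by this family of
    acidification models; every constant is overridable.  The aluminum
    subsystem can be switched off entirely (``al_enabled=False``) to model
    waters without a controlling solid phase.
    """

    log_KAl: float = 8.1              # gibbsite solubility, log10
    s_al: float = 3.0                 # pH–pAl slope
    pco2_fraction: float = 0.156      # CO2 partial pressure, % by volume
    henry_kH: float = -1.5            # Henry's law constant, log10 mol/L/atm
    carbonic_pK1: float = 6.3         # first carbonic-acid dissociation
    water_pKw: float = 14.0           # ion product of water
    al_hydrolysis: tuple[float, float, float] = (-5.0, -10.1, -22.7)
    oa_site_density: float = 10.0     # organic charge sites, μeq per mg C
    oa_pK1: float = 3.04
    oa_pK2: float = 4.51
    oa_pK3: float = 6.46
    al_enabled: bool = True

    def __post_init__(self):
        if self.s_al <= 0:
            raise SpeciationError("s_al must be positive")
        if self.pco2_fraction < 0:
            raise SpeciationError("pco2_fraction must be nonnegative")
        if not (self.oa_pK1 < self.oa_pK2 < self.oa_pK3):
            raise SpeciationError("organic pKs must be strictly increasing")
        if len(self.al_hydrolysis) != 3:
            raise SpeciationError("al_hydrolysis needs three cumulative constants")

    @property
    def pco2_atm(self) -> float:
        """pCO2 in atm at 1 atm total pressure."""
        return self.pco2_fraction / 100.0

    def with_(self, **overrides) -> "EquilibriumConstants":
        return replace(self, **overrides)


DEFAULT_CONSTANTS = EquilibriumConstants()


@dataclass(frozen=True)
class AluminumSpecies:
    """Aluminum speciation at a given pH (charge equivalents, μeq/L)."""

    al3: float
    aloh2: float
    aloh2p: float
    aloh4: float

    @property
    def cationic_charge(self) -> float:
        return self.al3 + self.aloh2 + self.aloh2p

    @property
    def al_i_mass(self) -> float:
        """Cationic inorganic aluminum as mass, μg/L."""
        molar_umol = self.al3 / 3.0 + self.aloh2 / 2.0 + self.aloh2p
        return molar_umol * AL_MOLAR_MASS


@dataclass(frozen=True)
class SpeciationResult:
    """Solved charge balance: pH plus every species, μeq/L (al_i_mass in μg/L)."""

    pH: float
    h: float
    oh: float
    hco3: float
    al3: float
    aloh2: float
    aloh2p: float
    aloh4: float
    al_i_mass: float
    oa_charge: float
    residual: float

    @property
    def positive_charge(self) -> float:
        """Solute positive charge excluding base cations, μeq/L."""
        return self.h + self.al3 + self.aloh2 + self.aloh2p

    @property
    def negative_charge(self) -> float:
        """Solute negative charge excluding strong acid anions, μeq/L."""
        return self.oh + self.hco3 + self.aloh4 + self.oa_charge


def _check_pH(pH: float) -> None:
    if not (2.0 <= pH <= 12.0):
        raise SpeciationError(f"pH {pH} outside the model's validity range [2, 12]")


def aluminum_speciation(
    pH, constants: EquilibriumConstants = DEFAULT_CONSTANTS
) -> AluminumSpecies:
    """Speciate aluminum against the gibbsite-like solid phase at a given pH.

    The free ion obeys ``pAl = s_al*pH - log_KAl``; the hydrolysis products
    follow from the cumulative constants ``*β_n`` of
    ``Al3+ + n H2O <-> Al(OH)n^(3-n) + n H+``.  Returns charge equivalents
    in μeq/L; ``al_i_mass`` converts the cationic pool to μg/L.
    """
    _check_pH(float(np.min(pH)) if np.ndim(pH) else pH)
    _check_pH(float(np.max(pH)) if np.ndim(pH) else pH)
    if not constants.al_enabled:
        return AluminumSpecies(0.0, 0.0, 0.0, 0.0)
    b1, b2, b4 = constants.al_hydrolysis
    log_al3 = constants.log_KAl - constants.s_al * pH  # mol/L, activity=conc
    al3 = 10.0 ** log_al3
    # [Al(OH)n] = *β_n [Al3+] / [H+]^n;  log form avoids under/overflow
    aloh2 = 10.0 ** (b1 + log_al3 + pH)
    aloh2p = 10.0 ** (b2 + log_al3 + 2.0 * pH)
    aloh4 = 10.0 ** (b4 + log_al3 + 4.0 * pH)
    to_ueq = 1e6
    return AluminumSpecies(
        al3=3.0 * al3 * to_ueq,
        aloh2=2.0 * aloh2 * to_ueq,
        aloh2p=aloh2p * to_ueq,
        aloh4=aloh4 * to_ueq,
    )


def carbonate_charge(pH, constants: EquilibriumConstants = DEFAULT_CONSTANTS):
    """Bicarbonate charge (μeq/L) in equilibrium with the configured pCO2.

    [HCO3-] = K1 * kH * pCO2 / [H+]; carbonate ion is neglected (negligible
    below pH ~8.3 at these CO2 pressures).
    """
    k1kh_pco2 = 10.0 ** (-constants.carbonic_pK1 + constants.henry_kH) * constants.pco2_atm
    return k1kh_pco2 * 10.0 ** np.asarray(pH, dtype=float) * 1e6 if np.ndim(pH) else (
        k1kh_pco2 * 10.0 ** pH * 1e6
    )


def organic_acid_charge(
    pH, toc: float, constants: EquilibriumConstants = DEFAULT_CONSTANTS
):
    """Organic anion charge ΣOA = [H2A-] + 2[HA2-] + 3[A3-] (μeq/L).

    The total charge-site pool is ``oa_site_density * toc`` μeq/L, i.e. the
    full-dissociation bound; the triprotic acid concentration is one third
    of that.  Dissociation follows the three configured pKs.
    """
    if toc < 0:
        raise SpeciationError("toc must be nonnegative")
    sites = constants.oa_site_density * toc  # μeq/L at full dissociation
    if sites == 0:
        return np.zeros_like(np.asarray(pH, dtype=float)) if np.ndim(pH) else 0.0
    h = 10.0 ** (-np.asarray(pH, dtype=float))
    k1 = 10.0 ** -constants.oa_pK1
    k2 = 10.0 ** -constants.oa_pK2
    k3 = 10.0 ** -constants.oa_pK3
    denom = h**3 + k1 * h**2 + k1 * k2 * h + k1 * k2 * k3
    charge_per_mol = (k1 * h**2 + 2 * k1 * k2 * h + 3 * k1 * k2 * k3) / denom
    out = (sites / 3.0) * charge_per_mol
    return out if np.ndim(pH) else float(out)


def charge_balance_residual(
    pH,
    comp: IonComposition,
    constants: EquilibriumConstants = DEFAULT_CONSTANTS,
):
    """Signed charge imbalance (μeq/L) at a trial pH.

    residual = (H+ + BC + cationic Al) - (SAA + HCO3- + OH- + Al(OH)4- + ΣOA).
    Every pH-dependent term moves the residual downward as pH rises, so the
    residual is strictly decreasing and the charge-balance root is unique.
    """
    pH_arr = np.asarray(pH, dtype=float)
    h = 10.0 ** (-pH_arr) * 1e6
    oh = 10.0 ** (pH_arr - constants.water_pKw) * 1e6
    hco3 = carbonate_charge(pH_arr, constants)
    oa = organic_acid_charge(pH_arr, comp.toc, constants)
    if constants.al_enabled:
        b1, b2, b4 = constants.al_hydrolysis
        log_al3 = constants.log_KAl - constants.s_al * pH_arr
        al_cat = (
            3.0 * 10.0 ** log_al3
            + 2.0 * 10.0 ** (b1 + log_al3 + pH_arr)
            + 10.0 ** (b2 + log_al3 + 2.0 * pH_arr)
        ) * 1e6
        aloh4 = 10.0 ** (b4 + log_al3 + 4.0 * pH_arr) * 1e6
    else:
        al_cat = np.zeros_like(pH_arr)
        aloh4 = np.zeros_like(pH_arr)
    res = (
        h
        + comp.base_cations
        + al_cat
        - comp.strong_acid_anions
        - hco3
        - oh
        - aloh4
        - oa
    )
    return res if np.ndim(pH) else float(res)


def _speciate_at(pH: float, comp: IonComposition, constants: EquilibriumConstants) -> SpeciationResult:
    al = aluminum_speciation(pH, constants) if 2.0 <= pH <= 12.0 else AluminumSpecies(0, 0, 0, 0)
    return SpeciationResult(
        pH=pH,
        h=10.0 ** (-pH) * 1e6,
        oh=10.0 ** (pH - constants.water_pKw) * 1e6,
        hco3=carbonate_charge(pH, constants),
        al3=al.al3,
        aloh2=al.aloh2,
        aloh2p=al.aloh2p,
        aloh4=al.aloh4,
        al_i_mass=al.al_i_mass,
        oa_charge=organic_acid_charge(pH, comp.toc, constants),
        residual=charge_balance_residual(pH, comp, constants),
    )


def solve_pH(
    comp: IonComposition,
    constants: EquilibriumConstants = DEFAULT_CONSTANTS,
    tolerance: float = DEFAULT_TOLERANCE,
    lake_id: str | None = None,
) -> SpeciationResult:
    """Solve the charge balance for pH by bisection on [3, 10].

    The residual is strictly decreasing in pH, so bisection converges to the
    unique root.  Iterates until the absolute residual is within
    ``tolerance`` (μeq/L).  Raises :class:`UnsolvableCompositionError`,
    naming the lake if given, when the residual does not change sign on the
    bracket.
    """
    lo, hi = PH_BRACKET
    r_lo = charge_balance_residual(lo, comp, constants)
    r_hi = charge_balance_residual(hi, comp, constants)
    if r_lo < 0 or r_hi > 0:
        raise UnsolvableCompositionError(
            f"charge-balance residual has no sign change on pH bracket {PH_BRACKET} "
            f"(residual({lo})={r_lo:.3g}, residual({hi})={r_hi:.3g} μeq/L)",
            lake_id=lake_id,
        )
    mid = 0.5 * (lo + hi)
    for _ in range(200):
        r_mid = charge_balance_residual(mid, comp, constants)
        if abs(r_mid) <= tolerance:
            break
        if r_mid > 0:
            lo = mid
        else:
            hi = mid
        new_mid = 0.5 * (lo + hi)
        if new_mid == mid:  # bracket exhausted at float precision
            break
        mid = new_mid
    return _speciate_at(mid, comp, constants)
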