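"""Calibration of the gibbsite solubility constant and Al toxicity curves.

The speciation model is tied to an observed pH by adjusting the single free
parameter ``log_KAl`` of the aluminum solid phase.  Most lakes do not need
any adjustment: at circumneutral pH the aluminum terms are a vanishing part
of the charge balance, so the solved pH is insensitive to K_Al and the
default constant is kept (flagged as insensitive rather than fitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .speciation import (
    DEFAULT_CONSTANTS,
    DEFAULT_TOLERANCE,
    EquilibriumConstants,
    IonComposition,
    SpeciationError,
    aluminum_speciation,
    solve_pH,
)

__all__ = [
    "CalibrationResult",
    "calibrate_KAl",
    "al_toxicity_curve",
    "DEFAULT_KAL_BOUNDS",
    "DEFAULT_KAL_SPREAD",
    "AL_I_CRITICAL",
]

#: Calibration bounds for log K_Al: the median 8.1 +/- half the 2.4 spread.
DEFAULT_KAL_BOUNDS = (6.9, 9.3)

#: log K_Al values used for the toxicity curve family (median and the
#: endpoints of the total spread of 2.4).
DEFAULT_KAL_SPREAD = (6.9, 8.1, 9.3)

#: Critical cationic inorganic-aluminum level for roach, μg/L.
AL_I_CRITICAL = 50.0

#: Minimum pH response (across the full K_Al bounds) for the solved pH to be
#: considered sensitive to K_Al at all.
SENSITIVITY_FLOOR = 0.01


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a K_Al calibration against an observed pH."""

    log_KAl: float
    modeled_pH: float
    observed_pH: float
    converged: bool
    insensitive: bool
    message: str = ""

    @property
    def is_default(self) -> bool:
        return self.log_KAl == DEFAULT_CONSTANTS.log_KAl


def calibrate_KAl(
    comp: IonComposition,
    observed_pH: float,
    constants: EquilibriumConstants = DEFAULT_CONSTANTS,
    bounds: tuple[float, float] = DEFAULT_KAL_BOUNDS,
    tolerance: float = 0.005,
) -> CalibrationResult:
    """Adjust log K_Al within ``bounds`` so the solved pH matches ``observed_pH``.

    Returns the default constant with ``insensitive=True`` when the solved pH
    barely responds to K_Al over the whole bounds (high-pH lakes, where the
    aluminum terms are negligible), and a non-converged report — not an
    exception — when the observed pH is unattainable within the bounds.
    ``tolerance`` is the accepted |modeled - observed| pH mismatch.
    """
    if not (3.0 <= observed_pH <= 10.0):
        raise SpeciationError(f"observed pH {observed_pH} outside [3, 10]")
    lo, hi = bounds
    if not lo < hi:
        raise SpeciationError("calibration bounds must be ordered")

    def modeled(log_kal: float) -> float:
        return solve_pH(comp, constants.with_(log_KAl=log_kal)).pH

    ph_lo, ph_hi = modeled(lo), modeled(hi)
    default_ph = modeled(constants.log_KAl)

    if abs(ph_hi - ph_lo) < SENSITIVITY_FLOOR:
        return CalibrationResult(
            log_KAl=constants.log_KAl,
            modeled_pH=default_ph,
            observed_pH=observed_pH,
            converged=abs(default_ph - observed_pH) <= tolerance,
            insensitive=True,
            message="solved pH insensitive to K_Al; default retained",
        )
    if abs(default_ph - observed_pH) <= tolerance:
        return CalibrationResult(
            log_KAl=constants.log_KAl,
            modeled_pH=default_ph,
            observed_pH=observed_pH,
            converged=True,
            insensitive=False,
            message="default K_Al already reproduces observed pH",
        )
    # More dissolving Al (larger K_Al) adds cationic charge and raises the
    # solved pH, so modeled pH is increasing in log_KAl.
    if not (min(ph_lo, ph_hi) - tolerance <= observed_pH <= max(ph_lo, ph_hi) + tolerance):
        return CalibrationResult(
            log_KAl=constants.log_KAl,
            modeled_pH=default_ph,
            observed_pH=observed_pH,
            converged=False,
            insensitive=False,
            message=(
                f"observed pH {observed_pH} unattainable within log_KAl bounds "
                f"{bounds} (modeled range {min(ph_lo, ph_hi):.3f}-{max(ph_lo, ph_hi):.3f})"
            ),
        )
    fitted = brentq(lambda k: modeled(k) - observed_pH, lo, hi, xtol=1e-6)
    return CalibrationResult(
        log_KAl=float(fitted),
        modeled_pH=modeled(float(fitted)),
        observed_pH=observed_pH,
        converged=True,
        insensitive=False,
        message="fitted",
    )


def al_toxicity_curve(
    constants: EquilibriumConstants = DEFAULT_CONSTANTS,
    pH_grid: np.ndarray | None = None,
    kal_values: tuple[float, ...] = DEFAULT_KAL_SPREAD,
    critical: float = AL_I_CRITICAL,
):
    """Tabulate cationic Al_i mass against pH for a family of K_Al values.

    Returns ``(table, crossings)`` where ``table`` is a pandas DataFrame with
    columns ``log_KAl, pH, al_i_mass`` and ``crossings`` maps each log K_Al
    to the largest pH at which Al_i still reaches ``critical`` μg/L (None if
    the curve never reaches it on the grid).
    """
    import pandas as pd

    if pH_grid is None:
        pH_grid = np.arange(3.5, 8.0 + 1e-9, 0.01)
    pH_grid = np.asarray(pH_grid, dtype=float)
    if pH_grid.min() < 3.5 - 1e-9 or pH_grid.max() > 8.0 + 1e-9:
        raise SpeciationError("pH grid must lie within [3.5, 8]")

    frames = []
    crossings: dict[float, float | None] = {}
    for kal in kal_values:
        consts = constants.with_(log_KAl=kal)
        mass = np.array([aluminum_speciation(p, consts).al_i_mass for p in pH_grid])
        frames.append(
            pd.DataFrame({"log_KAl": kal, "pH": pH_grid, "al_i_mass": mass})
        )
        f = lambda p: aluminum_speciation(p, consts).al_i_mass - critical
        if mass[0] < critical:
            crossings[kal] = None
        elif mass[-1] >= critical:
            crossings[kal] = float(pH_grid[-1])
        else:
            crossings[kal] = float(brentq(f, pH_grid[0], pH_grid[-1], xtol=1e-8))
    return pd.concat(frames, ignore_index=True), crossings
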