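"""Spray-dried powder quality-control equations and the formulation mass
balance.

Implements the standard microencapsulation bench metrics:

* moisture content, MC = (m_i - m_d)/m_i x 100
* water solubility from a dried supernatant aliquot (blank-corrected,
  dilution factor dispersion/aliquot)
* encapsulation efficiency, EE = (total oil - surface oil)/total oil x 100
* bulk density (m/V) and tapped density (m/V_f with a <1% convergence rule
  on the tapping series)
* Carr's Compressibility Index CI = (rho_t - rho_b)/rho_t x 100 and
  Hausner Ratio HR = rho_t/rho_b
* feed mass balance of an emulsion recipe: dry solids, feed solids
  fraction, and the oil mass fraction m_oil of the dry matrix
* lipid-core analyte concentration c_core = c_powder / m_oil

All replicate reporting follows the per-replicate convention: evaluate each
formula on each analytical replicate, then average — which for the
nonlinear quantities (EE, CI, HR) differs from evaluating the formula at
the replicate means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .errors import AssayInconsistencyError, ConvergenceError

__all__ = [
    "FormulationRecipe",
    "MassBalance",
    "FlowabilityResult",
    "moisture_content",
    "solubility",
    "encapsulation_efficiency",
    "bulk_density",
    "tapped_density",
    "flowability_indices",
    "formulation_mass_balance",
    "core_concentration",
    "g_ml_to_kg_m3",
    "round_half_up",
    "summarize_replicates",
]


@dataclass(frozen=True)
class FormulationRecipe:
    """Component masses of one emulsion batch.

    ``solutions`` is a list of (mass_g, solid_fraction) pairs for the aqueous
    polymer solutions (e.g. two 133 g portions of 15% w/w solution).
    """

    oil_mass: float
    emulsifier_mass: float
    solutions: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if self.oil_mass < 0 or self.emulsifier_mass < 0:
            raise ValueError("masses must be >= 0")
        for m, f in self.solutions:
            if m < 0:
                raise ValueError("solution masses must be >= 0")
            if not (0 <= f <= 1):
                raise ValueError("solid fractions must be in [0, 1]")


@dataclass(frozen=True)
class MassBalance:
    dry_solids: float          # g
    total_feed_mass: float     # g
    feed_solids_fraction: float
    m_oil: float               # oil fraction of the dry matrix


@dataclass(frozen=True)
class FlowabilityResult:
    rho_b: float
    rho_t: float
    carr_index: float   # percent
    hausner_ratio: float


def moisture_content(m_initial: float, m_dried: float) -> float:
    """Moisture percent from oven drying: (m_i - m_d)/m_i x 100."""
    if m_dried > m_initial:
        raise AssayInconsistencyError(
            f"dried mass {m_dried} g exceeds initial mass {m_initial} g"
        )
    if m_initial <= 0:
        raise ValueError("initial mass must be positive")
    return (m_initial - m_dried) / m_initial * 100.0


def solubility(
    residue_mass: float,
    powder_mass: float = 0.100,
    blank_residue: float = 0.0,
    dispersion_mass: float = 25.0,
    aliquot_mass: float = 10.0,
) -> float:
    """Water solubility percent of the initially added powder.

    The blank residue is subtracted from the aliquot residue before scaling
    by the dilution factor (dispersion/aliquot, 2.5 for the standard
    25 g / 10 g protocol).  A negative blank-corrected residue is floored at
    zero with a warning.
    """
    if powder_mass <= 0 or dispersion_mass <= 0 or aliquot_mass <= 0:
        raise ValueError("masses must be positive")
    if aliquot_mass > dispersion_mass:
        raise ValueError("aliquot cannot exceed the dispersion mass")
    corrected = residue_mass - blank_residue
    if corrected < 0:
        warnings.warn(
            "blank-corrected residue is negative; flooring at 0", stacklevel=2
        )
        corrected = 0.0
    return corrected * (dispersion_mass / aliquot_mass) / powder_mass * 100.0


def encapsulation_efficiency(surface_oil: float, total_oil: float) -> float:
    """EE percent = (total - surface)/total x 100."""
    if total_oil == 0:
        raise AssayInconsistencyError("total oil is zero; EE undefined")
    if surface_oil < 0 or total_oil < 0:
        raise ValueError("oil masses must be >= 0")
    if surface_oil > total_oil:
        raise AssayInconsistencyError(
            f"surface oil {surface_oil} exceeds total oil {total_oil}"
        )
    return (total_oil - surface_oil) / total_oil * 100.0


def bulk_density(mass_g: float, volume_ml: float) -> float:
    """Bulk density in g/mL from loosely poured powder."""
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    return mass_g / volume_ml


def tapped_density(mass_g: float, volume_series_ml) -> float:
    """Tapped density in g/mL from a settling series.

    Verifies that the last two readings differ by < 1% (relative), i.e. the
    tapping has converged, then returns m / V_f.
    """
    series = [float(v) for v in volume_series_ml]
    if len(series) < 2:
        raise ValueError("need at least two volume readings")
    if any(v <= 0 for v in series):
        raise ValueError("volumes must be positive")
    if any(b > a for a, b in zip(series, series[1:])):
        raise ValueError("tapping series must be non-increasing")
    rel = abs(series[-1] - series[-2]) / series[-2]
    if rel >= 0.01:
        raise ConvergenceError(
            f"tapping not converged: last relative change {rel * 100:.2f}% >= 1%"
        )
    return mass_g / series[-1]


def flowability_indices(rho_b: float, rho_t: float) -> FlowabilityResult:
    """Carr's Index and Hausner Ratio from bulk and tapped density.

    Units must match (both g/mL or both kg/m^3); the indices are unitless.
    If rho_t < rho_b (a mis-measured series) the values are still returned,
    with a warning.
    """
    if rho_b <= 0 or rho_t <= 0:
        raise ValueError("densities must be positive")
    if rho_t < rho_b:
        warnings.warn(
            "tapped density below bulk density: indices will be out of the "
            "physical range",
            stacklevel=2,
        )
    ci = (rho_t - rho_b) / rho_t * 100.0
    hr = rho_t / rho_b
    return FlowabilityResult(rho_b=rho_b, rho_t=rho_t, carr_index=ci,
                             hausner_ratio=hr)


def formulation_mass_balance(recipe: FormulationRecipe) -> MassBalance:
    """Dry solids, total feed mass, feed solids fraction, and the oil mass
    fraction of the dry matrix."""
    solution_solids = sum(m * f for m, f in recipe.solutions)
    solution_mass = sum(m for m, _ in recipe.solutions)
    dry = recipe.oil_mass + recipe.emulsifier_mass + solution_solids
    total = recipe.oil_mass + recipe.emulsifier_mass + solution_mass
    if total <= 0:
        raise ValueError("recipe has zero total mass")
    m_oil = recipe.oil_mass / dry if dry > 0 else 0.0
    return MassBalance(
        dry_solids=dry,
        total_feed_mass=total,
        feed_solids_fraction=dry / total,
        m_oil=m_oil,
    )


def core_concentration(c_powder: float, m_oil: float) -> float:
    """Analyte concentration in the lipid core (per g oil) from its powder
    concentration (per g powder) and the dry-matrix oil mass fraction."""
    if not (0 < m_oil <= 1):
        raise ValueError("m_oil must be in (0, 1]")
    if c_powder < 0:
        raise ValueError("c_powder must be >= 0")
    return c_powder / m_oil


def g_ml_to_kg_m3(rho_g_ml: float) -> float:
    """Exact unit conversion g/mL -> kg/m^3 (x1000)."""
    return rho_g_ml * 1000.0


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up rounding for report tables (numpy/python round half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_replicates(values) -> tuple[float, float, int]:
    """Mean, sample SD (n-1), and n of per-replicate metric values — the
    canonical reporting path for triplicate assays."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)
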