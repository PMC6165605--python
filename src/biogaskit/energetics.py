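"""Stoichiometric gas composition and pretreatment energy balance.

The Buswell/Boyle equation predicts the CH4/CO2 split of biogas from the
elemental composition CcHhOoNnSs of the feedstock:

    CcHhOoNnSs + (4c-h-2o+3n+2s)/4 H2O ->
        (4c-h+2o+3n+2s)/8 CO2 + (4c+h-2o-3n-2s)/8 CH4 + n NH3 + s H2S

where c..s are molar amounts.  The energy side converts specific methane
volume to energy via the lower heating value of methane (33 kJ/L at 25 degC
and 1.01 bar) and compares it with the sensible heat needed to warm the
pretreatment water, m_w * c_w * dT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "UltimateAnalysis",
    "StoichiometryResult",
    "EnergyBalance",
    "boyle_composition",
    "methane_volume",
    "round_half_up",
    "biogas_energy",
    "heating_energy",
    "net_energy",
]

# IUPAC 2021 standard atomic weights; the integer values many elemental-
# analysis papers use are available via integer_masses=True.
_ATOMIC_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "S": 32.06}
_ATOMIC_MASSES_INTEGER = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0, "S": 32.0}


@dataclass(frozen=True)
class UltimateAnalysis:
    """Elemental mass fractions of dry matter, in percent."""

    carbon: float
    hydrogen: float
    nitrogen: float
    oxygen: float
    sulphur: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.carbon, self.hydrogen, self.nitrogen, self.oxygen, self.sulphur)
        if any(v < 0 for v in vals):
            raise ValueError("mass fractions must be non-negative")
        if sum(vals) > 100.5:
            raise ValueError("mass fractions sum above 100% beyond rounding tolerance")


@dataclass(frozen=True)
class StoichiometryResult:
    """Molar composition and predicted gas split per 100 g dry matter."""

    molar_c: float
    molar_h: float
    molar_o: float
    molar_n: float
    molar_s: float
    ch4_coefficient: float
    co2_coefficient: float

    @property
    def ch4_fraction(self) -> float:
        return self.ch4_coefficient / (self.ch4_coefficient + self.co2_coefficient)


@dataclass(frozen=True)
class EnergyBalance:
    """Biogas energy versus pretreatment heat input, kJ per kg initial VS."""

    biogas_energy_kj: float
    heating_energy_kj: float

    @property
    def net_kj(self) -> float:
        return self.biogas_energy_kj - self.heating_energy_kj

    @property
    def verdict(self) -> str:
        return "negative" if self.net_kj < 0 else "positive"


def boyle_composition(ua: UltimateAnalysis, integer_masses: bool = False) -> StoichiometryResult:
    """Predict the CH4/CO2 split from an ultimate analysis.

    ``integer_masses`` switches from IUPAC atomic masses to the integer masses
    (12, 1, 16, 14, 32) commonly used in hand calculations.
    """
    if ua.carbon <= 0:
        raise ValueError("carbon fraction must be positive")
    masses = _ATOMIC_MASSES_INTEGER if integer_masses else _ATOMIC_MASSES
    c = ua.carbon / masses["C"]
    h = ua.hydrogen / masses["H"]
    o = ua.oxygen / masses["O"]
    n = ua.nitrogen / masses["N"]
    s = ua.sulphur / masses["S"]
    ch4 = (4 * c + h - 2 * o - 3 * n - 2 * s) / 8.0
    co2 = (4 * c - h + 2 * o + 3 * n + 2 * s) / 8.0
    if ch4 < 0 or co2 < 0:
        raise ValueError(
            "negative stoichiometric coefficient: composition is not digestible "
            "under the Buswell/Boyle model"
        )
    return StoichiometryResult(c, h, o, n, s, ch4, co2)


def methane_volume(biogas_yield_ml_per_gvs: float, ch4_fraction: float) -> float:
    """Specific methane volume (mL/g VS) given a volumetric CH4 fraction."""
    if not 0.0 <= ch4_fraction <= 1.0:
        raise ValueError("ch4_fraction must lie in [0, 1]")
    return biogas_yield_ml_per_gvs * ch4_fraction


def round_half_up(x: float) -> int:
    """Report-style rounding: halves round away from zero, not to even."""
    return int(math.floor(x + 0.5))


def biogas_energy(methane_volume_l_per_kgvs: float, lhv_kj_per_l: float = 33.0) -> float:
    """Energy in the produced methane, kJ per kg initial VS."""
    if methane_volume_l_per_kgvs < 0 or lhv_kj_per_l < 0:
        raise ValueError("inputs must be non-negative")
    return methane_volume_l_per_kgvs * lhv_kj_per_l


def heating_energy(
    target_temp_c: float,
    water_mass_kg_per_kgvs: float = 367.0,
    specific_heat_kj_per_kg_c: float = 4.2,
    start_temp_c: float = 30.0,
) -> float:
    """Sensible heat to warm the pretreatment water, kJ per kg initial VS.

    m_w * c_w * (T_target - T_start); defaults are 367 kg water per kg VS,
    4.2 kJ/kg/degC and a 30 degC starting temperature.
    """
    if target_temp_c < start_temp_c:
        raise ValueError("target temperature must not be below start temperature")
    return water_mass_kg_per_kgvs * specific_heat_kj_per_kg_c * (target_temp_c - start_temp_c)


def net_energy(biogas_energy_kj: float, heating_energy_kj: float) -> EnergyBalance:
    """Net specific energy gain/loss of a pretreatment; net >= 0 is 'positive'."""
    return EnergyBalance(biogas_energy_kj, heating_energy_kj)
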