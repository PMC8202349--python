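"""Closed-vial CH4 accounting for microcosms and pore-water vials.

Headspace CH4 mass follows the ideal gas law, n = f p V / (R T), with f
the CH4 headspace volume fraction.  Pore-water CH4 adds the dissolved
phase through Henry's law (c = K_H p_CH4) so that, at equilibrium, total
CH4 in the extraction vial equals the CH4 originally carried by the
extracted pore water.  Potential oxidation rates come from an ordinary
least-squares fit of headspace mass against time in a closed microcosm:
a zero-order (linear) consumption model, reported per gram of dry soil
and day.

Units: volumes mL (converted to L internally), temperatures degC in the
specs (K internally), pressures atm, masses ug, rates ug g^-1 d^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class GasConstants:
    R: float = 0.082057          # L atm mol^-1 K^-1
    henry_KH: float = 1.4e-3     # mol L^-1 atm^-1, CH4 in water at 21 degC
    M_CH4: float = 16.04         # g mol^-1

    def __post_init__(self) -> None:
        if min(self.R, self.henry_KH, self.M_CH4) <= 0:
            raise ValueError("gas constants must be positive")


@dataclass(frozen=True)
class MicrocosmSpec:
    """Closed serum-bottle incubation: ~15 g wet peat in a 175-mL bottle
    with 34 mL added air and 1 mL injected CH4, incubated at 8 degC."""

    bottle_volume: float = 175.0   # mL
    soil_wet_mass: float = 15.0    # g
    soil_density: float = 1.0      # g/mL
    water_content: float = 0.9     # wet-mass fraction
    added_air: float = 34.0        # mL
    injected_ch4: float = 1.0      # mL
    incubation_temp: float = 8.0   # degC
    measurement_temp: float = 21.0  # degC (GC lab temperature)
    pressure: float = 1.0          # atm

    def __post_init__(self) -> None:
        if self.headspace_volume_ml <= 0:
            raise ValueError("non-positive headspace volume")
        if not 0.0 <= self.water_content < 1.0:
            raise ValueError("water_content must be in [0, 1)")

    @property
    def headspace_volume_ml(self) -> float:
        """Gas volume: bottle minus soil plus the added air and CH4."""
        return (self.bottle_volume - self.soil_wet_mass / self.soil_density
                + self.added_air + self.injected_ch4)

    @property
    def dry_mass(self) -> float:
        return self.soil_wet_mass * (1.0 - self.water_content)

    @property
    def initial_ch4_fraction(self) -> float:
        """Headspace CH4 volume fraction right after injecting pure CH4."""
        return self.injected_ch4 / self.headspace_volume_ml


@dataclass(frozen=True)
class VialSpec:
    """Pore-water extraction vial: 5 mL pore water in a 20-mL N2-flushed
    serum vial, equilibrated at room temperature."""

    vial_volume: float = 20.0   # mL
    water_volume: float = 5.0   # mL
    temp: float = 21.0          # degC
    pressure: float = 1.0       # atm

    def __post_init__(self) -> None:
        if not 0 < self.water_volume < self.vial_volume:
            raise ValueError("need 0 < water_volume < vial_volume")


@dataclass
class GasTimeSeries:
    """Headspace CH4 volume fractions at strictly increasing timepoints (h)."""

    timepoints: Sequence[float]
    ch4_fraction: Sequence[float]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        f = np.asarray(self.ch4_fraction, dtype=float)
        if t.size != f.size or t.size < 2:
            raise ValueError("need >= 2 matching timepoints")
        if not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if (f < 0).any():
            raise ValueError("negative fractions")
        self.timepoints = t
        self.ch4_fraction = f


def headspace_ch4_mass(
    fraction: float,
    volume_l: float,
    temp_k: float,
    pressure_atm: float = 1.0,
    c: GasConstants = GasConstants(),
) -> float:
    """Mass (ug) of CH4 in a headspace of ``volume_l`` litres at a given
    CH4 volume fraction, by the ideal gas law."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if min(volume_l, temp_k, pressure_atm) <= 0:
        raise ValueError("volume, temperature and pressure must be positive")
    mol = fraction * pressure_atm * volume_l / (c.R * temp_k)
    return mol * c.M_CH4 * 1e6


def porewater_ch4_concentration(
    vial: VialSpec, headspace_fraction: float, c: GasConstants = GasConstants()
) -> float:
    """CH4 concentration (mol/L) of the original pore water.

    The equilibrated vial holds CH4 in two phases: headspace gas
    (f p V_hs / RT by the ideal gas law) and dissolved gas
    (K_H * f p * V_water by Henry's law).  Their sum divided by the
    extracted pore-water volume is the in situ concentration.
    """
    if headspace_fraction < 0:
        raise ValueError("negative fraction")
    v_head = (vial.vial_volume - vial.water_volume) / 1000.0
    v_water = vial.water_volume / 1000.0
    p_ch4 = headspace_fraction * vial.pressure
    t_k = vial.temp + CELSIUS_OFFSET
    mol_gas = p_ch4 * v_head / (c.R * t_k)
    mol_dissolved = c.henry_KH * p_ch4 * v_water
    return (mol_gas + mol_dissolved) / v_water


@dataclass(frozen=True)
class OxidationRate:
    rate: float      # ug CH4 per g dry soil per day (consumption positive)
    slope: float     # ug per hour (negative while CH4 is consumed)
    r_squared: float


def oxidation_rate(
    series: GasTimeSeries,
    m: MicrocosmSpec = MicrocosmSpec(),
    c: GasConstants = GasConstants(),
) -> OxidationRate:
    """Potential CH4 oxidation rate from a closed-microcosm time series.

    Each headspace fraction is converted to a CH4 mass via the ideal gas
    law at the measurement temperature; the OLS slope of mass vs time
    (ug/h) is scaled to ug per g dry soil per day, consumption positive.
    """
    if m.dry_mass <= 0:
        raise ValueError("zero dry soil mass")
    t = series.timepoints
    v_l = m.headspace_volume_ml / 1000.0
    t_k = m.measurement_temp + CELSIUS_OFFSET
    masses = np.array([
        headspace_ch4_mass(f, v_l, t_k, m.pressure, c) for f in series.ch4_fraction
    ])
    slope, intercept = np.polyfit(t, masses, 1)
    fitted = slope * t + intercept
    ss_tot = float(((masses - masses.mean()) ** 2).sum())
    ss_res = float(((masses - fitted) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rate = -slope * 24.0 / m.dry_mass
    return OxidationRate(rate=float(rate), slope=float(slope), r_squared=float(r2))


def water_content(wet_mass: float, dry_mass: float) -> float:
    """Gravimetric water content in percent of wet mass."""
    if not 0 < dry_mass <= wet_mass:
        raise ValueError("need 0 < dry_mass <= wet_mass")
    return (wet_mass - dry_mass) / wet_mass * 100.0


def soil_organic_matter(dry_mass: float, ash_mass: float) -> float:
    """Loss on ignition in percent of dry mass."""
    if dry_mass <= 0 or not 0 <= ash_mass <= dry_mass:
        raise ValueError("need 0 <= ash_mass <= dry_mass, dry_mass > 0")
    return (dry_mass - ash_mass) / dry_mass * 100.0
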