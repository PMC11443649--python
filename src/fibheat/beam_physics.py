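"""Closed-form ion-beam arithmetic and the Fourier-law spot-heating model.

A focused ion beam delivers ``I / e`` ions per second.  Each ion of incident
energy ``E`` deposits a material- and energy-dependent fraction of ``E`` as
heat (nuclear/phonon plus electronic/ionization losses, tabulated per incident
energy in a :class:`StoppingRecord`).  Treating the irradiated spot as a disc
of diameter ``d_eff`` feeding heat through a slab of thickness equal to the
projected range ``R_proj`` into a material of conductivity ``k``, Fourier's
law gives the steady-state spot temperature rise

    dT = P * R_proj / (k * A_spot),      P = (heat loss per ion) * I / e,
                                         A_spot = pi * (d_eff / 2)**2.

Numerically ``P`` in watts equals the per-ion heat loss in eV times the beam
current in amperes.  All quantities here are scalars in SI units unless a
docstring says otherwise; dose bookkeeping follows the conventions of ion
microscopy (ions/cm^2, ions/us/nm^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

from .constants import ELEMENTARY_CHARGE, EV, ZERO_CELSIUS

__all__ = [
    "BeamPhysicsError",
    "StoppingRecord",
    "Material",
    "BeamSetting",
    "HeatingPrediction",
    "EnergyRatios",
    "arrival_rate",
    "mean_impact_interval",
    "impacts_in_window",
    "heat_flux",
    "effective_spot_diameter",
    "spot_area",
    "dose_rate",
    "dose",
    "delta_T_fourier",
    "predict_heating",
    "energy_ratios",
]

logger = logging.getLogger(__name__)


class BeamPhysicsError(ValueError):
    """Invalid beam-physics input (non-positive current, mismatched energies, ...)."""


@dataclass(frozen=True)
class StoppingRecord:
    """Per-ion energy bookkeeping for one incident ion energy.

    Values of this kind come from binary-collision Monte Carlo codes (SRIM/TRIM
    style): for each incident ion the mean energy routed to phonons and to
    ionization, the projected range, the sputter yield and the stopping power.
    The total heat loss per ion is ``phonon_loss + ionization_loss`` (held as a
    derived property so the bookkeeping identity cannot be violated).

    Parameters
    ----------
    energy : float
        Incident ion energy [keV].
    phonon_loss : float
        Per-ion energy lost to phonons [keV].
    ionization_loss : float
        Per-ion energy lost to ionization [keV].
    range_proj : float
        Projected range R_proj [m].
    sputter_yield : float
        Sputtered target atoms per incident ion [dimensionless].
    stopping_power : float
        Deposited energy per unit depth [eV/Angstrom].
    """

    energy: float
    phonon_loss: float
    ionization_loss: float
    range_proj: float
    sputter_yield: float
    stopping_power: float

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise BeamPhysicsError(f"incident energy must be > 0 keV, got {self.energy}")
        if self.phonon_loss < 0 or self.ionization_loss < 0:
            raise BeamPhysicsError("energy losses must be non-negative")
        if not 0 < self.heat_loss <= self.energy:
            raise BeamPhysicsError(
                f"heat loss {self.heat_loss} keV must lie in (0, {self.energy}] keV"
            )
        if self.range_proj <= 0:
            raise BeamPhysicsError("projected range must be > 0")
        if self.sputter_yield < 0:
            raise BeamPhysicsError("sputter yield must be >= 0")

    @property
    def heat_loss(self) -> float:
        """Per-ion energy converted to heat (phonons + ionization) [keV]."""
        return self.phonon_loss + self.ionization_loss

    @property
    def heat_loss_joule(self) -> float:
        """Per-ion heat input [J]."""
        return self.heat_loss * 1e3 * EV


@dataclass(frozen=True)
class Material:
    """Thermal constants of the target.

    ``alpha`` is stored independently of ``k / (rho * c_p)``: tabulated
    diffusivities for biological tissue frequently disagree with the quotient
    of the individually tabulated constants (different sources, hydration
    states).  The diffusion solver uses ``alpha``; energy-to-temperature
    conversion uses ``rho * c_p``.  A mismatch beyond 5% is logged.

    Parameters
    ----------
    k : float
        Thermal conductivity [W/m/K].
    rho : float
        Density [kg/m^3].
    c_p : float
        Specific heat capacity [J/kg/K].
    alpha : float
        Thermal diffusivity [m^2/s].
    damage_temp : float, optional
        Damage threshold temperature [degC] (e.g. collagen denaturation ~65).
    name : str, optional
        Preset name, for reporting.
    """

    k: float
    rho: float
    c_p: float
    alpha: float
    damage_temp: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("k", "rho", "c_p", "alpha"):
            if getattr(self, attr) <= 0:
                raise BeamPhysicsError(f"material constant {attr} must be > 0")
        implied = self.k / (self.rho * self.c_p)
        if abs(implied - self.alpha) > 0.05 * self.alpha:
            logger.warning(
                "material %s: stated alpha=%.3g m^2/s differs from k/(rho*c_p)=%.3g; "
                "the stated alpha drives diffusion, rho*c_p drives energy conversion",
                self.name or "<unnamed>", self.alpha, implied,
            )

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c_p [J/m^3/K]."""
        return self.rho * self.c_p


@dataclass(frozen=True)
class BeamSetting:
    """One FIB column configuration.

    Parameters
    ----------
    energy : float
        Incident ion energy [keV].
    current : float
        Beam current [A].
    native_diameter : float
        Focused (unblurred) spot diameter [m].
    blur : float
        Deliberate defocus blur diameter [m]; 0 means focused.
    overlap : float, optional
        Scan-point overlap fraction.  Carried as metadata only; it does not
        enter any per-spot quantity computed here.
    dwell : float
        Per-point dwell time [s].
    """

    energy: float
    current: float
    native_diameter: float
    blur: float = 0.0
    overlap: Optional[float] = None
    dwell: float = 1e-6

    def __post_init__(self) -> None:
        if self.current <= 0:
            raise BeamPhysicsError(f"beam current must be > 0 A, got {self.current}")
        if self.native_diameter <= 0:
            raise BeamPhysicsError("native spot diameter must be > 0")
        if self.blur < 0:
            raise BeamPhysicsError("blur must be >= 0")
        if self.dwell <= 0:
            raise BeamPhysicsError("dwell time must be > 0")


class EnergyRatios(NamedTuple):
    """Ratios of two stopping records (record A relative to record B)."""

    heat: float          #: heat-loss ratio A/B
    sputter: float       #: sputter-yield ratio A/B
    speed_per_heat: float  #: heat ratio / sputter ratio — relative milling speed per unit heat


def arrival_rate(setting: BeamSetting) -> float:
    """Mean ion arrival rate I/e [ions/s]."""
    if setting.current <= 0:
        raise BeamPhysicsError("current must be > 0")
    return setting.current / ELEMENTARY_CHARGE


def mean_impact_interval(setting: BeamSetting) -> float:
    """Mean time between successive ion impacts e/I [s]."""
    return 1.0 / arrival_rate(setting)


def impacts_in_window(setting: BeamSetting, window: float) -> int:
    """Number of equal-interval impacts within ``window`` seconds, first at t=0."""
    if window < 0:
        raise BeamPhysicsError("window must be >= 0")
    return int(math.floor(window * arrival_rate(setting))) + 1


def heat_flux(stopping: StoppingRecord, setting: BeamSetting) -> float:
    """Total heat power entering the sample [W].

    Per-ion heat loss [J] times arrival rate; numerically the per-ion heat
    loss in eV times the current in A.
    """
    if stopping.energy != setting.energy:
        raise BeamPhysicsError(
            f"stopping record is for {stopping.energy} keV but the beam is set "
            f"to {setting.energy} keV"
        )
    return stopping.heat_loss_joule * arrival_rate(setting)


def effective_spot_diameter(setting: BeamSetting) -> float:
    """Effective (heat-receiving) spot diameter [m]: max(native, blur).

    Deliberate defocus enlarges the footprint only once the blur disc exceeds
    the focused spot; otherwise the native diameter governs.
    """
    return max(setting.native_diameter, setting.blur)


def spot_area(setting: BeamSetting) -> float:
    """Effective spot area pi*(d_eff/2)^2 [m^2]."""
    d = effective_spot_diameter(setting)
    return math.pi * (d / 2.0) ** 2


def dose_rate(setting: BeamSetting) -> float:
    """Areal ion arrival rate [ions/us/nm^2]."""
    per_us = arrival_rate(setting) * 1e-6
    area_nm2 = spot_area(setting) * 1e18
    return per_us / area_nm2


def dose(setting: BeamSetting) -> float:
    """Areal dose accumulated over one dwell [ions/cm^2]."""
    area_cm2 = spot_area(setting) * 1e4
    return arrival_rate(setting) * setting.dwell / area_cm2


def delta_T_fourier(
    stopping: StoppingRecord, setting: BeamSetting, material: Material
) -> float:
    """Steady-state spot temperature rise [K] from the Fourier-law slab model.

    dT = P * R_proj / (k * A_spot) — heat flux P through a slab of thickness
    R_proj under the effective spot disc.
    """
    area = spot_area(setting)
    if area <= 0:
        raise BeamPhysicsError("effective spot area must be > 0")
    return heat_flux(stopping, setting) * stopping.range_proj / (material.k * area)


@dataclass(frozen=True)
class HeatingPrediction:
    """All derived per-spot quantities for one beam setting.

    Fields mirror the columns of a beam-parameter comparison table.
    """

    heat_flux: float        #: total heat power entering the sample [W]
    impact_interval: float  #: mean time between ions [s]
    impacts_per_ns: float   #: arrival rate [1/ns]
    dose_rate: float        #: [ions/us/nm^2]
    dose: float             #: per-dwell dose [ions/cm^2]
    delta_T: float          #: steady-state temperature rise [K]

    def damage_predicted(self, material: Material, ambient_c: float = 25.0) -> Optional[bool]:
        """Whether ambient + dT reaches the material damage threshold (None if no threshold)."""
        if material.damage_temp is None:
            return None
        return ambient_c + self.delta_T >= material.damage_temp


def predict_heating(
    stopping: StoppingRecord, setting: BeamSetting, material: Material
) -> HeatingPrediction:
    """Evaluate every closed-form quantity for one beam setting."""
    return HeatingPrediction(
        heat_flux=heat_flux(stopping, setting),
        impact_interval=mean_impact_interval(setting),
        impacts_per_ns=arrival_rate(setting) * 1e-9,
        dose_rate=dose_rate(setting),
        dose=dose(setting),
        delta_T=delta_T_fourier(stopping, setting, material),
    )


def energy_ratios(rec_a: StoppingRecord, rec_b: StoppingRecord) -> EnergyRatios:
    """Heat-loss and sputter-yield ratios of record A over record B.

    ``speed_per_heat`` is the quotient heat/sputter: how many times faster one
    can mill at the lower energy for the same heat budget (ions are cheaper in
    heat by the heat ratio but each removes fewer atoms by the sputter ratio).
    """
    if rec_b.heat_loss == 0 or rec_b.sputter_yield == 0 or rec_a.sputter_yield == 0:
        raise BeamPhysicsError("energy ratios need non-zero heat losses and sputter yields")
    heat = rec_a.heat_loss / rec_b.heat_loss
    sputter = rec_a.sputter_yield / rec_b.sputter_yield
    return EnergyRatios(heat=heat, sputter=sputter, speed_per_heat=heat / sputter)
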