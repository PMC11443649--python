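"""Built-in material and stopping-data presets, plus TOML loaders.

The stopping records are SRIM-derived per-ion energy bookkeeping for gallium
ions in human skin at the two incident energies of interest; the materials are
collagen/skin (the canonical thermally low-conductive biological target) and
amorphous/crystalline ice for cryo work.  A generic TOML loader is provided so
users can supply their own records without any SRIM file-format parsing.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Union

from .beam_physics import Material, StoppingRecord

__all__ = [
    "MATERIALS",
    "STOPPING_RECORDS",
    "get_material",
    "get_stopping",
    "load_material",
    "load_stopping",
]

#: Skin/collagen thermal constants; damage threshold = collagen denaturation (~65 degC).
#: Note the tabulated diffusivity exceeds k/(rho*c_p); both are kept (see Material docs).
SKIN_COLLAGEN = Material(
    k=0.29, rho=1079.0, c_p=3540.0, alpha=1.36e-7, damage_temp=65.0, name="skin_collagen"
)

#: Ice for cryo-FIB: conductivity 2-3 W/m/K (midpoint), standard ice density and
#: specific heat, diffusivity derived as k/(rho*c_p).
ICE_CRYO = Material(
    k=2.5, rho=917.0, c_p=2100.0, alpha=2.5 / (917.0 * 2100.0), damage_temp=None, name="ice_cryo"
)

MATERIALS = {
    "skin_collagen": SKIN_COLLAGEN,
    "ice_cryo": ICE_CRYO,
}

#: Ga+ in skin, 5 keV: 3.3 keV to phonons + 1.4 keV to ionization, R_proj = 154 A.
GA_5KEV = StoppingRecord(
    energy=5.0,
    phonon_loss=3.3,
    ionization_loss=1.4,
    range_proj=154e-10,
    sputter_yield=1.4,
    stopping_power=56.5,
)

#: Ga+ in skin, 30 keV: 17.1 keV to phonons + 11.8 keV to ionization, R_proj = 467 A.
GA_30KEV = StoppingRecord(
    energy=30.0,
    phonon_loss=17.1,
    ionization_loss=11.8,
    range_proj=467e-10,
    sputter_yield=2.9,
    stopping_power=83.8,
)

STOPPING_RECORDS = {
    "Ga_5keV": GA_5KEV,
    "Ga_30keV": GA_30KEV,
}


def get_material(name: str) -> Material:
    """Look up a material preset by name."""
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(MATERIALS)}"
        ) from None


def get_stopping(name_or_energy: Union[str, float]) -> StoppingRecord:
    """Look up a stopping record by preset name or by incident energy in keV."""
    if isinstance(name_or_energy, str):
        try:
            return STOPPING_RECORDS[name_or_energy]
        except KeyError:
            raise KeyError(
                f"unknown stopping record {name_or_energy!r}; "
                f"available: {sorted(STOPPING_RECORDS)}"
            ) from None
    for rec in STOPPING_RECORDS.values():
        if rec.energy == float(name_or_energy):
            return rec
    raise KeyError(f"no stopping record preset at {name_or_energy} keV")


def load_material(path: Union[str, Path]) -> Material:
    """Read a material from a flat TOML file (keys as in Material)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return Material(
        k=float(data["k"]),
        rho=float(data["rho"]),
        c_p=float(data["c_p"]),
        alpha=float(data["alpha"]),
        damage_temp=(float(data["damage_temp"]) if "damage_temp" in data else None),
        name=str(data.get("name", Path(path).stem)),
    )


def load_stopping(path: Union[str, Path]) -> StoppingRecord:
    """Read a stopping record from a flat TOML file (keys as in StoppingRecord)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return StoppingRecord(
        energy=float(data["energy"]),
        phonon_loss=float(data["phonon_loss"]),
        ionization_loss=float(data["ionization_loss"]),
        range_proj=float(data["range_proj"]),
        sputter_yield=float(data["sputter_yield"]),
        stopping_power=float(data["stopping_power"]),
    )
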