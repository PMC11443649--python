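"""Simulation output writers: ImageJ TIFF stacks, CSV traces, TOML sidecars."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Dict, Mapping, Union

import numpy as np
import pandas as pd
import tifffile

from .ftcs_sim import SimulationTrace, TemperatureField

__all__ = [
    "write_surface_stack",
    "write_field_stack",
    "write_trace_csv",
    "write_toml",
    "trace_metadata",
]


def write_surface_stack(trace: SimulationTrace, path: Union[str, Path]) -> None:
    """Write the stored surface planes as an ImageJ-compatible 32-bit TIFF stack.

    One page per snapshot, values in kelvin.  Requires the run to have used
    ``store_surface=True``.
    """
    if trace.surface_planes is None:
        raise ValueError("trace has no stored surface planes (store_surface=False)")
    tifffile.imwrite(
        str(path),
        trace.surface_planes.astype(np.float32),
        imagej=True,
        metadata={"axes": "TYX", "unit": "K"},
    )


def write_field_stack(field: TemperatureField, path: Union[str, Path]) -> None:
    """Write one 3D temperature field as a z-stack TIFF (one page per depth slice)."""
    # grid layout is (x, y, z); ImageJ stacks want (z, y, x)
    vol = np.transpose(field.values, (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(str(path), vol, imagej=True, metadata={"axes": "ZYX", "unit": "K"})


def write_trace_csv(trace: SimulationTrace, path: Union[str, Path]) -> None:
    """Write the maximum-temperature trace at snapshot cadence (time_ns, max_K, surface_max_K)."""
    pd.DataFrame(
        {
            "time_ns": trace.snapshot_times * 1e9,
            "max_K": trace.snapshot_max,
            "surface_max_K": trace.snapshot_surface_max,
        }
    ).to_csv(path, index=False)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_toml(data: Mapping[str, Any], path: Union[str, Path]) -> None:
    """Write a flat (or one-level-nested) mapping as TOML.

    Only the key-value subset needed for run metadata and presets; the stdlib
    ships a TOML reader but no writer.
    """
    lines = []
    tables = {}
    for key, value in data.items():
        if isinstance(value, Mapping):
            tables[key] = value
        else:
            lines.append(f"{key} = {_toml_value(value)}")
    for name, table in tables.items():
        lines.append("")
        lines.append(f"[{name}]")
        for key, value in table.items():
            lines.append(f"{key} = {_toml_value(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def trace_metadata(trace: SimulationTrace, current: float) -> Dict[str, Any]:
    """Flatten a trace's run configuration for the sidecar file."""
    g, s = trace.grid, trace.source
    return {
        "current_A": current,
        "seed": trace.seed,
        "dt_s": trace.dt,
        "n_impacts": trace.n_impacts,
        "duration_ns": float(trace.step_times[-1] * 1e9),
        "grid": {
            "dx_m": g.dx, "nx": g.nx, "ny": g.ny, "nz": g.nz, "t_room_K": g.t_room,
        },
        "source": {
            "ion_energy_keV": s.ion_energy,
            "heat_fraction": s.heat_fraction,
            "track_dims_m": list(s.track_dims),
            "profile": s.profile,
            "spot_diameter_m": s.spot_diameter,
        },
    }
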