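"""3D explicit (forward-time centered-space) transient heat-equation solver.

Solves dT/dt = alpha * laplacian(T) on a uniform voxel grid with an
ion-impact heat source: each arriving ion instantaneously raises the
temperature of a small sub-surface cuboid ("track") by

    dT_track = f * E_ion / (rho * c_p * V_track)

where ``f`` is the fraction of the incident energy converted to heat.  The
domain mimics a small volume of specimen under the beam: the four lateral
faces and the bottom are clamped to ambient (the surrounding bulk is a
thermostat), while the top face is insulated (no heat loss into vacuum).

Stability of the explicit scheme is enforced with the conservative bound
dt <= dx^2 / (8 * alpha) (stricter than the classic 3D von Neumann limit
dx^2 / (6 * alpha)).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .beam_physics import Material
from .constants import EV, ROOM_TEMPERATURE
from .synthetic_data import ImpactEvent, generate_stream
from ._kernels import ftcs_step

__all__ = [
    "GridSpec",
    "SourceSpec",
    "TemperatureField",
    "SimulationTrace",
    "StabilityError",
    "ConfigurationError",
    "DepositError",
    "FitError",
    "stability_timestep",
    "deposit_impact",
    "step",
    "run_simulation",
    "simulate_single_impact",
    "cooling_time_constant",
    "fit_exponential_decay",
]

logger = logging.getLogger(__name__)


class StabilityError(RuntimeError):
    """Requested timestep violates the explicit-scheme stability bound."""


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration (spot larger than domain, ...)."""


class DepositError(ValueError):
    """An ion track does not fit inside the non-clamped part of the domain."""


class FitError(RuntimeError):
    """Cooling-constant fit failed (non-decaying or non-positive trace)."""


@dataclass(frozen=True)
class GridSpec:
    """Uniform voxel grid.  Defaults: 600 x 600 x 400 nm at dx = 5 nm.

    Axis convention: z index 0 is the top (free) surface; z grows downward.
    """

    dx: float = 5e-9
    nx: int = 120
    ny: int = 120
    nz: int = 80
    t_room: float = ROOM_TEMPERATURE

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ConfigurationError("dx must be > 0")
        if min(self.nx, self.ny, self.nz) < 4:
            raise ConfigurationError("need at least 4 voxels per axis")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Domain size (x, y, z) [m]."""
        return (self.nx * self.dx, self.ny * self.dx, self.nz * self.dx)


@dataclass(frozen=True)
class SourceSpec:
    """Ion-impact heat-source model.

    Each impact deposits ``heat_fraction * ion_energy`` as heat, spread
    uniformly over a cuboid track of dimensions ``track_dims`` whose top face
    sits at the surface, centered laterally on the impact point.  Impact
    positions follow ``profile`` over a spot of diameter ``spot_diameter``
    (disc diameter, or Gaussian FWHM).

    Parameters
    ----------
    ion_energy : float
        Incident ion energy [keV].
    heat_fraction : float
        Fraction of the incident energy converted to heat (0, 1].
    track_dims : (float, float, float)
        Track cuboid (x, y, z) [m]; must be integer multiples of the grid dx.
    profile : {"disc", "gaussian"}
    spot_diameter : float
        Beam spot diameter [m].
    """

    ion_energy: float = 5.0
    heat_fraction: float = 0.9
    track_dims: Tuple[float, float, float] = (10e-9, 10e-9, 20e-9)
    profile: Literal["disc", "gaussian"] = "disc"
    spot_diameter: float = 246e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.heat_fraction <= 1.0:
            raise ConfigurationError("heat_fraction must be in [0, 1]")
        if self.ion_energy < 0:
            raise ConfigurationError("ion energy must be >= 0")
        if self.spot_diameter <= 0:
            raise ConfigurationError("spot diameter must be > 0")

    @property
    def heat_per_ion(self) -> float:
        """Deposited heat per impact [J]."""
        return self.heat_fraction * self.ion_energy * 1e3 * EV

    def track_voxels(self, grid: GridSpec) -> Tuple[int, int, int]:
        """Track size in voxels; raises unless dims are multiples of dx."""
        counts = []
        for d in self.track_dims:
            n = round(d / grid.dx)
            if n < 1 or abs(n * grid.dx - d) > 1e-6 * grid.dx:
                raise ConfigurationError(
                    f"track dimension {d} m is not a positive multiple of dx={grid.dx} m"
                )
            counts.append(n)
        return tuple(counts)  # type: ignore[return-value]


@dataclass
class TemperatureField:
    """Voxel temperature snapshot [K] at a simulation time [s]."""

    values: np.ndarray
    time: float
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def ambient(cls, grid: GridSpec, time: float = 0.0) -> "TemperatureField":
        return cls(values=np.full(grid.shape, grid.t_room), time=time, grid=grid)

    @property
    def surface(self) -> np.ndarray:
        """Top-face (z = 0) temperatures, shape (nx, ny)."""
        return self.values[:, :, 0]

    def excess_energy(self, material: Material) -> float:
        """Total thermal energy above ambient, sum rho*c_p*(T - t_room)*dx^3 [J]."""
        dv = self.grid.dx ** 3
        return float(
            material.volumetric_heat_capacity
            * (self.values - self.grid.t_room).sum()
            * dv
        )


def _quantize_mK(a: np.ndarray) -> np.ndarray:
    """Round temperatures to millikelvin (the storage precision used for snapshots)."""
    return np.round(a * 1e3) / 1e3


@dataclass
class SimulationTrace:
    """Recorded output of one transient run.

    ``step_times`` / ``max_trace`` / ``surface_max_trace`` are per solver step
    (the state *after* each step).  ``snapshot_times`` marks the configured
    snapshot cadence (default 0.1 ns); stored arrays (surface planes, 3D
    fields) are quantized to millikelvin.
    """

    grid: GridSpec
    source: SourceSpec
    dt: float
    seed: Optional[int]
    n_impacts: int
    step_times: np.ndarray
    max_trace: np.ndarray
    surface_max_trace: np.ndarray
    snapshot_indices: np.ndarray          #: indices into the per-step arrays
    surface_planes: Optional[np.ndarray]  #: (n_snapshots, nx, ny) float32, or None
    fields: Dict[float, np.ndarray] = field(default_factory=dict)
    final_field: Optional[TemperatureField] = None

    @property
    def snapshot_times(self) -> np.ndarray:
        return self.step_times[self.snapshot_indices]

    @property
    def snapshot_max(self) -> np.ndarray:
        return self.max_trace[self.snapshot_indices]

    @property
    def snapshot_surface_max(self) -> np.ndarray:
        return self.surface_max_trace[self.snapshot_indices]

    def final_surface_rise(self) -> float:
        """Top-surface maximum minus ambient at the final snapshot [K]."""
        return float(self.snapshot_surface_max[-1] - self.grid.t_room)

    def quasi_steady_surface_rise(self, n_snapshots: int = 100) -> float:
        """Median surface-maximum rise over the final ``n_snapshots`` snapshots [K].

        The median damps the transient spikes of freshly deposited tracks and
        estimates the quasi-steady background the spot has reached.
        """
        tail = self.snapshot_surface_max[-n_snapshots:]
        return float(np.median(tail) - self.grid.t_room)

    def snapshot_phase_sensitivity(self, n_snapshots: int = 100) -> Tuple[float, float]:
        """(min, max) surface-maximum rise over the final snapshots [K].

        The surface maximum oscillates with the phase of the snapshot clock
        relative to the impact clock (a just-deposited track is transiently
        much hotter than the background); this range quantifies how much the
        reported final-snapshot value depends on that phase.
        """
        tail = self.snapshot_surface_max[-n_snapshots:] - self.grid.t_room
        return float(tail.min()), float(tail.max())


def stability_timestep(material: Material, grid: GridSpec) -> float:
    """Largest stable explicit timestep dx^2 / (8 * alpha) [s]."""
    return grid.dx ** 2 / (8.0 * material.alpha)


def _track_origin(
    grid: GridSpec, tvox: Tuple[int, int, int], x: float, y: float
) -> Tuple[int, int]:
    """Lateral start indices of the track block for an impact at (x, y).

    (x, y) are relative to the beam axis at the lateral domain center.  The
    block is snapped so its center is nearest the impact point, ties resolved
    toward the negative axis (round-half-down).
    """
    ax = x + grid.nx * grid.dx / 2.0
    ay = y + grid.ny * grid.dx / 2.0
    # round-half-down snap; the 1e-9-voxel epsilon keeps exact ties stable
    # against float noise in ax/dx
    ix0 = math.ceil(ax / grid.dx - tvox[0] / 2.0 - 0.5 - 1e-9)
    iy0 = math.ceil(ay / grid.dx - tvox[1] / 2.0 - 0.5 - 1e-9)
    return ix0, iy0


def _deposit_inplace(
    values: np.ndarray,
    grid: GridSpec,
    source: SourceSpec,
    material: Material,
    x: float,
    y: float,
    on_clip: str = "reject",
) -> None:
    tvox = source.track_voxels(grid)
    if tvox[2] > grid.nz - 1:
        raise DepositError("track depth reaches the bottom Dirichlet face")
    ix0, iy0 = _track_origin(grid, tvox, x, y)
    ix1, iy1 = ix0 + tvox[0], iy0 + tvox[1]
    if ix0 < 1 or iy0 < 1 or ix1 > grid.nx - 1 or iy1 > grid.ny - 1:
        if on_clip == "reject":
            raise DepositError(
                f"ion track at ({x:.3g}, {y:.3g}) m crosses a lateral Dirichlet face"
            )
        warnings.warn("ion track clipped at a lateral Dirichlet face", stacklevel=3)
        ix0, iy0 = max(ix0, 1), max(iy0, 1)
        ix1, iy1 = min(ix1, grid.nx - 1), min(iy1, grid.ny - 1)
        if ix0 >= ix1 or iy0 >= iy1:
            return
    v_track = tvox[0] * tvox[1] * tvox[2] * grid.dx ** 3
    dT = source.heat_per_ion / (material.volumetric_heat_capacity * v_track)
    values[ix0:ix1, iy0:iy1, 0 : tvox[2]] += dT


def deposit_impact(
    field: TemperatureField,
    event: ImpactEvent,
    source: SourceSpec,
    material: Material,
    on_clip: str = "reject",
) -> TemperatureField:
    """Return a new field with one ion track deposited.

    The track cuboid is raised uniformly by
    ``heat_fraction * E_ion / (rho * c_p * V_track)`` so the deposited thermal
    energy closes exactly on the grid.
    """
    out = field.values.copy()
    _deposit_inplace(out, field.grid, source, material, event.x, event.y, on_clip)
    return TemperatureField(values=out, time=field.time, grid=field.grid)


def step(
    field: TemperatureField,
    material: Material,
    dt: float,
    boundary: str = "dirichlet5",
) -> TemperatureField:
    """Advance the field by one explicit FTCS step of size ``dt``.

    Raises :class:`StabilityError` if ``dt`` exceeds dx^2/(8*alpha).
    """
    bound = stability_timestep(material, field.grid)
    if dt > bound * (1.0 + 1e-12):
        raise StabilityError(
            f"dt = {dt:.3e} s exceeds the stability bound {bound:.3e} s"
        )
    r = material.alpha * dt / field.grid.dx ** 2
    out = np.empty_like(field.values)
    ftcs_step(field.values, out, r, boundary=boundary)
    return TemperatureField(values=out, time=field.time + dt, grid=field.grid)


def _choose_dt(bound: float, snapshot_interval: float) -> float:
    """Largest dt <= stability bound that divides the snapshot interval evenly."""
    n_sub = max(1, math.ceil(snapshot_interval / bound - 1e-12))
    return snapshot_interval / n_sub


def run_simulation(
    grid: GridSpec,
    source: SourceSpec,
    material: Material,
    current: float,
    duration: float,
    seed: int = 0,
    *,
    dt: Optional[float] = None,
    snapshot_interval: float = 1e-10,
    store_surface: bool = False,
    store_final_field: bool = True,
    boundary: str = "dirichlet5",
    events: Optional[Sequence[ImpactEvent]] = None,
) -> SimulationTrace:
    """Run a transient beam-heating simulation.

    Ions arrive at exactly ``e / current`` intervals, the first at t = 0, at
    positions drawn per ``source.profile`` with the seeded counter-based RNG;
    each deposit is applied at the start of the solver step nearest its arrival
    time (ties rounded down).  Runs are bit-reproducible for a given seed.

    Parameters
    ----------
    current : float
        Beam current [A].  ``current = 0`` is allowed and means no impacts.
    duration : float
        Simulated time [s]; snapped to a whole number of steps.
    dt : float, optional
        Solver step [s].  Default: the largest step within the stability bound
        that lands snapshots exactly on steps (20 ps for the default grid,
        material and 0.1 ns cadence).
    snapshot_interval : float
        Snapshot cadence [s] (default 0.1 ns).
    store_surface : bool
        Keep the mK-quantized top-surface plane at every snapshot.
    store_final_field : bool
        Keep the full 3D field at the final snapshot.
    boundary : {"dirichlet5", "neumann_all"}
        "neumann_all" (all faces insulated) is a test configuration in which
        total thermal energy is conserved exactly.
    events : sequence of ImpactEvent, optional
        Explicit impact list overriding the generated stream.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    bound = stability_timestep(material, grid)
    if dt is None:
        dt = _choose_dt(bound, snapshot_interval)
    elif dt > bound * (1.0 + 1e-12):
        raise StabilityError(f"dt = {dt:.3e} s exceeds the stability bound {bound:.3e} s")

    tvox = source.track_voxels(grid)
    ex, ey, _ = grid.extent
    safe_radius = min(ex, ey) / 2.0 - (max(tvox[0], tvox[1]) / 2.0 + 1.0) * grid.dx
    if source.spot_diameter / 2.0 > safe_radius:
        raise ConfigurationError(
            f"spot diameter {source.spot_diameter:.3g} m does not fit the "
            f"{ex:.3g} x {ey:.3g} m domain with its track margin"
        )

    if events is None:
        if current < 0:
            raise ConfigurationError("current must be >= 0")
        if current > 0:
            stream = generate_stream(
                current,
                duration,
                profile=source.profile,
                seed=seed,
                diameter=source.spot_diameter,
                max_radius=safe_radius,
            )
            events = stream.events
        else:
            events = ()

    n_steps = max(1, round(duration / dt))
    snap_every = max(1, round(snapshot_interval / dt))

    # Impact step index: nearest multiple of dt, ties toward the earlier step.
    sched: Dict[int, List[ImpactEvent]] = {}
    for ev in events:
        idx = math.ceil(ev.time / dt - 0.5)
        if 0 <= idx < n_steps:
            sched.setdefault(idx, []).append(ev)
        else:
            logger.debug("dropping impact at t=%.3e s outside the stepped window", ev.time)
    n_impacts = sum(len(v) for v in sched.values())

    T = np.full(grid.shape, grid.t_room, dtype=np.float64)
    Tn = np.full(grid.shape, grid.t_room, dtype=np.float64)
    r = material.alpha * dt / grid.dx ** 2

    step_times = (np.arange(n_steps) + 1) * dt
    max_trace = np.empty(n_steps)
    surface_max_trace = np.empty(n_steps)
    snapshot_indices: List[int] = []
    surface_planes: List[np.ndarray] = [] if store_surface else None  # type: ignore

    for s in range(n_steps):
        for ev in sched.get(s, ()):
            _deposit_inplace(T, grid, source, material, ev.x, ev.y)
        gmax, smax = ftcs_step(T, Tn, r, boundary=boundary)
        T, Tn = Tn, T
        max_trace[s] = gmax
        surface_max_trace[s] = smax
        if (s + 1) % snap_every == 0 or s == n_steps - 1:
            snapshot_indices.append(s)
            if store_surface:
                surface_planes.append(_quantize_mK(T[:, :, 0]).astype(np.float32))

    final = None
    if store_final_field:
        final = TemperatureField(
            values=_quantize_mK(T), time=float(step_times[-1]), grid=grid
        )

    return SimulationTrace(
        grid=grid,
        source=source,
        dt=dt,
        seed=seed,
        n_impacts=n_impacts,
        step_times=step_times,
        max_trace=max_trace,
        surface_max_trace=surface_max_trace,
        snapshot_indices=np.asarray(snapshot_indices, dtype=np.intp),
        surface_planes=(np.stack(surface_planes) if store_surface else None),
        final_field=final,
    )


def simulate_single_impact(
    grid: GridSpec,
    source: SourceSpec,
    material: Material,
    duration: float,
    dt: Optional[float] = None,
) -> SimulationTrace:
    """Deposit one ion on the beam axis at t = 0 and let it cool.

    Records traces every step (snapshot cadence = dt) — the input for
    :func:`cooling_time_constant`.
    """
    bound = stability_timestep(material, grid)
    if dt is None:
        dt = bound
    return run_simulation(
        grid,
        source,
        material,
        current=0.0,
        duration=duration,
        dt=dt,
        snapshot_interval=dt,
        store_surface=False,
        store_final_field=False,
        events=[ImpactEvent(time=0.0, x=0.0, y=0.0)],
    )


def fit_exponential_decay(times: np.ndarray, excess: np.ndarray) -> float:
    """Least-squares fit of A*exp(-t/tau) to a decaying excess-temperature trace.

    Returns tau [s].  Raises :class:`FitError` for non-positive or
    non-decaying traces.
    """
    times = np.asarray(times, dtype=float)
    excess = np.asarray(excess, dtype=float)
    if len(times) < 3:
        raise FitError("need at least 3 samples to fit a decay constant")
    if np.any(excess <= 0):
        raise FitError("excess temperature must be positive throughout the fit window")
    if excess[-1] >= excess[0]:
        raise FitError("trace does not decay over the fit window")
    # log-linear least squares for the starting point, then nonlinear refine
    slope, intercept = np.polyfit(times, np.log(excess), 1)
    if slope >= 0:
        raise FitError("trace does not decay over the fit window")
    tau0, a0 = -1.0 / slope, math.exp(intercept)
    popt, _ = curve_fit(
        lambda t, a, tau: a * np.exp(-t / tau), times, excess, p0=(a0, tau0), maxfev=10000
    )
    return float(popt[1])


def cooling_time_constant(
    trace: SimulationTrace, fit_window: Tuple[float, float]
) -> float:
    """Cooling time constant tau [s] of a single-impact decay.

    Fits ``A * exp(-t / tau)`` to the peak-voxel excess temperature
    (``max_trace`` minus ambient) over ``fit_window = (t0, t1)``.
    """
    t0, t1 = fit_window
    sel = (trace.step_times >= t0) & (trace.step_times <= t1)
    if sel.sum() < 3:
        raise FitError("fit window contains fewer than 3 trace samples")
    return fit_exponential_decay(
        trace.step_times[sel], trace.max_trace[sel] - trace.grid.t_room
    )
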