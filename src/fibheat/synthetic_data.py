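"""Synthetic inputs: ion-impact event streams and analytic oracle fields.

The transient simulator consumes a stream of timestamped ion impacts.  The
stream emulated here is the one the numerical model assumes: arrivals at
*exactly* equal intervals e/I (shot noise is deliberately absent — the mean
interval is the modelled quantity), with surface positions drawn independently
per impact either uniformly on a circular spot or from a 2D Gaussian.

``analytic_fixture`` evaluates the instantaneous point-source solution of the
heat equation (free-space Gaussian kernel, optionally with an image source
mirrored across the insulated top surface) on a voxel grid.  It is the
closed-form oracle against which the finite-difference stepper is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .beam_physics import BeamPhysicsError, Material
from .constants import ELEMENTARY_CHARGE

__all__ = [
    "ImpactEvent",
    "ImpactStream",
    "generate_stream",
    "analytic_fixture",
    "GAUSSIAN_FWHM_TO_SIGMA",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian profile.
GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class ImpactEvent:
    """A single ion arrival: time [s] and surface position [m] relative to the beam axis."""

    time: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("impact time must be >= 0")


@dataclass(frozen=True)
class ImpactStream:
    """An ordered, reproducible sequence of ion impacts.

    Inter-arrival times are all exactly e/current; positions follow ``profile``
    ("disc": uniform on a circle of the given diameter; "gaussian": isotropic
    2D normal with FWHM equal to the given diameter, truncated at
    ``max_radius`` when one is set).
    """

    events: Tuple[ImpactEvent, ...]
    current: float
    profile: str
    diameter: float
    seed: int

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions [m]."""
        return np.array([(e.x, e.y) for e in self.events])


def _rng(seed: int) -> np.random.Generator:
    # Counter-based generator: reproducible, stream-splittable.
    return np.random.Generator(np.random.Philox(seed))


def generate_stream(
    current: float,
    duration: float,
    profile: str = "disc",
    seed: int = 0,
    diameter: float = 246e-9,
    max_radius: Optional[float] = None,
) -> ImpactStream:
    """Generate an equal-interval ion-impact stream.

    Parameters
    ----------
    current : float
        Beam current [A]; the inter-arrival time is e/current.
    duration : float
        Length of the stream [s].  ``floor(duration * I/e) + 1`` events are
        produced, the first at t = 0.
    profile : {"disc", "gaussian"}
        Spatial law for the impact positions.
    seed : int
        Seed for the counter-based RNG; identical seeds give identical streams.
    diameter : float
        Spot diameter [m]: disc diameter, or Gaussian FWHM.
    max_radius : float, optional
        Truncation radius [m] for the Gaussian profile (e.g. the domain edge);
        positions beyond it are re-drawn.
    """
    if duration <= 0:
        raise BeamPhysicsError("stream duration must be > 0")
    if current <= 0:
        raise BeamPhysicsError("current must be > 0")
    if diameter <= 0:
        raise BeamPhysicsError("spot diameter must be > 0")
    if profile not in ("disc", "gaussian"):
        raise ValueError(f"unknown beam profile {profile!r}")

    interval = ELEMENTARY_CHARGE / current
    n = int(math.floor(duration / interval)) + 1
    times = np.arange(n) * interval

    rng = _rng(seed)
    if profile == "disc":
        # Uniform on the disc: radial CDF proportional to r^2.
        r = (diameter / 2.0) * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2.0 * math.pi
        xs = r * np.cos(theta)
        ys = r * np.sin(theta)
    else:
        sigma = diameter * GAUSSIAN_FWHM_TO_SIGMA
        xs = rng.normal(0.0, sigma, n)
        ys = rng.normal(0.0, sigma, n)
        if max_radius is not None:
            bad = xs * xs + ys * ys > max_radius * max_radius
            while bad.any():
                m = int(bad.sum())
                xs[bad] = rng.normal(0.0, sigma, m)
                ys[bad] = rng.normal(0.0, sigma, m)
                bad = xs * xs + ys * ys > max_radius * max_radius

    events = tuple(
        ImpactEvent(time=float(t), x=float(x), y=float(y))
        for t, x, y in zip(times, xs, ys)
    )
    return ImpactStream(
        events=events, current=current, profile=profile, diameter=diameter, seed=seed
    )


def analytic_fixture(
    material: Material,
    Q: float,
    t: float,
    grid: "GridSpec",
    center: Optional[Tuple[float, float, float]] = None,
    image: bool = True,
):
    """Instantaneous point-source temperature field at elapsed time ``t``.

    Evaluates

        dT(r, t) = Q / (rho*c_p * (4*pi*alpha*t)^{3/2}) * exp(-r^2 / (4*alpha*t))

    at every voxel center, optionally adding the image source mirrored across
    the insulated top surface (z = 0 plane), and returns a
    :class:`~fibheat.ftcs_sim.TemperatureField` at ``grid.t_room + dT``.

    Parameters
    ----------
    material : Material
        Supplies alpha (spreading) and rho*c_p (energy-to-temperature).
    Q : float
        Deposited energy [J].
    t : float
        Elapsed diffusion time [s]; must be > 0 (the t=0 field is singular).
    grid : GridSpec
        Voxel grid; positions are absolute within [0, n*dx] per axis, z = 0 at
        the top surface.
    center : (x, y, z), optional
        Source position [m]; defaults to the lateral center at depth 1.5*dx.
    image : bool
        Add the mirror source at (x, y, -z) enforcing zero flux through z = 0.
    """
    from .ftcs_sim import TemperatureField  # deferred: avoids circular import

    if t <= 0:
        raise ValueError("analytic fixture is singular at t <= 0; need t > 0")
    if Q < 0:
        raise ValueError("deposited energy must be >= 0")

    dx = grid.dx
    if center is None:
        center = (grid.nx * dx / 2.0, grid.ny * dx / 2.0, 1.5 * dx)
    cx, cy, cz = center

    x = (np.arange(grid.nx) + 0.5) * dx
    y = (np.arange(grid.ny) + 0.5) * dx
    z = (np.arange(grid.nz) + 0.5) * dx
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    four_at = 4.0 * material.alpha * t
    norm = Q / (material.volumetric_heat_capacity * (math.pi * four_at) ** 1.5)
    r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    dT = norm * np.exp(-r2 / four_at)
    if image:
        r2i = (X - cx) ** 2 + (Y - cy) ** 2 + (Z + cz) ** 2
        dT = dT + norm * np.exp(-r2i / four_at)

    return TemperatureField(values=grid.t_room + dT, time=t, grid=grid)
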