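"""Cartesian grid descriptions shared by phantoms, beamforming and reconstruction.

All image-like arrays in this package are indexed ``[ix, iz]`` with ``x``
lateral (parallel to the transducer face, centered on the array) and ``z``
axial (depth, positive into the medium, ``z = 0`` at the array face).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Uniform 2-D Cartesian grid of pixel centers.

    Parameters
    ----------
    nx, nz : int
        Number of pixels laterally / axially.
    dx, dz : float
        Pixel spacing in meters.
    x0, z0 : float
        Position (m) of the center of pixel ``(0, 0)``.
    """

    nx: int
    nz: int
    dx: float
    dz: float
    x0: float
    z0: float

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.nz <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.dx <= 0 or self.dz <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.nz)

    @property
    def x(self) -> np.ndarray:
        """Lateral pixel-center coordinates (m)."""
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def z(self) -> np.ndarray:
        """Axial pixel-center coordinates (m)."""
        return self.z0 + self.dz * np.arange(self.nz)

    @property
    def extent_x(self) -> tuple[float, float]:
        """Lateral pixel-boundary extent (m)."""
        return (self.x0 - 0.5 * self.dx, self.x0 + (self.nx - 0.5) * self.dx)

    @property
    def extent_z(self) -> tuple[float, float]:
        return (self.z0 - 0.5 * self.dz, self.z0 + (self.nz - 0.5) * self.dz)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """``(X, Z)`` coordinate arrays of shape ``(nx, nz)``."""
        return np.meshgrid(self.x, self.z, indexing="ij")

    def coarsen(self, spacing: float) -> "Grid":
        """A grid covering the same field of view at (approximately) `spacing`."""
        lo_x, hi_x = self.extent_x
        lo_z, hi_z = self.extent_z
        nx = max(int(round((hi_x - lo_x) / spacing)), 3)
        nz = max(int(round((hi_z - lo_z) / spacing)), 3)
        dx = (hi_x - lo_x) / nx
        dz = (hi_z - lo_z) / nz
        return Grid(nx, nz, dx, dz, lo_x + 0.5 * dx, lo_z + 0.5 * dz)


def default_phantom_grid(width: float = 38e-3, depth: float = 50e-3,
                         pixel: float = 0.3e-3) -> Grid:
    """Phantom-definition grid: 38 mm lateral x 50 mm axial, 0.3 mm pixels,
    laterally centered on the array with the first row just below the face."""
    nx = int(round(width / pixel))
    nz = int(round(depth / pixel))
    x0 = -0.5 * (nx - 1) * pixel
    return Grid(nx, nz, pixel, pixel, x0, 0.5 * pixel)
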