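"""Delay-and-sum beamforming onto a fixed Cartesian grid.

Each transmit event (plane wave or diverging wave) is beamformed with an
assumed constant speed of sound ``c0`` onto the same grid, so frames from
different events share a sampling space for displacement estimation.  The
receive aperture is dynamic (width = depth / F-number) and either *full*
(centered above each image point) or *adapted* (center shifted by
``z tan(psi_psf)`` so the point-spread-function axis is aligned at a fixed
angle ``psi_psf`` across transmit events).  Pixels whose required aperture
extends beyond the physical array — or, for diverging waves, that fall
outside the transmit coverage cone — are marked invalid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .grids import Grid
from .rfsim import ChannelData, TxDescriptor

__all__ = [
    "BeamformConfig", "RFFrame", "das_beamform", "rx_aperture",
    "dw_coverage_mask", "envelope", "default_beamform_grid",
]


@dataclass(frozen=True)
class BeamformConfig:
    """Beamforming parameters.

    c0: assumed sound speed (m/s); 1500 for the simulation study, 1470 for
    tissue-phantom hardware emulation.  psi_psf in degrees; the adapted
    aperture is typically run at 0 and +-15.
    """

    c0: float = 1500.0
    f_number: float = 1.0
    aperture_mode: str = "full"  # "full" | "adapted"
    psi_psf: float = 0.0
    rx_apodization: str = "tukey"
    tukey_alpha: float = 0.25
    min_elements: int = 4
    dw_opening_angle: float = 35.0
    time_upsample: int = 4  # FFT upsampling of fast time before interpolation

    def __post_init__(self) -> None:
        if self.f_number <= 0:
            raise ValueError("f_number must be positive")
        if not abs(self.psi_psf) < 90:
            raise ValueError("|psi_psf| must be < 90 deg")
        if self.aperture_mode not in ("full", "adapted"):
            raise ValueError(f"unknown aperture mode {self.aperture_mode!r}")


@dataclass
class RFFrame:
    """One beamformed RF image with its validity mask and Tx metadata."""

    values: np.ndarray  # (nx, nz)
    valid: np.ndarray   # (nx, nz) bool
    grid: Grid
    tx_descriptor: TxDescriptor
    psi_psf: float
    aperture_mode: str
    c0: float


def default_beamform_grid(width: float = 38e-3, depth: float = 50e-3,
                          dx: float = 0.3e-3, dz: float = 37.5e-6) -> Grid:
    nx = int(round(width / dx))
    nz = int(round(depth / dz))
    return Grid(nx, nz, dx, dz, -0.5 * (nx - 1) * dx, 0.5 * dz)


def _tukey_taper(u: np.ndarray, alpha: float) -> np.ndarray:
    """Continuous Tukey taper over normalized aperture position u in [-1, 1]."""
    a = np.abs(u)
    w = np.zeros_like(a)
    inside = a <= 1.0
    flat = a <= 1.0 - alpha
    w[flat] = 1.0
    roll = inside & ~flat
    w[roll] = 0.5 * (1.0 + np.cos(np.pi * (a[roll] - (1.0 - alpha)) / alpha))
    return w


def rx_aperture(pixel_x: float, pixel_z: float, mode: str, psi_psf: float,
                f_number: float, element_x: np.ndarray
                ) -> tuple[tuple[int, int], bool]:
    """Receive-aperture element range for one image point.

    Aperture width is ``z / f_number``; in full mode it is centered above
    the pixel, in adapted mode at ``x + z tan(psi_psf)`` so the receive
    PSF axis sits at ``psi_psf``.  Returns the inclusive element index
    range and whether the full required range fits the physical array.
    """
    element_x = np.asarray(element_x)
    half = 0.5 * pixel_z / f_number
    center = pixel_x
    if mode == "adapted":
        center = pixel_x + pixel_z * np.tan(np.deg2rad(psi_psf))
    lo, hi = center - half, center + half
    valid = bool(lo >= element_x[0] - 1e-12) and bool(hi <= element_x[-1] + 1e-12)
    i0 = int(np.searchsorted(element_x, lo, side="left"))
    i1 = int(np.searchsorted(element_x, hi, side="right")) - 1
    return (i0, i1), valid


def dw_coverage_mask(source_x: float, grid: Grid,
                     opening_angle: float = 35.0) -> np.ndarray:
    """Pixels inside the diverging-wave insonification cone: the acoustic
    energy of a narrow-element transmit is delivered within a triangular
    opening of half-angle `opening_angle` about the depth axis."""
    if not 0.0 < opening_angle < 90.0:
        raise ValueError("opening angle must be in (0, 90) deg")
    X, Z = grid.meshgrid()
    return np.abs(X - source_x) <= Z * np.tan(np.deg2rad(opening_angle))


def _tx_times(desc: TxDescriptor, X: np.ndarray, Z: np.ndarray,
              element_x: np.ndarray, c0: float) -> np.ndarray:
    if desc.kind == "pw":
        th = np.deg2rad(desc.angle_deg)
        return (Z * np.cos(th) + X * np.sin(th)) / c0
    if desc.kind in ("dw", "element"):
        xs = element_x[desc.element]
        return np.hypot(X - xs, Z) / c0
    raise ValueError(f"cannot beamform event of kind {desc.kind!r}")


def das_beamform(data: ChannelData, event: int, grid: Grid,
                 config: BeamformConfig) -> RFFrame:
    """Delay-and-sum beamform one transmit event onto `grid`.

    Per pixel, receive channels inside the dynamic aperture are summed at
    the transmit travel time plus the pixel-to-element return time (both at
    the assumed ``c0``), with linear interpolation in fast time and a Tukey
    receive taper across the aperture.
    """
    desc = data.tx_descriptors[event]
    ex = data.transducer.element_x
    X, Z = grid.meshgrid()
    c0 = config.c0
    t_tx = _tx_times(desc, X, Z, ex, c0)

    half = 0.5 * Z / config.f_number
    center = X.copy()
    if config.aperture_mode == "adapted":
        center = X + Z * np.tan(np.deg2rad(config.psi_psf))
    valid = (center - half >= ex[0] - 1e-12) & (center + half <= ex[-1] + 1e-12)
    if desc.kind in ("dw", "element"):
        valid &= dw_coverage_mask(ex[desc.element], grid,
                                  config.dw_opening_angle)

    times = data.times
    rf = data.rf[event]
    up = max(int(config.time_upsample), 1)
    if up > 1:
        # band-limited upsampling: linear interpolation of critically
        # sampled RF has a sub-sample phase bias that is coherent per
        # transmit event and would leak into the tracked delays
        rf = signal.resample(rf, rf.shape[-1] * up, axis=-1)
        times = data.t0 + np.arange(rf.shape[-1]) / (data.fs * up)
    out = np.zeros(grid.shape)
    n_active = np.zeros(grid.shape, dtype=int)
    alpha = config.tukey_alpha if config.rx_apodization == "tukey" else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        for r in range(ex.size):
            u = (ex[r] - center) / half
            active = np.abs(u) <= 1.0
            if not active.any():
                continue
            w = _tukey_taper(u, alpha) if alpha > 0 else active.astype(float)
            t = t_tx + np.hypot(X - ex[r], Z) / c0
            samp = np.interp(t, times, rf[r], left=0.0, right=0.0)
            out += w * samp * active
            n_active += active
    valid &= n_active >= config.min_elements
    out[~valid] = 0.0
    return RFFrame(out, valid, grid, desc, config.psi_psf,
                   config.aperture_mode, c0)


def envelope(values: np.ndarray) -> np.ndarray:
    """Axial analytic-signal magnitude (QA only; tracking runs on RF)."""
    return np.abs(signal.hilbert(values, axis=-1))
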