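"""Ground-truth speed-of-sound phantoms and scatterer fields.

The numerical study emulated here uses 28 phantom cases on a
38 mm x 50 mm field of view: seven geometric cases (ellipse / circle /
layer inclusions at +-2% contrast on a 1500 m/s substrate, the last with
two circular inclusions) and 21 cases with randomly shaped inclusions
(1450-1550 m/s) on substrates whose mean varies in 1485-1515 m/s with an
additional smooth local variation bounded by +-3 m/s.  Displacement
tracking requires fully developed speckle, provided by perturbing the
density of a random 10% subset of medium pixels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Grid, default_phantom_grid

__all__ = [
    "SoSMap",
    "ScattererField",
    "make_geometric_phantom",
    "make_random_phantom",
    "make_scatterers",
    "make_homogeneous_phantom",
    "phantom_suite",
]


@dataclass
class SoSMap:
    """A gridded speed-of-sound field with named region masks.

    ``values`` holds sound speed in m/s on ``grid`` (shape ``(nx, nz)``);
    ``masks`` holds boolean region grids, conventionally ``inclusion`` and
    ``background`` (disjoint, jointly covering the grid for generated
    phantoms).
    """

    values: np.ndarray
    grid: Grid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SoS values must be finite")
        for name, m in self.masks.items():
            if m.shape != self.values.shape:
                raise ValueError(f"mask {name!r} shape mismatch")

    @property
    def slowness(self) -> np.ndarray:
        """Reciprocal field sigma = 1/c (s/m)."""
        return 1.0 / self.values

    def contrast(self) -> float:
        """Relative inclusion contrast (mean inclusion vs mean background);
        0 if either mask is absent or empty."""
        inc = self.masks.get("inclusion")
        bkg = self.masks.get("background")
        if inc is None or bkg is None or not inc.any() or not bkg.any():
            return 0.0
        mu_b = float(self.values[bkg].mean())
        return float((self.values[inc].mean() - mu_b) / mu_b)


@dataclass
class ScattererField:
    """Relative density perturbation at a random subset of medium pixels."""

    perturbation: np.ndarray
    grid: Grid
    fraction: float
    amplitude: float
    seed: int

    @property
    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """``(x, z)`` coordinates (m) of perturbed pixels."""
        ix, iz = np.nonzero(self.perturbation)
        return self.grid.x[ix], self.grid.z[iz]

    @property
    def amplitudes(self) -> np.ndarray:
        ix, iz = np.nonzero(self.perturbation)
        return self.perturbation[ix, iz]


def _feather(mask: np.ndarray, width_px: float) -> np.ndarray:
    """Hard mask -> [0,1] weight map, Gaussian-feathered when width > 0."""
    w = mask.astype(float)
    if width_px > 0:
        w = ndimage.gaussian_filter(w, sigma=width_px)
    return w


def make_geometric_phantom(grid: Grid | None = None, shape: str = "circle", *,
                           center: tuple[float, float] = (0.0, 25e-3),
                           radius: float = 5e-3,
                           radii: tuple[float, float] | None = None,
                           z_top: float | None = None,
                           z_bottom: float | None = None,
                           centers: tuple[tuple[float, float], ...] | None = None,
                           contrast: float = 0.02,
                           c_background: float = 1500.0,
                           feather_width: float = 0.0) -> SoSMap:
    """Geometric inclusion phantom: circle, ellipse, layer or two circles.

    ``contrast`` is the fractional SoS deviation of the inclusion (e.g.
    ``+0.02`` gives 1530 m/s on a 1500 m/s substrate).  ``feather_width``
    (m) optionally smooths the inclusion boundary with a Gaussian taper;
    the returned inclusion mask is the hard (pre-feather) support.
    """
    if grid is None:
        grid = default_phantom_grid()
    if abs(contrast) > 0.1:
        raise ValueError(f"|contrast|={abs(contrast)} exceeds 0.1")
    X, Z = grid.meshgrid()
    lo_x, hi_x = grid.extent_x
    lo_z, hi_z = grid.extent_z

    def _check_inside(cx: float, cz: float, rx: float, rz: float) -> None:
        for coord, lo, hi, r in ((cx, lo_x, hi_x, rx), (cz, lo_z, hi_z, rz)):
            if coord - r < lo or coord + r > hi:
                raise ValueError(
                    f"inclusion extent around coordinate {coord:.4g} m "
                    f"(half-size {r:.4g} m) exceeds grid [{lo:.4g}, {hi:.4g}] m")

    if shape == "circle":
        cx, cz = center
        _check_inside(cx, cz, radius, radius)
        mask = (X - cx) ** 2 + (Z - cz) ** 2 <= radius ** 2
    elif shape == "ellipse":
        cx, cz = center
        rx, rz = radii if radii is not None else (radius, 0.6 * radius)
        _check_inside(cx, cz, rx, rz)
        mask = ((X - cx) / rx) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0
    elif shape == "layer":
        zt = z_top if z_top is not None else center[1] - radius
        zb = z_bottom if z_bottom is not None else center[1] + radius
        if not (lo_z <= zt < zb <= hi_z):
            raise ValueError(
                f"layer [{zt:.4g}, {zb:.4g}] m outside grid depth "
                f"[{lo_z:.4g}, {hi_z:.4g}] m")
        mask = (Z >= zt) & (Z <= zb)
    elif shape == "two_circles":
        if centers is None:
            centers = ((-9e-3, 18e-3), (9e-3, 32e-3))
        mask = np.zeros(grid.shape, dtype=bool)
        for cx, cz in centers:
            _check_inside(cx, cz, radius, radius)
            mask |= (X - cx) ** 2 + (Z - cz) ** 2 <= radius ** 2
    else:
        raise ValueError(f"unknown shape {shape!r}")

    weight = _feather(mask, feather_width / max(grid.dx, grid.dz))
    values = c_background * (1.0 + contrast * weight)
    return SoSMap(values, grid,
                  masks={"inclusion": mask, "background": ~mask})


def make_random_phantom(grid: Grid | None = None, seed: int = 0, *,
                        inclusion_sos_range: tuple[float, float] = (1450.0, 1550.0),
                        background_mean_range: tuple[float, float] = (1485.0, 1515.0),
                        local_variation: float = 3.0,
                        area_fraction_range: tuple[float, float] = (0.02, 0.08),
                        blob_smooth_px: float = 6.0,
                        background_corr_px: float = 15.0) -> SoSMap:
    """Randomly shaped inclusion on a varying substrate.

    The inclusion support is the largest connected component of a
    Gaussian-smoothed white-noise field thresholded to a random target area
    fraction.  The substrate is a sampled mean plus low-pass-filtered noise
    rescaled to the ``local_variation`` bound.  Deterministic per seed.
    """
    if grid is None:
        grid = default_phantom_grid()
    if grid.nx < 8 or grid.nz < 8:
        raise ValueError(f"grid {grid.shape} degenerate: need >= 8 px per side")
    for rng_pair, name in ((inclusion_sos_range, "inclusion_sos_range"),
                           (background_mean_range, "background_mean_range")):
        if rng_pair[0] > rng_pair[1]:
            raise ValueError(f"{name} must be ordered")
    rng = np.random.default_rng(seed)

    noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), blob_smooth_px)
    target = rng.uniform(*area_fraction_range)
    thresh = np.quantile(noise, 1.0 - target)
    blob = noise > thresh
    labels, n = ndimage.label(blob)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        blob = labels == (1 + int(np.argmax(sizes)))

    c_mean = rng.uniform(*background_mean_range)
    local = ndimage.gaussian_filter(rng.standard_normal(grid.shape), background_corr_px)
    peak = np.abs(local).max()
    if peak > 0:
        local *= local_variation / peak
    background = c_mean + local

    c_inc = rng.uniform(*inclusion_sos_range)
    values = np.where(blob, c_inc, background)
    return SoSMap(values, grid,
                  masks={"inclusion": blob, "background": ~blob})


def make_homogeneous_phantom(grid: Grid | None = None,
                             c0: float = 1500.0) -> SoSMap:
    """Uniform medium; background mask covers everything."""
    if grid is None:
        grid = default_phantom_grid()
    values = np.full(grid.shape, float(c0))
    empty = np.zeros(grid.shape, dtype=bool)
    return SoSMap(values, grid, masks={"inclusion": empty, "background": ~empty})


def make_scatterers(grid: Grid | None = None, fraction: float = 0.10,
                    amplitude: float = 0.05, seed: int = 0) -> ScattererField:
    """Perturb a uniformly random `fraction` of the pixels by `amplitude`."""
    if grid is None:
        grid = default_phantom_grid()
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    chosen = rng.random(grid.shape) < fraction if fraction < 1.0 else \
        np.ones(grid.shape, dtype=bool)
    perturbation = np.where(chosen, amplitude, 0.0)
    return ScattererField(perturbation, grid, fraction, amplitude, seed)


def phantom_suite(seed: int = 0, grid: Grid | None = None) -> list[dict]:
    """The 28-case study set: 7 geometric + 21 random phantoms.

    Returns a list of dicts with keys ``case`` (1-based id), ``sos_map``,
    ``kind`` and ``contrast``; geometric cases occupy ids 1-6 and 28 (the
    two-circle case), random cases ids 7-27.
    """
    if grid is None:
        grid = default_phantom_grid()
    cases: dict[int, dict] = {}
    geo = [
        (1, "layer", dict(z_top=15e-3, z_bottom=25e-3, contrast=0.02)),
        (2, "layer", dict(z_top=20e-3, z_bottom=35e-3, contrast=-0.02)),
        (3, "circle", dict(center=(0.0, 20e-3), radius=6e-3, contrast=0.02)),
        (4, "circle", dict(center=(0.0, 25e-3), radius=4e-3, contrast=-0.02)),
        (5, "ellipse", dict(center=(0.0, 22e-3), radii=(9e-3, 5e-3), contrast=0.02)),
        (6, "ellipse", dict(center=(0.0, 28e-3), radii=(6e-3, 9e-3), contrast=-0.02)),
        (28, "two_circles", dict(radius=5e-3, contrast=0.02)),
    ]
    for case, shape, kw in geo:
        m = make_geometric_phantom(grid, shape, c_background=1500.0, **kw)
        cases[case] = dict(case=case, sos_map=m, kind="geometric",
                           contrast=m.contrast())
    for case in range(7, 28):
        m = make_random_phantom(grid, seed=seed * 1000 + case)
        cases[case] = dict(case=case, sos_map=m, kind="random",
                           contrast=m.contrast())
    suite = [cases[k] for k in sorted(cases)]
    n_geo = sum(1 for c in suite if c["kind"] == "geometric")
    assert len(suite) == 28 and n_geo == 7, "suite must be 7 geometric + 21 random"
    return suite
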