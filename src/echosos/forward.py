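"""Differential ray-path operator linking slowness to relative delays.

Each tracked delay measurement at image pixel p for a transmit pair (i, j)
is modeled as the difference of two travel paths: transmit leg of event i
to p plus the receive leg from p back to the array, minus the same for
event j.  With straight rays this is linear in the slowness map, giving a
sparse differential path matrix L whose rows are signed per-pixel
intersection lengths (Siddon traversal) on the reconstruction grid:

    predicted delay  =  L (sigma - sigma0)

Because both events of a pair are beamformed with the same receive PSF
alignment, their receive legs coincide and cancel in the difference; the
rows effectively carry the transmit-leg geometry.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .displacement import DelaySet
from .grids import Grid
from .rfsim import TxDescriptor

__all__ = ["PathMatrix", "trace_ray", "path_for_measurement", "build_L",
           "subsample_measurements"]


@dataclass
class PathMatrix:
    """Sparse differential path operator with aligned measurements.

    ``matrix`` is CSR, rows = delay measurements, cols = flattened
    reconstruction-grid pixels (row-major ``ix * nz + iz``); entries are
    signed path lengths (m).  ``delays`` is the aligned measurement vector
    (s); ``row_meta`` records ``(entry, ix, iz)`` per row on the
    measurement grid.
    """

    matrix: sparse.csr_matrix
    recon_grid: Grid
    delays: np.ndarray
    row_meta: np.ndarray  # structured: entry, ix, iz

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def trace_ray(p_start, p_end, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Exact pixel-boundary (Siddon) traversal of the segment p_start->p_end.

    Returns flattened pixel indices (``ix * nz + iz``) and the intersection
    length (m) of the segment with each pixel; the lengths sum to the
    Euclidean length of the segment clipped to the grid.
    """
    p0 = np.asarray(p_start, dtype=float)
    p1 = np.asarray(p_end, dtype=float)
    d = p1 - p0
    seg_len = float(np.hypot(*d))
    if seg_len == 0.0:
        raise ValueError("zero-length segment")
    xlo, xhi = grid.extent_x
    zlo, zhi = grid.extent_z

    # Liang-Barsky clip of the parameter interval [0, 1] to the grid box
    tmin, tmax = 0.0, 1.0
    for p, q, lo, hi in ((p0[0], d[0], xlo, xhi), (p0[1], d[1], zlo, zhi)):
        if q == 0.0:
            if p < lo or p > hi:
                return np.empty(0, dtype=np.intp), np.empty(0)
        else:
            t0, t1 = (lo - p) / q, (hi - p) / q
            if t0 > t1:
                t0, t1 = t1, t0
            tmin, tmax = max(tmin, t0), min(tmax, t1)
    if tmax <= tmin:
        return np.empty(0, dtype=np.intp), np.empty(0)

    ts = [np.array([tmin, tmax])]
    for p, q, lo, step, n in ((p0[0], d[0], xlo, grid.dx, grid.nx),
                              (p0[1], d[1], zlo, grid.dz, grid.nz)):
        if q != 0.0:
            planes = lo + step * np.arange(1, n)
            t = (planes - p) / q
            ts.append(t[(t > tmin) & (t < tmax)])
    t_all = np.unique(np.concatenate(ts))
    tm = 0.5 * (t_all[:-1] + t_all[1:])
    lengths = np.diff(t_all) * seg_len
    ix = np.clip(((p0[0] + tm * d[0] - xlo) / grid.dx).astype(np.intp),
                 0, grid.nx - 1)
    iz = np.clip(((p0[1] + tm * d[1] - zlo) / grid.dz).astype(np.intp),
                 0, grid.nz - 1)
    keep = lengths > 0
    flat = ix[keep] * grid.nz + iz[keep]
    lengths = lengths[keep]
    if flat.size and np.any(np.diff(np.sort(flat)) == 0):
        flat, inv = np.unique(flat, return_inverse=True)
        lengths = np.bincount(inv, weights=lengths)
    return flat, lengths


def _tx_leg(pixel, desc: TxDescriptor, element_x: np.ndarray,
            grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    x, z = pixel
    if desc.kind == "pw":
        th = np.deg2rad(desc.angle_deg)
        start = (x - z * np.tan(th), 0.0)
    elif desc.kind in ("dw", "element"):
        start = (float(element_x[desc.element]), 0.0)
    else:
        raise ValueError(f"no path geometry for Tx kind {desc.kind!r}")
    return trace_ray(start, (x, z), grid)


def path_for_measurement(pixel, tx_descriptor: TxDescriptor, psi_psf: float,
                         recon_grid: Grid, element_x: np.ndarray,
                         coverage_opening_deg: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """One event's full travel path through pixel ``(x, z)``.

    Transmit leg: for a plane wave, the straight ray along the propagation
    direction from the array face to the pixel; for a diverging wave, the
    ray from the source element.  Receive leg: the ray from the pixel back
    to the array along the PSF alignment direction ``psi_psf`` (vertical at
    0).  The dot product of the returned per-pixel lengths with a slowness
    map is the event's predicted echo time at the pixel.
    """
    x, z = pixel
    if tx_descriptor.kind in ("dw", "element") and coverage_opening_deg is not None:
        xs = float(element_x[tx_descriptor.element])
        if abs(x - xs) > z * np.tan(np.deg2rad(coverage_opening_deg)):
            raise ValueError(
                f"pixel ({x:.4g}, {z:.4g}) m outside the transmit coverage "
                f"cone of element at x={xs:.4g} m")
    tx_idx, tx_len = _tx_leg(pixel, tx_descriptor, element_x, recon_grid)
    rx_end = (x + z * np.tan(np.deg2rad(psi_psf)), 0.0)
    rx_idx, rx_len = trace_ray((x, z), rx_end, recon_grid)
    idx = np.concatenate([tx_idx, rx_idx])
    lens = np.concatenate([tx_len, rx_len])
    if idx.size and np.any(np.diff(np.sort(idx)) == 0):
        idx, inv = np.unique(idx, return_inverse=True)
        lens = np.bincount(inv, weights=lens)
    return idx, lens


def build_L(delay_set: DelaySet, recon_grid: Grid,
            descriptors: dict, element_x: np.ndarray,
            stride: int | tuple[int, int] = 1) -> PathMatrix:
    """Assemble the differential path matrix for every valid measurement.

    ``descriptors`` maps the Tx labels of ``delay_set.pair_table`` (angles
    for PW, element indices for DW) to :class:`TxDescriptor`.  Row order is
    (entry, ix, iz) row-major over valid measurement pixels, optionally
    thinned by `stride` (an int, or per-axis ``(lateral, axial)`` ints)
    along the image axes.  Each row is the path of
    event i minus the path of event j; the shared receive leg cancels.
    """
    g = delay_set.grid
    X = g.x
    Z = g.z
    rows_i: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    meta = []
    delays = []
    tx_cache: dict = {}

    def tx_path(label, ix, iz):
        key = (label, ix, iz)
        if key not in tx_cache:
            tx_cache[key] = _tx_leg((X[ix], Z[iz]), descriptors[label],
                                    element_x, recon_grid)
        return tx_cache[key]

    sx, sz = (stride, stride) if np.isscalar(stride) else stride
    row = 0
    for entry, (tx_i, tx_j, _psi) in enumerate(delay_set.pair_table):
        if tx_i not in descriptors or tx_j not in descriptors:
            raise ValueError(f"pair ({tx_i}, {tx_j}) missing from descriptors")
        vmask = delay_set.valid[entry]
        for ix in range(0, g.nx, sx):
            for iz in range(0, g.nz, sz):
                if not vmask[ix, iz]:
                    continue
                ii, li = tx_path(tx_i, ix, iz)
                ij, lj = tx_path(tx_j, ix, iz)
                idx = np.concatenate([ii, ij])
                val = np.concatenate([li, -lj])
                cols.append(idx)
                vals.append(val)
                rows_i.append(np.full(idx.size, row, dtype=np.intp))
                meta.append((entry, ix, iz))
                delays.append(delay_set.delays[entry, ix, iz])
                row += 1
    n_cols = recon_grid.nx * recon_grid.nz
    if row == 0:
        mat = sparse.csr_matrix((0, n_cols))
    else:
        mat = sparse.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows_i), np.concatenate(cols))),
            shape=(row, n_cols)).tocsr()
        mat.sum_duplicates()
    meta_arr = np.array(meta, dtype=[("entry", np.intp), ("ix", np.intp),
                                     ("iz", np.intp)])
    return PathMatrix(mat, recon_grid, np.asarray(delays, dtype=float), meta_arr)


def subsample_measurements(L: PathMatrix, n: int = 10_000,
                           seed: int = 0) -> PathMatrix:
    """Uniform random row subset without replacement (all rows if fewer
    than `n` are available); rows and delays stay aligned."""
    total = L.n_rows
    if total <= n:
        return L
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(total, size=n, replace=False))
    return PathMatrix(L.matrix[pick], L.recon_grid, L.delays[pick],
                      L.row_meta[pick])
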