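"""Regularized slowness reconstruction.

The slowness map is recovered by the limited-angle CT inverse problem

    sigma_hat = argmin_sigma || L (sigma - sigma0) - dtau ||_1
                             + lambda || D sigma ||_1

where L is the differential path matrix, dtau the tracked relative delays,
sigma0 the constant slowness assumed during beamforming, and D an
anisotropically weighted stack of gradient filters (Sobel horizontal /
vertical, Roberts diagonals) that suppresses the streaking artifacts
typical of limited-angle data.  Both L1 norms are replaced by the smooth
surrogate ``phi(r) = sqrt(r^2 + eps^2) - eps`` and the problem is solved
with L-BFGS.

Internally the optimization variable is the dimensionless ``u = sigma/
sigma0`` and delays are expressed in microseconds, so ``lambda`` is a
dimensionless weight of order 1-10.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse

from .forward import PathMatrix
from .grids import Grid
from .phantoms import SoSMap

__all__ = ["ReconConfig", "RegularizerD", "build_regularizer", "solve_sos"]

# gradient kernels over (ix, iz) image axes (x lateral, z axial)
_SOBEL_LATERAL = np.array([[-1., -2., -1.], [0., 0., 0.], [1., 2., 1.]]) / 4.0
_SOBEL_AXIAL = _SOBEL_LATERAL.T
_ROBERTS_A = np.array([[1., 0.], [0., -1.]])
_ROBERTS_B = np.array([[0., 1.], [-1., 0.]])


@dataclass(frozen=True)
class ReconConfig:
    """Solver parameters.

    lam: regularization weight (dimensionless, internal scaling above).
    kappa: anisotropy weight in [0, 1]; 0.9 weights axial Sobel gradients
    by kappa and lateral ones by 2 - kappa (diagonals by 1).
    sigma0: initial/assumed slowness (s/m), the reciprocal beamforming SoS.
    l1_epsilon: data-term smoothing (s); reg_epsilon: regularizer smoothing
    on the relative slowness (dimensionless).
    """

    lam: float = 5.0
    kappa: float = 0.9
    sigma0: float = 1.0 / 1500.0
    l1_epsilon: float = 1e-9
    reg_epsilon: float = 1e-4
    max_iter: int = 500
    tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if self.l1_epsilon <= 0 or self.reg_epsilon <= 0:
            raise ValueError("smoothing epsilons must be positive")


@dataclass
class RegularizerD:
    """Stacked, direction-weighted gradient operator on the recon grid."""

    matrix: sparse.csr_matrix
    kappa: float
    grid: Grid
    n_directions: int = 4


def _kernel_operator(kernel: np.ndarray, grid: Grid) -> sparse.csr_matrix:
    """Sparse 'valid' convolution matrix of `kernel` over the flattened grid."""
    kh, kw = kernel.shape
    nx, nz = grid.nx, grid.nz
    oi = np.arange(nx - kh + 1)
    oj = np.arange(nz - kw + 1)
    I0, J0 = np.meshgrid(oi, oj, indexing="ij")
    n_rows = I0.size
    rows, cols, vals = [], [], []
    r = np.arange(n_rows)
    for di in range(kh):
        for dj in range(kw):
            if kernel[di, dj] == 0:
                continue
            c = ((I0 + di) * nz + (J0 + dj)).ravel()
            rows.append(r)
            cols.append(c)
            vals.append(np.full(n_rows, kernel[di, dj]))
    return sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rows, nx * nz)).tocsr()


def build_regularizer(recon_grid: Grid, kappa: float = 0.9) -> RegularizerD:
    """Anisotropic gradient stack: axial Sobel weighted by `kappa`, lateral
    Sobel by ``2 - kappa``, the two Roberts diagonals by 1.  Every kernel is
    zero-sum, so constant maps have exactly zero response."""
    if recon_grid.nx < 3 or recon_grid.nz < 3:
        raise ValueError("regularizer needs a grid of at least 3x3")
    blocks = [
        (2.0 - kappa) * _kernel_operator(_SOBEL_LATERAL, recon_grid),
        kappa * _kernel_operator(_SOBEL_AXIAL, recon_grid),
        _kernel_operator(_ROBERTS_A, recon_grid),
        _kernel_operator(_ROBERTS_B, recon_grid),
    ]
    return RegularizerD(sparse.vstack(blocks).tocsr(), kappa, recon_grid)


def solve_sos(L: PathMatrix, config: ReconConfig,
              regularizer: RegularizerD | None = None,
              delays: np.ndarray | None = None) -> tuple[SoSMap, dict]:
    """Minimize the smoothed Eq.-style objective and return the SoS map.

    Returns ``(sos_map, diagnostics)`` with the reconstruction in m/s on
    the reconstruction grid and a diagnostics dict holding the objective
    history (monotone non-increasing across accepted iterates), iteration
    count, convergence status and a divergence flag.
    """
    dtau = L.delays if delays is None else np.asarray(delays, dtype=float)
    if dtau.shape[0] != L.n_rows:
        raise ValueError("delays misaligned with L rows")
    if not (np.all(np.isfinite(dtau)) and np.all(np.isfinite(L.matrix.data))):
        raise ValueError("non-finite inputs to the solver")
    if L.n_rows == 0:
        raise ValueError("need at least one valid measurement")
    if regularizer is None:
        regularizer = build_regularizer(L.recon_grid, config.kappa)

    c0 = 1.0 / config.sigma0
    A = (L.matrix * (1e6 / c0)).tocsr()   # maps u = sigma/sigma0 to micro-s
    b = dtau * 1e6
    D = regularizer.matrix
    lam = config.lam
    eps_d = config.l1_epsilon * 1e6
    eps_r = config.reg_epsilon

    def objective(v: np.ndarray) -> tuple[float, np.ndarray]:
        r = A @ v - b
        sd = np.sqrt(r * r + eps_d * eps_d)
        g = D @ v
        sr = np.sqrt(g * g + eps_r * eps_r)
        f = float(np.sum(sd - eps_d) + lam * np.sum(sr - eps_r))
        grad = A.T @ (r / sd) + lam * (D.T @ (g / sr))
        return f, grad

    history: list[float] = []
    v0 = np.zeros(A.shape[1])
    history.append(objective(v0)[0])

    def cb(vk):
        history.append(objective(vk)[0])

    res = optimize.minimize(
        objective, v0, jac=True, method="L-BFGS-B", callback=cb,
        options=dict(maxiter=config.max_iter, ftol=config.tolerance,
                     gtol=1e-12, maxcor=20))
    v = res.x
    hist = np.asarray(history)
    diverged = bool(np.any(np.diff(hist) > config.tolerance * max(hist[0], 1.0)))
    u = 1.0 + v
    sos = (c0 / u).reshape(L.recon_grid.shape)
    diag = dict(objective_history=hist, n_iter=int(res.nit),
                converged=bool(res.success), diverged=diverged,
                final_objective=float(hist[-1]), message=str(res.message))
    return SoSMap(sos, L.recon_grid), diag
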