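"""End-to-end driver: phantom -> RF simulation -> beamforming ->
displacement tracking -> path matrix -> inversion -> evaluation.

A single :class:`RunConfig` describes one acquisition-and-reconstruction
run; one seed controls every stochastic stage (phantom, scatterers,
measurement subsampling), so a fixed configuration reproduces bitwise.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from . import beamform as bf
from . import displacement as disp
from . import forward, invert, metrics, phantoms, rfsim
from .grids import Grid

log = logging.getLogger("echosos")

__all__ = ["RunConfig", "run_end_to_end", "resample_to"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full imaging run (all lengths in meters)."""

    scheme: str = "dw"                 # "dw" | "pw"
    seed: int = 0
    # medium
    phantom_kind: str = "homogeneous"  # homogeneous|geometric|random
    phantom_params: dict = field(default_factory=dict)
    c_background: float = 1500.0
    fov_width: float = 28.8e-3
    fov_depth: float = 26e-3
    phantom_pixel: float = 0.3e-3
    sim_pixel: float = 75e-6   # simulation/scatterer grid: dense enough for speckle
    scatterer_fraction: float = 0.10
    scatterer_amplitude: float = 0.05
    # acquisition
    n_channels: int = 96
    pitch: float = 300e-6
    fc: float = 5e6
    fs: float = 40e6
    n_half_cycles: int = 3
    fractional_bandwidth: float = 0.60
    directivity_cutoff_deg: float = 35.0
    # beamforming
    c0: float = 1500.0
    f_number: float = 1.0
    aperture_mode: str = "full"        # "full" | "adapted"
    psi_psf_list: tuple[float, ...] = (0.0,)
    beamform_dx: float = 0.3e-3
    beamform_dz: float = 37.5e-6  # lambda/8 axially: keeps the RF carrier well sampled
    # tracking
    M: int = 9
    delta_theta: float = 2.0
    delta_phi: float = 8.0
    delta_channel: int = 13  # ~same disparity/aperture ratio as 17 ch on a 128-element array
    fan: tuple[float, float] = (-20.0, 20.0)
    window_len: int = 48   # 2.4 us two-way at lambda/8 axial spacing
    max_lag: int = 8
    ncc_threshold: float = 0.5
    # reconstruction
    recon_pixel: float = 1.5e-3
    measurement_spacing: float = 0.6e-3
    subsample_n: int = 10_000
    lam: float = 2.0
    kappa: float = 0.9
    max_iter: int = 500

    def __post_init__(self) -> None:
        # validate eagerly so bad configs fail before any compute
        self.pairing_spec()
        bf.BeamformConfig(c0=self.c0, f_number=self.f_number,
                          aperture_mode=self.aperture_mode)
        invert.ReconConfig(lam=self.lam, kappa=self.kappa,
                           sigma0=1.0 / self.c0)
        if self.aperture_mode == "full" and tuple(self.psi_psf_list) != (0.0,):
            raise ValueError("full aperture implies psi_psf = 0 only")

    def pairing_spec(self) -> disp.PairingSpec:
        return disp.PairingSpec(
            scheme=self.scheme, M=self.M, delta_theta=self.delta_theta,
            delta_phi=self.delta_phi, delta_channel=self.delta_channel,
            fan=self.fan)

    def transducer(self) -> rfsim.Transducer:
        return rfsim.Transducer(self.n_channels, self.pitch, self.fc, self.fs)

    def phantom_grid(self) -> Grid:
        return self._square_grid(self.phantom_pixel)

    def sim_grid(self) -> Grid:
        return self._square_grid(self.sim_pixel)

    def _square_grid(self, p: float) -> Grid:
        nx = int(round(self.fov_width / p))
        nz = int(round(self.fov_depth / p))
        return Grid(nx, nz, p, p, -0.5 * (nx - 1) * p, 0.5 * p)

    def beamform_grid(self) -> Grid:
        nx = int(round(self.fov_width / self.beamform_dx))
        nz = int(round(self.fov_depth / self.beamform_dz))
        return Grid(nx, nz, self.beamform_dx, self.beamform_dz,
                    -0.5 * (nx - 1) * self.beamform_dx, 0.5 * self.beamform_dz)

    def recon_grid(self) -> Grid:
        return self.phantom_grid().coarsen(self.recon_pixel)


def _build_phantom(config: RunConfig) -> phantoms.SoSMap:
    g = config.phantom_grid()
    kind = config.phantom_kind
    if kind == "homogeneous":
        return phantoms.make_homogeneous_phantom(g, config.c_background)
    if kind == "geometric":
        return phantoms.make_geometric_phantom(
            g, c_background=config.c_background, **config.phantom_params)
    if kind == "random":
        return phantoms.make_random_phantom(g, seed=config.seed,
                                            **config.phantom_params)
    raise ValueError(f"unknown phantom kind {kind!r}")


def resample_to(m: phantoms.SoSMap, grid: Grid) -> phantoms.SoSMap:
    """Bilinearly resample a SoS map (and nearest-resample its masks) onto
    another grid covering the same field of view."""
    src = m.grid
    X, Z = grid.meshgrid()
    ci = (X - src.x0) / src.dx
    cj = (Z - src.z0) / src.dz
    vals = ndimage.map_coordinates(m.values, [ci, cj], order=1, mode="nearest")
    masks = {k: ndimage.map_coordinates(v.astype(float), [ci, cj], order=0,
                                        mode="nearest") > 0.5
             for k, v in m.masks.items()}
    return phantoms.SoSMap(vals, grid, masks=masks)


def _tracked_events(config: RunConfig, pairs: list[tuple]) -> list:
    """Tx labels that must be simulated/beamformed: pair ends for DW, full
    delta_theta chains for PW."""
    if config.scheme == "dw":
        labels = sorted({e for p in pairs for e in p})
    else:
        labels = set()
        for lo, hi in pairs:
            n = int(round((hi - lo) / config.delta_theta))
            labels.update(lo + k * config.delta_theta for k in range(n + 1))
        labels = sorted(labels)
    return labels


def _decimate_delayset(ds: disp.DelaySet, stride: tuple[int, int]
                       ) -> disp.DelaySet:
    """Block-aggregate delay maps onto the measurement stride: each output
    entry is the median of the valid delays in its block (median NCC as
    quality); a block is valid when at least a quarter of it is."""
    sx, sz = stride
    if sx == 1 and sz == 1:
        return ds
    g = ds.grid
    nE = ds.delays.shape[0]
    nx = (g.nx + sx - 1) // sx
    nz = (g.nz + sz - 1) // sz
    grid = Grid(nx, nz, g.dx * sx, g.dz * sz, g.x0, g.z0)
    delays = np.zeros((nE, nx, nz))
    quality = np.zeros((nE, nx, nz))
    valid = np.zeros((nE, nx, nz), dtype=bool)
    for e in range(nE):
        for bx in range(nx):
            for bz in range(nz):
                blk = np.s_[e, bx * sx:(bx + 1) * sx, bz * sz:(bz + 1) * sz]
                v = ds.valid[blk]
                n = v.size
                if v.sum() * 4 >= n:
                    delays[e, bx, bz] = np.median(ds.delays[blk][v])
                    quality[e, bx, bz] = np.median(ds.quality[blk][v])
                    valid[e, bx, bz] = True
    return disp.DelaySet(delays, quality, valid, ds.pair_table, grid,
                         scheme=ds.scheme)


def _estimate_delays(config: RunConfig, frames: dict,
                     pairs: list[tuple]) -> disp.DelaySet:
    """NCC tracking over all pairs and PSF alignments -> DelaySet (seconds)."""
    grid = next(iter(frames.values())).grid
    entries, table = [], []
    for psi in config.psi_psf_list:
        if config.scheme == "dw":
            for a, b in pairs:  # delay of the higher-element event w.r.t. the lower
                dm = disp.ncc_axial(frames[(b, psi)], frames[(a, psi)],
                                    config.window_len, config.max_lag,
                                    config.ncc_threshold)
                entries.append(dm)
                table.append((b, a, psi))
        else:
            # one tracking map per delta_theta increment, shared by all chains
            angles = _tracked_events(config, pairs)
            inc = {}
            for lo, hi in zip(angles[:-1], angles[1:]):
                if abs(hi - lo - config.delta_theta) < 1e-9:
                    inc[(lo, hi)] = disp.ncc_axial(
                        frames[(hi, psi)], frames[(lo, psi)],
                        config.window_len, config.max_lag,
                        config.ncc_threshold)
            for lo, hi in pairs:
                n = int(round((hi - lo) / config.delta_theta))
                chain = [inc[(lo + k * config.delta_theta,
                              lo + (k + 1) * config.delta_theta)]
                         for k in range(n)]
                dm = disp.accumulate_pw(chain, config.delta_theta, hi - lo)
                entries.append(dm)
                table.append((hi, lo, psi))
    delays = np.stack([
        disp.correct_psf_angle(
            disp.lag_to_seconds(dm.lag, grid, config.c0), psi)
        for dm, (_, _, psi) in zip(entries, table)])
    quality = np.stack([dm.ncc for dm in entries])
    valid = np.stack([dm.valid for dm in entries])
    return disp.DelaySet(delays, quality, valid, table, grid,
                         scheme=config.scheme)


def run_end_to_end(config: RunConfig, return_intermediates: bool = False
                   ) -> tuple[phantoms.SoSMap, metrics.EvalResult, dict]:
    """Execute the full chain; returns (reconstruction, evaluation, info).

    ``info`` records per-stage counts and, with ``return_intermediates``,
    the phantom, channel data, frames, delay set and path matrix.
    """
    info: dict = {"config": asdict(config)}
    stage = "config"
    try:
        stage = "phantom"
        truth = _build_phantom(config)
        sim_grid = config.sim_grid()
        truth_sim = truth if sim_grid == truth.grid else \
            resample_to(truth, sim_grid)
        scat = phantoms.make_scatterers(
            sim_grid, config.scatterer_fraction,
            config.scatterer_amplitude, seed=config.seed + 1)
        info["n_scatterers"] = int(np.count_nonzero(scat.perturbation))

        stage = "rfsim"
        tdx = config.transducer()
        pulse = rfsim.Pulse(fc=config.fc, n_half_cycles=config.n_half_cycles)
        ms = rfsim.simulate_multistatic(
            tdx, truth_sim, scat, pulse,
            directivity_cutoff_deg=config.directivity_cutoff_deg)
        ms = rfsim.bandpass(ms, config.fractional_bandwidth)

        stage = "pairing"
        spec = config.pairing_spec()
        if config.scheme == "dw":
            pairs = disp.select_pairs(spec, range(config.n_channels))
        else:
            lo, hi = config.fan
            n_ang = int(round((hi - lo) / config.delta_theta))
            avail = [lo + k * config.delta_theta for k in range(n_ang + 1)]
            pairs = disp.select_pairs(spec, avail)
        labels = _tracked_events(config, pairs)
        info["n_pairs"] = len(pairs)

        stage = "recompose"
        if config.scheme == "dw":
            data = rfsim.recompose_dw(ms, labels)
        else:
            data = rfsim.recompose_pw(ms, labels, c0=config.c0)
        info["n_events"] = data.n_events
        log.info("stage=recompose events=%d", data.n_events)

        stage = "beamform"
        bgrid = config.beamform_grid()
        frames = {}
        for k, label in enumerate(labels):
            for psi in config.psi_psf_list:
                cfg = bf.BeamformConfig(
                    c0=config.c0, f_number=config.f_number,
                    aperture_mode=config.aperture_mode, psi_psf=psi,
                    dw_opening_angle=config.directivity_cutoff_deg)
                frames[(label, psi)] = bf.das_beamform(data, k, bgrid, cfg)
        info["n_frames"] = len(frames)
        info["valid_pixel_fraction"] = float(
            np.mean([f.valid.mean() for f in frames.values()]))
        log.info("stage=beamform frames=%d valid_frac=%.3f",
                 len(frames), info["valid_pixel_fraction"])

        stage = "displacement"
        delay_set = _estimate_delays(config, frames, pairs)
        info["n_valid_delays"] = int(delay_set.valid.sum())
        log.info("stage=displacement valid_delays=%d", info["n_valid_delays"])
        if info["n_valid_delays"] == 0:
            raise ValueError("no valid delay measurements")

        stage = "forward"
        rgrid = config.recon_grid()
        ex = tdx.element_x
        if config.scheme == "dw":
            descriptors = {e: rfsim.TxDescriptor("dw", element=e)
                           for e in labels}
        else:
            descriptors = {a: rfsim.TxDescriptor("pw", angle_deg=a)
                           for a in labels}
        stride = (max(int(round(config.measurement_spacing / bgrid.dx)), 1),
                  max(int(round(config.measurement_spacing / bgrid.dz)), 1))
        delay_meas = _decimate_delayset(delay_set, stride)
        L = forward.build_L(delay_meas, rgrid, descriptors, ex)
        col_support = np.asarray(np.abs(L.matrix).sum(axis=0)).ravel()
        coverage = (col_support > 0).reshape(rgrid.shape)
        Ls = forward.subsample_measurements(L, config.subsample_n,
                                            seed=config.seed + 2)
        info["n_rows"] = L.n_rows
        info["n_rows_subsampled"] = Ls.n_rows
        log.info("stage=forward rows=%d subsampled=%d", L.n_rows, Ls.n_rows)

        stage = "invert"
        rc = invert.ReconConfig(lam=config.lam, kappa=config.kappa,
                                sigma0=1.0 / config.c0,
                                max_iter=config.max_iter,
                                seed=config.seed + 2)
        recon, diag = invert.solve_sos(Ls, rc)
        info["solver"] = {k: diag[k] for k in
                          ("n_iter", "converged", "diverged", "final_objective")}

        stage = "evaluate"
        truth_r = resample_to(truth, rgrid)
        eval_mask = metrics.pw_side_mask(rgrid, 0.10) & coverage
        if not eval_mask.any():
            eval_mask = coverage
        r = metrics.rmse(recon, truth_r, eval_mask)
        c = None
        if abs(truth.contrast()) >= metrics.CNR_MIN_CONTRAST:
            inc = truth_r.masks["inclusion"] & eval_mask
            bkg = truth_r.masks["background"] & eval_mask
            if inc.any() and bkg.any():
                c = metrics.cnr(recon, inc, bkg)
        result = metrics.EvalResult(
            rmse=r, cnr=c, method=config.scheme,
            params=dict(lam=config.lam,
                        delta=(config.delta_channel if config.scheme == "dw"
                               else config.delta_phi)))
        info["coverage"] = coverage
        info["eval_mask"] = eval_mask
        info["truth_on_recon_grid"] = truth_r
        if return_intermediates:
            info.update(truth=truth, scatterers=scat, channel_data=data,
                        frames=frames, delay_set=delay_set, L=L,
                        L_subsampled=Ls, diagnostics=diag)
        return recon, result, info
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
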