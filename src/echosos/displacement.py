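"""Apparent axial displacement estimation between beamformed RF frames.

Frames beamformed from different transmit events show small apparent axial
shifts wherever the true slowness deviates from the beamforming assumption.
These shifts are estimated per pixel by windowed, zero-mean normalized
cross-correlation (NCC) along the axial direction, with envelope-guided
integer-lobe selection and cosine-fit sub-sample refinement.

For plane waves, tracking runs between small angle increments
``delta_theta`` (0.5 or 2 degrees) to avoid speckle decorrelation and phase
wrapping, and the increments are accumulated into the target angular
disparity ``delta_phi``.  For diverging waves, frames of transmits
separated by ``delta_channel`` elements are tracked directly.  A fixed
number ``M`` of pair combinations (default 9) feeds the reconstruction;
delays from PSF-aligned (adapted-aperture) frames are projected onto the
axial axis by ``cos(psi_psf)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .beamform import RFFrame
from .grids import Grid

__all__ = [
    "PairingSpec", "DelayMap", "DelaySet", "ncc_axial", "accumulate_pw",
    "select_pairs", "correct_psf_angle", "lag_to_seconds",
]


@dataclass(frozen=True)
class PairingSpec:
    """Which transmit events are paired for displacement tracking."""

    scheme: str  # "pw" | "dw"
    M: int = 9
    delta_theta: float = 2.0    # pw tracking increment (deg)
    delta_phi: float = 8.0      # pw accumulated disparity (deg)
    delta_channel: int = 17     # dw transmit-element separation
    fan: tuple[float, float] = (-20.0, 20.0)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.scheme == "pw":
            k = self.delta_phi / self.delta_theta
            if abs(k - round(k)) > 1e-9 or round(k) < 1:
                raise ValueError(
                    f"delta_phi={self.delta_phi} must be a positive integer "
                    f"multiple of delta_theta={self.delta_theta}")
        elif self.scheme == "dw":
            if self.delta_channel < 1:
                raise ValueError("delta_channel must be >= 1")
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def n_increments(self) -> int:
        return int(round(self.delta_phi / self.delta_theta))


@dataclass
class DelayMap:
    """Per-pixel displacement between one frame pair: lag in axial grid
    samples, NCC quality, validity; optionally the Tx labels it connects."""

    lag: np.ndarray
    ncc: np.ndarray
    valid: np.ndarray
    tx_i: float | int | None = None
    tx_j: float | int | None = None


@dataclass
class DelaySet:
    """Relative-delay measurements for M pairs (x PSF alignments).

    ``delays`` holds seconds, shape ``(n_entries, nx, nz)``; ``pair_table``
    rows are ``(tx_i, tx_j, psi_psf)``.
    """

    delays: np.ndarray
    quality: np.ndarray
    valid: np.ndarray
    pair_table: list[tuple]
    grid: Grid
    scheme: str = "dw"

    def __post_init__(self) -> None:
        if len(self.pair_table) != self.delays.shape[0]:
            raise ValueError("pair_table length must match delay entries")
        if not np.all(np.isfinite(self.delays[self.valid])):
            raise ValueError("valid delays must be finite")


def ncc_axial(frame_i: RFFrame, frame_j: RFFrame, window_len: int = 48,
              max_lag: int = 8, ncc_threshold: float = 0.0) -> DelayMap:
    """Per-pixel axial NCC displacement of `frame_i` relative to `frame_j`.

    Positive lag means the content of ``frame_i`` sits deeper:
    ``frame_i(z) ~ frame_j(z - lag)``.  The integer argmax over lags in
    ``[-max_lag, max_lag]`` (selected under the envelope-correlation peak
    to avoid carrier-period hops) is refined by a cosine fit.  Valid only
    where both frames (and the full correlation window, at every lag) are
    valid and in bounds.
    """
    if frame_i.grid != frame_j.grid:
        raise ValueError("frames must share the beamforming grid")
    a = frame_i.values
    b = frame_j.values
    nz = a.shape[1]
    if window_len > nz:
        raise ValueError(f"window ({window_len}) longer than axial extent ({nz})")
    w = int(window_len)
    lags = np.arange(-max_lag, max_lag + 1)

    def _win_mean(x):
        return ndimage.uniform_filter1d(x, w, axis=1, mode="nearest")

    def _ncc_scores(x, y):
        xm = x - _win_mean(x)
        x_var = _win_mean(xm * xm)
        out = np.empty((lags.size, *x.shape))
        for k, lag in enumerate(lags):
            ys = np.roll(y, lag, axis=1)
            ym = ys - _win_mean(ys)
            num = _win_mean(xm * ym)
            den = np.sqrt(np.maximum(x_var * _win_mean(ym * ym), 0.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                out[k] = np.where(den > 0, num / den, 0.0)
        return out

    scores = _ncc_scores(a, b)
    # RF correlation oscillates at the carrier, so the raw argmax can hop to
    # a neighboring carrier-period lobe.  The envelope cross-correlation is
    # smooth and hop-free: use its peak to select the lobe, then refine on
    # the RF scores within one sample of it.
    best = np.argmax(scores, axis=0)
    if lags.size >= 5:
        from scipy.signal import hilbert
        env_scores = _ncc_scores(np.abs(hilbert(a, axis=1)),
                                 np.abs(hilbert(b, axis=1)))
        k_env = np.argmax(env_scores, axis=0)
        offsets = np.arange(-1, 2)
        cand = np.clip(k_env[None] + offsets[:, None, None], 0, lags.size - 1)
        cand_scores = np.take_along_axis(scores, cand.reshape(3, *k_env.shape),
                                         axis=0)
        guided = np.take_along_axis(
            cand.reshape(3, *k_env.shape),
            np.argmax(cand_scores, axis=0)[None], axis=0)[0]
        # the raw RF argmax is the accurate estimate when it sits under the
        # envelope peak; when it strays a carrier period away it has hopped
        best = np.where(np.abs(best - k_env) <= 2, best, guided)
    ncc = np.take_along_axis(scores, best[None], axis=0)[0]
    km = np.clip(best, 1, lags.size - 2)
    c0 = np.take_along_axis(scores, km[None], axis=0)[0]
    cm = np.take_along_axis(scores, (km - 1)[None], axis=0)[0]
    cp = np.take_along_axis(scores, (km + 1)[None], axis=0)[0]
    # sub-sample refinement: cosine fit (matched to the carrier-oscillating
    # RF correlation), falling back to a 3-point parabola off-model
    denom = cm - 2 * c0 + cp
    with np.errstate(invalid="ignore", divide="ignore"):
        parab = np.where(np.abs(denom) > 1e-12, 0.5 * (cm - cp) / denom, 0.0)
        cos_arg = (cm + cp) / (2 * c0)
        ok = (np.abs(c0) > 1e-12) & (np.abs(cos_arg) < 1.0 - 1e-9)
        omega = np.arccos(np.clip(cos_arg, -1.0, 1.0))
        cosine = -np.arctan2(cm - cp, 2 * c0 * np.sin(omega)) / \
            np.where(omega > 1e-9, omega, 1.0)
        delta = np.where(ok & (omega > 1e-9), cosine, parab)
    delta = np.clip(delta, -1.0, 1.0)
    lag = lags[km] + delta

    half = w // 2
    in_bounds = np.zeros_like(a, dtype=bool)
    lo = half + max_lag
    hi = nz - half - max_lag
    if hi > lo:
        in_bounds[:, lo:hi] = True
    both = frame_i.valid & frame_j.valid
    # the window (shifted by up to max_lag) must lie in the valid region
    both = ndimage.minimum_filter1d(both, w + 2 * max_lag, axis=1,
                                    mode="constant", cval=False)
    valid = both & in_bounds
    # a peak on the search boundary is unresolved, not a measurement
    valid &= (best > 0) & (best < lags.size - 1)
    if ncc_threshold > 0:
        valid &= ncc >= ncc_threshold
    lag = np.where(valid, lag, 0.0)
    return DelayMap(lag, ncc, valid,
                    tx_i=_tx_label(frame_i), tx_j=_tx_label(frame_j))


def _tx_label(frame: RFFrame):
    d = frame.tx_descriptor
    return d.angle_deg if d.kind == "pw" else d.element


def accumulate_pw(increments: list[DelayMap], delta_theta: float,
                  delta_phi: float) -> DelayMap:
    """Chain ``delta_theta`` tracking increments into one ``delta_phi``
    disparity: lags add, validity is the conjunction, quality the minimum."""
    k = int(round(delta_phi / delta_theta))
    if len(increments) != k:
        raise ValueError(
            f"need {k} increments of {delta_theta} deg to span {delta_phi} deg, "
            f"got {len(increments)}")
    for a, b in zip(increments[:-1], increments[1:]):
        if a.tx_j is not None and b.tx_i is not None and \
                not np.isclose(a.tx_i, b.tx_j):
            raise ValueError(
                f"non-contiguous chain: increment ends at {a.tx_i} deg but "
                f"next starts from {b.tx_j} deg")
    lag = sum(m.lag for m in increments)
    valid = np.logical_and.reduce([m.valid for m in increments])
    ncc = np.minimum.reduce([m.ncc for m in increments])
    return DelayMap(np.where(valid, lag, 0.0), ncc, valid,
                    tx_i=increments[-1].tx_i, tx_j=increments[0].tx_j)


def select_pairs(spec: PairingSpec, available_tx) -> list[tuple]:
    """Deterministically place the M tracked pairs.

    DW: pairs ``(e, e + delta_channel)`` with first elements uniformly
    spaced across the array (the single pair sits at the array center for
    M=1).  PW: M symmetric angle pairs ``(c - delta_phi/2, c + delta_phi/2)``
    with centers uniformly spaced within the fan, snapped to the
    ``delta_theta`` angle grid.
    """
    avail = list(available_tx)
    if spec.scheme == "dw":
        n = len(avail)
        last = n - 1 - spec.delta_channel
        if last < 0:
            raise ValueError(
                f"delta_channel={spec.delta_channel} exceeds array of {n} elements")
        if spec.M == 1:
            firsts = np.array([last // 2])
        else:
            firsts = np.unique(np.round(np.linspace(0, last, spec.M)).astype(int))
        if firsts.size < spec.M:
            raise ValueError(
                f"cannot place M={spec.M} distinct pairs with "
                f"delta_channel={spec.delta_channel} on {n} elements")
        return [(avail[f], avail[f + spec.delta_channel]) for f in firsts]

    angles = np.asarray(avail, dtype=float)
    lo, hi = angles.min(), angles.max()
    if hi - lo < spec.delta_phi:
        raise ValueError(
            f"fan [{lo}, {hi}] deg too narrow for delta_phi={spec.delta_phi} deg")
    # place the lower angle of each pair on the delta_theta grid so every
    # chain endpoint is an available transmit angle
    n_steps = int(round((hi - lo - spec.delta_phi) / spec.delta_theta))
    if spec.M == 1:
        starts = np.array([round(n_steps / 2)])
    else:
        starts = np.round(np.linspace(0, n_steps, spec.M)).astype(int)
    pairs = []
    for k in starts:
        start = lo + k * spec.delta_theta
        pairs.append((start, start + spec.delta_phi))
    for th_i, th_j in pairs:
        for th in (th_i, th_j):
            if not np.isclose(angles, th).any():
                raise ValueError(f"pair angle {th} deg not among available angles")
    if len(set(pairs)) < spec.M:
        raise ValueError(
            f"cannot place M={spec.M} distinct pairs of disparity "
            f"{spec.delta_phi} deg on the {spec.delta_theta} deg grid in "
            f"[{lo}, {hi}] deg")
    return pairs


def correct_psf_angle(delays: np.ndarray, psi_psf: float) -> np.ndarray:
    """Project delays measured along a PSF axis at `psi_psf` degrees onto
    the axial direction: multiply by cos(psi_psf)."""
    return delays * np.cos(np.deg2rad(psi_psf))


def lag_to_seconds(lag_px: np.ndarray, grid: Grid, c0: float) -> np.ndarray:
    """Axial-sample lag -> echo-time delay.  A feature displaced one axial
    pixel deeper corresponds to a (two-way) arrival-time shift of
    ``2 dz / c0``."""
    return lag_px * (2.0 * grid.dz / c0)
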