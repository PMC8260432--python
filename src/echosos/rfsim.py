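"""Ray-based synthesis of multistatic RF channel data and transmit recomposition.

A full-matrix capture is simulated by straight-ray travel-time
superposition: each transmit element insonifies every density-perturbation
scatterer, whose echo is received on every channel at the two-leg
slowness line-integral arrival time, with 1/sqrt(geometric spreading)
amplitude and an optional cosine element-directivity falloff.  Any transmit
scheme that is linear in the per-element transmissions — angled plane
waves, single-element diverging waves, Walsh-Hadamard coded events — is
then recomposed from the multistatic set by superposition.

This is a first-order delay model: diffraction, multiple scattering,
attenuation and aberration physics of a full-wave solver are deliberately
not reproduced; arrival times, which drive the tomography downstream, are
exact for straight rays.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal
from scipy.linalg import hadamard as _hadamard_matrix

from .phantoms import ScattererField, SoSMap

__all__ = [
    "Transducer", "Pulse", "TxDescriptor", "ChannelData",
    "simulate_multistatic", "recompose_pw", "recompose_dw",
    "hadamard_encode", "hadamard_decode", "bandpass",
]


@dataclass(frozen=True)
class Transducer:
    """Linear array: 128 elements, 300 um pitch, 5 MHz center frequency by
    default; element centers on z=0, laterally centered on x=0."""

    n_channels: int = 128
    pitch: float = 300e-6
    fc: float = 5e6
    fs: float = 40e6

    def __post_init__(self) -> None:
        if self.fs < 4 * self.fc:
            raise ValueError(f"fs={self.fs:g} Hz below 4*fc={4 * self.fc:g} Hz")

    @property
    def element_x(self) -> np.ndarray:
        n = self.n_channels
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def aperture(self) -> float:
        return (self.n_channels - 1) * self.pitch


@dataclass(frozen=True)
class Pulse:
    """Windowed-sinusoid transmit pulse: `n_half_cycles` half cycles at `fc`
    under a Hann taper, mean-subtracted so the sampled waveform has exactly
    zero DC content."""

    fc: float = 5e6
    n_half_cycles: int = 3
    envelope: str = "hann"

    @property
    def duration(self) -> float:
        return self.n_half_cycles / (2.0 * self.fc)

    def samples(self, fs: float) -> tuple[np.ndarray, int]:
        """Sampled waveform and the index of its (temporal) center."""
        if fs < 4 * self.fc:
            raise ValueError(f"fs={fs:g} Hz too low to sample a {self.fc:g} Hz pulse")
        n = max(int(round(self.duration * fs)) | 1, 3)  # odd length, exact center
        t = np.arange(n) / fs
        w = signal.windows.hann(n) if self.envelope == "hann" else np.ones(n)
        s = w * np.sin(2 * np.pi * self.fc * t)
        s -= s.mean()
        peak = np.abs(s).max()
        if peak > 0:
            s /= peak
        return s, (n - 1) // 2


@dataclass(frozen=True)
class TxDescriptor:
    """Per-event transmit description: a single `element` for multistatic /
    DW events, an `angle_deg` for recomposed plane waves, or a Hadamard
    `code_row`."""

    kind: str  # "element" | "pw" | "dw" | "hadamard"
    element: int | None = None
    angle_deg: float | None = None
    code_row: int | None = None
    apodization: str | None = None


@dataclass
class ChannelData:
    """RF tensor ``rf[tx_event, rx_channel, sample]`` with acquisition metadata.

    ``t0`` is the time of the first sample relative to the transmit
    reference (the firing instant for multistatic/DW; the instant the
    plane wavefront crosses the array center for PW events).
    """

    rf: np.ndarray
    fs: float
    t0: float
    tx_descriptors: list[TxDescriptor]
    transducer: Transducer
    fc: float = 5e6
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=float)
        if self.rf.ndim != 3:
            raise ValueError("rf must be [tx_event, rx_channel, sample]")
        if len(self.tx_descriptors) != self.rf.shape[0]:
            raise ValueError("tx_descriptors length must match event count")
        if not np.all(np.isfinite(self.rf)):
            raise ValueError("rf contains non-finite samples")

    @property
    def n_events(self) -> int:
        return self.rf.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.rf.shape[2]) / self.fs


def _one_way_times(transducer: Transducer, sos_map: SoSMap,
                   sx: np.ndarray, sz: np.ndarray,
                   integration_step: float = 0.15e-3) -> np.ndarray:
    """Travel time (s) from every element to every scatterer along straight
    rays, by midpoint-rule integration of the slowness map (exact when the
    map is uniform)."""
    ex = transducer.element_x
    r = np.hypot(sx[None, :] - ex[:, None], sz[None, :])  # (ne, ns)
    sigma = sos_map.slowness
    if np.ptp(sos_map.values) == 0:
        return r / sos_map.values.flat[0]
    g = sos_map.grid
    step = min(integration_step, 0.5 * max(g.dx, g.dz))
    k = max(int(np.ceil(r.max() / step)), 4)
    u = (np.arange(k) + 0.5) / k
    times = np.empty_like(r)
    for e in range(ex.size):  # chunk per element to bound memory
        xs = ex[e] + u[None, :] * (sx[:, None] - ex[e])
        zs = u[None, :] * sz[:, None]
        ci = (xs - g.x0) / g.dx
        cj = (zs - g.z0) / g.dz
        vals = ndimage.map_coordinates(sigma, [ci.ravel(), cj.ravel()],
                                       order=1, mode="nearest")
        times[e] = vals.reshape(sx.size, k).mean(axis=1) * r[e]
    return times


def simulate_multistatic(transducer: Transducer, sos_map: SoSMap,
                         scatterers: ScattererField, pulse: Pulse | None = None,
                         *, directivity_cutoff_deg: float | None = 35.0,
                         pad_time: float = 2e-6) -> ChannelData:
    """Full-matrix capture: one event per transmit element, all channels
    receiving.

    Echo arrival time for (tx element e, scatterer s, rx element r) is the
    slowness line integral e->s plus s->r; amplitude is the scatterer
    perturbation over sqrt(r_tx * r_rx), times an optional cosine
    directivity window cut off at `directivity_cutoff_deg` from the element
    normal (emulating the triangular insonification opening of a single
    narrow element).
    """
    if pulse is None:
        pulse = Pulse(fc=transducer.fc)
    if scatterers.grid != sos_map.grid:
        raise ValueError("scatterer grid must be congruent with the SoS map grid")
    g = sos_map.grid
    sx, sz = scatterers.positions
    amp = scatterers.amplitudes
    lo_x, hi_x = g.extent_x
    lo_z, hi_z = g.extent_z
    if sx.size and (sx.min() < lo_x or sx.max() > hi_x or
                    sz.min() < lo_z or sz.max() > hi_z):
        raise ValueError("scatterer outside the SoS map grid")

    fs = transducer.fs
    pulse_samples, center = pulse.samples(fs)
    ne = transducer.n_channels
    if sx.size == 0:
        n_samp = int(round(pad_time * fs)) + pulse_samples.size
        rf = np.zeros((ne, ne, n_samp))
        desc = [TxDescriptor("element", element=e) for e in range(ne)]
        return ChannelData(rf, fs, 0.0, desc, transducer, fc=pulse.fc)

    T = _one_way_times(transducer, sos_map, sx, sz)  # (ne, ns)
    ex = transducer.element_x
    r = np.hypot(sx[None, :] - ex[:, None], sz[None, :])
    r = np.maximum(r, transducer.pitch)
    weight = 1.0 / np.sqrt(r)
    if directivity_cutoff_deg is not None:
        theta = np.arctan2(np.abs(sx[None, :] - ex[:, None]), sz[None, :])
        cutoff = np.deg2rad(directivity_cutoff_deg)
        weight = weight * np.cos(theta) * (theta <= cutoff)

    t_max = 2 * T.max() + pad_time
    n_samp = int(np.ceil(t_max * fs)) + pulse_samples.size
    rf = np.zeros((ne, ne, n_samp))
    rx_off = np.arange(ne)[:, None] * n_samp
    for e in range(ne):
        t_tot = T[e][None, :] + T  # (n_rx, ns)
        a = amp[None, :] * weight[e][None, :] * weight
        pos = t_tot * fs
        i0 = np.floor(pos).astype(np.intp)
        frac = pos - i0
        flat = (rx_off + i0).ravel()
        trace = np.bincount(flat, weights=(a * (1.0 - frac)).ravel(),
                            minlength=ne * n_samp)
        trace += np.bincount(flat + 1, weights=(a * frac).ravel(),
                             minlength=ne * n_samp)[:ne * n_samp]
        rf[e] = trace[:ne * n_samp].reshape(ne, n_samp)
    full = signal.fftconvolve(rf, pulse_samples[None, None, :], mode="full")
    rf = full[..., center:center + n_samp]
    desc = [TxDescriptor("element", element=e) for e in range(ne)]
    return ChannelData(rf, fs, 0.0, desc, transducer, fc=pulse.fc)


def _require_multistatic(data: ChannelData) -> None:
    for i, d in enumerate(data.tx_descriptors):
        if d.kind != "element" or d.element != i:
            raise ValueError(
                "input must be a complete multistatic capture "
                f"(event {i} has descriptor {d})")


def _fractional_delay(x: np.ndarray, shift_samples: float) -> np.ndarray:
    """y(t) = x(t - shift): linear-interpolation time shift along last axis."""
    n = x.shape[-1]
    pos = np.arange(n) - shift_samples
    i0 = np.floor(pos).astype(np.intp)
    frac = pos - i0
    i0c = np.clip(i0, 0, n - 1)
    i1c = np.clip(i0 + 1, 0, n - 1)
    valid0 = (i0 >= 0) & (i0 <= n - 1)
    valid1 = (i0 + 1 >= 0) & (i0 + 1 <= n - 1)
    return x[..., i0c] * (1 - frac) * valid0 + x[..., i1c] * frac * valid1


def recompose_pw(multistatic: ChannelData, angles_deg,
                 apodization: str = "tukey", tukey_alpha: float = 0.25,
                 c0: float = 1500.0) -> ChannelData:
    """Synthesize angled plane-wave events from the multistatic capture.

    Element e fires at ``x_e sin(theta) / c0`` so the wavefront crosses the
    array center at the transmit reference time; events are the apodized
    sums of the correspondingly delayed single-element events.  Delays are
    applied spectrally (exact for band-limited RF): sub-sample
    interpolation bias here would turn into a coherent per-angle delay
    offset, which the ill-conditioned limited-angle inversion amplifies
    into a global speed-of-sound offset.
    """
    _require_multistatic(multistatic)
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if np.any(np.abs(angles) > 45):
        bad = angles[np.abs(angles) > 45][0]
        raise ValueError(f"|angle| = {abs(bad):g} deg exceeds 45 deg")
    ex = multistatic.transducer.element_x
    ne = ex.size
    if apodization == "tukey":
        apod = signal.windows.tukey(ne, tukey_alpha)
    elif apodization in ("rect", "none"):
        apod = np.ones(ne)
    else:
        raise ValueError(f"unknown apodization {apodization!r}")
    fs = multistatic.fs
    n = multistatic.rf.shape[2]
    # zero-pad so the circular spectral shift cannot wrap echo energy
    max_shift = int(np.ceil(np.abs(ex).max() * np.sin(np.deg2rad(45)) / c0 * fs))
    n_pad = n + max_shift + 8
    spectra = np.fft.rfft(multistatic.rf, n_pad, axis=2)  # (ne, n_rx, n_freq)
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / fs)
    out = np.empty((angles.size, ne, n))
    for a, ang in enumerate(angles):
        tau = ex * np.sin(np.deg2rad(ang)) / c0  # firing time per element
        phase = np.exp(-2j * np.pi * freqs[None, :] * tau[:, None])
        acc = np.einsum("ef,erf->rf", apod[:, None] * phase, spectra)
        out[a] = np.fft.irfft(acc, n_pad, axis=1)[:, :n]
    desc = [TxDescriptor("pw", angle_deg=float(a), apodization=apodization)
            for a in angles]
    return ChannelData(out, fs, multistatic.t0, desc, multistatic.transducer,
                       fc=multistatic.fc)


def recompose_dw(multistatic: ChannelData, tx_elements) -> ChannelData:
    """Diverging-wave events are single-element transmissions: a selection of
    multistatic events, relabeled."""
    _require_multistatic(multistatic)
    idx = list(tx_elements)
    if len(idx) == 0:
        raise ValueError("tx_elements must be non-empty")
    ne = multistatic.n_events
    for e in idx:
        if not 0 <= e < ne:
            raise ValueError(f"tx element {e} out of range [0, {ne})")
    rf = multistatic.rf[idx].copy()
    desc = [TxDescriptor("dw", element=int(e)) for e in idx]
    return ChannelData(rf, multistatic.fs, multistatic.t0, desc,
                       multistatic.transducer, fc=multistatic.fc)


def hadamard_encode(multistatic: ChannelData) -> ChannelData:
    """Walsh-Hadamard coded events: event k = sum_e H[k, e] * event_e."""
    _require_multistatic(multistatic)
    n = multistatic.n_events
    if n & (n - 1) != 0:
        raise ValueError(f"Hadamard coding needs a power-of-two event count, got {n}")
    H = _hadamard_matrix(n).astype(float)
    rf = np.tensordot(H, multistatic.rf, axes=(1, 0))
    desc = [TxDescriptor("hadamard", code_row=k) for k in range(n)]
    return ChannelData(rf, multistatic.fs, multistatic.t0, desc,
                       multistatic.transducer, fc=multistatic.fc)


def hadamard_decode(encoded: ChannelData) -> ChannelData:
    """Inverse Walsh-Hadamard transform back to single-element events."""
    n = encoded.n_events
    if n & (n - 1) != 0:
        raise ValueError(f"Hadamard decoding needs a power-of-two event count, got {n}")
    for k, d in enumerate(encoded.tx_descriptors):
        if d.kind != "hadamard" or d.code_row != k:
            raise ValueError(f"event {k} is not Hadamard-coded in order ({d})")
    H = _hadamard_matrix(n).astype(float)
    rf = np.tensordot(H.T / n, encoded.rf, axes=(1, 0))
    desc = [TxDescriptor("element", element=e) for e in range(n)]
    return ChannelData(rf, encoded.fs, encoded.t0, desc, encoded.transducer,
                       fc=encoded.fc)


def bandpass(data: ChannelData, fractional_bandwidth: float = 0.60,
             numtaps: int = 121) -> ChannelData:
    """Zero-phase band-pass around the pulse center frequency with passband
    width ``fractional_bandwidth * fc`` (a 60% fractional bandwidth passes
    3.5-6.5 MHz at fc = 5 MHz)."""
    if fractional_bandwidth <= 0:
        raise ValueError("fractional bandwidth must be positive")
    fc, fs = data.fc, data.fs
    f_lo = fc * (1 - 0.5 * fractional_bandwidth)
    f_hi = fc * (1 + 0.5 * fractional_bandwidth)
    if f_hi >= fs / 2:
        raise ValueError(
            f"passband edge {f_hi:g} Hz exceeds Nyquist {fs / 2:g} Hz")
    taps = signal.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=fs)
    padlen = min(3 * numtaps, data.rf.shape[2] - 1)
    rf = signal.filtfilt(taps, [1.0], data.rf, axis=2, padlen=padlen)
    return replace(data, rf=rf)
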