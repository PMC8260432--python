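import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echosos import (Grid, Pulse, ScattererField, SoSMap, Transducer,
                     bandpass, envelope, hadamard_decode, hadamard_encode,
                     make_homogeneous_phantom, make_scatterers,
                     recompose_dw, recompose_pw, simulate_multistatic)
from echosos.rfsim import ChannelData, TxDescriptor


def _single_scatterer(grid, x, z, amp=1.0):
    pert = np.zeros(grid.shape)
    ix = int(np.argmin(np.abs(grid.x - x)))
    iz = int(np.argmin(np.abs(grid.z - z)))
    pert[ix, iz] = amp
    return ScattererField(pert, grid, 0.01, amp, 0), grid.x[ix], grid.z[iz]


@pytest.fixture(scope="module")
def small_transducer():
    return Transducer(n_channels=8, pitch=1e-3, fs=40e6)


@pytest.fixture(scope="module")
def small_multistatic(small_transducer):
    g = Grid(21, 80, 0.5e-3, 0.5e-3, -5e-3, 0.25e-3)
    medium = make_homogeneous_phantom(g, 1500.0)
    scat, _, _ = _single_scatterer(g, 0.0, 15e-3)
    return simulate_multistatic(small_transducer, medium, scat)


class TestSimulate:
    def test_pulse_echo_two_way_time(self, small_transducer):
        g = Grid(21, 80, 0.5e-3, 0.5e-3, -5e-3, 0.25e-3)
        medium = make_homogeneous_phantom(g, 1500.0)
        e = 4  # element at x = +0.5 mm
        scat, xs, zs = _single_scatterer(g, small_transducer.element_x[e], 15e-3)
        d = simulate_multistatic(small_transducer, medium, scat)
        peak = np.argmax(envelope(d.rf[e, e])) / d.fs
        assert abs(peak - 2 * zs / 1500.0) <= 1.0 / d.fs

    def test_layered_medium_closed_form_time(self, small_transducer):
        g = Grid(21, 80, 0.5e-3, 0.5e-3, -5e-3, 0.25e-3)
        vals = np.full(g.shape, 1400.0)
        vals[:, g.z > 10e-3] = 1600.0  # c1 over c2, interface at 10 mm
        medium = SoSMap(vals, g)
        e = 4
        scat, xs, zs = _single_scatterer(g, small_transducer.element_x[e], 18e-3)
        d = simulate_multistatic(small_transducer, medium, scat)
        z1 = 10e-3  # bilinear sampling puts the effective interface midway
        expected = 2 * (z1 / 1400.0 + (zs - z1) / 1600.0)
        peak = np.argmax(envelope(d.rf[e, e])) / d.fs
        assert abs(peak - expected) <= 1.0 / d.fs

    def test_empty_scene_is_silent(self, small_transducer):
        g = Grid(15, 30, 1e-3, 1e-3, -7e-3, 0.5e-3)
        medium = make_homogeneous_phantom(g, 1500.0)
        scat = ScattererField(np.zeros(g.shape), g, 0.01, 0.0, 0)
        d = simulate_multistatic(small_transducer, medium, scat)
        assert np.all(d.rf == 0)

    def test_incongruent_scatterer_grid_rejected(self, small_transducer):
        g1 = Grid(15, 30, 1e-3, 1e-3, -7e-3, 0.5e-3)
        g2 = Grid(15, 30, 0.9e-3, 1e-3, -7e-3, 0.5e-3)
        with pytest.raises(ValueError, match="congruent"):
            simulate_multistatic(small_transducer,
                                 make_homogeneous_phantom(g1),
                                 make_scatterers(g2, 0.1, 0.05, 0))


class TestRecomposePW:
    def test_event_count_for_81_angle_fan(self, small_multistatic):
        angles = np.arange(-20, 20.25, 0.5)
        out = recompose_pw(small_multistatic, angles)
        assert out.n_events == 81
        assert out.tx_descriptors[0].kind == "pw"

    def test_zero_angle_rect_taper_is_plain_sum(self, small_multistatic):
        out = recompose_pw(small_multistatic, [0.0], apodization="rect")
        assert np.allclose(out.rf[0], small_multistatic.rf.sum(axis=0))

    def test_single_event_reduces_to_delay(self, small_multistatic):
        ms = small_multistatic
        keep = 2
        rf = np.zeros_like(ms.rf)
        rf[keep] = ms.rf[keep]
        lone = ChannelData(rf, ms.fs, ms.t0, ms.tx_descriptors, ms.transducer,
                           fc=ms.fc)
        ang = 30.0  # element 2 at x = -1.5 mm: delay is exactly -20 samples
        out = recompose_pw(lone, [ang], apodization="rect")
        tau = ms.transducer.element_x[keep] * np.sin(np.deg2rad(ang)) / 1500.0
        shift = int(round(tau * ms.fs))
        assert shift * 1.0 == pytest.approx(tau * ms.fs)  # integer by design
        ref = np.zeros_like(ms.rf[keep])
        if shift <= 0:
            ref[:, :shift or None] = ms.rf[keep][:, -shift:]
        else:
            ref[:, shift:] = ms.rf[keep][:, :-shift]
        peak = np.abs(ref).max()
        assert np.allclose(out.rf[0], ref, atol=1e-9 * peak)

    def test_linearity_of_recomposition(self, small_multistatic):
        ms = small_multistatic
        doubled = ChannelData(2.0 * ms.rf, ms.fs, ms.t0, ms.tx_descriptors,
                              ms.transducer, fc=ms.fc)
        a = recompose_pw(ms, [5.0])
        b = recompose_pw(doubled, [5.0])
        assert np.allclose(b.rf, 2.0 * a.rf)

    def test_steep_angle_rejected(self, small_multistatic):
        with pytest.raises(ValueError, match="45"):
            recompose_pw(small_multistatic, [50.0])


class TestRecomposeDW:
    def test_selection_identity(self, small_multistatic):
        out = recompose_dw(small_multistatic, [5])
        assert np.array_equal(out.rf[0], small_multistatic.rf[5])
        assert out.tx_descriptors[0] == TxDescriptor("dw", element=5)

    def test_full_reorder(self, small_multistatic):
        order = list(range(small_multistatic.n_events))[::-1]
        out = recompose_dw(small_multistatic, order)
        assert np.array_equal(out.rf, small_multistatic.rf[order])

    def test_empty_and_out_of_range_rejected(self, small_multistatic):
        with pytest.raises(ValueError, match="non-empty"):
            recompose_dw(small_multistatic, [])
        with pytest.raises(ValueError, match="out of range"):
            recompose_dw(small_multistatic, [99])


class TestHadamard:
    def test_round_trip_lossless(self, small_multistatic):
        dec = hadamard_decode(hadamard_encode(small_multistatic))
        peak = np.abs(small_multistatic.rf).max()
        assert np.abs(dec.rf - small_multistatic.rf).max() < 1e-10 * peak

    def test_first_row_is_sum_of_events(self):
        tdx = Transducer(n_channels=4, pitch=1e-3, fs=40e6)
        rf = np.zeros((4, 4, 32))
        for e in range(4):  # unit impulses at distinct times
            rf[e, :, 4 * e + 2] = 1.0
        ms = ChannelData(rf, 40e6, 0.0,
                         [TxDescriptor("element", element=e) for e in range(4)],
                         tdx)
        enc = hadamard_encode(ms)
        assert np.allclose(enc.rf[0], rf.sum(axis=0))

    def test_zero_tensor_round_trip(self):
        tdx = Transducer(n_channels=4, pitch=1e-3, fs=40e6)
        ms = ChannelData(np.zeros((4, 4, 16)), 40e6, 0.0,
                         [TxDescriptor("element", element=e) for e in range(4)],
                         tdx)
        assert np.all(hadamard_decode(hadamard_encode(ms)).rf == 0)

    def test_non_power_of_two_rejected(self):
        tdx = Transducer(n_channels=6, pitch=1e-3, fs=40e6)
        ms = ChannelData(np.zeros((6, 6, 16)), 40e6, 0.0,
                         [TxDescriptor("element", element=e) for e in range(6)],
                         tdx)
        with pytest.raises(ValueError, match="power-of-two"):
            hadamard_encode(ms)


class TestBandpass:
    def _tone(self, freq, fs=40e6, n=2000, fc=5e6):
        tdx = Transducer(n_channels=4, pitch=1e-3, fs=fs)
        t = np.arange(n) / fs
        rf = np.broadcast_to(np.sin(2 * np.pi * freq * t), (4, 4, n)).copy()
        return ChannelData(rf, fs, 0.0,
                           [TxDescriptor("element", element=e) for e in range(4)],
                           tdx, fc=fc)

    def test_center_tone_preserved(self):
        out = bandpass(self._tone(5e6))
        mid = np.s_[500:1500]
        ratio = np.abs(out.rf[0, 0, mid]).max() / 1.0
        assert abs(ratio - 1.0) < 0.05

    def test_third_harmonic_attenuated_40dB(self):
        out = bandpass(self._tone(15e6))
        mid = np.s_[500:1500]
        assert np.abs(out.rf[0, 0, mid]).max() < 10 ** (-40 / 20)

    def test_zero_in_zero_out(self):
        tdx = Transducer(n_channels=4, pitch=1e-3, fs=40e6)
        ms = ChannelData(np.zeros((4, 4, 500)), 40e6, 0.0,
                         [TxDescriptor("element", element=e) for e in range(4)],
                         tdx)
        assert np.all(bandpass(ms).rf == 0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(self._tone(5e6), fractional_bandwidth=-0.1)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(self._tone(5e6, fs=20e6), fractional_bandwidth=2.2)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_hadamard_round_trip_random_tensors(seed):
    rng = np.random.default_rng(seed)
    tdx = Transducer(n_channels=8, pitch=1e-3, fs=40e6)
    rf = rng.standard_normal((8, 8, 64))
    ms = ChannelData(rf, 40e6, 0.0,
                     [TxDescriptor("element", element=e) for e in range(8)],
                     tdx)
    dec = hadamard_decode(hadamard_encode(ms))
    assert np.abs(dec.rf - rf).max() < 1e-10 * np.abs(rf).max()


def test_pulse_zero_mean_and_support():
    for n_half in (3, 4):
        p = Pulse(fc=5e6, n_half_cycles=n_half)
        s, center = p.samples(40e6)
        assert abs(s.mean()) <= 0.01 * np.abs(s).max()
        assert 0 < center < s.size
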