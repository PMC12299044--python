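"""RF synthesis: pulse-echo traces and the three imaging modes."""

import numpy as np
import pytest
from scipy.signal import hilbert

from fastecho import (
    Excitation,
    ScattererField,
    build_linear_array,
    element_quadrature,
    simulate_bmode,
    simulate_plane_wave,
    simulate_synthetic_aperture,
    transient_pressure,
)
from fastecho.rf import BModeScanConfig, pulse_echo_trace


@pytest.fixture(scope="module")
def small_element(medium):
    return build_linear_array(1, 0.3e-3, 7e-3, 0.0)


def monostatic(medium, z, exc, fs=16e6):
    arr = build_linear_array(1, 0.3e-3, 7e-3, 0.0)
    q = element_quadrature(arr)
    pT = transient_pressure(arr.positions[0], [0, 0, z], exc, medium, q, fs=fs)
    return pulse_echo_trace(pT, pT, 1.0, medium)


class TestPulseEchoTrace:
    def test_zero_amplitude_and_linearity(self, medium, pulse_3mhz, array128, quad128):
        pT = transient_pressure(
            array128.positions[64], [0, 0, 0.03], pulse_3mhz, medium, quad128,
            fs=16e6,
        )
        assert not np.any(pulse_echo_trace(pT, pT, 0.0, medium).data)
        t1 = pulse_echo_trace(pT, pT, 1.0, medium)
        t2 = pulse_echo_trace(pT, pT, 2.0, medium)
        assert np.allclose(t2.data, 2.0 * t1.data)

    def test_start_time_is_sum_of_inputs(self, medium, pulse_3mhz, array128, quad128):
        pT = transient_pressure(
            array128.positions[64], [0, 0, 0.03], pulse_3mhz, medium, quad128,
            fs=16e6,
        )
        tr = pulse_echo_trace(pT, pT, 1.0, medium)
        assert tr.start == 2 * pT.start - 1  # one padding sample for the derivative

    def test_monostatic_envelope_peak_time(self, medium):
        # point at z=30 mm: envelope peak at 2z/c plus the two-way pulse
        # center offset, within half the pulse length
        exc = Excitation(f0=3e6, n_cycles=1)
        tr = monostatic(medium, 0.030, exc)
        env = np.abs(hilbert(tr.data))
        t_peak = (tr.start + np.argmax(env)) / tr.fs
        t_expect = 2 * 0.030 / medium.sound_speed + exc.duration
        assert 2 * 0.030 / 1540 == pytest.approx(38.96e-6, rel=1e-3)
        assert abs(t_peak - t_expect) <= exc.duration / 2

    def test_mismatched_fs_rejected(self, medium, pulse_3mhz, array128, quad128):
        pa = transient_pressure(
            array128.positions[64], [0, 0, 0.03], pulse_3mhz, medium, quad128,
            fs=16e6,
        )
        pb = transient_pressure(
            array128.positions[64], [0, 0, 0.03], pulse_3mhz, medium, quad128,
            fs=32e6,
        )
        with pytest.raises(ValueError):
            pulse_echo_trace(pa, pb, 1.0, medium)

    def test_far_field_inverse_square_decay(self, medium):
        # two-way amplitude ~ 1/r^2 for a point-like (small) element
        arr = build_linear_array(1, 0.3e-3, 0.3e-3, 0.0)
        exc = Excitation(f0=3e6, n_cycles=1)
        q = element_quadrature(arr, 1, 2)

        def peak(z):
            pT = transient_pressure(arr.positions[0], [0, 0, z], exc, medium, q, fs=64e6)
            return np.abs(hilbert(pulse_echo_trace(pT, pT, 1.0, medium).data)).max()

        ratio = peak(0.05) / peak(0.10)
        assert ratio == pytest.approx(4.0, rel=0.05)


class TestSyntheticAperture:
    @pytest.fixture(scope="class")
    def rf(self, medium, pulse_3mhz):
        arr = build_linear_array(4, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(
            positions=np.array([[0.002, 0.0005, 0.025]]),
            amplitudes=np.array([1.3]),
        )
        return simulate_synthetic_aperture(arr, scat, pulse_3mhz, medium, fs=16e6)

    def test_one_event_per_element(self, rf):
        assert len(rf) == 4
        assert all(len(ev.tx_indices) == 1 for ev in rf.events)

    def test_reciprocity(self, rf):
        # transmit i / receive j equals transmit j / receive i exactly
        assert np.allclose(rf.data[0][3], rf.data[3][0], rtol=0, atol=1e-12)
        assert np.abs(rf.data[0][3]).max() > 0

    def test_superposition_over_scatterers(self, medium, pulse_3mhz, rf):
        arr = build_linear_array(4, 0.3e-3, 7e-3, 0.05e-3)
        s1 = ScattererField(np.array([[0.002, 0.0005, 0.025]]), np.array([1.3]))
        s2 = ScattererField(np.array([[-0.001, 0.0, 0.030]]), np.array([-0.7]))
        both = simulate_synthetic_aperture(
            arr, s1 + s2, pulse_3mhz, medium, fs=16e6
        )
        a = simulate_synthetic_aperture(
            arr, s1, pulse_3mhz, medium, fs=16e6, grid=both.grid
        )
        b = simulate_synthetic_aperture(
            arr, s2, pulse_3mhz, medium, fs=16e6, grid=both.grid
        )
        for k in range(4):
            assert np.allclose(both.data[k], a.data[k] + b.data[k], atol=1e-12)

    def test_empty_scatterer_field_rejected(self, medium, pulse_3mhz):
        arr = build_linear_array(2, 0.3e-3, 7e-3, 0.05e-3)
        empty = (np.empty((0, 3)), np.empty(0))
        with pytest.raises(ValueError):
            simulate_synthetic_aperture(arr, empty, pulse_3mhz, medium, fs=16e6)

    def test_axial_shift_moves_echo_by_two_way_time(self, medium, pulse_3mhz):
        arr = build_linear_array(1, 0.3e-3, 7e-3, 0.05e-3)
        dz = 1.5e-3
        s0 = ScattererField(np.array([[0.0, 0.0, 0.030]]), np.array([1.0]))
        s1 = ScattererField(np.array([[0.0, 0.0, 0.030 + dz]]), np.array([1.0]))
        r0 = simulate_synthetic_aperture(arr, s0, pulse_3mhz, medium, fs=16e6)
        r1 = simulate_synthetic_aperture(
            arr, s1, pulse_3mhz, medium, fs=16e6, grid=r0.grid
        )
        c0 = np.correlate(r1.data[0][0], r0.data[0][0], "full")
        lag = np.argmax(c0) - len(r0.data[0][0]) + 1
        expected = 2 * dz / medium.sound_speed * 16e6
        assert abs(lag - expected) <= 1.0


class TestPlaneWave:
    def test_single_element_equals_synthetic_aperture(self, medium, pulse_3mhz):
        arr = build_linear_array(1, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.001, 0.0, 0.02]]), np.array([1.0]))
        pw = simulate_plane_wave(arr, scat, pulse_3mhz, medium, 16e6, [0.0])
        sa = simulate_synthetic_aperture(
            arr, scat, pulse_3mhz, medium, fs=16e6, grid=pw.grid
        )
        assert np.allclose(pw.data[0], sa.data[0], atol=1e-12)

    def test_zero_angle_symmetric_channels(self, medium, pulse_3mhz):
        arr = build_linear_array(8, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.0, 0.0, 0.03]]), np.array([1.0]))
        pw = simulate_plane_wave(arr, scat, pulse_3mhz, medium, 16e6, [0.0])
        env = np.abs(hilbert(pw.data[0], axis=-1))
        peaks = env.argmax(axis=1)
        assert np.array_equal(peaks, peaks[::-1])

    def test_event_per_angle_with_offsets(self, medium, pulse_3mhz):
        arr = build_linear_array(8, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.0, 0.0, 0.03]]), np.array([1.0]))
        pw = simulate_plane_wave(
            arr, scat, pulse_3mhz, medium, 16e6, [-6.0, 0.0, 6.0]
        )
        assert [ev.angle_deg for ev in pw.events] == [-6.0, 0.0, 6.0]
        assert all(ev.delays.delays.min() >= 0 for ev in pw.events)

    def test_no_angles_rejected(self, medium, pulse_3mhz):
        arr = build_linear_array(2, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.0, 0.0, 0.03]]), np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_plane_wave(arr, scat, pulse_3mhz, medium, 16e6, [])


class TestBMode:
    def test_single_element_subaperture_reduces_to_sa(self, medium, pulse_3mhz):
        arr = build_linear_array(3, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.0, 0.0, 0.03]]), np.array([1.0]))
        bm = simulate_bmode(
            arr, scat, pulse_3mhz, medium, 16e6,
            scan_config=BModeScanConfig(
                n_subaperture=1, focus_depth=0.03,
                aline_positions=np.array([arr.centers_x[1]]),
            ),
        )
        sa = simulate_synthetic_aperture(
            arr, scat, pulse_3mhz, medium, fs=16e6, grid=bm.grid,
            tx_elements=[1],
        )
        assert np.allclose(bm.data[0], sa.data[0], atol=1e-12)

    def test_hanning_apodization_shape(self, medium, pulse_3mhz):
        arr = build_linear_array(80, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.0, 0.0, 0.06]]), np.array([1.0]))
        bm = simulate_bmode(
            arr, scat, pulse_3mhz, medium, 16e6,
            scan_config=BModeScanConfig(
                n_subaperture=64, focus_depth=0.06,
                aline_positions=np.array([0.0]),
            ),
        )
        apod = bm.events[0].apodization
        assert apod[0] == pytest.approx(0.0, abs=1e-12)
        assert apod.max() == pytest.approx(1.0, abs=1e-3)

    def test_subaperture_clamped_at_edges(self, medium, pulse_3mhz):
        arr = build_linear_array(8, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.0, 0.0, 0.03]]), np.array([1.0]))
        bm = simulate_bmode(
            arr, scat, pulse_3mhz, medium, 16e6,
            scan_config=BModeScanConfig(
                n_subaperture=4, focus_depth=0.03,
                aline_positions=np.array([arr.centers_x[0], arr.centers_x[-1]]),
            ),
        )
        assert bm.events[0].tx_indices[0] == 0
        assert bm.events[1].tx_indices[-1] == 7

    def test_oversized_subaperture_rejected(self, medium, pulse_3mhz):
        arr = build_linear_array(8, 0.3e-3, 7e-3, 0.05e-3)
        scat = ScattererField(np.array([[0.0, 0.0, 0.03]]), np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_bmode(
                arr, scat, pulse_3mhz, medium, 16e6,
                scan_config=BModeScanConfig(n_subaperture=16),
            )
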