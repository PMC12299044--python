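"""Transient-field evaluation: quadrature rules, causality, far-field
limit, delayed copies, and the intermediate cache."""

import numpy as np
import pytest

from fastecho import (
    Excitation,
    Medium,
    build_intermediate_cache,
    build_linear_array,
    delayed_copy,
    element_quadrature,
    transient_pressure,
    uniform_quadrature,
)
from fastecho.field import SingularGeometryError, Waveform
from tests.conftest import waveform_nrmse


class TestQuadratureSets:
    def test_single_node_at_center(self):
        arr = build_linear_array(1, 2e-3, 3e-3, 0.0)
        q = element_quadrature(arr, 1, 1)
        assert q.order == 1
        assert np.allclose(q.offsets, 0.0)
        assert q.weights[0] == pytest.approx(arr.element_area)

    def test_2x2_gauss_nodes_on_unit_square(self):
        arr = build_linear_array(1, 1.0, 1.0, 0.0)
        q = element_quadrature(arr, 2, 2)
        expected = 1.0 / (2.0 * np.sqrt(3.0))
        assert np.allclose(np.sort(np.abs(q.offsets), axis=0), expected)
        assert np.allclose(q.weights, 0.25)

    @pytest.mark.parametrize("orders", [(1, 6), (2, 25), (3, 3)])
    def test_weights_sum_to_area(self, array128, orders):
        q = element_quadrature(array128, *orders)
        assert q.weights.sum() == pytest.approx(array128.element_area)

    def test_uniform_weights_sum_to_area(self, array128):
        q = uniform_quadrature(array128, 0.1e-3)
        assert q.weights.sum() == pytest.approx(array128.element_area)
        assert np.all(q.weights > 0)

    def test_invalid_orders_rejected(self, array128):
        with pytest.raises(ValueError):
            element_quadrature(array128, 0, 6)
        with pytest.raises(ValueError):
            uniform_quadrature(array128, -1.0)


class TestTransientPressure:
    def test_causal_support(self, array128, medium, pulse_3mhz, quad128):
        point = np.array([5e-3, 1e-3, 0.030])
        w = transient_pressure(
            array128.positions[64], point, pulse_3mhz, medium, quad128, fs=32e6
        )
        d_near = np.linalg.norm(point - array128.positions[64]) - 4e-3
        first_nonzero = w.start + np.flatnonzero(w.data)[0]
        assert first_nonzero / w.fs >= d_near / medium.sound_speed

    def test_far_field_point_source_amplitude(self, medium):
        # z >> aperture: peak -> rho0 * A * max|dw/dt| / (2 pi z)
        arr = build_linear_array(1, 0.3e-3, 0.3e-3, 0.0)
        exc = Excitation(f0=3e6, n_cycles=1)
        z = 0.2
        w = transient_pressure(
            arr.positions[0], [0, 0, z], exc, medium, element_quadrature(arr, 2, 2),
            fs=256e6,
        )
        expected = (
            medium.density * arr.element_area * 2 * np.pi * exc.f0 / (2 * np.pi * z)
        )
        assert np.abs(w.data).max() == pytest.approx(expected, rel=0.01)

    def test_six_abscissa_matches_dense_oracle(self, array128, medium, pulse_3mhz):
        lam = medium.sound_speed / pulse_3mhz.f0
        point = np.array([0.0, 0.0, 0.060])
        w6 = transient_pressure(
            array128.positions[64], point, pulse_3mhz, medium,
            element_quadrature(array128, 1, 6), fs=64e6,
        )
        wd = transient_pressure(
            array128.positions[64], point, pulse_3mhz, medium,
            uniform_quadrature(array128, lam / 8), fs=64e6,
        )
        assert waveform_nrmse(w6, wd) < 1e-3

    def test_quadrature_order_convergence(self, array128, medium, pulse_3mhz):
        """NRMSE against the dense oracle is non-increasing in elevation
        order (plateaus allowed)."""
        lam = medium.sound_speed / pulse_3mhz.f0
        point = np.array([3e-3, 0.0, 0.045])
        ref = transient_pressure(
            array128.positions[64], point, pulse_3mhz, medium,
            uniform_quadrature(array128, lam / 16), fs=64e6,
        )
        errs = []
        for oy in (1, 2, 4, 8):
            w = transient_pressure(
                array128.positions[64], point, pulse_3mhz, medium,
                element_quadrature(array128, 1, oy), fs=64e6,
            )
            errs.append(waveform_nrmse(w, ref))
        assert all(b <= a * 1.05 for a, b in zip(errs, errs[1:]))

    def test_linearity_in_amplitude(self, array128, medium, quad128):
        point = np.array([0.0, 0.0, 0.04])
        w1 = transient_pressure(
            array128.positions[0], point, Excitation(3e6, 1, amplitude=1.0),
            medium, quad128, fs=32e6,
        )
        w3 = transient_pressure(
            array128.positions[0], point, Excitation(3e6, 1, amplitude=3.0),
            medium, quad128, fs=32e6,
        )
        assert np.allclose(w3.data, 3.0 * w1.data, rtol=1e-12, atol=1e-9)

    def test_point_on_face_rejected(self, array128, medium, pulse_3mhz, quad128):
        with pytest.raises(SingularGeometryError):
            transient_pressure(
                array128.positions[0], array128.positions[0], pulse_3mhz,
                medium, quad128, fs=32e6,
            )


class TestDelayedCopy:
    @pytest.fixture()
    def waveform(self, array128, medium, pulse_3mhz, quad128):
        return transient_pressure(
            array128.positions[64], [1e-3, 0.0, 0.035], pulse_3mhz, medium,
            quad128, fs=16e6,
        )

    @pytest.mark.parametrize("mode", ["analytic", "cached_linear"])
    def test_zero_delay_identity(self, waveform, mode):
        out = delayed_copy(waveform, 0.0, mode)
        n = len(waveform.data)
        assert out.start == waveform.start
        assert np.allclose(out.data[:n], waveform.data, rtol=1e-9, atol=1e-12)

    def test_integer_sample_delay_exact(self, waveform):
        k = 7
        delay = k / waveform.fs
        lin = delayed_copy(waveform, delay, "cached_linear")
        ana = delayed_copy(waveform, delay, "analytic")
        assert lin.start == waveform.start + k
        assert np.allclose(lin.data[: len(waveform.data)], waveform.data)
        a, b = (
            np.trim_zeros(ana.data, "b"),
            np.trim_zeros(lin.data, "b"),
        )
        assert np.allclose(ana.data[: len(waveform.data)], waveform.data, atol=1e-9)

    def test_upsampled_beats_linear_on_half_sample_shift(
        self, array128, medium, pulse_3mhz
    ):
        cache = build_intermediate_cache(
            build_linear_array(1, 0.3e-3, 7e-3, 0.05e-3),
            np.array([[0.0, 0.0, 0.03]]), pulse_3mhz, medium, 16e6,
            element_quadrature(array128), upsample=4,
        )
        w = cache.get(0, 0)
        delay = 0.5 / w.fs
        truth = delayed_copy(
            transient_pressure(
                np.zeros(3), [0.0, 0.0, 0.03], pulse_3mhz, medium,
                element_quadrature(array128), fs=16e6,
            ),
            delay, "analytic",
        )
        lin = delayed_copy(w, delay, "cached_linear")
        ups = delayed_copy(w, delay, "cached_upsampled")
        assert waveform_nrmse(ups, truth) < waveform_nrmse(lin, truth)

    def test_analytic_requires_generator(self):
        w = Waveform(fs=1e6, start=0, data=np.ones(4))
        with pytest.raises(ValueError):
            delayed_copy(w, 1e-7, "analytic")
        with pytest.raises(ValueError):
            delayed_copy(w, 1e-7, "cached_upsampled")


class TestIntermediateCache:
    def test_cardinality_and_zero_delay_hit(self, medium, pulse_3mhz):
        arr = build_linear_array(2, 0.3e-3, 7e-3, 0.05e-3)
        pts = np.array([[0, 0, 0.03], [1e-3, 0, 0.035], [-2e-3, 0, 0.04]])
        quad = element_quadrature(arr)
        cache = build_intermediate_cache(arr, pts, pulse_3mhz, medium, 16e6, quad)
        assert cache.n_elements == 2 and cache.n_points == 3
        direct = transient_pressure(
            arr.positions[1], pts[2], pulse_3mhz, medium, quad, fs=16e6
        )
        cached = cache.get(1, 2)
        a, b = (
            cached.data[: len(direct.data)],
            direct.data[: len(cached.data)],
        )
        n = min(len(a), len(b))
        off = direct.start - cached.start
        assert abs(off) <= 2
        assert waveform_nrmse(cached, direct) < 1e-12
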