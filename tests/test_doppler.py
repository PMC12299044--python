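"""Kasai color Doppler chain on constructed ensembles."""

import numpy as np
import pytest

from fastecho import (
    BeamformingGrid,
    DopplerEnsemble,
    Medium,
    autocorrelation_velocity,
    lateral_average_profile,
    magnitude_threshold,
    spatial_smooth,
    wall_filter,
)
from fastecho.doppler import VelocityMap


def make_grid(nz=24, nx=16, dz=0.5e-3, dx=0.35e-3):
    return BeamformingGrid(
        x=(np.arange(nx) - (nx - 1) / 2) * dx,
        z=0.030 + np.arange(nz) * dz,
        f_number=1.5,
    )


def make_ensemble(phase_step, K=10, fprf=5e3, f0=2.5e6, theta=0.0,
                  amplitude=1.0, grid=None, medium=None):
    """Uniform-phase-progression ensemble: s_k = A * exp(i*k*phase_step).

    A positive phase step is what a scatterer approaching the array by
    c*phase_step/(4*pi*f0) per pulse interval produces.
    """
    grid = grid or make_grid()
    medium = medium or Medium()
    base = amplitude * np.ones(grid.shape, dtype=complex)
    frames = np.stack([base * np.exp(1j * k * phase_step) for k in range(K)])
    return DopplerEnsemble(
        frames=frames, fprf=fprf, f0=f0, angle_rad=theta, medium=medium,
        grid=grid,
    )


class TestWallFilter:
    def test_static_ensemble_cancels_exactly(self):
        ens = make_ensemble(0.0)
        out = wall_filter(ens)
        assert not np.any(out.frames)

    def test_static_component_removed_from_mixture(self):
        grid = make_grid()
        moving = make_ensemble(0.3, grid=grid)
        static = make_ensemble(0.0, amplitude=25.0, grid=grid)
        mixed = DopplerEnsemble(
            frames=moving.frames + static.frames, fprf=5e3, f0=2.5e6,
            angle_rad=0.0, medium=Medium(), grid=grid,
        )
        out = wall_filter(mixed)
        expected = wall_filter(moving)
        assert np.allclose(out.frames, expected.frames)

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(0)
        grid = make_grid()
        frames = rng.standard_normal((8,) + grid.shape) + 1j * rng.standard_normal(
            (8,) + grid.shape
        )
        ens = DopplerEnsemble(frames=frames, fprf=5e3, f0=2.5e6,
                              angle_rad=0.0, medium=Medium(), grid=grid)
        out = wall_filter(ens)
        assert np.allclose(out.frames.mean(axis=0), 0.0, atol=1e-14)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            make_ensemble(0.0, K=1)


class TestMagnitudeThreshold:
    def test_two_pixel_closed_form(self):
        grid = make_grid(nz=1, nx=2)
        frames = np.ones((4, 1, 2), dtype=complex)
        frames[:, 0, 1] = 0.5
        ens = DopplerEnsemble(frames=frames, fprf=5e3, f0=2.5e6,
                              angle_rad=0.0, medium=Medium(), grid=grid)
        mask = magnitude_threshold(ens, cutoff_db=4.0)
        # 0.5 < 10^(-4/20) = 0.631 -> masked
        assert mask[0, 0] and not mask[0, 1]

    def test_infinite_cutoff_keeps_all(self):
        ens = make_ensemble(0.1)
        assert magnitude_threshold(ens, cutoff_db=np.inf).all()

    def test_zero_ensemble_all_false(self):
        grid = make_grid()
        ens = DopplerEnsemble(
            frames=np.zeros((3,) + grid.shape, dtype=complex), fprf=5e3,
            f0=2.5e6, angle_rad=0.0, medium=Medium(), grid=grid,
        )
        assert not magnitude_threshold(ens).any()


class TestAutocorrelationVelocity:
    def test_static_gives_zero(self):
        vmap = autocorrelation_velocity(make_ensemble(0.0))
        assert np.allclose(vmap.v, 0.0)

    def test_eighth_wavelength_displacement_identity(self):
        # approach by dz = lambda/8 per pulse: phase +pi/2, v = dz * fPRF
        c, f0, fprf = 1540.0, 2.5e6, 5e3
        dz = c / f0 / 8
        vmap = autocorrelation_velocity(make_ensemble(np.pi / 2))
        expected = dz * fprf
        assert expected == pytest.approx(c * fprf / (8 * f0))
        assert np.allclose(vmap.v, expected, rtol=1e-6)

    def test_flow_reversal_negates(self):
        vp = autocorrelation_velocity(make_ensemble(0.7))
        vn = autocorrelation_velocity(make_ensemble(-0.7))
        assert np.allclose(vn.v, -vp.v, rtol=1e-12)

    def test_nyquist_bound_never_exceeded(self):
        rng = np.random.default_rng(1)
        grid = make_grid()
        frames = rng.standard_normal((12,) + grid.shape) + 1j * rng.standard_normal(
            (12,) + grid.shape
        )
        for theta in (0.0, np.radians(45.0)):
            ens = DopplerEnsemble(frames=frames, fprf=5e3, f0=2.5e6,
                                  angle_rad=theta, medium=Medium(), grid=grid)
            vmap = autocorrelation_velocity(ens)
            assert np.all(np.abs(vmap.v) <= vmap.nyquist * (1 + 1e-12))
            assert vmap.nyquist == pytest.approx(
                1540.0 * 5e3 / (4 * 2.5e6 * np.cos(theta))
            )

    def test_invariance_to_global_phase_and_scale(self):
        ens = make_ensemble(0.5)
        ref = autocorrelation_velocity(ens).v
        mod = DopplerEnsemble(
            frames=3.7 * np.exp(1j * 1.2) * ens.frames, fprf=ens.fprf,
            f0=ens.f0, angle_rad=ens.angle_rad, medium=ens.medium,
            grid=ens.grid,
        )
        assert np.allclose(autocorrelation_velocity(mod).v, ref, rtol=1e-12)

    def test_angle_correction_and_degeneracy(self):
        v0 = autocorrelation_velocity(make_ensemble(0.4)).v
        v45 = autocorrelation_velocity(make_ensemble(0.4, theta=np.radians(45))).v
        assert np.allclose(v45, v0 / np.cos(np.radians(45)))
        with pytest.raises(ValueError):
            autocorrelation_velocity(make_ensemble(0.4, theta=np.pi / 2))

    def test_masked_pixels_zeroed(self):
        ens = make_ensemble(0.5)
        mask = np.zeros(ens.grid.shape, dtype=bool)
        mask[0, 0] = True
        vmap = autocorrelation_velocity(ens, mask)
        assert vmap.v[0, 0] != 0.0
        assert not np.any(vmap.v[1:, :])


class TestSpatialSmooth:
    def test_constant_map_unchanged(self):
        grid = make_grid()
        vmap = VelocityMap(v=np.full(grid.shape, 0.3),
                           valid=np.ones(grid.shape, bool), nyquist=1.0,
                           grid=grid)
        out = spatial_smooth(vmap, 1.54e-3, 1.57e-3)
        assert np.allclose(out.v, 0.3)

    def test_single_pixel_window_identity(self):
        grid = make_grid()
        rng = np.random.default_rng(2)
        vmap = VelocityMap(v=rng.standard_normal(grid.shape),
                           valid=np.ones(grid.shape, bool), nyquist=1.0,
                           grid=grid)
        out = spatial_smooth(vmap, 1e-6, 1e-6)
        assert np.allclose(out.v, vmap.v)

    def test_impulse_response_is_hamming_outer_product(self):
        grid = make_grid()
        v = np.zeros(grid.shape)
        v[12, 8] = 1.0
        vmap = VelocityMap(v=v, valid=np.ones(grid.shape, bool), nyquist=1.0,
                           grid=grid)
        out = spatial_smooth(vmap, 3 * 0.5e-3, 3 * 0.35e-3)
        k = np.outer(np.hamming(3), np.hamming(3))
        k /= k.sum()
        assert np.allclose(out.v[11:14, 7:10], k)

    def test_oversized_window_rejected(self):
        grid = make_grid(nz=4, nx=4)
        vmap = VelocityMap(v=np.zeros(grid.shape),
                           valid=np.ones(grid.shape, bool), nyquist=1.0,
                           grid=grid)
        with pytest.raises(ValueError):
            spatial_smooth(vmap, 1.0, 1.0)


class TestLateralProfile:
    def test_uniform_map_flat_profile(self):
        grid = make_grid()
        vmap = VelocityMap(v=np.full(grid.shape, 0.5),
                           valid=np.ones(grid.shape, bool), nyquist=1.0,
                           grid=grid)
        x, raw, norm = lateral_average_profile(vmap, np.ones(grid.shape, bool))
        assert np.allclose(raw, 0.5)
        assert np.allclose(norm, 1.0)

    def test_antisymmetric_map_gives_odd_profile(self):
        grid = make_grid(nx=17)
        X = np.tile(grid.x, (len(grid.z), 1))
        v = X / np.abs(grid.x).max() + 1.0  # odd part + offset at center
        vmap = VelocityMap(v=v, valid=np.ones(grid.shape, bool), nyquist=2.0,
                           grid=grid)
        x, raw, norm = lateral_average_profile(vmap, np.ones(grid.shape, bool))
        odd = raw - 1.0
        assert np.allclose(odd, -odd[::-1], atol=1e-12)

    def test_empty_region_rejected(self):
        grid = make_grid()
        vmap = VelocityMap(v=np.zeros(grid.shape),
                           valid=np.ones(grid.shape, bool), nyquist=1.0,
                           grid=grid)
        with pytest.raises(ValueError):
            lateral_average_profile(vmap, np.zeros(grid.shape, bool))
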