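"""Acquisition-model operator contracts: adjointness, linearity, energy,
calibration-based sensitivity and phase estimation, noise injection."""

import numpy as np
import pytest

from rhomap import phantom as ph
from rhomap.operators import (
    CoilProfile,
    ImageSequence,
    MultiCoilKSpace,
    add_noise,
    adjoint,
    calib_slices,
    estimate_phase_map,
    estimate_sensitivities,
    forward,
)


def _rand_img(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestForwardAdjoint:
    def test_zero_image_gives_zero_kspace(self, tiny_problem):
        tsl = tiny_problem["tsl"]
        x = ImageSequence(np.zeros((8, 8, 2), complex), tsl)
        y = forward(x, tiny_problem["coils"], tiny_problem["mask"])
        assert np.all(y.data == 0)

    def test_unit_coil_roundtrip(self):
        rng = np.random.default_rng(0)
        tsl = np.array([2.0, 4.0])
        coils = CoilProfile(
            np.ones((8, 8, 1), complex), np.ones((8, 8), complex), np.ones((8, 8), bool)
        )
        x = ImageSequence(_rand_img(rng, (8, 8, 2)), tsl)
        xr = adjoint(forward(x, coils), coils)
        assert np.linalg.norm(xr.data - x.data) / np.linalg.norm(x.data) < 1e-10

    @pytest.mark.parametrize("with_mask", [False, True])
    def test_adjoint_dot_product_identity(self, tiny_problem, with_mask):
        rng = np.random.default_rng(1)
        tsl = tiny_problem["tsl"]
        mask = tiny_problem["mask"] if with_mask else None
        x = _rand_img(rng, (8, 8, 2))
        y = _rand_img(rng, (8, 8, 2, 2))
        fx = forward(ImageSequence(x, tsl), tiny_problem["coils"], mask).data
        aty = adjoint(MultiCoilKSpace(y, tsl), tiny_problem["coils"], mask).data
        lhs = np.vdot(y, fx)
        rhs = np.vdot(aty, x)
        assert abs(lhs - rhs) / abs(rhs) < 1e-10

    def test_linearity(self, tiny_problem):
        rng = np.random.default_rng(2)
        tsl = tiny_problem["tsl"]
        a, b = 1.7 - 0.3j, -0.6 + 2.1j
        x1, x2 = _rand_img(rng, (8, 8, 2)), _rand_img(rng, (8, 8, 2))
        co, mk = tiny_problem["coils"], tiny_problem["mask"]
        lhs = forward(ImageSequence(a * x1 + b * x2, tsl), co, mk).data
        rhs = a * forward(ImageSequence(x1, tsl), co, mk).data + b * forward(
            ImageSequence(x2, tsl), co, mk
        ).data
        assert np.abs(lhs - rhs).max() < 1e-12 * max(1.0, np.abs(rhs).max())

    def test_energy_preserved_single_unit_coil(self):
        rng = np.random.default_rng(3)
        tsl = np.array([2.0, 4.0, 6.0])
        coils = CoilProfile(
            np.ones((16, 12, 1), complex),
            np.ones((16, 12), complex),
            np.ones((16, 12), bool),
        )
        x = ImageSequence(_rand_img(rng, (16, 12, 3)), tsl)
        y = forward(x, coils)
        assert np.isclose(np.linalg.norm(y.data), np.linalg.norm(x.data))

    def test_fully_sampled_adjoint_inverts_with_normalized_coils(self, small_dataset):
        xr = adjoint(small_dataset["y"], small_dataset["coils"])
        x = small_dataset["x"]
        err = np.linalg.norm(xr.data - x.data) / np.linalg.norm(x.data)
        assert err < 1e-10

    def test_shape_mismatch_raises(self, tiny_problem):
        tsl = tiny_problem["tsl"]
        x = ImageSequence(np.zeros((10, 8, 2), complex), tsl)
        with pytest.raises(ValueError):
            forward(x, tiny_problem["coils"], None)


class TestSensitivityEstimation:
    def test_recovers_known_smooth_profiles(self):
        maps = ph.make_ground_truth(32, 32, seed=5)
        x = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
        coils = ph.make_coil_profile(32, 32, 4, seed=6, image_for_phase=maps.c)
        y = forward(x, coils)
        prof = estimate_sensitivities(y, calib_extent=(11, 11))
        ip = np.abs(
            np.sum(np.conj(prof.sensitivities) * coils.sensitivities, axis=-1)
        )
        assert np.median(ip[prof.support_mask]) > 0.95

    def test_uniform_single_coil_constant_magnitude(self):
        maps = ph.make_ground_truth(32, 32, seed=7)
        x = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
        coils = CoilProfile(
            np.ones((32, 32, 1), complex),
            np.ones((32, 32), complex),
            np.ones((32, 32), bool),
        )
        y = forward(x, coils)
        prof = estimate_sensitivities(y, calib_extent=(11, 11))
        mags = np.abs(prof.sensitivities[prof.support_mask, 0])
        assert np.allclose(mags, 1.0, atol=1e-6)

    def test_native_calibration_extent_accepted(self):
        maps = ph.make_ground_truth(128, 64, seed=8)
        x = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
        coils = ph.make_coil_profile(128, 64, 4, seed=9)
        y = forward(x, coils)
        prof = estimate_sensitivities(y, calib_extent=(39, 19))
        assert prof.sensitivities.shape == (128, 64, 4)

    def test_oversized_extent_rejected(self, tiny_problem):
        with pytest.raises(ValueError):
            calib_slices(8, 8, (9, 3))


class TestPhaseMap:
    def _combined_lowres(self, y, calib_extent, prof):
        from rhomap.operators import _lowres_coil_images

        low = _lowres_coil_images(y, calib_extent)
        return np.sum(np.conj(prof.sensitivities) * low, axis=-1)

    def test_constant_global_phase_compensated(self):
        maps = ph.make_ground_truth(32, 32, seed=10)
        maps.c = np.abs(maps.c) * np.exp(1j * np.pi / 4)  # constant phase
        x = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
        sens = ph.make_coil_profile(32, 32, 4, seed=11).sensitivities
        coils = CoilProfile(
            np.abs(sens) / np.sqrt((np.abs(sens) ** 2).sum(-1))[..., None],
            np.ones((32, 32), complex),
            np.ones((32, 32), bool),
        )  # real-valued true sensitivities
        y = forward(x, coils)
        prof = estimate_sensitivities(y, calib_extent=(11, 11))
        combined = self._combined_lowres(y, (11, 11), prof)
        compensated = prof.phase_map * combined
        resid = np.angle(compensated[prof.support_mask])
        assert np.abs(resid).max() < 1e-6

    def test_real_phantom_gives_unit_phase_map(self):
        maps = ph.make_ground_truth(32, 32, seed=12)
        maps.c = np.abs(maps.c).astype(complex)
        x = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
        sens = ph.make_coil_profile(32, 32, 3, seed=13).sensitivities
        coils = CoilProfile(
            np.abs(sens) / np.sqrt((np.abs(sens) ** 2).sum(-1))[..., None],
            np.ones((32, 32), complex),
            np.ones((32, 32), bool),
        )
        y = forward(x, coils)
        prof = estimate_sensitivities(y, calib_extent=(11, 11))
        resid = np.angle(prof.phase_map[prof.support_mask])
        assert np.abs(resid).max() < 1e-6

    def test_linear_phase_ramp_mostly_compensated(self):
        maps = ph.make_ground_truth(32, 32, seed=14)
        yy, zz = np.mgrid[0:32, 0:32]
        ramp = 0.04 * (yy - 16) + 0.06 * (zz - 16)
        maps.c = np.abs(maps.c) * np.exp(1j * ramp)
        x = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
        sens = ph.make_coil_profile(32, 32, 4, seed=15).sensitivities
        coils = CoilProfile(
            np.abs(sens) / np.sqrt((np.abs(sens) ** 2).sum(-1))[..., None],
            np.ones((32, 32), complex),
            np.ones((32, 32), bool),
        )
        y = forward(x, coils)
        prof = estimate_sensitivities(y, calib_extent=(11, 11))
        combined = self._combined_lowres(y, (11, 11), prof)
        resid = np.angle(prof.phase_map * combined)[prof.support_mask]
        assert np.median(np.abs(resid)) < 0.05


class TestAddNoise:
    def test_zero_sd_identity(self, tiny_problem):
        rng = np.random.default_rng(4)
        y = MultiCoilKSpace(_rand_img(rng, (8, 8, 2, 2)), tiny_problem["tsl"])
        yn = add_noise(y, 0.0, seed=1)
        assert np.array_equal(yn.data, y.data)

    def test_deterministic_under_seed(self, tiny_problem):
        rng = np.random.default_rng(5)
        y = MultiCoilKSpace(_rand_img(rng, (8, 8, 2, 2)), tiny_problem["tsl"])
        a = add_noise(y, 0.5, seed=42).data
        b = add_noise(y, 0.5, seed=42).data
        assert np.array_equal(a, b)

    def test_empirical_sd(self):
        tsl = np.array([2.0, 4.0])
        y = MultiCoilKSpace(np.zeros((50, 50, 2, 10), complex), tsl)
        yn = add_noise(y, 1.0, seed=0)
        assert abs(yn.data.real.std() - 1.0) < 0.01
        assert abs(yn.data.imag.std() - 1.0) < 0.01

    def test_negative_sd_rejected(self, tiny_problem):
        y = MultiCoilKSpace(np.zeros((8, 8, 2, 2), complex), tiny_problem["tsl"])
        with pytest.raises(ValueError):
            add_noise(y, -0.1, seed=0)
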