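import numpy as np
import pytest

from rhomap import phantom as ph
from rhomap.operators import ImageSequence, MultiCoilKSpace, add_noise, forward
from rhomap.sampling import poisson_disk_mask


@pytest.fixture(scope="session")
def small_dataset():
    """Noiseless 48x32x10, 4-coil synthetic slice with ground truth."""
    y, mask, maps, coils = ph.make_dataset(48, 32, nc=4, af=1.0, noise_sd=0.0, seed=0)
    x = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
    return dict(y=y, mask=mask, maps=maps, coils=coils, x=x)


@pytest.fixture(scope="session")
def tiny_problem():
    """8x8x2 two-coil instance for operator identities."""
    rng = np.random.default_rng(7)
    tsl = np.array([2.0, 4.0])
    sens = rng.standard_normal((8, 8, 2)) + 1j * rng.standard_normal((8, 8, 2))
    sos = np.sqrt((np.abs(sens) ** 2).sum(-1))
    sens /= sos[..., None]
    phase = np.exp(1j * rng.uniform(-np.pi, np.pi, (8, 8)))
    from rhomap.operators import CoilProfile

    coils = CoilProfile(sens, phase, np.ones((8, 8), bool))
    mask = poisson_disk_mask(8, 8, 2, 1.6, calib_extent=(3, 3), seed=3)
    return dict(coils=coils, mask=mask, tsl=tsl, rng=rng)


@pytest.fixture(scope="session")
def desk_training_suite():
    """24x24x6 noisy slices at AF 4 for VN experiments (shared, seeded)."""
    tsl = np.array([2.0, 4.0, 8.0, 15.0, 30.0, 55.0])
    out = []
    for j in range(20):
        maps = ph.make_ground_truth(24, 24, seed=100 + j)
        xs = ph.synthesize_sequence(maps, tsl)
        coils = ph.make_coil_profile(24, 24, 4, seed=200 + j, image_for_phase=maps.c)
        y = add_noise(forward(xs, coils), ph.snr_to_noise_sd(maps, 30.0), seed=300 + j)
        mask = poisson_disk_mask(24, 24, 6, 4.0, seed=400 + j)
        yS = MultiCoilKSpace(y.data * mask.pattern[..., None], tsl)
        out.append((yS, coils, mask, xs))
    return out
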