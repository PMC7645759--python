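"""Synthetic 2D+time T1rho-weighted data with known ground truth.

Generates piecewise-smooth parameter maps — five curved band-shaped
"cartilage" regions (MFC, MTC, LFC, LTC, PC) on a smooth mono-exponential
background — synthesises the complex image sequence from the mono / bi-
exponential relaxation models, forms multi-coil k-space through smooth coil
profiles, and optionally adds complex Gaussian k-space noise.

The geometry is procedural (arcs and bands), not anatomical: only the
statistical and temporal structure of cartilage relaxometry data is
emulated.  Relaxation times respect the short (0.5-10 ms) / long
(10-300 ms) component ranges; biexponential fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .operators import CoilProfile, ImageSequence, add_noise, forward
from .sampling import poisson_disk_mask

__all__ = [
    "TSL_DEFAULT",
    "ROI_NAMES",
    "PhantomConfig",
    "GroundTruthMaps",
    "make_ground_truth",
    "synthesize_sequence",
    "make_coil_profile",
    "make_dataset",
    "snr_to_noise_sd",
]

#: spin-lock times in ms used by the reference protocol
TSL_DEFAULT = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 25.0, 35.0, 45.0, 55.0])

#: ROI label codes; 0 is background
ROI_NAMES = {1: "MFC", 2: "MTC", 3: "LFC", 4: "LTC", 5: "PC"}


@dataclass
class PhantomConfig:
    """Parameter-draw ranges for the procedural ground truth.

    All times in ms.  ``biexp_prob`` is the probability that a cartilage
    voxel carries a biexponential decay; the rest are monoexponential with
    the long-component time.
    """

    tau_s_range: tuple = (3.0, 8.0)
    tau_l_range: tuple = (30.0, 80.0)
    f_s_range: tuple = (0.25, 0.45)
    biexp_prob: float = 0.7
    background_tau_range: tuple = (20.0, 60.0)
    roi_magnitude: tuple = (0.8, 1.2)
    background_magnitude: tuple = (0.2, 0.5)
    phase_amplitude_rad: float = 0.5  # smooth low-order image phase


@dataclass
class GroundTruthMaps:
    """Per-voxel ground-truth relaxation parameters and ROI labels."""

    c: np.ndarray  # complex (ny, nz)
    f_s: np.ndarray  # in [0, 1]
    f_l: np.ndarray
    tau_s: np.ndarray  # ms, short component where defined
    tau_l: np.ndarray  # ms, long component
    is_biexp: np.ndarray  # bool
    roi_labels: np.ndarray  # int, 0 background, 1..5 per ROI_NAMES

    def __post_init__(self) -> None:
        if not np.allclose(self.f_s + self.f_l, 1.0):
            raise ValueError("fractions must sum to one")

    @property
    def tau_mono(self) -> np.ndarray:
        """Effective monoexponential time at mono voxels (f_s in {0, 1})."""
        return np.where(self.f_s >= 0.5, self.tau_s, self.tau_l)


def _curved_band(ny, nz, center, radius, width, ang0, ang1):
    """Boolean mask of an annular arc (the procedural 'cartilage' shape)."""
    yy, zz = np.mgrid[0:ny, 0:nz]
    dy = yy - center[0]
    dz = zz - center[1]
    rr = np.hypot(dy, dz)
    ang = np.arctan2(dz, dy)
    in_ring = np.abs(rr - radius) <= width / 2.0
    a = (ang - ang0) % (2 * np.pi)
    span = (ang1 - ang0) % (2 * np.pi)
    return in_ring & (a <= span)


def make_ground_truth(
    ny: int, nz: int, seed: int = 0, config: PhantomConfig | None = None
) -> GroundTruthMaps:
    """Draw a deterministic procedural ground truth on an (ny, nz) grid."""
    if ny < 16 or nz < 16:
        raise ValueError("grid must be at least 16 x 16")
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)

    labels = np.zeros((ny, nz), dtype=int)
    # five arc bands at quasi-random positions/orientations
    for k in range(1, 6):
        cy = rng.uniform(0.2, 0.8) * ny
        cz = rng.uniform(0.2, 0.8) * nz
        radius = rng.uniform(0.18, 0.35) * min(ny, nz)
        width = rng.uniform(0.10, 0.18) * min(ny, nz)
        ang0 = rng.uniform(0, 2 * np.pi)
        ang1 = ang0 + rng.uniform(0.9 * np.pi, 1.6 * np.pi)
        band = _curved_band(ny, nz, (cy, cz), radius, width, ang0, ang1)
        labels[band & (labels == 0)] = k

    def smooth_field(lo, hi, sigma):
        f = gaussian_filter(rng.standard_normal((ny, nz)), sigma)
        f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
        return lo + (hi - lo) * f

    # background: smooth mono maps (long component carries the decay)
    tau_l = smooth_field(*cfg.background_tau_range, sigma=max(ny, nz) / 8)
    tau_s = np.full((ny, nz), 5.0)
    f_s = np.zeros((ny, nz))
    magnitude = smooth_field(*cfg.background_magnitude, sigma=max(ny, nz) / 10)
    is_biexp = np.zeros((ny, nz), dtype=bool)

    for k in ROI_NAMES:
        sel = labels == k
        n = int(sel.sum())
        if n == 0:
            continue
        bi = rng.random(n) < cfg.biexp_prob
        tau_s[sel] = rng.uniform(*cfg.tau_s_range, size=n)
        tau_l[sel] = rng.uniform(*cfg.tau_l_range, size=n)
        fs = np.where(bi, rng.uniform(*cfg.f_s_range, size=n), 0.0)
        f_s[sel] = fs
        is_biexp[sel] = bi
        magnitude[sel] = rng.uniform(*cfg.roi_magnitude, size=n)

    # smooth low-order image phase (constant + gentle spatial variation)
    phase = cfg.phase_amplitude_rad * gaussian_filter(
        rng.standard_normal((ny, nz)), max(ny, nz) / 6
    )
    phase = phase - phase.mean() + rng.uniform(-np.pi / 4, np.pi / 4)
    c = magnitude * np.exp(1j * phase)

    return GroundTruthMaps(
        c=c,
        f_s=f_s,
        f_l=1.0 - f_s,
        tau_s=tau_s,
        tau_l=tau_l,
        is_biexp=is_biexp,
        roi_labels=labels,
    )


def synthesize_sequence(maps: GroundTruthMaps, tsl: np.ndarray) -> ImageSequence:
    """Evaluate the mono/biexponential decay models at the spin-lock times.

    x(t) = c (f_s exp(-t/tau_s) + f_l exp(-t/tau_l)); mono voxels have
    f_s in {0, 1} so the expression reduces to c exp(-t/tau).
    """
    tsl = np.asarray(tsl, dtype=float)
    if np.any(tsl <= 0) or np.any(np.diff(tsl) <= 0):
        raise ValueError("tsl must be positive and strictly increasing")
    used_s = maps.f_s > 0
    used_l = maps.f_l > 0
    if np.any(maps.tau_s[used_s] <= 0) or np.any(maps.tau_l[used_l] <= 0):
        raise ValueError("relaxation times must be positive where used")
    t = tsl[None, None, :]
    decay = maps.f_s[:, :, None] * np.exp(
        -t / np.maximum(maps.tau_s, 1e-9)[:, :, None]
    ) + maps.f_l[:, :, None] * np.exp(-t / np.maximum(maps.tau_l, 1e-9)[:, :, None])
    return ImageSequence(maps.c[:, :, None] * decay, tsl)


def make_coil_profile(
    ny: int, nz: int, nc: int, seed: int = 0, image_for_phase: np.ndarray | None = None
) -> CoilProfile:
    """Smooth synthetic coil profile: Gaussian-bump magnitudes around the
    field of view, smooth low-order coil phases, unit sum-of-squares.

    If ``image_for_phase`` is given, the returned ``phase_map`` is the
    compensating phasor of that image (conjugate of its unit phase), so the
    adjoint reconstruction of data formed from it is near zero-phase.
    """
    rng = np.random.default_rng(seed)
    yy, zz = np.mgrid[0:ny, 0:nz]
    sens = np.zeros((ny, nz, nc), dtype=complex)
    for i in range(nc):
        ang = 2 * np.pi * i / nc + rng.uniform(-0.2, 0.2)
        cy = ny / 2 + 0.6 * ny * np.cos(ang) / 2
        cz = nz / 2 + 0.6 * nz * np.sin(ang) / 2
        w = rng.uniform(0.5, 0.9) * max(ny, nz)
        mag = np.exp(-(((yy - cy) ** 2) + (zz - cz) ** 2) / (2 * w**2))
        ph = (
            rng.uniform(-np.pi, np.pi)
            + rng.uniform(-1, 1) * np.pi * (yy - ny / 2) / ny
            + rng.uniform(-1, 1) * np.pi * (zz - nz / 2) / nz
        )
        sens[:, :, i] = mag * np.exp(1j * ph)
    sos = np.sqrt(np.sum(np.abs(sens) ** 2, axis=-1))
    sens /= np.where(sos > 1e-12, sos, 1.0)[:, :, None]
    if image_for_phase is not None:
        m = np.abs(image_for_phase)
        phase_map = np.where(
            m > 1e-12, np.conj(image_for_phase) / np.where(m > 0, m, 1), 1.0
        )
    else:
        phase_map = np.ones((ny, nz), dtype=complex)
    support = np.ones((ny, nz), dtype=bool)
    return CoilProfile(sens, phase_map, support)


def make_dataset(
    ny: int,
    nz: int,
    tsl: np.ndarray | None = None,
    nc: int = 15,
    af: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    config: PhantomConfig | None = None,
) -> tuple:
    """Full synthetic acquisition: (kspace, mask, ground truth, coils).

    The returned k-space is fully sampled (apply the mask to undersample);
    ``noise_sd`` adds complex Gaussian noise per component.  Defaults match
    the reference protocol: 10 TSLs 2/4/6/8/10/15/25/35/45/55 ms, 15 coils.
    """
    tsl = TSL_DEFAULT.copy() if tsl is None else np.asarray(tsl, dtype=float)
    maps = make_ground_truth(ny, nz, seed=seed, config=config)
    x = synthesize_sequence(maps, tsl)
    coils = make_coil_profile(ny, nz, nc, seed=seed + 1, image_for_phase=maps.c)
    y = forward(x, coils)  # fully sampled
    if noise_sd > 0:
        y = add_noise(y, noise_sd, seed=seed + 2)
    else:
        y.noise_sd = 0.0
    mask = poisson_disk_mask(ny, nz, tsl.size, af, seed=seed + 3)
    return y, mask, maps, coils


def snr_to_noise_sd(maps: GroundTruthMaps, snr_db: float = 30.0) -> float:
    """k-space noise SD giving the requested first-TSL image-domain SNR.

    With a unitary FFT and unit-SOS coils, image-domain coil-combined noise
    SD equals the k-space per-component SD, so SNR is set against the mean
    ROI magnitude at the first spin-lock time.
    """
    roi = maps.roi_labels > 0
    sig = np.abs(maps.c[roi]).mean() if roi.any() else np.abs(maps.c).mean()
    return float(sig / 10 ** (snr_db / 20.0))
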