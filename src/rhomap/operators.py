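"""Multi-coil Fourier acquisition model for 2D+time T1rho-weighted imaging.

The forward model is ``y = S F C x``: an image sequence ``x`` (Ny, Nz, Nt) is
phase-restored and weighted by coil sensitivities (``C``), Fourier-transformed
per frame and coil (``F``, unitary), and undersampled by a binary pattern
(``S``).  The adjoint ``C* F* S*`` is the zero-filled / fully-sampled
reference reconstruction.

Conventions
-----------
- k-space arrays are stored FFT-shifted: the DC sample and the calibration
  block sit at the centre of the (ky, kz) grid.
- The 2D FFT over (y, z) is unitary (``norm="ortho"``), so the adjoint of
  ``F`` is its inverse and ``forward``/``adjoint`` are exact adjoints.
- Coil sensitivities are normalised to unit sum-of-squares magnitude on the
  support, so ``C* C`` acts as the identity there and the adjoint of the
  fully-sampled forward model is its left inverse.
- ``phase_map`` stores the *compensating* unit phasor: ``adjoint`` multiplies
  the coil-combined image by it (yielding a near-zero-phase image for
  complex-valued fitting) and ``forward`` multiplies by its conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageSequence",
    "MultiCoilKSpace",
    "CoilProfile",
    "SamplingMask",
    "forward",
    "adjoint",
    "estimate_sensitivities",
    "estimate_phase_map",
    "estimate_coil_profile",
    "add_noise",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _check_tsl(tsl: np.ndarray) -> np.ndarray:
    tsl = np.asarray(tsl, dtype=float)
    if tsl.ndim != 1:
        raise ValueError("tsl must be a 1D vector of spin-lock times")
    if np.any(tsl <= 0) or np.any(np.diff(tsl) <= 0):
        raise ValueError("tsl must be strictly increasing and positive")
    return tsl


@dataclass
class ImageSequence:
    """Complex 2D+time image stack for one slice, indexed (y, z, t)."""

    data: np.ndarray
    tsl: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise ValueError("image data must be (Ny, Nz, Nt)")
        self.tsl = _check_tsl(self.tsl)
        if self.data.shape[2] != self.tsl.size:
            raise ValueError("Nt of data does not match length of tsl")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class MultiCoilKSpace:
    """Complex k-space samples indexed (ky, kz, t, coil), FFT-shifted."""

    data: np.ndarray
    tsl: np.ndarray
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("k-space data must be (Ny, Nz, Nt, Nc)")
        self.tsl = _check_tsl(self.tsl)
        if self.data.shape[2] != self.tsl.size:
            raise ValueError("Nt of k-space does not match length of tsl")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one coil")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class CoilProfile:
    """Coil sensitivities plus phase-compensation map and support mask."""

    sensitivities: np.ndarray  # (Ny, Nz, Nc) complex, unit SOS on support
    phase_map: np.ndarray  # (Ny, Nz) complex, |.| = 1 on support
    support_mask: np.ndarray  # (Ny, Nz) bool

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=complex)
        self.phase_map = np.asarray(self.phase_map, dtype=complex)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if self.sensitivities.ndim != 3:
            raise ValueError("sensitivities must be (Ny, Nz, Nc)")
        if self.phase_map.shape != self.sensitivities.shape[:2]:
            raise ValueError("phase_map shape mismatch")
        if self.support_mask.shape != self.phase_map.shape:
            raise ValueError("support_mask shape mismatch")


@dataclass
class SamplingMask:
    """Binary (ky, kz, t) sampling pattern with a centred calibration block."""

    pattern: np.ndarray
    calib_extent: tuple = (0, 0)
    achieved_af: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern)
        if self.pattern.ndim != 3:
            raise ValueError("mask pattern must be (Ny, Nz, Nt)")
        self.pattern = (self.pattern != 0).astype(np.uint8)
        nnz = int(self.pattern.sum())
        if nnz > 0:
            self.achieved_af = self.pattern.size / nnz


def calib_slices(ny: int, nz: int, calib_extent: tuple) -> tuple:
    """Index slices of the centred calibration rectangle on an (ny, nz) grid."""
    cy, cz = calib_extent
    if cy > ny or cz > nz:
        raise ValueError(
            f"calibration extent {calib_extent} exceeds grid ({ny}, {nz})"
        )
    y0 = ny // 2 - cy // 2
    z0 = nz // 2 - cz // 2
    return slice(y0, y0 + cy), slice(z0, z0 + cz)


# ---------------------------------------------------------------------------
# FFT helpers (unitary, centred)
# ---------------------------------------------------------------------------

def fft2c(img: np.ndarray) -> np.ndarray:
    """Unitary centred 2D FFT over the first two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Unitary centred 2D inverse FFT over the first two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )


# ---------------------------------------------------------------------------
# forward / adjoint
# ---------------------------------------------------------------------------

def _check_geometry(shape_img, coils: CoilProfile, mask: SamplingMask | None):
    ny, nz, nt = shape_img
    if coils.sensitivities.shape[:2] != (ny, nz):
        raise ValueError(
            f"coil profile grid {coils.sensitivities.shape[:2]} does not "
            f"match image grid {(ny, nz)}"
        )
    if mask is not None and mask.pattern.shape != (ny, nz, nt):
        raise ValueError(
            f"mask shape {mask.pattern.shape} does not match {(ny, nz, nt)}"
        )


def forward(
    x: ImageSequence,
    coils: CoilProfile,
    mask: SamplingMask | None = None,
) -> MultiCoilKSpace:
    """Apply the acquisition operator ``S F C`` to an image sequence.

    ``C`` multiplies by the conjugate phase-compensation map (restoring the
    raw image phase) and by each coil sensitivity; ``F`` is the unitary 2D
    FFT per frame; ``S`` zeroes unsampled k-space positions.
    """
    _check_geometry(x.shape, coils, mask)
    xc = np.conj(coils.phase_map)[:, :, None] * x.data  # (Ny, Nz, Nt)
    weighted = xc[:, :, :, None] * coils.sensitivities[:, :, None, :]
    ksp = fft2c(weighted)
    if mask is not None:
        ksp = ksp * mask.pattern[:, :, :, None]
    return MultiCoilKSpace(ksp, x.tsl)


def adjoint(
    y: MultiCoilKSpace,
    coils: CoilProfile,
    mask: SamplingMask | None = None,
) -> ImageSequence:
    """Apply the adjoint ``C* F* S*``: the reference / zero-filled recon.

    Coil combination is the conjugate-sensitivity weighted sum followed by
    multiplication with the phase-compensation map.
    """
    _check_geometry(y.shape[:3], coils, mask)
    ksp = y.data
    if mask is not None:
        ksp = ksp * mask.pattern[:, :, :, None]
    imgs = ifft2c(ksp)
    combined = np.sum(np.conj(coils.sensitivities)[:, :, None, :] * imgs, axis=-1)
    return ImageSequence(coils.phase_map[:, :, None] * combined, y.tsl)


# ---------------------------------------------------------------------------
# calibration-based sensitivity / phase estimation
# ---------------------------------------------------------------------------

def _lowres_coil_images(
    calib_kspace: MultiCoilKSpace, calib_extent: tuple
) -> np.ndarray:
    """Apodised zero-padded reconstruction of the calibration block, t = 0."""
    ny, nz, _, nc = calib_kspace.shape
    sy, sz = calib_slices(ny, nz, calib_extent)
    cy, cz = calib_extent
    win = np.outer(np.hanning(cy + 2)[1:-1], np.hanning(cz + 2)[1:-1])
    ksp = np.zeros((ny, nz, nc), dtype=complex)
    ksp[sy, sz, :] = calib_kspace.data[sy, sz, 0, :] * win[:, :, None]
    return ifft2c(ksp)


def estimate_sensitivities(
    calib_kspace: MultiCoilKSpace,
    calib_extent: tuple = (39, 19),
    support_threshold: float = 0.1,
    smooth_sigma: float = 1.5,
) -> CoilProfile:
    """Estimate smooth coil sensitivities from the calibration region.

    A simplified autocalibration estimator: low-resolution coil images from
    the apodised, zero-padded calibration block are divided by their
    root-sum-of-squares, phase-referenced to the strongest coil (so the
    shared image phase cancels out of the sensitivities), smoothed, and
    renormalised to unit sum-of-squares magnitude.  The returned profile
    carries ``phase_map`` from :func:`estimate_phase_map`.
    """
    lowres = _lowres_coil_images(calib_kspace, calib_extent)  # (Ny, Nz, Nc)
    rsos = np.sqrt(np.sum(np.abs(lowres) ** 2, axis=-1))
    support = rsos > support_threshold * rsos.max()
    safe = np.where(rsos > 1e-12 * rsos.max(), rsos, 1.0)
    sens = lowres / safe[:, :, None]
    # phase reference: the shared low-res image phase cancels in s_i / |s_ref|-phase
    ref = int(np.argmax(np.sum(np.abs(lowres) ** 2, axis=(0, 1))))
    ref_phase = np.exp(-1j * np.angle(lowres[:, :, ref]))
    sens = sens * ref_phase[:, :, None]
    sm = gaussian_filter(sens.real, sigma=(smooth_sigma, smooth_sigma, 0))
    sm = sm + 1j * gaussian_filter(sens.imag, sigma=(smooth_sigma, smooth_sigma, 0))
    sos = np.sqrt(np.sum(np.abs(sm) ** 2, axis=-1))
    sm = sm / np.where(sos > 1e-12, sos, 1.0)[:, :, None]
    phase = estimate_phase_map(
        calib_kspace, calib_extent=calib_extent, _sens=sm, _lowres=lowres
    )
    return CoilProfile(sm, phase, support)


def estimate_phase_map(
    calib_kspace: MultiCoilKSpace,
    calib_extent: tuple = (39, 19),
    smooth_sigma: float = 2.0,
    _sens: np.ndarray | None = None,
    _lowres: np.ndarray | None = None,
) -> np.ndarray:
    """Low-order phase-compensation map from the calibration region.

    Returns the unit-magnitude *compensating* phasor: multiplying the
    coil-combined calibration image by it yields a near-zero-phase image.
    The phase is derived from the low-resolution (hence spatially smooth)
    coil-combined image at the first spin-lock time and smoothed further.
    """
    if _sens is None or _lowres is None:
        prof = estimate_sensitivities(calib_kspace, calib_extent)
        return prof.phase_map
    combined = np.sum(np.conj(_sens) * _lowres, axis=-1)
    mag = np.abs(combined)
    phasor = np.where(mag > 1e-12 * mag.max(), combined / np.where(mag > 0, mag, 1), 1.0)
    comp = np.conj(phasor)
    sm = gaussian_filter(comp.real, smooth_sigma) + 1j * gaussian_filter(
        comp.imag, smooth_sigma
    )
    m = np.abs(sm)
    return np.where(m > 1e-12, sm / np.where(m > 0, m, 1), 1.0)


def estimate_coil_profile(
    calib_kspace: MultiCoilKSpace, calib_extent: tuple = (39, 19), **kwargs
) -> CoilProfile:
    """Convenience wrapper: sensitivities + phase map in one profile."""
    return estimate_sensitivities(calib_kspace, calib_extent, **kwargs)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(y: MultiCoilKSpace, sd: float, seed: int) -> MultiCoilKSpace:
    """Add i.i.d. complex Gaussian noise (sd per real/imag component)."""
    if sd < 0:
        raise ValueError("noise standard deviation must be >= 0")
    if sd == 0:
        return MultiCoilKSpace(y.data.copy(), y.tsl, noise_sd=0.0)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(y.data.shape) + 1j * rng.standard_normal(y.data.shape)
    return MultiCoilKSpace(y.data + sd * noise, y.tsl, noise_sd=sd)
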