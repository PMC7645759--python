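"""Poisson-disk 2D+time k-space undersampling patterns.

Masks have a fully-sampled, centred calibration rectangle (default 39x19 on
a 128x64 grid, scaled proportionally and rounded to odd for other grids) at
every frame, and dart-thrown samples elsewhere with a per-frame minimum
pairwise distance.  The disk radius is found by bisection so the dart count
reaches the target density; surplus samples are then removed at random so
the achieved acceleration factor (AF = total samples / measured samples)
matches the request within 2% (exact up to integer rounding).
"""

from __future__ import annotations

import numpy as np

from .operators import SamplingMask, calib_slices

__all__ = ["poisson_disk_mask", "acceleration_factor", "default_calib_extent"]

#: calibration extent used throughout: 39 x 19 on the native 128 x 64 grid
CALIB_REF = (39, 19)
GRID_REF = (128, 64)


def default_calib_extent(ny: int, nz: int) -> tuple:
    """Scale the reference 39x19 calibration block to an (ny, nz) grid.

    Proportional scaling, rounded to odd integers, clipped to the grid.
    """

    def _odd(v: float, lim: int) -> int:
        k = max(1, int(round(v)))
        if k % 2 == 0:
            k -= 1
        return min(k, lim if lim % 2 == 1 else lim - 1)

    return (
        _odd(CALIB_REF[0] * ny / GRID_REF[0], ny),
        _odd(CALIB_REF[1] * nz / GRID_REF[1], nz),
    )


def _dart_throw(
    candidates: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Greedy dart throwing: accept points at least ``r`` apart.

    ``candidates`` is an (n, 2) integer array; a random order is drawn from
    ``rng``.  Returns a boolean accept vector aligned with ``candidates``.
    Uses a cell grid of size r/sqrt(2) so each cell holds at most one point.
    """
    n = candidates.shape[0]
    if r <= 1.0:
        return np.ones(n, dtype=bool)  # grid spacing already >= 1
    order = rng.permutation(n)
    cell = r / np.sqrt(2.0)
    reach = int(np.ceil(r / cell))
    grid: dict = {}
    accept = np.zeros(n, dtype=bool)
    r2 = r * r
    for idx in order:
        py, pz = candidates[idx]
        cy, cz = int(py // cell), int(pz // cell)
        ok = True
        for gy in range(cy - reach, cy + reach + 1):
            for gz in range(cz - reach, cz + reach + 1):
                q = grid.get((gy, gz))
                if q is not None:
                    dy = py - q[0]
                    dz = pz - q[1]
                    if dy * dy + dz * dz < r2:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            accept[idx] = True
            grid[(cy, cz)] = (py, pz)
    return accept


def _frame_pattern(
    ny: int,
    nz: int,
    calib_extent: tuple,
    n_target: int,
    rng: np.random.Generator,
) -> tuple:
    """One (ny, nz) frame: full calibration block + n_target disk samples.

    Returns (frame, disk_radius); samples outside the calibration block are
    pairwise at least ``disk_radius`` apart.
    """
    sy, sz = calib_slices(ny, nz, calib_extent)
    in_calib = np.zeros((ny, nz), dtype=bool)
    in_calib[sy, sz] = True
    cand = np.argwhere(~in_calib)
    frame = np.zeros((ny, nz), dtype=np.uint8)
    frame[sy, sz] = 1
    if n_target <= 0:
        return frame, float(max(ny, nz))
    if n_target >= cand.shape[0]:
        frame[~in_calib] = 1
        return frame, 1.0

    # bisect the disk radius: largest r whose dart count still reaches the
    # target, so removing surplus preserves the minimum-distance property
    r_lo, r_hi = 1.0, 2.0 * np.sqrt(ny * nz / max(n_target, 1))
    acc_lo = _dart_throw(cand, r_lo, rng)
    for _ in range(14):
        r_mid = 0.5 * (r_lo + r_hi)
        acc = _dart_throw(cand, r_mid, rng)
        if int(acc.sum()) >= n_target:
            r_lo, acc_lo = r_mid, acc
        else:
            r_hi = r_mid
        if r_hi - r_lo < 0.05:
            break
    accepted = np.flatnonzero(acc_lo)
    surplus = accepted.size - n_target
    if surplus > 0:
        drop = rng.choice(accepted, size=surplus, replace=False)
        acc_lo = acc_lo.copy()
        acc_lo[drop] = False
    pts = cand[acc_lo]
    frame[pts[:, 0], pts[:, 1]] = 1
    return frame, r_lo


def poisson_disk_mask(
    ny: int,
    nz: int,
    nt: int,
    af: float,
    calib_extent: tuple | None = None,
    seed: int = 0,
    shared_across_frames: bool = False,
) -> SamplingMask:
    """Generate a 2D+time Poisson-disk undersampling mask.

    Parameters
    ----------
    ny, nz, nt
        Grid dimensions (phase encodes x spin-lock times).
    af
        Requested acceleration factor (total / measured samples), >= 1.
    calib_extent
        (rows, cols) of the always-sampled centred calibration block;
        default scales 39x19 from the native 128x64 grid.
    seed
        Seed for the deterministic dart-throwing RNG.
    shared_across_frames
        If True a single 2D disk pattern is reused at every frame;
        the default draws an independent pattern per frame
        (complementary sampling across spin-lock times).
    """
    if calib_extent is None:
        calib_extent = default_calib_extent(ny, nz)
    cy, cz = calib_extent
    calib_slices(ny, nz, calib_extent)  # validates extent
    total = ny * nz * nt
    calib_per_frame = cy * cz
    af_max = ny * nz / calib_per_frame
    if not 1.0 <= af <= af_max:
        raise ValueError(
            f"acceleration factor {af} infeasible: must lie in [1, {af_max:.3f}] "
            f"for a {cy}x{cz} calibration block on a {ny}x{nz} grid"
        )
    n_total_target = int(round(total / af))
    n_extra_total = n_total_target - nt * calib_per_frame
    rng = np.random.default_rng(seed)
    # spread the non-calibration budget evenly, remainder on the first frames
    base, rem = divmod(max(n_extra_total, 0), nt)
    pattern = np.zeros((ny, nz, nt), dtype=np.uint8)
    radii = []
    if shared_across_frames:
        frame, r = _frame_pattern(ny, nz, calib_extent, base + (1 if rem else 0), rng)
        pattern[:] = frame[:, :, None]
        radii = [r] * nt
    else:
        for t in range(nt):
            n_t = base + (1 if t < rem else 0)
            pattern[:, :, t], r = _frame_pattern(ny, nz, calib_extent, n_t, rng)
            radii.append(r)
    mask = SamplingMask(pattern, calib_extent=calib_extent)
    mask.disk_radii = radii  # per-frame minimum-distance radius actually used
    return mask


def acceleration_factor(mask: SamplingMask) -> float:
    """AF of a mask: total k-space entries over measured (nonzero) entries."""
    nnz = int(mask.pattern.sum())
    if nnz == 0:
        raise ValueError("mask has no sampled positions")
    return mask.pattern.size / nnz
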