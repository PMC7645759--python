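"""Reconstruction and parametric-map quality metrics.

nRMSE for image sequences, (median) normalized absolute deviation for
parameter maps, ROI mean / population SD summaries, two-scan coefficient
of variation, and balanced one-way ANOVA.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import f_oneway

from .fitting import ParameterMaps
from .operators import ImageSequence

__all__ = [
    "nrmse",
    "nad",
    "mnad",
    "roi_mean",
    "roi_sd",
    "cv",
    "anova_one_way",
    "BIEXP_PARAMETERS",
]

#: map parameters scored by NAD/MNAD; 'tau' is the mono time
BIEXP_PARAMETERS = ("f_s", "f_l", "tau_s", "tau_l")


def nrmse(x_hat: ImageSequence, x_ref: ImageSequence) -> float:
    """||x_hat - x_ref||_2 / ||x_ref||_2 over the full complex sequence."""
    if x_hat.data.shape != x_ref.data.shape:
        raise ValueError("shapes must match")
    denom = np.linalg.norm(x_ref.data)
    if denom == 0:
        raise ValueError("reference sequence is identically zero")
    return float(np.linalg.norm(x_hat.data - x_ref.data) / denom)


def nad(p: float, p_ref: float) -> float:
    """|p - p_ref| / ((p + p_ref) / 2) — symmetric relative deviation."""
    s = p + p_ref
    if s <= 0:
        raise ValueError("NAD requires p + p_ref > 0")
    return abs(p - p_ref) / (s / 2.0)


def _valid_in_both(maps: ParameterMaps, ref: ParameterMaps, parameter: str):
    """Voxels scored for a parameter: mono time needs a valid fit in both
    maps; biexponential parameters need both maps to accept biexp (F-test
    and >= 5% fractions), a two-sided exclusion."""
    biexp = parameter in BIEXP_PARAMETERS
    for key, fit in maps.fits.items():
        rfit = ref.fits.get(key)
        if rfit is None:
            continue
        if biexp:
            if fit.model == "biexp" and rfit.model == "biexp":
                yield key, getattr(fit, parameter), getattr(rfit, parameter)
        else:
            if fit.model != "invalid" and rfit.model != "invalid":
                yield key, getattr(fit, parameter), getattr(rfit, parameter)


def mnad(
    maps: ParameterMaps,
    ref_maps: ParameterMaps,
    roi: int | str = "all",
    parameter: str = "tau",
) -> float:
    """Median NAD of a parameter over ROI voxels valid in both maps.

    ``roi`` is a label code or ``"all"``; returns NaN (with no valid
    voxels) as the undefined-result flag.
    """
    if parameter not in ("tau",) + BIEXP_PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    vals = []
    for (iy, iz), p, p_ref in _valid_in_both(maps, ref_maps, parameter):
        if roi != "all" and maps.roi_labels[iy, iz] != roi:
            continue
        if p + p_ref > 0:
            vals.append(nad(p, p_ref))
    if not vals:
        return float("nan")
    return float(np.median(vals))


def _roi_values(maps: ParameterMaps, roi, parameter) -> np.ndarray:
    biexp = parameter in BIEXP_PARAMETERS
    vals = []
    for (iy, iz), fit in maps.fits.items():
        if roi != "all" and maps.roi_labels[iy, iz] != roi:
            continue
        if biexp and fit.model != "biexp":
            continue
        if fit.model == "invalid":
            continue
        vals.append(getattr(fit, parameter))
    return np.asarray(vals, dtype=float)


def roi_mean(maps: ParameterMaps, roi, parameter: str = "tau") -> float:
    """Arithmetic mean of a parameter over the valid ROI voxels."""
    v = _roi_values(maps, roi, parameter)
    if v.size == 0:
        raise ValueError("empty valid voxel set")
    return float(v.mean())


def roi_sd(maps: ParameterMaps, roi, parameter: str = "tau") -> float:
    """Population SD (1/N normalization) over the valid ROI voxels."""
    v = _roi_values(maps, roi, parameter)
    if v.size == 0:
        raise ValueError("empty valid voxel set")
    return float(v.std(ddof=0))


def cv(scan_means: tuple) -> float:
    """Two-scan coefficient of variation: SD (1/N) over mean."""
    a, b = scan_means
    m = 0.5 * (a + b)
    if m <= 0:
        raise ValueError("CV requires a positive mean")
    sd = float(np.std([a, b], ddof=0))
    return sd / m


def anova_one_way(groups: list) -> float:
    """p-value of a balanced one-way ANOVA across method groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = {len(g) for g in groups}
    if len(sizes) != 1 or sizes.pop() < 2:
        raise ValueError("groups must be equal-sized with >= 2 entries")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if all(np.allclose(g, groups[0]) for g in groups[1:]) and all(
        np.ptp(g) == 0 for g in groups
    ):
        return 1.0  # identical constant groups: F = 0 by convention
    return float(f_oneway(*groups).pvalue)
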