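"""HDF5 / NIfTI / CSV persistence.

HDF5 layout for one slice dataset:

    /kspace   complex (Ny, Nz, Nt, Nc)
    /tsl      float (Nt,), ms
    /mask     uint8 (Ny, Nz, Nt)            [optional]
    /sens     complex (Ny, Nz, Nc)          [optional]
    /phase    complex (Ny, Nz)              [optional]
    /support  uint8 (Ny, Nz)                [optional]
    /gt/...   ground-truth parameter maps   [optional]
    attrs: version, af, seed, noise_sd, calib_extent
"""

from __future__ import annotations

import numpy as np

import h5py
import nibabel as nib

from .fitting import ParameterMaps
from .operators import CoilProfile, ImageSequence, MultiCoilKSpace, SamplingMask
from .phantom import GroundTruthMaps

__all__ = [
    "FORMAT_VERSION",
    "save_dataset",
    "load_dataset",
    "save_image_sequence",
    "load_image_sequence",
    "save_vn_parameters",
    "load_vn_parameters",
    "save_parameter_maps_h5",
    "load_parameter_maps_h5",
    "export_maps_nifti",
    "export_labels_nifti",
]

FORMAT_VERSION = "1.0"


def _require_version(f: h5py.File, path: str) -> None:
    v = f.attrs.get("version")
    if v is None:
        raise IOError(f"{path}: missing format version attribute")
    if str(v).split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise IOError(f"{path}: unsupported format version {v!r}")


def save_dataset(
    path: str,
    kspace: MultiCoilKSpace,
    mask: SamplingMask | None = None,
    coils: CoilProfile | None = None,
    gt: GroundTruthMaps | None = None,
    seed: int | None = None,
) -> None:
    """Write a slice dataset (k-space, mask, coil profile, ground truth)."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.create_dataset("kspace", data=kspace.data)
        f.create_dataset("tsl", data=kspace.tsl)
        if kspace.noise_sd is not None:
            f.attrs["noise_sd"] = kspace.noise_sd
        if seed is not None:
            f.attrs["seed"] = seed
        if mask is not None:
            f.create_dataset("mask", data=mask.pattern)
            f.attrs["af"] = mask.achieved_af
            f.attrs["calib_extent"] = list(mask.calib_extent)
        if coils is not None:
            f.create_dataset("sens", data=coils.sensitivities)
            f.create_dataset("phase", data=coils.phase_map)
            f.create_dataset("support", data=coils.support_mask.astype(np.uint8))
        if gt is not None:
            g = f.create_group("gt")
            g.create_dataset("c", data=gt.c)
            for name in ("f_s", "f_l", "tau_s", "tau_l"):
                g.create_dataset(name, data=getattr(gt, name))
            g.create_dataset("is_biexp", data=gt.is_biexp.astype(np.uint8))
            g.create_dataset("roi_labels", data=gt.roi_labels)


def load_dataset(path: str) -> dict:
    """Read a slice dataset; returns a dict of domain objects."""
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as e:
        raise IOError(f"cannot open dataset {path!r}: {e}") from e
    with f:
        _require_version(f, path)
        tsl = f["tsl"][()]
        out: dict = {
            "kspace": MultiCoilKSpace(
                f["kspace"][()], tsl, noise_sd=f.attrs.get("noise_sd")
            )
        }
        if "mask" in f:
            out["mask"] = SamplingMask(
                f["mask"][()], calib_extent=tuple(f.attrs.get("calib_extent", (0, 0)))
            )
        if "sens" in f:
            out["coils"] = CoilProfile(
                f["sens"][()], f["phase"][()], f["support"][()].astype(bool)
            )
        if "gt" in f:
            g = f["gt"]
            out["gt"] = GroundTruthMaps(
                c=g["c"][()],
                f_s=g["f_s"][()],
                f_l=g["f_l"][()],
                tau_s=g["tau_s"][()],
                tau_l=g["tau_l"][()],
                is_biexp=g["is_biexp"][()].astype(bool),
                roi_labels=g["roi_labels"][()],
            )
    return out


def save_image_sequence(path: str, x: ImageSequence, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.create_dataset("image", data=x.data)
        f.create_dataset("tsl", data=x.tsl)
        for k, v in attrs.items():
            f.attrs[k] = v


def load_image_sequence(path: str) -> ImageSequence:
    with h5py.File(path, "r") as f:
        _require_version(f, path)
        return ImageSequence(f["image"][()], f["tsl"][()])


def save_vn_parameters(path: str, params) -> None:
    """Serialize VN parameters with a layer/filter group structure."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["n_layers"] = len(params.layers)
        f.attrs["knot_range"] = params.knot_range
        f.attrs["n_knots"] = params.n_knots
        for m, layer in enumerate(params.layers):
            g = f.create_group(f"layer_{m:02d}")
            g.create_dataset("filters", data=layer.filters)
            g.create_dataset("act_weights", data=layer.act_weights)
            g.attrs["alpha"] = layer.alpha


def load_vn_parameters(path: str):
    from .vn import VNLayer, VNParameters

    with h5py.File(path, "r") as f:
        _require_version(f, path)
        layers = []
        for m in range(int(f.attrs["n_layers"])):
            g = f[f"layer_{m:02d}"]
            layers.append(
                VNLayer(
                    g["filters"][()], g["act_weights"][()], float(g.attrs["alpha"])
                )
            )
        return VNParameters(
            layers,
            knot_range=float(f.attrs["knot_range"]),
            n_knots=int(f.attrs["n_knots"]),
        )


_FIT_FIELDS = (
    "tau",
    "f_s",
    "f_l",
    "tau_s",
    "tau_l",
    "sse_mono",
    "sse_bi",
    "f_ratio",
)


def save_parameter_maps_h5(path: str, maps: ParameterMaps) -> None:
    """HDF5 bundle of fitted maps: parameters, SSEs, F-ratios, validity."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.create_dataset("roi_labels", data=maps.roi_labels)
        f.create_dataset("tsl", data=maps.tsl)
        for name in _FIT_FIELDS:
            f.create_dataset(name, data=maps.array(name))
        f.create_dataset("biexp_accepted", data=maps.biexp_accepted().astype(np.uint8))


def load_parameter_maps_h5(path: str) -> ParameterMaps:
    """Rebuild a :class:`ParameterMaps` from its HDF5 bundle."""
    from .fitting import VoxelFit

    with h5py.File(path, "r") as f:
        _require_version(f, path)
        labels = f["roi_labels"][()]
        tsl = f["tsl"][()]
        arrays = {name: f[name][()] for name in _FIT_FIELDS}
        accepted = f["biexp_accepted"][()].astype(bool)
    fits = {}
    for iy, iz in np.argwhere(labels > 0):
        tau = arrays["tau"][iy, iz]
        model = (
            "biexp" if accepted[iy, iz] else ("mono" if np.isfinite(tau) else "invalid")
        )
        fits[(int(iy), int(iz))] = VoxelFit(
            model=model,
            **{name: arrays[name][iy, iz] for name in _FIT_FIELDS},
        )
    return ParameterMaps(fits=fits, roi_labels=labels, tsl=tsl)


def _nifti(arr: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr, dtype=np.float32)[:, :, None], np.eye(4))


def export_maps_nifti(prefix: str, maps: ParameterMaps) -> list:
    """One NIfTI volume per fitted parameter; returns the written paths."""
    paths = []
    for name in _FIT_FIELDS:
        p = f"{prefix}_{name}.nii.gz"
        nib.save(_nifti(maps.array(name)), p)
        paths.append(p)
    return paths


def export_labels_nifti(path: str, roi_labels: np.ndarray) -> None:
    nib.save(_nifti(roi_labels), path)
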