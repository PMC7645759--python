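"""End-to-end accelerated-mapping experiment on synthetic data.

Reproduces the study design at configurable scale: generate train/test
synthetic slice datasets (half with k-space noise), tune the CS
regularization coefficient beta per transform on the training group, train
the VN variants on the training group, reconstruct the test group at each
acceleration factor, fit mono/biexponential maps on the ROIs, and tabulate
nRMSE and MNAD per method and AF.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import cs as cs_mod
from . import vn as vn_mod
from .fitting import fit_map
from .metrics import BIEXP_PARAMETERS, mnad, nrmse
from .operators import ImageSequence, MultiCoilKSpace, adjoint
from .phantom import (
    TSL_DEFAULT,
    make_dataset,
    snr_to_noise_sd,
    synthesize_sequence,
)
from .sampling import poisson_disk_mask

__all__ = ["ExperimentConfig", "run_experiment", "save_bundle", "load_bundle"]

KNOWN_METHODS = ("REF", "ZF", "CS-S", "CS-ST", "VN-S", "VN-ST")


@dataclass
class ExperimentConfig:
    """Configuration of the synthetic train/test experiment.

    The default desk scale (48x32x10 slices, 4 coils, AF sweep {2, 4, 6})
    keeps a full run in CPU minutes; counts mirror the study's ~4:3
    train/test split with half the sequences carrying k-space noise.
    """

    ny: int = 48
    nz: int = 32
    nc: int = 4
    n_train: int = 6
    n_test: int = 4
    af_list: tuple = (2.0, 4.0, 6.0)
    methods: tuple = ("ZF", "CS-ST", "VN-S")
    snr_db: float = 30.0
    seed: int = 0
    fit_maps: bool = True
    cs_max_iter: int = 200
    tune_max_iter: int = 60
    n_tune_pairs: int = 2
    vn_preset: str = "desk"
    vn_epochs: int | None = 20
    vn_train_af: float | None = None  # default: middle of af_list

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["af_list"] = list(self.af_list)
        d["methods"] = list(self.methods)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _make_slices(cfg: ExperimentConfig, n: int, seed0: int) -> list:
    """Generate n slice datasets; odd indices carry k-space noise."""
    out = []
    for i in range(n):
        seed = seed0 + 17 * i
        y, _, maps, coils = make_dataset(
            cfg.ny, cfg.nz, nc=cfg.nc, af=1.0, noise_sd=0.0, seed=seed
        )
        gt_seq = synthesize_sequence(maps, TSL_DEFAULT)
        noisy = i % 2 == 1
        if noisy:
            from .operators import add_noise

            sd = snr_to_noise_sd(maps, cfg.snr_db)
            y = add_noise(y, sd, seed=seed + 5)
        out.append(dict(y=y, maps=maps, coils=coils, gt=gt_seq, noisy=noisy, seed=seed))
    return out


def _reconstruct(method, y, coils, mask, betas, vn_params):
    if method == "ZF":
        return adjoint(y, coils, mask)
    if method in ("CS-S", "CS-ST"):
        transform = "sfd" if method == "CS-S" else "stfd"
        cfg = cs_mod.CSConfig(transform=transform, beta=betas[transform])
        x, _ = cs_mod.cs_reconstruct(y, coils, mask, cfg)
        return x
    if method in ("VN-S", "VN-ST"):
        return vn_mod.vn_forward(y, coils, mask, vn_params[(method, mask._af_key)])
    raise ValueError(f"unknown method {method!r}")


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full experiment; returns tables, tuned parameters and logs.

    The result dict carries ``nrmse_table`` and ``mnad_table`` DataFrames
    (per dataset / AF / method), the tuned betas, trained VN parameter
    objects, and per-stage timings.
    """
    for m in cfg.methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {KNOWN_METHODS}")
    timings: dict = {}
    t0 = time.time()
    train = _make_slices(cfg, cfg.n_train, seed0=cfg.seed + 1000)
    test = _make_slices(cfg, cfg.n_test, seed0=cfg.seed + 9000)
    timings["simulate"] = time.time() - t0

    af_list = tuple(cfg.af_list)
    tune_af = cfg.vn_train_af or (af_list[len(af_list) // 2] if af_list else None)

    # --- CS beta tuning on the training group -----------------------------
    betas = {}
    cs_methods = [m for m in cfg.methods if m.startswith("CS-")]
    t0 = time.time()
    for method in cs_methods:
        transform = "sfd" if method == "CS-S" else "stfd"
        pairs = []
        for j, d in enumerate(train[: cfg.n_tune_pairs]):
            mask = poisson_disk_mask(
                cfg.ny, cfg.nz, d["y"].tsl.size, tune_af, seed=cfg.seed + 300 + j
            )
            yS = MultiCoilKSpace(
                d["y"].data * mask.pattern[:, :, :, None], d["y"].tsl
            )
            pairs.append((yS, d["coils"], mask, d["gt"]))
        betas[transform], _ = cs_mod.tune_beta(
            pairs, transform=transform, max_iter=cfg.tune_max_iter
        )
    timings["tune_beta"] = time.time() - t0

    # --- VN training on the training group (per variant and AF) ----------
    vn_params: dict = {}
    vn_info: dict = {}
    vn_methods = [m for m in cfg.methods if m.startswith("VN-")]
    t0 = time.time()
    for method in vn_methods:
        variant = "s" if method == "VN-S" else "st"
        tc = vn_mod.preset_train_config(cfg.vn_preset, variant, seed=cfg.seed)
        if cfg.vn_epochs is not None:
            tc.epochs = cfg.vn_epochs
        for af in af_list:
            tset = []
            for j, d in enumerate(train):
                mask = poisson_disk_mask(
                    cfg.ny, cfg.nz, d["y"].tsl.size, af, seed=cfg.seed + 500 + j
                )
                yS = MultiCoilKSpace(
                    d["y"].data * mask.pattern[:, :, :, None], d["y"].tsl
                )
                tset.append((yS, d["coils"], mask, d["gt"]))
            p, info = vn_mod.train_vn(tset, tc, variant=variant)
            vn_params[(method, af)] = p
            vn_info[(method, af)] = info
    timings["train_vn"] = time.time() - t0

    # --- reference maps (fit of the noiseless ground-truth sequence) ------
    ref_maps = {}
    if cfg.fit_maps:
        t0 = time.time()
        for j, d in enumerate(test):
            ref_maps[j] = fit_map(d["gt"], d["maps"].roi_labels)
        timings["fit_reference"] = time.time() - t0

    # --- test-group sweep --------------------------------------------------
    nrmse_rows, mnad_rows = [], []
    t0 = time.time()
    for j, d in enumerate(test):
        full_ref = adjoint(d["y"], d["coils"])  # fully-sampled reference
        if "REF" in cfg.methods:
            nrmse_rows.append(
                dict(dataset=j, af=1.0, method="REF", nrmse=nrmse(full_ref, d["gt"]))
            )
            if cfg.fit_maps:
                m_ref = fit_map(full_ref, d["maps"].roi_labels)
                for par in ("tau",) + BIEXP_PARAMETERS:
                    mnad_rows.append(
                        dict(
                            dataset=j, af=1.0, method="REF", parameter=par,
                            mnad=mnad(m_ref, ref_maps[j], "all", par),
                        )
                    )
        sweep = [m for m in cfg.methods if m != "REF"]
        for af in af_list if sweep else []:
            mask = poisson_disk_mask(
                cfg.ny, cfg.nz, d["y"].tsl.size, af, seed=cfg.seed + 700 + j
            )
            mask._af_key = af
            yS = MultiCoilKSpace(
                d["y"].data * mask.pattern[:, :, :, None], d["y"].tsl
            )
            for method in sweep:
                x_hat = _reconstruct(method, yS, d["coils"], mask, betas, vn_params)
                nrmse_rows.append(
                    dict(dataset=j, af=af, method=method, nrmse=nrmse(x_hat, d["gt"]))
                )
                if cfg.fit_maps:
                    m_hat = fit_map(x_hat, d["maps"].roi_labels)
                    for par in ("tau",) + BIEXP_PARAMETERS:
                        mnad_rows.append(
                            dict(
                                dataset=j, af=af, method=method, parameter=par,
                                mnad=mnad(m_hat, ref_maps[j], "all", par),
                            )
                        )
    timings["test_sweep"] = time.time() - t0

    return {
        "config": cfg,
        "betas": betas,
        "vn_params": vn_params,
        "vn_info": vn_info,
        "nrmse_table": pd.DataFrame(
            nrmse_rows, columns=["dataset", "af", "method", "nrmse"]
        ),
        "mnad_table": pd.DataFrame(
            mnad_rows, columns=["dataset", "af", "method", "parameter", "mnad"]
        ),
        "timings": timings,
    }


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------

def save_bundle(path: str, results: dict) -> None:
    """Persist experiment outputs under a directory (HDF5 + CSV + YAML)."""
    import os

    from .io import save_vn_parameters

    os.makedirs(path, exist_ok=True)
    results["config"].to_yaml(os.path.join(path, "config.yaml"))
    results["nrmse_table"].to_csv(os.path.join(path, "nrmse.csv"), index=False)
    results["mnad_table"].to_csv(os.path.join(path, "mnad.csv"), index=False)
    with open(os.path.join(path, "betas.yaml"), "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in results["betas"].items()}, fh)
    for (method, af), p in results.get("vn_params", {}).items():
        save_vn_parameters(
            os.path.join(path, f"vn_{method.lower()}_af{af:g}.h5"), p
        )


def load_bundle(path: str) -> dict:
    """Load a saved bundle directory back into memory."""
    import glob
    import os

    from .io import load_vn_parameters

    if not os.path.isdir(path):
        raise IOError(f"bundle directory not found: {path!r}")
    out: dict = {
        "config": ExperimentConfig.from_yaml(os.path.join(path, "config.yaml")),
        "nrmse_table": pd.read_csv(os.path.join(path, "nrmse.csv")),
        "mnad_table": pd.read_csv(os.path.join(path, "mnad.csv")),
    }
    with open(os.path.join(path, "betas.yaml")) as fh:
        out["betas"] = yaml.safe_load(fh)
    out["vn_params"] = {}
    for p in glob.glob(os.path.join(path, "vn_*.h5")):
        out["vn_params"][os.path.basename(p)] = load_vn_parameters(p)
    return out
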