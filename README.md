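# rhomap

Accelerated mono- and biexponential T<sub>1ρ</sub> mapping of knee
cartilage from undersampled multi-coil MRI, for quantitative-MRI
researchers who want a complete, reproducible desk-scale pipeline:
synthetic 2D+time k-space with known ground truth, Poisson-disk
retrospective undersampling, compressed-sensing (CS) and variational-
network (VN) image reconstruction, complex-valued relaxometry fitting with
F-test model selection, and the associated error and repeatability
metrics.

## The problem and the models

T<sub>1ρ</sub>-weighted imaging acquires an image sequence at several
spin-lock times (TSLs); cartilage voxels decay mono- or biexponentially,

```
mono:   x(t) = c · exp(−t/τ)
biexp:  x(t) = c · ( f_s · exp(−t/τ_s) + f_l · exp(−t/τ_l) ),   f_s + f_l = 1
```

with complex amplitude `c`, short component τ_s ∈ [0.5, 10] ms and long
component τ_l ∈ [10, 300] ms.  Mapping all voxels requires many TSLs and
long scans, so k-space is undersampled and reconstructed by either

- **CS** — `min_x ‖y_S − S F C x‖₂² + λ‖T x‖₁` with spatial (SFD) or
  spatio-temporal (STFD) finite differences, solved by a monotone FISTA;
  λ = β·‖C\*F\*S\*y‖∞ with β tuned on training data over a 12-point log
  grid (ratio 12.3285) plus bisection; or
- **VN** — M unrolled gradient-like layers
  `x_{m+1} = x_m − Σ_i K*_{m,i} Φ'_{m,i}(K_{m,i} x_m) + α_m C*F*S*(y_S − S F C x_m)`
  whose filters, pointwise activations (Gaussian-RBF mixtures) and step
  sizes are learned with ADAM.

Fitting is complex-valued bounded trust-region nonlinear least squares
(avoiding the Rician magnitude bias); a voxel counts as biexponential only
if the nested-model F-ratio exceeds 5.14 (the 0.95 quantile of F(2, 6) at
10 TSLs) and both fractions are at least 5%.  Map accuracy is scored by
the median normalized absolute deviation (MNAD) per region of interest,
reconstructions by nRMSE.

## Worked example

```python
import numpy as np
from rhomap import phantom as ph
from rhomap.cs import CSConfig, cs_reconstruct
from rhomap.fitting import fit_map
from rhomap.metrics import mnad, nrmse
from rhomap.operators import MultiCoilKSpace, adjoint

y, mask, maps, coils = ph.make_dataset(48, 32, nc=4, af=4.0,
                                       noise_sd=0.003, seed=0)
x_true = ph.synthesize_sequence(maps, ph.TSL_DEFAULT)
yS = MultiCoilKSpace(y.data * mask.pattern[..., None], y.tsl)

zf = adjoint(yS, coils, mask)                       # zero-filled adjoint
cs, info = cs_reconstruct(yS, coils, mask,
                          CSConfig(transform="stfd", beta=0.005))
print(f"nRMSE  zero-filled {nrmse(zf, x_true):.3f}   CS-ST {nrmse(cs, x_true):.3f}")

ref = fit_map(x_true, maps.roi_labels)              # ground-truth maps
fit = fit_map(cs, maps.roi_labels)
print(f"MNAD(mono tau) = {mnad(fit, ref, 'all', 'tau'):.3f}")
```

prints (seed 0):

```
nRMSE  zero-filled 0.236   CS-ST 0.097
MNAD(mono tau) = 0.109
```

i.e. at four-fold acceleration the spatio-temporal CS reconstruction carries
9.7% sequence error against the noiseless truth (vs 23.6% for the
zero-filled adjoint), and its monoexponential time maps deviate from the
ground-truth-fit maps by a median of 10.9%.

A `rhomap` command-line tool exposes the stages individually
(`simulate`, `make-mask`, `recon-cs`, `train-vn`, `recon-vn`, `fit`,
`evaluate`, `run-all`); see `rhomap --help`.

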