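# Methods

This note documents the models, numerical choices and limitations behind
`rhomap`.

## Acquisition model and conventions

The forward model is `y = S F C x` for a 2D+time image sequence
`x ∈ C^{Ny×Nz×Nt}` (two phase-encode axes by spin-lock times; the readout
axis is assumed separated upstream by a 1D FFT).  Conventions:

- **FFT**: unitary (`norm="ortho"`) centred 2D FFT per frame and coil, so
  `F* = F⁻¹` and the adjoint dot-product identity holds to rounding.
  k-space arrays are stored FFT-shifted with the calibration block centred.
- **Coils**: sensitivities are normalised to unit sum-of-squares magnitude
  on the support, making `C*C` the identity there; the fully-sampled
  adjoint `C*F*y` is then an exact left inverse, which is what makes it
  usable as the reference reconstruction.
- **Phase compensation** is part of `C`: `phase_map` stores the unit
  compensating phasor, applied by the adjoint after coil combination so
  reconstructed images are near zero-phase for complex-valued fitting
  (the forward operator applies its conjugate).  It is estimated once per
  slice from the first spin-lock time; re-estimating per TSL would only
  matter for phase drift between TSLs, which the model excludes.
- **Sensitivity estimation** is a simplified autocalibration: apodised
  zero-padded reconstruction of the calibration block (default 39×19,
  scaled proportionally and rounded to odd for other grids), divided by
  the root-sum-of-squares image, phase-referenced to the strongest coil
  (which cancels the shared image phase out of the sensitivities),
  Gaussian-smoothed and renormalised.  This is not an eigen-decomposition
  (ESPIRiT-style) estimator; it is accurate for smooth profiles and is
  validated against known profiles in the tests.

## Poisson-disk undersampling

Masks are generated per frame by greedy dart throwing with a minimum
pairwise distance, the radius found by bisection so the dart count reaches
the target density; surplus samples are removed at random, which preserves
the minimum-distance property while hitting the requested acceleration
factor exactly up to integer rounding (well within the 2% contract).  The
calibration block is always fully sampled at every frame.  Frames get
independent patterns by default (complementary sampling across TSLs); a
shared-pattern variant is a flag.  Density is uniform outside the
calibration block — the fully-sampled centre already supplies the
low-frequency weighting.

## CS reconstruction

`min_x ‖y_S − SFCx‖₂² + λ‖Tx‖₁` with first-order spatial differences
(SFD) or those plus second-order temporal differences (STFD), both with
zero boundaries so transform and adjoint are exact transposes.  The solver
is a monotone FISTA: the accepted iterate is the better of the proximal
candidate and the previous iterate, while momentum is always built from
the candidate, so the cost trace is non-increasing by construction and
progress survives an occasionally inexact prox.  Details:

- The non-separable prox of `‖T·‖₁` runs 20 warm-started dual
  projected-gradient steps (step `1/‖T‖²`, with `‖T‖² ≤ 8` for SFD and
  `≤ 24` for STFD).
- The gradient step uses `1/L` with `L = 2·σmax(A*A)` estimated by 20
  power iterations and a 1.05 safety factor.
- Stopping: relative iterate change `< 1e-5` (only counted on accepted
  moves) or 600 iterations; non-convergence is flagged, not raised.
- λ is a single scalar: either given directly or as `β·‖C*F*S*y‖∞`.
  `tune_beta` minimises the summed squared training error over the
  12-point log grid spanning 1e-6..1e6 (consecutive ratio `10^(12/11)` ≈
  12.3285) and then refines with 12 bisection probes around the best
  bracket.

At tight tolerance (1e-7, 2000 iterations) the solver's objective agrees
with a 50,000-iteration plain proximal-gradient reference to ~1e-6
relative on the test problem; the 1e-5 default trades that accuracy for
speed.

## Variational network

M fixed layers of
`x_{m+1} = x_m − Σ_i K*_{m,i} Φ'_{m,i}(K_{m,i} x_m) + α_m C*F*S*(y_S − SFCx_m)`.
The printed form of the layer equation can be read with the
data-consistency term *subtracted*, which would step away from the data;
we implement the standard gradient-descent sign above.

- **Complex handling**: images are two real channels; filters are real
  over both channels (spatial k×k×1 or spatio-temporal k×k×3); `K*` is
  the matched transposed convolution.  Convolutions are zero-padded and
  evaluated in a batched FFT domain (one padded grid per layer), which is
  numerically identical to direct 'same' convolution and is what makes
  CPU training practical.
- **Activations**: weighted sums of 31 Gaussian RBFs on fixed, evenly
  spaced knots in [−1, 1], with σ twice the knot spacing (wide enough
  that a linear function is representable to <1e-2); inputs outside the
  range are clipped, so activations are bounded.  Inputs are scaled into
  this range by normalising each sequence by the peak magnitude of its
  zero-filled adjoint.
- **Training**: ADAM (lr 1e-3) on the summed squared complex output
  error; gradients come from a hand-derived backpropagation verified
  against finite differences to <1e-4 relative; step sizes are clamped
  non-negative after each update; a random 10% validation split is held
  out.  Divergence (non-finite loss) aborts with a diagnostic.
- **Presets**: `full` (M=10, N_k=24, 11×11(×3) filters, 50 epochs,
  batch 40/20) records the full-scale, GPU-class configuration; `desk` (M=5, N_k=8,
  5×5(×3), 30 epochs, batch 8) is the CPU-sized configuration used by the
  tests and the experiment pipeline.  No constraints (e.g. zero-mean
  filters) are imposed on filters.

## Relaxometry fitting and model selection

Complex-valued residuals (stacked real/imaginary) are minimised by
bounded trust-region nonlinear least squares (`scipy`'s TRF with analytic
Jacobians); mono over `(Re c, Im c, τ)` with τ ∈ [0.1, 500] ms — wider
than the short/long classification ranges, so classification stays a
separate step — and biexp over `(Re c, Im c, f_s, τ_s, τ_l)` with
τ_s ∈ [0.5, 10], τ_l ∈ [10, 300], f_l = 1 − f_s.  Internal tolerances are
tighter (1e-12) than the nominal 1e-5 update rule so noiseless round
trips recover parameters to 1e-6 (mono) / 1e-3 (biexp); iteration caps
2000/4000.

Biexponential fits are seeded from the mono result (short: τ_s = τ,
τ_l = 45 ms, f_s = 0.7; long: τ_l = τ, τ_s = 4 ms, f_s = 0.3); a
complementary second start is also tried and the lower-SSE solution kept,
because a single seed frequently misses the global optimum on
near-degenerate voxels.  If the biexponential SSE still exceeds the mono
SSE, the mono-equivalent degenerate point is substituted, so reported
`SSE_bi ≤ SSE_mono` always (model nesting).

Selection: `F = ((SSE_mono − SSE_bi)/2) / (SSE_bi/(n−4))` accepted at the
0.95 quantile of F(2, n−4) — 5.14 at n = 10 TSLs.  This counts each TSL
as one observation and `c` as one parameter; it is the unique
degrees-of-freedom convention under which the printed 5.14 cutoff is the
0.05-level quantile.  Note that as a statistical test this rule is
*conservative*: the mono model sits on the boundary of the biexponential
family (f_s ∈ {0,1}, with the complementary time unidentified), so the
likelihood-ratio statistic is not F-distributed and the empirical
false-positive rate on pure-mono noisy voxels falls well below the
nominal 5% (the acceptance script measures it).  This conservatism is a
property of the selection rule itself, not of the optimizer — it persists
under dense multi-start fitting.  Voxels also need both fractions ≥ 5%
to count as biexponential; failing voxels keep their mono fit and are
excluded from biexponential evaluations (two-sided exclusion when two
maps are compared).

## Metrics

nRMSE over the full complex sequence; NAD = |p − p_ref|/((p + p_ref)/2)
and its ROI median (MNAD), computed only over voxels valid in *both*
maps (for biexponential parameters: both maps accept biexp); ROI mean and
population SD (1/N, as the repeatability analysis defines it — CV
inherits this convention for the two-scan case); balanced one-way ANOVA
(`scipy.stats.f_oneway` behind the module surface).  Complex amplitudes
are not NAD-scored (NAD is defined for positive reals); times and
fractions are.

## Synthetic data

The generator produces procedural, not anatomical, geometry: five curved
band-shaped cartilage-like ROIs (labelled MFC, MTC, LFC, LTC, PC) on a
smooth monoexponential background.  Per-ROI parameters are drawn
uniformly within the component ranges (τ_s ∈ [3, 8] ms, τ_l ∈ [30, 80]
ms, f_s ∈ [0.25, 0.45]); by default 70% of cartilage voxels are
biexponential.  Image phase is smooth and low-order; coil profiles are
Gaussian-bump magnitudes with smooth phases, SOS-normalised.  The default
noise level targets 30 dB first-TSL image SNR (`snr_to_noise_sd`), a
typical in-vivo level for this protocol; k-space noise is complex
Gaussian per component.  The default TSL protocol is
2/4/6/8/10/15/25/35/45/55 ms.

What passing tests on this phantom do **not** show: robustness to
anatomy-specific aliasing structure, B0/B1 artifacts, motion, chemical
shift, or sensitivity-estimation error on real coil arrays.  The phantom
closes the simulate→reconstruct→fit loop with exactly known truth, which
is the property the validation needs.

## Experiment pipeline and problem sizes

`run_experiment` mirrors the study design at desk scale: train/test
synthetic groups in a ≈4:3 split with half the slices noisy, β tuned per
transform on training pairs, VN variants trained per acceleration factor,
then the test sweep with nRMSE (against the noiseless truth) and MNAD
(against maps fitted to the noiseless truth) per method and AF.  The
default configuration uses 48×32×10 slices, 4 coils and AF {2, 4, 6};
the acceptance runs use 4 training + 2 test slices, 12 VN-S epochs and a
reduced tuning iteration cap — sizes chosen so a full run stays in CPU
minutes while leaving the qualitative orderings (error grows with AF;
tuned CS-ST and trained VN-S beat the zero-filled adjoint) intact.

## Known limitations

- The sensitivity estimator is calibration-only and degrades for sharply
  varying coil profiles; support thresholding is a single relative cut.
- VN training at the `full` preset is provided but not exercised by the
  tests (CPU cost); desk-scale results should not be read as evidence of
  full-scale reconstruction quality.
- The F-test calibration issue above: the 5.14 rule under-accepts
  biexponential voxels relative to its nominal level; with complex-valued
  residuals the observation-counting convention compounds this.
- The two-scan CV uses the 1/N SD convention for consistency with the ROI
  SD definition; with n = 2 the 1/(N−1) convention would simply double it.
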