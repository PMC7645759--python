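"""l1-regularized compressed-sensing reconstruction.

Solves  min_x ||y_S - S F C x||_2^2 + lambda ||T x||_1  with T either the
spatial finite difference (SFD, first order in y and z per frame) or the
spatio-temporal finite difference (STFD, SFD plus second-order temporal
differences).  The solver is a monotone FISTA with restart: accelerated
proximal gradient whose cost trace is non-increasing by construction.  The
non-separable prox of ||T . ||_1 is computed by an inner dual
projected-gradient loop (warm-started across outer iterations).

The regularization weight may be given directly (``lam``) or through the
data-adaptive rule  lambda = beta * max |C* F* S* y|  (``beta``); ``tune_beta``
searches beta over 12 log-spaced points spanning 1e-6..1e6 (consecutive
ratio 10^(12/11) ~= 12.3285) followed by 12 bisection refinement steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import (
    CoilProfile,
    ImageSequence,
    MultiCoilKSpace,
    SamplingMask,
    adjoint,
    forward,
)  # SamplingMask kept in the public signatures

__all__ = [
    "CSConfig",
    "sfd",
    "sfd_adjoint",
    "stfd",
    "stfd_adjoint",
    "lambda_from_beta",
    "cs_reconstruct",
    "tune_beta",
    "beta_grid",
]


# ---------------------------------------------------------------------------
# sparsifying transforms (zero-boundary, exact transposes)
# ---------------------------------------------------------------------------

def sfd(x: np.ndarray) -> np.ndarray:
    """Spatial finite differences, order 1, per frame.

    Input (ny, nz, nt) complex; output (2, ny, nz, nt): forward differences
    along y and z with the difference at the last index set to zero.
    """
    d = np.zeros((2,) + x.shape, dtype=x.dtype)
    d[0, :-1] = x[1:] - x[:-1]
    d[1, :, :-1] = x[:, 1:] - x[:, :-1]
    return d


def sfd_adjoint(d: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`sfd` (negative divergence)."""
    x = np.zeros(d.shape[1:], dtype=d.dtype)
    x[1:] += d[0, :-1]
    x[:-1] -= d[0, :-1]
    x[:, 1:] += d[1, :, :-1]
    x[:, :-1] -= d[1, :, :-1]
    return x


def stfd(x: np.ndarray) -> np.ndarray:
    """Spatio-temporal finite differences: SFD plus second-order temporal.

    Output (3, ny, nz, nt); the temporal channel holds
    x(t-1) - 2 x(t) + x(t+1) at interior t, zero at the ends.  Requires
    at least three frames.
    """
    if x.shape[2] < 3:
        raise ValueError("STFD needs at least 3 frames (Nt >= 3)")
    d = np.zeros((3,) + x.shape, dtype=x.dtype)
    d[:2] = sfd(x)
    d[2, :, :, 1:-1] = x[:, :, :-2] - 2 * x[:, :, 1:-1] + x[:, :, 2:]
    return d


def stfd_adjoint(d: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`stfd`."""
    x = sfd_adjoint(d[:2])
    g = d[2, :, :, 1:-1]
    x[:, :, :-2] += g
    x[:, :, 1:-1] -= 2 * g
    x[:, :, 2:] += g
    return x


_TRANSFORMS = {
    "sfd": (sfd, sfd_adjoint, 8.0),  # ||T||^2 upper bounds
    "stfd": (stfd, stfd_adjoint, 24.0),
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CSConfig:
    """CS reconstruction settings.

    Exactly one of ``lam`` / ``beta`` must be set.  ``tol`` is the relative
    iterate-change stopping threshold; iteration caps follow the reference
    protocol (600 outer, 20 inner dual prox steps).
    """

    transform: str = "stfd"
    lam: float | None = None
    beta: float | None = None
    tol: float = 1e-5
    max_iter: int = 600
    inner_iter: int = 20

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError("transform must be 'sfd' or 'stfd'")
        if (self.lam is None) == (self.beta is None):
            raise ValueError("set exactly one of lam / beta")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def lambda_from_beta(
    beta: float,
    y: MultiCoilKSpace,
    coils: CoilProfile,
    mask: SamplingMask | None,
) -> float:
    """Data-adaptive regularization weight: beta * max |C* F* S* y|."""
    zf = adjoint(y, coils, mask)
    return float(beta * np.max(np.abs(zf.data)))


# ---------------------------------------------------------------------------
# solver pieces
# ---------------------------------------------------------------------------

def _power_iteration_L(coils, mask, shape, tsl, n_iter=20, seed=0):
    """Spectral norm estimate of A*A for A = S F C, with safety factor."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = adjoint(forward(ImageSequence(v, tsl), coils, mask), coils, mask).data
        lam = np.linalg.norm(w)
        if lam < 1e-30:
            return 1.0
        v = w / lam
    return float(lam) * 1.05


def _prox_l1_T(z, step_lam, T, Tt, norm_T2, p0, n_inner):
    """prox of step_lam * ||T . ||_1 at z, via dual projected gradient.

    Solves max_{|p|<=step_lam} -1/2 ||z - T* p||^2 ... by gradient
    projection with step 1/||T||^2, warm-started at p0.  Returns (x, p).
    """
    p = p0
    tau = 1.0 / norm_T2
    for _ in range(n_inner):
        grad = T(z - Tt(p))
        p = p + tau * grad
        mag = np.abs(p)
        over = mag > step_lam
        if np.any(over):
            p = np.where(over, p * (step_lam / np.where(mag > 0, mag, 1)), p)
    return z - Tt(p), p


def cs_reconstruct(
    y: MultiCoilKSpace,
    coils: CoilProfile,
    mask: SamplingMask | None,
    cfg: CSConfig,
) -> tuple:
    """Monotone accelerated proximal-gradient CS reconstruction.

    Returns ``(ImageSequence, info)`` where ``info`` carries the cost trace
    (non-increasing), the regularization weight used, the iteration count
    and a convergence flag.  Initialized at the zero-filled adjoint; stops
    when ||x_{i+1} - x_i|| / ||x_{i+1}|| < tol or at ``max_iter``.
    """
    T, Tt, norm_T2 = _TRANSFORMS[cfg.transform]
    lam = (
        cfg.lam
        if cfg.lam is not None
        else lambda_from_beta(cfg.beta, y, coils, mask)
    )
    tsl = y.tsl
    yS = y.data if mask is None else y.data * mask.pattern[:, :, :, None]
    y_masked = MultiCoilKSpace(yS, tsl)

    def A(ximg):
        return forward(ImageSequence(ximg, tsl), coils, mask).data

    def At(kdata):
        return adjoint(MultiCoilKSpace(kdata, tsl), coils, mask).data

    x0 = At(yS)
    L = 2.0 * _power_iteration_L(coils, mask, x0.shape, tsl)
    step = 1.0 / L

    def f(ximg):
        r = A(ximg) - yS
        return float(np.vdot(r, r).real)

    def cost(ximg):
        return f(ximg) + lam * float(np.sum(np.abs(T(ximg))))

    # monotone FISTA: the accepted iterate is the better of the proximal
    # candidate and the previous iterate; momentum is built from the
    # candidate either way, so progress continues after a non-decreasing
    # candidate (inexact prox) without breaking monotonicity.
    x = x0
    x_prev = x0
    z = x0
    t_mom = 1.0
    p_warm = np.zeros_like(T(x0))
    costs = [cost(x)]
    converged = False
    n_it = 0
    for n_it in range(1, cfg.max_iter + 1):
        grad = 2.0 * At(A(z) - yS)
        v = z - step * grad
        if lam > 0:
            u, p_warm = _prox_l1_T(
                v, step * lam, T, Tt, norm_T2, p_warm, cfg.inner_iter
            )
        else:
            u = v
        c_u = cost(u)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        accepted = c_u <= costs[-1]
        if accepted:
            x_new, c_new = u, c_u
        else:
            x_new, c_new = x, costs[-1]
        z = (
            x_new
            + (t_mom / t_new) * (u - x_new)
            + ((t_mom - 1.0) / t_new) * (x_new - x_prev)
        )
        denom = np.linalg.norm(x_new)
        rel = np.linalg.norm(x_new - x_prev) / denom if denom > 0 else 0.0
        x_prev, x, t_mom = x, x_new, t_new
        costs.append(c_new)
        if accepted and rel < cfg.tol:
            converged = True
            break
    info = {
        "cost": np.array(costs),
        "lam": lam,
        "iterations": n_it,
        "converged": converged,
    }
    return ImageSequence(x, tsl), info


# ---------------------------------------------------------------------------
# beta search
# ---------------------------------------------------------------------------

def beta_grid() -> np.ndarray:
    """The 12-point log grid spanning 1e-6..1e6 (ratio 10^(12/11))."""
    return np.logspace(-6.0, 6.0, 12)


def tune_beta(
    training_pairs: list,
    transform: str = "stfd",
    n_refine: int = 12,
    **solver_kwargs,
) -> tuple:
    """Pick beta minimizing sum_j ||x_hat(beta, j) - x_ref_j||_2^2.

    ``training_pairs`` is a nonempty list of (y, coils, mask, x_ref) with
    ``x_ref`` an :class:`ImageSequence` (ground truth or fully-sampled
    reference).  The 12-point log grid is searched first, then ``n_refine``
    bisection steps shrink the bracket around the best grid value.  Extra
    keyword arguments (e.g. ``max_iter``) are forwarded to the solver
    config.  Returns ``(beta, info)``.
    """
    if not training_pairs:
        raise ValueError("training set must be nonempty")

    def score(beta):
        err = 0.0
        for yj, coilsj, maskj, xrefj in training_pairs:
            cfg = CSConfig(transform=transform, beta=float(beta), **solver_kwargs)
            xj, _ = cs_reconstruct(yj, coilsj, maskj, cfg)
            err += float(np.linalg.norm(xj.data - xrefj.data) ** 2)
        return err

    grid = beta_grid()
    errors = [score(b) for b in grid]
    i_best = int(np.argmin(errors))
    lg = np.log10(grid)
    lo = lg[max(i_best - 1, 0)]
    hi = lg[min(i_best + 1, lg.size - 1)]
    best_b, best_e = lg[i_best], errors[i_best]
    trace = list(zip(grid.tolist(), errors))
    # bisection refinement: probe midpoints of the larger half-bracket
    for _ in range(n_refine):
        mid = 0.5 * (lo + best_b) if (best_b - lo) >= (hi - best_b) else 0.5 * (
            best_b + hi
        )
        e_mid = score(10.0**mid)
        trace.append((10.0**mid, e_mid))
        if e_mid < best_e:
            if mid < best_b:
                hi = best_b
            else:
                lo = best_b
            best_b, best_e = mid, e_mid
        else:
            if mid < best_b:
                lo = mid
            else:
                hi = mid
    info = {"trace": trace, "error": best_e}
    return float(10.0**best_b), info
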