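"""Rudin-Osher-Fatemi total-variation denoising.

The TV seminorm of an image f is

    ||f||_TV = sum_{m,n} sqrt( (f[m,n]-f[m-1,n])^2 + (f[m,n]-f[m,n-1])^2 )

with backward differences and replicate padding (an out-of-range neighbour
equals the pixel itself, so boundary differences vanish). The ROF objective
balances this edge-preserving roughness penalty against fidelity to the
observed image I:

    phi[f | I] = ||f||_TV + (lambda/2) * sum (I - f)^2

Small lambda flattens the image, large lambda keeps it close to the data.
The minimizer is found by explicit gradient descent on the epsilon-smoothed
objective with backtracking line search, which guarantees a monotone
non-increasing objective trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionError
from .image import Image

_MAX_HALVINGS = 60


@dataclass(frozen=True)
class TVParams:
    """Solver configuration for :func:`denoise_tv`.

    lam
        Fidelity weight lambda (> 0). The study value is 0.1.
    epsilon
        Smoothing constant added inside the gradient-magnitude square root
        so the objective is differentiable everywhere.
    step
        Initial gradient-descent step size; halved whenever a trial step
        would increase the objective.
    max_iters
        Cap on accepted iterations.
    rel_tol
        Stop when the relative objective decrease of an accepted step falls
        below this threshold.
    """

    lam: float = 0.1
    epsilon: float = 1e-8
    step: float = 0.1
    max_iters: int = 200
    rel_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ConfigurationError(f"lam must be > 0, got {self.lam}")
        if self.epsilon <= 0:
            raise ConfigurationError(f"epsilon must be > 0, got {self.epsilon}")
        if self.step <= 0:
            raise ConfigurationError(f"step must be > 0, got {self.step}")
        if self.max_iters < 1:
            raise ConfigurationError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.rel_tol < 0:
            raise ConfigurationError(f"rel_tol must be >= 0, got {self.rel_tol}")


@dataclass
class DenoiseResult:
    """Denoised image plus the solver's convergence record."""

    image: Image
    objective_trace: np.ndarray  # phi at f0 and after each accepted step
    iterations_run: int
    converged: bool


def _as_array(img: Image | np.ndarray) -> np.ndarray:
    return img.values if isinstance(img, Image) else np.asarray(img, dtype=np.float64)


def _diffs(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Backward differences with replicate padding (zero on first row/col)."""
    dx = np.zeros_like(f)
    dy = np.zeros_like(f)
    dx[1:, :] = f[1:, :] - f[:-1, :]
    dy[:, 1:] = f[:, 1:] - f[:, :-1]
    return dx, dy


def tv_seminorm(img: Image | np.ndarray, epsilon: float = 0.0) -> float:
    """Total-variation seminorm; ``epsilon > 0`` gives the smoothed variant
    ``sum sqrt(dx^2 + dy^2 + epsilon)`` used inside the solver."""
    if epsilon < 0:
        raise ConfigurationError("epsilon must be >= 0")
    f = _as_array(img)
    dx, dy = _diffs(f)
    return float(np.sqrt(dx * dx + dy * dy + epsilon).sum())


def rof_objective(f: Image | np.ndarray, observed: Image | np.ndarray,
                  params: TVParams) -> float:
    """ROF objective phi[f | I] = ||f||_TV,eps + (lam/2) * sum (I - f)^2."""
    fa = _as_array(f)
    ia = _as_array(observed)
    if fa.shape != ia.shape:
        raise DimensionError(f"shape mismatch: f {fa.shape} vs I {ia.shape}")
    fidelity = 0.5 * params.lam * float(((ia - fa) ** 2).sum())
    return tv_seminorm(fa, params.epsilon) + fidelity


def _objective_gradient(f: np.ndarray, observed: np.ndarray,
                        params: TVParams) -> np.ndarray:
    """Analytic gradient of the epsilon-smoothed ROF objective.

    Each pixel (m, n) appears in up to three square-root terms: its own, and
    as the backward neighbour inside the terms of (m+1, n) and (m, n+1).
    """
    dx, dy = _diffs(f)
    w = np.sqrt(dx * dx + dy * dy + params.epsilon)
    gx = dx / w
    gy = dy / w
    grad = gx + gy
    grad[:-1, :] -= gx[1:, :]
    grad[:, :-1] -= gy[:, 1:]
    grad += params.lam * (f - observed)
    return grad


def _line_search(f: np.ndarray, grad: np.ndarray, observed: np.ndarray,
                 params: TVParams, obj: float) -> tuple[float, float] | None:
    """Monotone step along the negative gradient.

    A bounded scalar minimization picks the step in (0, params.step] that
    minimizes the objective along the ray; because the chosen step varies
    continuously with the data, the iterate sequence does too (a step
    quantized in powers of two would make the endpoint jump between nearby
    inputs). If the scalar search fails to decrease the objective, fall back
    to halving from params.step; returns None when no decrease exists.
    """
    from scipy.optimize import minimize_scalar

    def along(t: float) -> float:
        return rof_objective(f - t * grad, observed, params)

    res = minimize_scalar(along, bounds=(0.0, params.step), method="bounded",
                          options={"xatol": 1e-8 * params.step})
    if res.fun <= obj:
        return float(res.x), float(res.fun)
    tau = params.step
    for _ in range(_MAX_HALVINGS):
        obj_new = along(tau)
        if obj_new <= obj:
            return tau, obj_new
        tau *= 0.5
    return None


def denoise_tv(observed: Image, params: TVParams | None = None) -> DenoiseResult:
    """Minimize the ROF objective by monotone gradient descent from f0 = I.

    Each iteration moves along the negative gradient of the epsilon-smoothed
    objective with a line-searched step bounded by ``params.step``; a step
    that would increase the objective is rejected (halving fallback), so the
    recorded objective trace is non-increasing by construction. Iteration
    stops when the relative objective decrease drops below ``rel_tol``, when
    no decrease can be found, or at ``max_iters``.
    """
    params = params or TVParams()
    if not np.all(np.isfinite(observed.values)):
        raise ValueError("input image contains non-finite values")
    I = observed.values
    f = I.copy()
    obj = rof_objective(f, I, params)
    trace = [obj]
    iterations = 0
    converged = False
    for _ in range(params.max_iters):
        grad = _objective_gradient(f, I, params)
        step = _line_search(f, grad, I, params, obj)
        if step is None:
            # no descent step found: numerically at a minimum
            converged = True
            break
        tau, obj_new = step
        rel = (obj - obj_new) / max(abs(obj), np.finfo(float).tiny)
        f = f - tau * grad
        obj = obj_new
        trace.append(obj)
        iterations += 1
        if rel < params.rel_tol:
            converged = True
            break
    out = observed.with_values(f, stage=f"tv(lam={params.lam})")
    return DenoiseResult(image=out, objective_trace=np.asarray(trace),
                         iterations_run=iterations, converged=converged)
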