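"""Posterior-mean estimation by variational Bayes.

The posterior of (f, v_eps, v_f) is approximated by a separable law
minimising the Kullback-Leibler divergence.  Two factorisations are
implemented:

*partial separability* — f keeps a full multivariate-normal factor, so the
iteration maintains the complete covariance matrix Sigma of the PC vector;

*full separability* — every coordinate f_j gets its own normal factor, and
the mean update becomes a Gauss-Seidel sweep (each coordinate uses the
already-updated values of its predecessors) with a scalar variance per
coordinate.

In both cases the variance factors are inverse-gamma with *constant* shape
parameters (alpha0 + 1/2); only the scales move, through the residual and
the posterior second moments.  Expected precisions are the inverse-gamma
inverse moments alpha/beta.  All factors are initialised from the NIPL
constants, i.e. unit expected precisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .dictionary import Dictionary, PCVector
from .model import IGHyperparameters, StoppingRule

__all__ = [
    "VBAPosteriorPartial",
    "VBAPosteriorFull",
    "ig_inverse_moment",
    "vba_partial_update_f",
    "vba_partial_update_noise",
    "vba_partial_update_prior",
    "run_vba_partial",
    "vba_full_update_fj",
    "run_vba_full",
]


@dataclass
class VBAPosteriorPartial:
    """Mean-field posterior with a full covariance factor for f."""

    f_mean: PCVector
    sigma: NDArray[np.float64]
    alpha_eps: NDArray[np.float64]
    beta_eps: NDArray[np.float64]
    alpha_f: NDArray[np.float64]
    beta_f: NDArray[np.float64]
    iteration: int
    converged: bool = True
    trace: list[float] = field(default_factory=list)


@dataclass
class VBAPosteriorFull:
    """Fully factorised posterior: per-coordinate normal factors for f."""

    f_mean: PCVector
    var: NDArray[np.float64]
    alpha_eps: NDArray[np.float64]
    beta_eps: NDArray[np.float64]
    alpha_f: NDArray[np.float64]
    beta_f: NDArray[np.float64]
    iteration: int
    converged: bool = True
    trace: list[float] = field(default_factory=list)


def ig_inverse_moment(alpha: float, beta: float) -> float:
    """E[x^-1] under an inverse-gamma(alpha, beta) law: alpha/beta."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("inverse-gamma parameters must be strictly positive")
    return alpha / beta


def vba_partial_update_f(
    d: Dictionary,
    g: NDArray[np.float64],
    v_eps_inv_hat: NDArray[np.float64],
    v_f_inv_hat: NDArray[np.float64],
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Normal factor of f: Sigma = (H' We H + Wf)^-1, mean = Sigma H' We g.

    We / Wf are the diagonal expected-precision matrices.  Computed through
    a Cholesky factorisation of the (SPD) precision matrix.
    """
    if np.any(v_eps_inv_hat <= 0) or np.any(v_f_inv_hat <= 0):
        raise ValueError("expected precisions must be strictly positive")
    A = (d.matrix.T * v_eps_inv_hat) @ d.matrix
    A[np.diag_indices_from(A)] += v_f_inv_hat
    try:
        c = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("posterior precision matrix is indefinite") from exc
    c_inv = np.linalg.solve(c, np.eye(c.shape[0]))
    sigma = c_inv.T @ c_inv
    f_mean = sigma @ (d.matrix.T @ (v_eps_inv_hat * np.asarray(g, float)))
    return f_mean, sigma


def vba_partial_update_noise(
    g: NDArray[np.float64],
    d: Dictionary,
    f_mean: NDArray[np.float64],
    sigma: NDArray[np.float64],
    h: IGHyperparameters,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """IG factors of v_eps: shape alpha_eps0 + 1/2, scale from H_i Sigma H_i' + r_i^2."""
    residual = np.asarray(g, float) - d.matrix @ f_mean
    quad = np.einsum("ij,jk,ik->i", d.matrix, sigma, d.matrix)
    alpha = np.full(residual.size, h.alpha_eps0 + 0.5)
    beta = h.beta_eps0 + 0.5 * (quad + residual**2)
    return alpha, beta


def vba_partial_update_prior(
    f_mean: NDArray[np.float64], sigma: NDArray[np.float64], h: IGHyperparameters
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """IG factors of v_f: shape alpha_f0 + 1/2, scale from f_j^2 + Sigma_jj."""
    alpha = np.full(f_mean.size, h.alpha_f0 + 0.5)
    beta = h.beta_f0 + 0.5 * (f_mean**2 + np.diag(sigma))
    return alpha, beta


def run_vba_partial(
    g: NDArray[np.float64],
    d: Dictionary,
    h: IGHyperparameters | None = None,
    stop: StoppingRule | None = None,
) -> VBAPosteriorPartial:
    """Iterate f-factor -> noise factors -> prior factors until stable."""
    h = h or IGHyperparameters()
    stop = stop or StoppingRule()
    g = np.asarray(g, dtype=float)
    n, k = d.matrix.shape
    v_eps_inv = np.full(n, ig_inverse_moment(h.alpha_eps0, h.beta_eps0))
    v_f_inv = np.full(k, ig_inverse_moment(h.alpha_f0, h.beta_f0))
    f_old = np.zeros(k)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, stop.max_iter + 1):
        f_mean, sigma = vba_partial_update_f(d, g, v_eps_inv, v_f_inv)
        alpha_eps, beta_eps = vba_partial_update_noise(g, d, f_mean, sigma, h)
        alpha_f, beta_f = vba_partial_update_prior(f_mean, sigma, h)
        v_eps_inv = alpha_eps / beta_eps
        v_f_inv = alpha_f / beta_f
        trace.append(float(np.linalg.norm(f_mean - f_old)))
        if stop.fired(f_mean, f_old):
            converged = True
            break
        f_old = f_mean
    return VBAPosteriorPartial(
        f_mean=PCVector(f_mean, d.period_grid, basis=d.basis),
        sigma=sigma,
        alpha_eps=alpha_eps,
        beta_eps=beta_eps,
        alpha_f=alpha_f,
        beta_f=beta_f,
        iteration=it,
        converged=converged,
        trace=trace,
    )


def vba_full_update_fj(
    d: Dictionary,
    g: NDArray[np.float64],
    v_eps_inv_hat: NDArray[np.float64],
    v_fj_inv_hat: float,
    f_others: NDArray[np.float64],
    j: int,
) -> tuple[float, float]:
    """Coordinate factor of f_j given the other coordinates' current means.

    Returns the mean H_j' We (g - H_{-j} f_{-j}) / (||We^(1/2) H_j||^2 + wf_j)
    and the variance 1/denominator.
    """
    if v_fj_inv_hat <= 0 or np.any(v_eps_inv_hat <= 0):
        raise ValueError("expected precisions must be strictly positive")
    col = d.matrix[:, j]
    denom = float(np.sum(v_eps_inv_hat * col * col) + v_fj_inv_hat)
    partial_residual = np.asarray(g, float) - d.matrix @ f_others + col * f_others[j]
    mean = float(np.sum(col * v_eps_inv_hat * partial_residual) / denom)
    return mean, 1.0 / denom


def run_vba_full(
    g: NDArray[np.float64],
    d: Dictionary,
    h: IGHyperparameters | None = None,
    stop: StoppingRule | None = None,
) -> VBAPosteriorFull:
    """Coordinate-wise VBA: one ascending Gauss-Seidel sweep per iteration.

    After each sweep the noise scales use the diagonal-covariance quadratic
    term sum_j H_ij^2 var_j plus the squared residual, and the prior scales
    use f_j^2 + var_j.

    One Gauss-Seidel sweep moves f far less than one joint solve, and the
    dictionary columns of neighbouring periods are strongly correlated, so
    the default sweep budget is much larger than for the partial scheme
    (each sweep costs only O(N*K)).
    """
    h = h or IGHyperparameters()
    stop = stop or StoppingRule(max_iter=5000)
    g = np.asarray(g, dtype=float)
    n, k = d.matrix.shape
    v_eps_inv = np.full(n, ig_inverse_moment(h.alpha_eps0, h.beta_eps0))
    v_f_inv = np.full(k, ig_inverse_moment(h.alpha_f0, h.beta_f0))
    f = np.zeros(k)
    var = np.zeros(k)
    sq_matrix = d.matrix**2
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, stop.max_iter + 1):
        f_old = f.copy()
        residual = g - d.matrix @ f
        for j in range(k):
            col = d.matrix[:, j]
            denom = np.sum(v_eps_inv * col * col) + v_f_inv[j]
            partial_residual = residual + col * f[j]
            f_j = np.sum(col * v_eps_inv * partial_residual) / denom
            residual = partial_residual - col * f_j
            f[j] = f_j
            var[j] = 1.0 / denom
        alpha_eps = np.full(n, h.alpha_eps0 + 0.5)
        beta_eps = h.beta_eps0 + 0.5 * (sq_matrix @ var + residual**2)
        alpha_f = np.full(k, h.alpha_f0 + 0.5)
        beta_f = h.beta_f0 + 0.5 * (f**2 + var)
        v_eps_inv = alpha_eps / beta_eps
        v_f_inv = alpha_f / beta_f
        trace.append(float(np.linalg.norm(f - f_old)))
        if stop.fired(f, f_old):
            converged = True
            break
    return VBAPosteriorFull(
        f_mean=PCVector(f.copy(), d.period_grid, basis=d.basis),
        var=var.copy(),
        alpha_eps=alpha_eps,
        beta_eps=beta_eps,
        alpha_f=alpha_f,
        beta_f=beta_f,
        iteration=it,
        converged=converged,
        trace=trace,
    )
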