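"""Shared pieces of the hierarchical model.

The noise and the PC coefficients are modelled as Gaussians whose variances
are themselves unknown, with conjugate inverse-gamma priors — an infinite
Gaussian scale mixture whose marginal is a Student's t, heavy-tailed and
sparsity enforcing.  Four positive constants parameterise the hierarchy;
taking them all close to zero (0.001) gives the non-informative prior law
(NIPL) used throughout, so the variances are driven by the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IGHyperparameters", "StoppingRule", "solve_weighted_normal"]


@dataclass(frozen=True)
class IGHyperparameters:
    """Inverse-gamma shape/scale constants of the noise and signal hierarchies."""

    alpha_eps0: float = 0.001
    beta_eps0: float = 0.001
    alpha_f0: float = 0.001
    beta_f0: float = 0.001

    def __post_init__(self) -> None:
        for name in ("alpha_eps0", "beta_eps0", "alpha_f0", "beta_f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class StoppingRule:
    """Stop when the relative change of f falls below ``rel_tol``.

    ``max_iter`` caps the number of sweeps; hitting it sets a non-converged
    flag on the returned state rather than raising.
    """

    rel_tol: float = 1e-6
    max_iter: int = 200

    def fired(self, f_new: np.ndarray, f_old: np.ndarray) -> bool:
        denom = np.linalg.norm(f_old)
        if denom == 0.0:
            return bool(np.linalg.norm(f_new) == 0.0)
        return bool(np.linalg.norm(f_new - f_old) / denom < self.rel_tol)


def solve_weighted_normal(
    H: np.ndarray, g: np.ndarray, noise_precision: np.ndarray, coef_precision: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve [H' W H + D] x = H' W g for diagonal W, D > 0.

    Returns the solution and the (symmetric positive definite) normal matrix.
    Uses a Cholesky solve; never forms an explicit inverse.
    """
    A = (H.T * noise_precision) @ H
    A[np.diag_indices_from(A)] += coef_precision
    b = H.T @ (noise_precision * g)
    try:
        c = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise np.linalg.LinAlgError("normal matrix is not positive definite") from exc
    return np.linalg.solve(c.T, np.linalg.solve(c, b)), A
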