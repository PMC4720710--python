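"""Comparison methods: FFT periodogram analytics and Gaussian-prior estimators.

For a record of length T hours the discrete Fourier transform only
represents periods T/k, so a 96-h record has no grid point between 19.2 and
32 h apart from 24 h: any circadian component between those values is
attributed to 24 h.  The helpers here quantify that resolution limit.

The Gaussian-prior estimators tie all PC coefficients to a single shared
variance (a stationary, non-sparsity-enforcing prior).  With fixed
variances both reduce to ridge/Tikhonov solutions; letting the shared
variance adapt pools information across all coefficients, so no coefficient
can be shrunk selectively and the estimated spectra stay dense.
"""

from __future__ import annotations

from math import gcd

import numpy as np
from numpy.typing import NDArray

from .dictionary import Dictionary, PCVector
from .model import IGHyperparameters, StoppingRule, solve_weighted_normal
from .jmap import JMAPState, jmap_criterion, jmap_update_noise_variance
from .vba import VBAPosteriorPartial, vba_partial_update_f, vba_partial_update_noise

__all__ = [
    "fft_period_spectrum",
    "fft_neighbor_periods",
    "minimal_record_length",
    "gaussian_jmap",
    "gaussian_pm",
    "dominant_period",
]


def fft_period_spectrum(
    signal: NDArray[np.float64], step: float
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Single-sided amplitude spectrum against the representable periods.

    Amplitudes are normalised as 2|G_k|/N so an on-grid unit cosine has
    amplitude 1.  Periods are N*step/k for k = 1..floor(N/2), returned in
    increasing period order.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 4:
        raise ValueError("need at least 4 samples for a periodogram")
    spectrum = np.fft.rfft(signal)
    k = np.arange(1, n // 2 + 1)
    amplitudes = 2.0 * np.abs(spectrum[k]) / n
    periods = n * step / k
    order = np.argsort(periods)
    return periods[order], amplitudes[order]


def fft_neighbor_periods(target: float, record_hours: float) -> tuple[float, float]:
    """The representable periods adjacent to ``target`` on a record's FFT grid."""
    k = record_hours / target
    if not np.isclose(k, round(k)):
        raise ValueError(
            f"{target} h is not on the FFT grid of a {record_hours}-h record"
        )
    k = int(round(k))
    if k < 1:
        raise ValueError("target period exceeds the record length")
    below = record_hours / (k + 1)
    above = record_hours / (k - 1) if k > 1 else float("inf")
    return below, above


def minimal_record_length(periods: set[int] | list[int] | tuple[int, ...]) -> int:
    """Shortest record (hours) on whose FFT grid every given period lies.

    This is the least common multiple of the periods; only integer periods
    are supported (a documented limitation).  Resolving {23, 24, 25} h
    requires 13800 h, i.e. 575 days of recording.
    """
    values = sorted(set(periods))
    if not values:
        raise ValueError("need at least one period")
    if any((not float(p).is_integer()) or p <= 0 for p in values):
        raise ValueError("periods must be positive integers")
    out = 1
    for p in values:
        p = int(p)
        out = out * p // gcd(out, p)
    return out


def _tied_prior_start(d: Dictionary) -> tuple[NDArray[np.float64], float]:
    n, k = d.matrix.shape
    return np.ones(n), 1.0


def gaussian_jmap(
    g: NDArray[np.float64],
    d: Dictionary,
    h: IGHyperparameters | None = None,
    stop: StoppingRule | None = None,
) -> JMAPState:
    """Joint MAP with a stationary Gaussian prior (one shared v_f).

    The shared variance maximises its conditional density given all
    coefficients jointly: v_f = (beta_f0 + sum_j f_j^2 / 2)/(alpha_f0 + 1 + K/2).
    Noise variances are per-sample, as in the sparsity-enforcing model.
    """
    h = h or IGHyperparameters()
    stop = stop or StoppingRule()
    g = np.asarray(g, dtype=float)
    n, k = d.matrix.shape
    v_eps, v_f = _tied_prior_start(d)
    f_old = np.zeros(k)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, stop.max_iter + 1):
        coef, _ = solve_weighted_normal(d.matrix, g, 1.0 / v_eps, np.full(k, 1.0 / v_f))
        f = PCVector(coef, d.period_grid, basis=d.basis)
        v_eps = jmap_update_noise_variance(g, d, f, h)
        v_f = float((h.beta_f0 + 0.5 * np.sum(coef**2)) / (h.alpha_f0 + 1.0 + k / 2.0))
        trace.append(jmap_criterion(g, d, f, v_eps, np.full(k, v_f), h))
        if stop.fired(coef, f_old):
            converged = True
            break
        f_old = coef
    return JMAPState(
        f=f,
        v_eps=v_eps,
        v_f=np.full(k, v_f),
        criterion=trace[-1],
        iteration=it,
        converged=converged,
        trace=trace,
    )


def gaussian_pm(
    g: NDArray[np.float64],
    d: Dictionary,
    h: IGHyperparameters | None = None,
    stop: StoppingRule | None = None,
) -> VBAPosteriorPartial:
    """Posterior mean via VBA with one shared signal variance.

    The pooled inverse-gamma factor has shape alpha_f0 + K/2 and scale
    beta_f0 + sum_j (f_j^2 + Sigma_jj)/2; its expected precision is shared
    by every coefficient.
    """
    h = h or IGHyperparameters()
    stop = stop or StoppingRule()
    g = np.asarray(g, dtype=float)
    n, k = d.matrix.shape
    v_eps_inv = np.full(n, h.alpha_eps0 / h.beta_eps0)
    v_f_inv = h.alpha_f0 / h.beta_f0
    f_old = np.zeros(k)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, stop.max_iter + 1):
        f_mean, sigma = vba_partial_update_f(d, g, v_eps_inv, np.full(k, v_f_inv))
        alpha_eps, beta_eps = vba_partial_update_noise(g, d, f_mean, sigma, h)
        v_eps_inv = alpha_eps / beta_eps
        alpha_f = h.alpha_f0 + k / 2.0
        beta_f = h.beta_f0 + 0.5 * float(np.sum(f_mean**2) + np.trace(sigma))
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
        alpha_f=np.full(k, alpha_f),
        beta_f=np.full(k, beta_f),
        iteration=it,
        converged=converged,
        trace=trace,
    )


def dominant_period(
    periods: NDArray[np.float64],
    amplitudes: NDArray[np.float64],
    band: tuple[float, float] = (8.0, 32.0),
) -> float:
    """Period of maximal amplitude within the band; ties go to the smaller period."""
    periods = np.asarray(periods, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    mask = (periods >= band[0]) & (periods <= band[1])
    if not np.any(mask):
        raise ValueError(f"no grid period inside the band {band}")
    in_periods = periods[mask]
    in_amp = amplitudes[mask]
    order = np.argsort(in_periods)  # ascending, so argmax returns the smaller tie
    in_periods, in_amp = in_periods[order], in_amp[order]
    return float(in_periods[np.argmax(in_amp)])
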