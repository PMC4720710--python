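"""Result assembly and file round-trips for reproducible runs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .dictionary import Dictionary, amplitude_spectrum
from .model import IGHyperparameters, StoppingRule
from .jmap import run_jmap
from .vba import run_vba_full, run_vba_partial
from .baselines import dominant_period, fft_period_spectrum, gaussian_jmap, gaussian_pm
from .pipeline import l2_relative_error

__all__ = ["estimate", "write_result", "read_result", "METHODS"]

METHODS = ("jmap", "vba-partial", "vba-full", "gauss-jmap", "gauss-pm", "fft")


def estimate(
    g: np.ndarray,
    d: Dictionary,
    method: str,
    h: IGHyperparameters | None = None,
    stop: StoppingRule | None = None,
    g0: np.ndarray | None = None,
    f_true: np.ndarray | None = None,
) -> dict[str, Any]:
    """Run one estimator and assemble a JSON-serialisable result record.

    When the truth is supplied the record carries the relative errors
    delta_f (PC vector), delta_g0 (noiseless signal) and delta_g (data).
    """
    g = np.asarray(g, dtype=float)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "fft":
        periods, amps = fft_period_spectrum(g, d.time_grid.step)
        result: dict[str, Any] = {
            "method": method,
            "periods": periods.tolist(),
            "amplitudes": amps.tolist(),
            "dominant_period": dominant_period(periods, amps),
        }
        return result

    runners = {
        "jmap": run_jmap,
        "vba-partial": run_vba_partial,
        "vba-full": run_vba_full,
        "gauss-jmap": gaussian_jmap,
        "gauss-pm": gaussian_pm,
    }
    state = runners[method](g, d, h, stop)
    f_hat = state.f if hasattr(state, "f") else state.f_mean
    spectrum = amplitude_spectrum(f_hat)
    g_hat = d.matrix @ f_hat.coefficients
    result = {
        "method": method,
        "periods": d.period_grid.periods.tolist(),
        "basis": d.basis,
        "coefficients": f_hat.coefficients.tolist(),
        "amplitudes": spectrum.tolist(),
        "dominant_period": dominant_period(d.period_grid.periods, spectrum),
        "iterations": state.iteration,
        "converged": state.converged,
        "delta_g": l2_relative_error(g, g_hat),
    }
    if hasattr(state, "sigma"):
        result["posterior_variance"] = np.diag(state.sigma).tolist()
    elif hasattr(state, "var"):
        result["posterior_variance"] = np.asarray(state.var).tolist()
    if g0 is not None:
        result["delta_g0"] = l2_relative_error(np.asarray(g0, float), g_hat)
    if f_true is not None:
        result["delta_f"] = l2_relative_error(np.asarray(f_true, float), f_hat.coefficients)
    return result


def write_result(result: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(result, indent=2))


def read_result(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def read_series(path: str | Path, value_column: str = "value") -> pd.DataFrame:
    """Read a (time_hours, value) CSV time series."""
    frame = pd.read_csv(path)
    if "time_hours" not in frame.columns:
        raise ValueError("series CSV must have a 'time_hours' column")
    if value_column not in frame.columns:
        raise ValueError(f"series CSV must have a {value_column!r} column")
    return frame
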