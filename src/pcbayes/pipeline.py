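"""Metrics, preprocessing of real recordings and moving-window stability scans.

Chronobiological recordings (for example minute-sampled locomotor activity)
are aggregated to hourly samples, zero-meaned and normalised to [-10, 10]
before estimation.  To probe whether the dominant circadian period is stable
over the course of an experiment, the hourly series is cut into 4-day
windows shifted by one day and the chosen estimator is run on each window;
the per-window amplitude spectra stacked into a matrix make drift of the
dominant period directly visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .dictionary import Dictionary, amplitude_spectrum
from .model import IGHyperparameters, StoppingRule
from .jmap import run_jmap
from .vba import run_vba_full, run_vba_partial
from .baselines import dominant_period, fft_period_spectrum, gaussian_jmap, gaussian_pm

__all__ = [
    "l2_relative_error",
    "preprocess",
    "moving_windows",
    "stability_scan",
    "WindowSet",
    "StabilityMatrix",
    "ESTIMATORS",
]

HOURS_PER_DAY = 24
WINDOW_DAYS = 4


@dataclass(frozen=True)
class WindowSet:
    """4-day windows cut from an hourly series, shifted day by day."""

    windows: tuple[tuple[int, NDArray[np.float64]], ...]  # (start day, 96 samples)
    source_length_days: int


@dataclass(frozen=True)
class StabilityMatrix:
    """Per-window amplitude spectra plus the in-band dominant periods.

    ``amplitudes[w, j]`` is the estimated amplitude of period ``periods[j]``
    in window ``w``; failed windows carry NaN rows and a NaN dominant period.
    """

    periods: NDArray[np.float64]
    amplitudes: NDArray[np.float64]
    dominant: NDArray[np.float64]
    method: str

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.amplitudes, columns=[f"{p:g}h" for p in self.periods]
        )
        frame.insert(0, "dominant_period", self.dominant)
        return frame


def l2_relative_error(x: NDArray[np.float64], x_hat: NDArray[np.float64]) -> float:
    """Squared-norm relative error ||x - x_hat||^2 / ||x||^2."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("vectors must have equal length")
    denom = float(np.sum(x**2))
    if denom == 0.0:
        raise ValueError("relative error is undefined for a zero reference")
    return float(np.sum((x - x_hat) ** 2) / denom)


def preprocess(
    values: NDArray[np.float64], step_hours: float, aggregate: str = "mean"
) -> NDArray[np.float64]:
    """Hourly, zero-mean series normalised so max |value| = 10.

    ``step_hours`` must divide one hour (e.g. 1/60 for minute sampling) or
    equal it.  Sub-hourly samples are aggregated per hour by mean (default)
    or sum.  A constant input becomes all zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    per_hour = 1.0 / step_hours
    if not np.isclose(per_hour, round(per_hour)) or per_hour < 1:
        raise ValueError("sampling step must divide 1 h (or equal it)")
    per_hour = int(round(per_hour))
    n_hours = values.size // per_hour
    if n_hours == 0:
        raise ValueError("series shorter than one hour")
    trimmed = values[: n_hours * per_hour].reshape(n_hours, per_hour)
    hourly = trimmed.mean(axis=1) if aggregate == "mean" else trimmed.sum(axis=1)
    hourly = hourly - hourly.mean()
    peak = np.max(np.abs(hourly))
    if peak > 0:
        hourly = hourly * (10.0 / peak)
    return hourly


def moving_windows(
    series: NDArray[np.float64], window_days: int = WINDOW_DAYS, shift_days: int = 1
) -> WindowSet:
    """Cut ``window_days``-long windows shifted by ``shift_days`` from an hourly series."""
    series = np.asarray(series, dtype=float)
    window_len = window_days * HOURS_PER_DAY
    if series.size < window_len:
        raise ValueError(
            f"series has {series.size} hourly samples; at least {window_len} required"
        )
    days = series.size // HOURS_PER_DAY
    starts = range(0, days - window_days + 1, shift_days)
    windows = tuple(
        (start, series[start * HOURS_PER_DAY : start * HOURS_PER_DAY + window_len])
        for start in starts
    )
    return WindowSet(windows=windows, source_length_days=days)


def _spectrum_jmap(seg, d, h, stop):
    return amplitude_spectrum(run_jmap(seg, d, h, stop).f)


def _spectrum_vba_partial(seg, d, h, stop):
    return amplitude_spectrum(run_vba_partial(seg, d, h, stop).f_mean)


def _spectrum_vba_full(seg, d, h, stop):
    return amplitude_spectrum(run_vba_full(seg, d, h, stop).f_mean)


def _spectrum_gauss_jmap(seg, d, h, stop):
    return amplitude_spectrum(gaussian_jmap(seg, d, h, stop).f)


def _spectrum_gauss_pm(seg, d, h, stop):
    return amplitude_spectrum(gaussian_pm(seg, d, h, stop).f_mean)


ESTIMATORS: dict[str, Callable] = {
    "jmap": _spectrum_jmap,
    "vba-partial": _spectrum_vba_partial,
    "vba-full": _spectrum_vba_full,
    "gauss-jmap": _spectrum_gauss_jmap,
    "gauss-pm": _spectrum_gauss_pm,
}


def stability_scan(
    ws: WindowSet,
    method: str,
    d: Dictionary | None = None,
    h: IGHyperparameters | None = None,
    stop: StoppingRule | None = None,
    band: tuple[float, float] = (8.0, 32.0),
) -> StabilityMatrix:
    """Run one estimator per window and collect spectra and dominant periods.

    ``method`` is one of the model-based estimators or ``"fft"``.  A window
    on which the estimator fails (e.g. an all-zero segment) is recorded as a
    NaN row and the scan continues.
    """
    from .dictionary import PeriodGrid, TimeGrid, build_dictionary

    if method != "fft" and method not in ESTIMATORS:
        raise ValueError(f"unknown method {method!r}")
    window_len = len(ws.windows[0][1])
    if method == "fft":
        ref_periods, _ = fft_period_spectrum(np.zeros(window_len), 1.0)
        in_band = (ref_periods >= band[0]) & (ref_periods <= band[1])
        periods = ref_periods[in_band]
    else:
        if d is None:
            # split cos/sin basis: recordings carry unknown component phases
            d = build_dictionary(
                TimeGrid.hourly(window_len), PeriodGrid.circadian(), basis="split"
            )
        periods = d.period_grid.periods

    rows = []
    dominants = []
    for _, segment in ws.windows:
        try:
            if method == "fft":
                grid, amps = fft_period_spectrum(segment, 1.0)
                amps = amps[in_band]
            else:
                if not np.any(segment):
                    raise ValueError("all-zero window")
                amps = ESTIMATORS[method](segment, d, h, stop)
            rows.append(amps)
            dominants.append(dominant_period(periods, amps, band))
        except (ValueError, np.linalg.LinAlgError):
            rows.append(np.full(periods.size, np.nan))
            dominants.append(np.nan)
    return StabilityMatrix(
        periods=periods,
        amplitudes=np.vstack(rows),
        dominant=np.asarray(dominants, dtype=float),
        method=method,
    )
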