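"""Forward model for periodic-component estimation.

A uniformly sampled signal ``g`` of length ``N`` is modelled as a linear
combination of sinusoids whose periods live on a fixed grid (the *circadian
domain*, 8-32 h by default).  The design matrix ``H`` linking the
periodic-component (PC) coefficient vector ``f`` to the signal,
``g = H f + noise``, comes in two conventions:

``basis="summed"``
    One column per period with entries ``cos(2*pi*t/p) + sin(2*pi*t/p)``.
    Every component then has a fixed phase (pi/4) and the PC vector has one
    signed coefficient per period.  On the default 4-day hourly grid this
    96x25 matrix has a 2-norm condition number of about 5.68e10.

``basis="split"``
    Separate cosine and sine blocks, ``N x 2M``, so each period carries a
    free amplitude *and* phase.  Amplitudes are recovered by the Euclidean
    pairing ``sqrt(a_j^2 + b_j^2)``.

Columns are deliberately not normalised: the conditioning of the raw
construction is itself a quantity of interest for this ill-posed problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "TimeGrid",
    "PeriodGrid",
    "Dictionary",
    "PCVector",
    "build_dictionary",
    "condition_number",
    "synthesize_signal",
    "amplitude_spectrum",
]

_SPACING_TOL = 1e-9


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling instants, in hours."""

    times: NDArray[np.float64]
    step: float
    n_samples: int = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("time grid needs at least two samples")
        deltas = np.diff(times)
        if np.any(deltas <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.max(np.abs(deltas - self.step)) >= _SPACING_TOL:
            raise ValueError("sampling is not uniform at the declared step")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "n_samples", times.size)

    @classmethod
    def hourly(cls, n_hours: int, start: float = 0.0) -> "TimeGrid":
        return cls(times=start + np.arange(n_hours, dtype=float), step=1.0)


@dataclass(frozen=True)
class PeriodGrid:
    """Candidate periods, in hours, strictly increasing."""

    periods: NDArray[np.float64]
    m_periods: int = field(init=False)

    def __post_init__(self) -> None:
        periods = np.asarray(self.periods, dtype=float)
        if periods.ndim != 1 or periods.size == 0:
            raise ValueError("period grid must be a non-empty 1-d array")
        if np.any(periods <= 0):
            raise ValueError("all periods must be positive")
        if np.any(np.diff(periods) <= 0):
            raise ValueError("periods must be strictly increasing (no duplicates)")
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "m_periods", periods.size)

    @classmethod
    def circadian(cls, low: int = 8, high: int = 32, step: int = 1) -> "PeriodGrid":
        """Integer periods across the circadian domain, default 8..32 h."""
        return cls(periods=np.arange(low, high + 1, step, dtype=float))

    def index_of(self, period: float) -> int:
        idx = np.flatnonzero(np.isclose(self.periods, period))
        if idx.size == 0:
            raise ValueError(f"period {period} h is not on the grid")
        return int(idx[0])


@dataclass(frozen=True)
class Dictionary:
    """Design matrix H together with the grids that generated it."""

    matrix: NDArray[np.float64]
    time_grid: TimeGrid
    period_grid: PeriodGrid
    basis: str = "summed"

    @property
    def n_coefficients(self) -> int:
        return self.matrix.shape[1]

    def to_json(self, path: str | Path) -> None:
        """Self-describing export: grids in the header, matrix as a list."""
        payload = {
            "basis": self.basis,
            "times": self.time_grid.times.tolist(),
            "step": self.time_grid.step,
            "periods": self.period_grid.periods.tolist(),
            "matrix": self.matrix.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Dictionary":
        payload = json.loads(Path(path).read_text())
        return cls(
            matrix=np.asarray(payload["matrix"], dtype=float),
            time_grid=TimeGrid(np.asarray(payload["times"]), payload["step"]),
            period_grid=PeriodGrid(np.asarray(payload["periods"])),
            basis=payload["basis"],
        )


@dataclass(frozen=True)
class PCVector:
    """Periodic-component coefficient vector on a period grid.

    ``basis="summed"`` stores one signed coefficient per period (length M);
    ``basis="split"`` stores the cosine block followed by the sine block
    (length 2M).
    """

    coefficients: NDArray[np.float64]
    period_grid: PeriodGrid
    basis: str = "summed"

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        expected = self.period_grid.m_periods * (2 if self.basis == "split" else 1)
        if coef.size != expected:
            raise ValueError(
                f"coefficient vector has length {coef.size}, "
                f"expected {expected} for basis={self.basis!r}"
            )
        object.__setattr__(self, "coefficients", coef)


def build_dictionary(
    time_grid: TimeGrid, period_grid: PeriodGrid, basis: str = "summed"
) -> Dictionary:
    """Build the forward operator H on the given grids.

    Parameters
    ----------
    basis:
        ``"summed"`` for one cos+sin column per period (N x M),
        ``"split"`` for separate cosine and sine blocks (N x 2M).
    """
    if basis not in ("summed", "split"):
        raise ValueError(f"unknown basis {basis!r}")
    phase = 2.0 * np.pi * time_grid.times[:, None] / period_grid.periods[None, :]
    cos, sin = np.cos(phase), np.sin(phase)
    matrix = cos + sin if basis == "summed" else np.hstack([cos, sin])
    return Dictionary(matrix=matrix, time_grid=time_grid, period_grid=period_grid, basis=basis)


def condition_number(d: Dictionary) -> float:
    """2-norm condition number (ratio of extreme singular values) of H."""
    if d.matrix.size == 0:
        raise ValueError("empty dictionary matrix")
    s = np.linalg.svd(d.matrix, compute_uv=False)
    if s[0] == 0.0:
        raise np.linalg.LinAlgError("all-zero dictionary matrix is degenerate")
    return float(s[0] / s[-1])


def synthesize_signal(d: Dictionary, f: PCVector | ArrayLike) -> NDArray[np.float64]:
    """Noiseless signal H @ f."""
    coef = f.coefficients if isinstance(f, PCVector) else np.asarray(f, dtype=float)
    if isinstance(f, PCVector) and f.basis != d.basis:
        raise ValueError(f"PC vector basis {f.basis!r} does not match dictionary {d.basis!r}")
    if coef.size != d.n_coefficients:
        raise ValueError(
            f"coefficient vector length {coef.size} does not match "
            f"dictionary with {d.n_coefficients} columns"
        )
    return d.matrix @ coef


def amplitude_spectrum(f: PCVector) -> NDArray[np.float64]:
    """One non-negative amplitude per period.

    For the split basis this is the Euclidean pairing sqrt(a^2 + b^2) of the
    cosine/sine coefficients; for the summed basis it is |f_j|, the absolute
    PC coefficient (the per-component waveform is then
    f_j*sqrt(2)*cos(2*pi*t/p_j - pi/4)).
    """
    m = f.period_grid.m_periods
    if f.basis == "split":
        a, b = f.coefficients[:m], f.coefficients[m:]
        return np.hypot(a, b)
    return np.abs(f.coefficients)
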