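"""Noncompartmental analysis (NCA) of cycle-1 blood activity concentrations.

Cmax/Tmax are read off the observed maxima.  The terminal rate lambda_z is a
log-linear regression over a contiguous tail of at least three post-peak
points, choosing the tail that maximizes adjusted R^2 (a conventional,
deterministic selection rule).  Pre-dose and immediately-post-infusion
samples never enter the terminal fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    NoTerminalPhaseError,
)
from .nuclide import LN2

__all__ = [
    "ConcentrationMeasurement",
    "NCAResult",
    "nca",
    "geometric_summary",
    "percent_decline",
]

#: samples earlier than this (pre-dose, "1 min") are excluded from lambda_z
_EARLY_CUTOFF_H = 0.05


@dataclass(frozen=True)
class ConcentrationMeasurement:
    patient_id: str
    time_h: float
    conc: float
    below_limit_flag: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise InvalidInputError(f"time must be finite and >= 0, got {self.time_h}")
        if not math.isfinite(self.conc) or self.conc < 0:
            raise InvalidInputError(f"concentration must be finite and >= 0, got {self.conc}")


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax_h: float
    lambda_z_per_h: float
    t_half_h: float
    n_terminal_points: int
    r_squared: float


def nca(curve: Sequence[ConcentrationMeasurement]) -> NCAResult:
    """Cmax, Tmax, terminal rate and half-life from one concentration curve."""
    if not curve:
        raise InsufficientDataError("empty concentration curve")
    pts = sorted(curve, key=lambda m: m.time_h)
    times = np.array([m.time_h for m in pts])
    if np.unique(times).size != times.size:
        raise InvalidInputError("duplicate sampling times for one patient")
    concs = np.array([m.conc for m in pts])
    if not np.any(concs > 0):
        raise InsufficientDataError("no positive concentrations")
    imax = int(np.argmax(concs))
    cmax, tmax = float(concs[imax]), float(times[imax])

    usable = [
        (m.time_h, m.conc)
        for m in pts
        if m.time_h > tmax and m.time_h > _EARLY_CUTOFF_H and m.conc > 0 and not m.below_limit_flag
    ]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable terminal points after Tmax, got {len(usable)}"
        )
    t = np.array([u[0] for u in usable])
    logc = np.log([u[1] for u in usable])

    best = None  # (adj_r2, n_points, slope, r2)
    for L in range(3, t.size + 1):
        tt, yy = t[-L:], logc[-L:]
        fit = sps.linregress(tt, yy)
        if fit.slope >= 0:
            continue
        r2 = float(fit.rvalue**2)
        adj = 1.0 - (1.0 - r2) * (L - 1) / (L - 2)
        # tie-break toward the longer tail
        if best is None or (adj, L) > (best[0], best[1]):
            best = (adj, L, float(fit.slope), r2)
    if best is None:
        raise NoTerminalPhaseError("no decreasing terminal phase found")
    _, n_term, slope, r2 = best
    lam_z = -slope
    return NCAResult(
        cmax=cmax,
        tmax_h=tmax,
        lambda_z_per_h=lam_z,
        t_half_h=LN2 / lam_z,
        n_terminal_points=n_term,
        r_squared=min(max(r2, 0.0), 1.0),
    )


def geometric_summary(values: Sequence[float]) -> tuple[float, float]:
    """(geometric mean, geometric CV in percent) of positive values.

    geo CV% = 100 * sqrt(exp(s^2) - 1), s the sample SD of the logs.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 values for a geometric summary")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise InvalidInputError("all values must be finite and > 0")
    logs = np.log(v)
    s = float(np.std(logs, ddof=1))
    return float(np.exp(np.mean(logs))), 100.0 * math.sqrt(math.expm1(s * s))


def percent_decline(reference_value: float, later_value: float) -> float:
    """100 * (reference - later) / reference."""
    if reference_value <= 0:
        raise InvalidInputError(f"reference value must be > 0, got {reference_value}")
    if later_value < 0:
        raise InvalidInputError("later value must be >= 0")
    return 100.0 * (reference_value - later_value) / reference_value
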