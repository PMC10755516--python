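"""Cohort aggregation and predicted-vs-observed statistics.

Cumulative doses over the treatment course are *predicted* by linear
extrapolation of the cycle-1 dose per unit activity (d1 * planned total
activity) and *observed* by summing the per-cycle doses actually derived
from measurements.  The cohort comparison across the at-risk organs uses a
paired one-sample Hotelling T^2 on the per-patient difference vectors, with
Bonferroni adjustment over the family of cycle-level comparisons.
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
    RankDeficiencyError,
    SingularCovarianceError,
    UndefinedRatioError,
)

__all__ = [
    "CumulativeDoseRecord",
    "CohortSummary",
    "HotellingResult",
    "predict_cumulative",
    "observed_cumulative",
    "relative_difference",
    "summarize",
    "hotelling_paired",
    "bonferroni",
]


@dataclass(frozen=True)
class CumulativeDoseRecord:
    """Predicted and (when complete) observed cumulative dose for one organ."""

    patient_id: str
    organ: str
    d1_Gy_per_GBq: float
    predicted_Gy: float
    n_cycles_completed: int
    observed_Gy: float | None = None


@dataclass(frozen=True)
class CohortSummary:
    """mean (min-max), SD summary of one cohort column."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    degenerate: bool = False  # single value: SD reported as 0

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
        }


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_raw: float
    p_adjusted: float
    organs: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "t2": self.t2,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "organs": list(self.organs),
        }


def predict_cumulative(d1_Gy_per_GBq: float, planned_total_GBq: float = 44.4) -> float:
    """Extrapolated cumulative dose: cycle-1 dose per unit activity times the
    planned total administered activity."""
    if d1_Gy_per_GBq < 0 or planned_total_GBq < 0:
        raise InvalidInputError("inputs must be >= 0")
    return d1_Gy_per_GBq * planned_total_GBq


def observed_cumulative(cycle_doses_Gy: Sequence[float]) -> float:
    """Sum of per-cycle absorbed doses actually derived from measurements."""
    if len(cycle_doses_Gy) == 0:
        raise InsufficientDataError("no per-cycle doses supplied")
    if any(d < 0 for d in cycle_doses_Gy):
        raise InvalidInputError("per-cycle doses must be >= 0")
    return float(sum(cycle_doses_Gy))


def relative_difference(predicted_mean: float, observed_mean: float) -> float:
    """Signed percent difference 100 * (predicted - observed) / observed."""
    if observed_mean <= 0:
        raise UndefinedRatioError(f"observed mean must be > 0, got {observed_mean}")
    return 100.0 * (predicted_mean - observed_mean) / observed_mean


def summarize(values: Sequence[float]) -> CohortSummary:
    """n, mean, sample SD (n-1), min, max of a cohort column."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("cannot summarize an empty list")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("values must be finite")
    degenerate = v.size == 1
    sd = 0.0 if degenerate else float(np.std(v, ddof=1))
    return CohortSummary(
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=sd,
        min=float(np.min(v)),
        max=float(np.max(v)),
        degenerate=degenerate,
    )


def hotelling_paired(
    predicted: np.ndarray,
    observed: np.ndarray,
    m_comparisons: int = 1,
    organs: Sequence[str] = (),
) -> HotellingResult:
    """Paired one-sample Hotelling T^2 on predicted - observed.

    T^2 = n * dbar' Sigma^-1 dbar with Sigma the sample covariance of the
    difference vectors; F = T^2 (n - p) / (p (n - 1)) ~ F(p, n - p) under
    the null of zero mean difference.  When the mean difference is exactly
    zero the statistic is zero and p = 1 regardless of the covariance.
    """
    P = np.atleast_2d(np.asarray(predicted, dtype=float))
    O = np.atleast_2d(np.asarray(observed, dtype=float))
    if P.ndim == 2 and P.shape[1] != O.shape[1] or P.shape[0] != O.shape[0]:
        raise InvalidInputError("predicted and observed must have the same shape")
    d = P - O
    n, p = d.shape
    if n <= p:
        raise RankDeficiencyError(f"need n > p, got n={n}, p={p}")
    if m_comparisons < 1:
        raise InvalidInputError("m_comparisons must be >= 1")
    dbar = d.mean(axis=0)
    # differences at floating-point precision of the data scale are zero:
    # feeding them to the quadratic form would test numerical round-off
    data_scale = max(float(np.max(np.abs(P))), float(np.max(np.abs(O))), 1e-300)
    if np.all(np.abs(dbar) <= 1e-9 * data_scale):
        t2 = 0.0
    else:
        cov = np.cov(d, rowvar=False, ddof=1).reshape(p, p)
        try:
            sol = np.linalg.solve(cov, dbar)
        except np.linalg.LinAlgError:
            raise SingularCovarianceError(
                "singular covariance of differences; consider a smaller organ subset"
            )
        if not np.all(np.isfinite(sol)) or np.linalg.cond(cov) > 1e14:
            raise SingularCovarianceError(
                "near-singular covariance of differences; consider a smaller organ subset"
            )
        t2 = float(n * dbar @ sol)
    f_stat = t2 * (n - p) / (p * (n - 1))
    p_raw = 1.0 if t2 == 0.0 else float(sps.f.sf(f_stat, p, n - p))
    return HotellingResult(
        t2=t2,
        f_stat=f_stat,
        df1=p,
        df2=n - p,
        p_raw=p_raw,
        p_adjusted=bonferroni(p_raw, m_comparisons),
        organs=tuple(organs),
    )


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p_raw)."""
    if not (0.0 <= p_raw <= 1.0) or not math.isfinite(p_raw):
        raise InvalidInputError(f"p-value out of [0, 1]: {p_raw}")
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    return min(1.0, m * p_raw)
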