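"""Organ time-activity curve (TAC) fitting and time-integrated activity (TIA).

Cycle-1 organ activities are measured at a handful of imaging times
(typically 2, 24, 48 and 168 h after administration).  Each region is fitted
with a sum of exponentials A(t) = sum_i a_i * exp(-r_i * t); the fit supplies

* the analytic time-integrated activity  TIA = sum_i a_i / r_i  (MBq*h),
* the fitted activity at arbitrary times (used to scale later cycles from a
  single measurement), and
* the effective half-life ln2 / r_terminal.

Fitting minimizes *relative* residuals, because organ activities span orders
of magnitude and quantification noise is multiplicative.  The terminal rate
is clamped to be no smaller than the physical decay constant: biological
clearance cannot make an effective half-life longer than the physical one.

Model policy: mono-exponential with fewer than 4 distinct points.  With
exactly 4 points the biexponential (4 parameters, possibly with one
negative amplitude describing an uptake phase) is *saturated* - it
interpolates any 4 points, so residual-based criteria cannot discriminate
and would systematically prefer it on pure noise; selection is therefore
structural at that design: the biexponential is chosen only when the data
are peak-shaped (an initial rise to a maximum followed by monotone decline,
the uptake-washout pattern that a mono-exponential cannot represent).  With
5 or more points the models compete under corrected AIC on the relative
residuals (plain AIC when the small-sample correction is undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidActivityError,
    InvalidFitError,
    InvalidInputError,
    MissingInputError,
)
from .nuclide import LN2, NuclideData

__all__ = [
    "ActivityMeasurement",
    "TACFit",
    "ModelPolicy",
    "fit_tac",
    "fit_tac_arrays",
    "tia",
    "normalized_disintegrations",
    "effective_half_life",
]


@dataclass(frozen=True)
class ActivityMeasurement:
    """One quantified activity at one time point.

    ``unit`` is ``"MBq"`` for imaging regions and ``"MBq_per_mL"`` for blood
    activity concentrations; the numeric pipeline is agnostic to which, it
    only matters for bookkeeping and validation.
    """

    patient_id: str
    cycle: int
    region: str
    time_h: float
    value: float
    unit: str = "MBq"

    def __post_init__(self) -> None:
        if not (1 <= int(self.cycle) <= 6):
            raise InvalidInputError(f"cycle must be 1-6, got {self.cycle}")
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise InvalidInputError(f"time_h must be finite and >= 0, got {self.time_h}")
        if not math.isfinite(self.value) or self.value < 0:
            raise InvalidInputError(f"activity must be finite and >= 0, got {self.value}")
        if self.unit not in ("MBq", "MBq_per_mL"):
            raise InvalidInputError(f"unknown unit {self.unit!r}")


@dataclass(frozen=True)
class TACFit:
    """Fitted sum-of-exponentials time-activity model for one region.

    ``terms`` is a sequence of (amplitude, rate) pairs with all rates > 0;
    the smallest rate is the terminal rate.  ``fit_quality`` is the sum of
    squared relative residuals at the fitted points.
    """

    region: str
    model: Literal["mono", "biexp"]
    terms: tuple[tuple[float, float], ...]
    fit_quality: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.terms:
            raise InvalidFitError("fit has no terms")
        if any(r <= 0 or not math.isfinite(r) for _, r in self.terms):
            raise InvalidFitError("all rates must be positive and finite")
        if not any(a > 0 for a, _ in self.terms):
            raise InvalidFitError("at least one amplitude must be positive")

    @property
    def terminal_rate(self) -> float:
        return min(r for _, r in self.terms)

    def predict(self, t):
        """Fitted activity A(t) = sum a_i exp(-r_i t)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for a, r in self.terms:
            out = out + a * np.exp(-r * t)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelPolicy:
    """Controls model selection and the biexponential search.

    ``biexp_min_points``: minimum number of distinct time points before a
    biexponential is attempted.  ``nonneg_span_half_lives`` sets the grid
    over which a candidate with a negative amplitude must stay non-negative
    (multiples of the physical half-life).  ``rate_max_per_h`` bounds both
    rates; half-lives shorter than ~25 s are not physiological at imaging
    time scales.
    """

    biexp_min_points: int = 4
    nonneg_span_half_lives: float = 10.0
    nonneg_grid_n: int = 512
    rate_max_per_h: float = 100.0


_DEFAULT_POLICY = ModelPolicy()


def _relative_weights(y: np.ndarray) -> np.ndarray:
    # floor avoids division blow-up at (rare) zero observations
    floor = 1e-12 * float(np.max(y))
    return np.maximum(y, floor if floor > 0 else 1e-300)


def _loglinear(t: np.ndarray, logy: np.ndarray) -> tuple[float, float]:
    """Unweighted straight-line fit of log-activity: returns (intercept, slope)."""
    tm = t.mean()
    ym = logy.mean()
    stt = float(np.sum((t - tm) ** 2))
    slope = float(np.sum((t - tm) * (logy - ym)) / stt) if stt > 0 else 0.0
    return ym - slope * tm, slope


def _levenberg_marquardt(resid, jac, p0, clip, max_iter=30):
    """Small dense Levenberg-Marquardt minimizer of 0.5*||resid||^2.

    ``clip`` maps a parameter vector onto the feasible box.  Written by
    hand because the fits are tiny (2 or 4 parameters, <= ~10 points) and
    run tens of thousands of times in simulation studies; generic solver
    overhead dominates otherwise.
    """
    p = clip(np.asarray(p0, dtype=float))
    r = resid(p)
    cost = float(r @ r)
    mu = 1e-3
    for _ in range(max_iter):
        J = jac(p)
        g = J.T @ r
        A = J.T @ J
        diag = np.diag(A).copy()
        diag[diag <= 0] = 1e-12
        accepted = False
        converged = False
        for _ in range(12):
            try:
                step = np.linalg.solve(A + mu * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            pn = clip(p + step)
            rn = resid(pn)
            cn = float(rn @ rn)
            if np.isfinite(cn) and cn < cost:
                # step-size convergence test against the *pre-step* params
                converged = bool(np.all(np.abs(step) <= 1e-13 * (np.abs(p) + 1e-30)))
                p, r, cost = pn, rn, cn
                mu = max(mu * 0.3, 1e-14)
                accepted = True
                break
            mu *= 10.0
            if mu > 1e13:
                break
        if not accepted or converged or cost < 1e-28:
            break
    return p, cost


def _mono_fit(t: np.ndarray, y: np.ndarray, lam_min: float, rate_max: float):
    """Weighted mono-exponential fit with the terminal-rate clamp.

    Log-linear regression (exact on noiseless data) refined by a
    relative-residual Levenberg-Marquardt polish.  Returns ((a, r), rss).
    """
    w = _relative_weights(y)
    pos = y > 0
    if pos.sum() >= 2:
        intercept, slope = _loglinear(t[pos], np.log(y[pos]))
        rate0 = float(np.clip(-slope, lam_min, rate_max))
        amp0 = float(np.exp(intercept))
    else:
        rate0, amp0 = lam_min, float(np.max(y))

    def resid(p):
        return (p[0] * np.exp(-p[1] * t) - y) / w

    def jac(p):
        e = np.exp(-p[1] * t)
        return np.column_stack((e / w, -p[0] * t * e / w))

    def clip(p):
        return np.array([max(p[0], 0.0), float(np.clip(p[1], lam_min, rate_max))])

    p, rss = _levenberg_marquardt(resid, jac, [amp0, rate0], clip, max_iter=15)
    return (float(p[0]), float(p[1])), rss


def _amp_matrix(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    return np.exp(-np.outer(t, rates))


def _biexp_residual_and_jac(t, y, w):
    def resid(p):
        a1, r1, a2, r2 = p
        return (a1 * np.exp(-r1 * t) + a2 * np.exp(-r2 * t) - y) / w

    def jac(p):
        a1, r1, a2, r2 = p
        e1 = np.exp(-r1 * t)
        e2 = np.exp(-r2 * t)
        J = np.empty((t.size, 4))
        J[:, 0] = e1 / w
        J[:, 1] = -a1 * t * e1 / w
        J[:, 2] = e2 / w
        J[:, 3] = -a2 * t * e2 / w
        return J

    return resid, jac


def _gauss_newton_polish(p, t, y, w, lam_min, rate_max, iters=12):
    """Drive a near-interpolating 4-point biexp fit to machine precision."""
    resid, jac = _biexp_residual_and_jac(t, y, w)
    best = np.array(p, dtype=float)
    best_rss = float(np.sum(resid(best) ** 2))
    x = best.copy()
    for _ in range(iters):
        r = resid(x)
        J = jac(x)
        try:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        except np.linalg.LinAlgError:
            break
        x = x + step
        x[1] = np.clip(x[1], lam_min, rate_max)
        x[3] = np.clip(x[3], lam_min, rate_max)
        rss = float(np.sum(resid(x) ** 2))
        if not np.isfinite(rss):
            break
        if rss < best_rss:
            best_rss, best = rss, x.copy()
    return best, best_rss


def _biexp_starts(t, y, mono_params, lam_min, rate_max):
    """Deterministic multi-start list seeded from log-linear sub-fits."""
    a_m, r_m = mono_params
    starts = []
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    # tail sub-fit on the last two positive points -> slow term
    pos = ys > 0
    if pos.sum() >= 2:
        tp, yp = ts[pos], ys[pos]
        r1 = math.log(max(yp[-2] / yp[-1], 1.0 + 1e-9)) / (tp[-1] - tp[-2])
        r1 = float(np.clip(r1, lam_min, rate_max))
        a1 = float(yp[-1] * math.exp(r1 * tp[-1]))
        resid0 = ys - a1 * np.exp(-r1 * ts)
        # fast term from the residuals at the first two points
        if resid0[0] > 0 and resid0.size >= 2 and resid0[1] > 0 and resid0[0] > resid0[1]:
            r2 = math.log(resid0[0] / resid0[1]) / (ts[1] - ts[0])
            r2 = float(np.clip(r2, lam_min, rate_max))
            a2 = float(resid0[0] * math.exp(r2 * ts[0]))
        elif resid0[0] < 0:
            # uptake phase: negative fast amplitude
            mag = -resid0[0]
            denom = -resid0[1] if resid0.size >= 2 and resid0[1] < 0 else mag * 1e-3
            r2 = math.log(max(mag / max(denom, 1e-300), 1.0 + 1e-9)) / (ts[1] - ts[0])
            r2 = float(np.clip(r2, lam_min, rate_max))
            a2 = float(-mag * math.exp(r2 * ts[0]))
        else:
            r2, a2 = min(10.0 * r1, rate_max), 0.3 * a1
        starts.append([a1, r1, a2, r2])
    # perturbations of the mono fit (fixed, deterministic)
    for frac, mult in ((0.5, 10.0), (-0.5, 5.0), (0.2, 30.0)):
        starts.append([a_m, max(r_m, lam_min), frac * a_m, min(mult * max(r_m, lam_min), rate_max)])
    return starts


def _biexp_fit(t, y, lam_min, policy: ModelPolicy, mono_params):
    """Multi-start biexponential fit; returns (terms, rss) or None."""
    w = _relative_weights(y)
    resid, jac = _biexp_residual_and_jac(t, y, w)

    def clip(p):
        q = np.array(p, dtype=float)
        q[1] = np.clip(q[1], lam_min, policy.rate_max_per_h)
        q[3] = np.clip(q[3], lam_min, policy.rate_max_per_h)
        return q

    best = None
    for x0 in _biexp_starts(t, y, mono_params, lam_min, policy.rate_max_per_h):
        p, rss = _levenberg_marquardt(resid, jac, x0, clip)
        if best is None or rss < best[1]:
            best = (p, rss)
        if rss < 1e-24:  # exact interpolation reached; no better start exists
            break
    if best is None:
        return None
    p, rss = best
    # near-interpolation: polish to machine precision (needed so that later
    # cycles scaled by the fitted value reproduce noiseless data exactly)
    if rss < 1e-4:
        p, rss = _gauss_newton_polish(p, t, y, w, lam_min, policy.rate_max_per_h)
    a1, r1, a2, r2 = (float(v) for v in p)
    terms = tuple(sorted(((a1, r1), (a2, r2)), key=lambda ar: ar[1]))
    # terminal amplitude must be positive, rates distinct enough to matter
    if terms[0][0] <= 0:
        return None
    if not all(np.isfinite(v) for pair in terms for v in pair):
        return None
    # every term must be visible in the data: a component that is negligible
    # at all observed times is pure extrapolation whose integral the data
    # cannot constrain
    t_min = float(np.min(t))
    y_scale = float(np.max(np.abs(y)))
    for a, r2_ in terms:
        if abs(a) * math.exp(-r2_ * t_min) < 1e-9 * y_scale:
            return None
    # non-negativity of the predicted curve over the support
    if any(a < 0 for a, _ in terms):
        span = policy.nonneg_span_half_lives * LN2 / lam_min
        grid = np.linspace(0.0, span, policy.nonneg_grid_n)
        pred = sum(a * np.exp(-r * grid) for a, r in terms)
        if np.min(pred) < -1e-9 * max(abs(a) for a, _ in terms):
            return None
    return terms, rss


def _aic_scores(n: int, candidates: dict[str, tuple[int, float]]) -> dict[str, float]:
    """AICc on relative residuals; plain AIC if any correction is undefined."""
    use_correction = all(n - k - 1 > 0 for k, _ in candidates.values())
    scores = {}
    for name, (k, rss) in candidates.items():
        # floor keeps exact interpolants comparable instead of -inf
        aic = n * math.log(max(rss, 1e-30) / n) + 2 * k
        if use_correction:
            aic += 2 * k * (k + 1) / (n - k - 1)
        scores[name] = aic
    return scores


def fit_tac_arrays(
    time_h: Sequence[float],
    activity: Sequence[float],
    nuclide: NuclideData,
    region: str = "",
    policy: ModelPolicy | None = None,
) -> TACFit:
    """Fit a TAC from parallel time/activity arrays (core routine)."""
    policy = policy or _DEFAULT_POLICY
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(activity, dtype=float)
    if t.size != y.size:
        raise InvalidInputError("time and activity arrays differ in length")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if np.unique(t).size < 2:
        raise InsufficientDataError(
            f"region {region or '?'}: need >= 2 measurements at distinct times, got {np.unique(t).size}"
        )
    if np.any(y < 0) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise InvalidInputError(f"region {region or '?'}: activities must be finite and >= 0")
    if np.all(y == 0):
        raise DegenerateInputError(f"region {region or '?'}: all activities are zero")

    lam_min = nuclide.lambda_phys
    mono_params, mono_rss = _mono_fit(t, y, lam_min, policy.rate_max_per_h)
    candidates: dict[str, tuple[tuple[tuple[float, float], ...], float]] = {
        "mono": ((mono_params,), mono_rss)
    }
    n_distinct = np.unique(t).size
    saturated = n_distinct == 4 and t.size == 4
    # a biexponential represents monotone decline or one uptake peak
    # (rise -> peak -> monotone fall); other patterns are noise
    tol = 1e-12 * float(np.max(y))
    i_max = int(np.argmax(y))
    peak_shaped = (
        i_max > 0
        and bool(np.all(np.diff(y[: i_max + 1]) > tol))
        and bool(np.all(np.diff(y[i_max:]) < tol))
    )
    if n_distinct >= policy.biexp_min_points and not (saturated and not peak_shaped):
        bi = _biexp_fit(t, y, lam_min, policy, mono_params)
        if bi is not None:
            candidates["biexp"] = bi

    if "biexp" not in candidates:
        model = "mono"
    elif saturated:
        # saturated design: structural selection (see module docstring);
        # only reached when the data are peak-shaped
        model = "biexp"
    else:
        scores = _aic_scores(
            t.size, {m: (2 * len(terms), rss) for m, (terms, rss) in candidates.items()}
        )
        model = min(scores, key=lambda m: (scores[m], m))
    terms, rss = candidates[model]
    if not all(math.isfinite(a) for a, _ in terms) or not any(a > 0 for a, _ in terms):
        raise FitFailureError(f"region {region or '?'}: fit did not converge to a valid curve")
    return TACFit(region=region, model=model, terms=terms, fit_quality=rss, n_points=int(t.size))


def fit_tac(
    measurements: Sequence[ActivityMeasurement],
    nuclide: NuclideData,
    policy: ModelPolicy | None = None,
) -> TACFit:
    """Fit a TAC for one region/cycle from measurement records.

    All measurements must share patient, region and cycle; at least two
    distinct time points are required.
    """
    if len(measurements) < 2:
        raise InsufficientDataError(
            f"need >= 2 measurements, got {len(measurements)}"
        )
    regions = {m.region for m in measurements}
    cycles = {m.cycle for m in measurements}
    patients = {m.patient_id for m in measurements}
    if len(regions) != 1 or len(cycles) != 1 or len(patients) != 1:
        raise InvalidInputError(
            f"measurements mix regions/cycles/patients: {regions}, {cycles}, {patients}"
        )
    region = next(iter(regions))
    return fit_tac_arrays(
        [m.time_h for m in measurements],
        [m.value for m in measurements],
        nuclide,
        region=region,
        policy=policy,
    )


def tia(
    fit: TACFit,
    mode: Literal["analytic", "hybrid"] = "analytic",
    measurements: Sequence[ActivityMeasurement] | None = None,
) -> float:
    """Time-integrated activity (MBq*h) of a fitted curve.

    ``analytic``: closed-form integral 0 -> inf, sum a_i / r_i.

    ``hybrid``: trapezoid over the observed time range (using the observed
    activities), the 0 -> first-point head integrated under the fitted curve,
    and an analytic tail from the last measured activity using the terminal
    rate.  Requires the original measurements.
    """
    if any(r <= 0 for _, r in fit.terms):
        raise InvalidFitError("all rates must be positive for integration")
    analytic = float(sum(a / r for a, r in fit.terms))
    if mode == "analytic":
        return analytic
    if mode != "hybrid":
        raise InvalidInputError(f"unknown TIA mode {mode!r}")
    if measurements is None:
        raise MissingInputError("hybrid TIA requires the original measurements")
    t = np.asarray([m.time_h for m in measurements], dtype=float)
    y = np.asarray([m.value for m in measurements], dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    head = float(sum((a / r) * (1.0 - math.exp(-r * t[0])) for a, r in fit.terms))
    body = float(np.trapezoid(y, t))
    tail = float(y[-1] / fit.terminal_rate)
    return head + body + tail


def normalized_disintegrations(tia_MBq_h: float, injected_MBq: float) -> float:
    """TIA per unit injected activity (hours); the phantom-software input."""
    if injected_MBq <= 0:
        raise InvalidActivityError(f"injected activity must be > 0, got {injected_MBq}")
    if tia_MBq_h < 0:
        raise InvalidInputError("TIA must be >= 0")
    return tia_MBq_h / injected_MBq


def effective_half_life(fit: TACFit) -> float:
    """ln2 / terminal rate (hours); never exceeds the physical half-life
    because the terminal rate is clamped at the physical decay constant."""
    return LN2 / fit.terminal_rate
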