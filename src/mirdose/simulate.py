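"""Synthetic dosimetry-cohort generator.

Emulates the sampling design of a multi-centre radioligand-therapy
dosimetry substudy: 30 patients, 7.4 GBq per cycle for up to 6 cycles,
four imaging time points (2/24/48/168 h) in cycle 1, one (48 h) in cycles
2-6, blood sampling in cycle 1 only, and a dosimetry-evaluable patient
count that shrinks over cycles (29/21/21/19/13/10).

Each organ follows mono-exponential biological washout multiplied by
physical decay; uptake fractions and biological half-lives vary across
patients (lognormal) and across cycles (lognormal multipliers).  The
whole-body curve is the sum of the organ curves plus an explicit
fast-clearing remainder compartment, which guarantees mass balance
(whole body >= sum of organs) by construction.  Blood is biexponential
with the terminal effective half-life sampled lognormally.

Uptake fractions are calibrated at construction time so that the implied
mean cycle-1 dose per unit activity matches published organ dosimetry for
^177Lu-PSMA-617 (e.g. kidneys 0.43 Gy/GBq, lacrimal glands 2.1 Gy/GBq):
with mono-exponential kinetics the mean dose per unit activity is
f * S_self / lambda_eff, so f = d_target * lambda_eff / S_self after a
one-pass correction for the remainder-of-body cross-dose.

Every measurement carries multiplicative lognormal noise with mean 1.
All randomness flows from the design seed; the same seed reproduces the
cohort bit for bit.  The generator also returns the hidden ground truth
(kinetic parameters, exact analytic TIAs, exact doses) for
parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .dose import (
    MarrowParams,
    SMatrix,
    SphereModelParams,
    organ_dose,
    red_marrow_dose,
    sphere_self_dose,
)
from .errors import AlignmentError, DesignError, InvalidParameterError
from .kinetics import ActivityMeasurement
from .nuclide import LN2, LU177, NuclideData

__all__ = [
    "OrganPrior",
    "RemainderPrior",
    "BloodPrior",
    "KineticPrior",
    "CohortDesign",
    "SyntheticCohort",
    "generate_cohort",
    "recovery_report",
]

LACRIMAL = "lacrimal_glands"
WHOLE_BODY = "whole_body"
BLOOD = "blood"
RED_MARROW = "red_marrow"
REMAINDER = "remainder_of_body"


@dataclass(frozen=True)
class OrganPrior:
    """Inter-patient prior for one organ's kinetics.

    ``dose_per_gbq``: calibration target for the cohort-mean cycle-1
    absorbed dose per unit activity (Gy/GBq); ``cv_uptake`` the lognormal
    inter-patient CV of the uptake fraction; ``bio_half_life_h`` the median
    biological washout half-life.
    """

    dose_per_gbq: float
    bio_half_life_h: float
    cv_uptake: float
    cv_bio: float = 0.25
    #: optional uptake-phase half-life; when set the organ curve rises to a
    #: peak before washing out (biexponential with a negative fast term)
    uptake_half_life_h: float | None = None


@dataclass(frozen=True)
class RemainderPrior:
    """Fast-clearing remainder compartment (renal excretion pathway)."""

    bio_half_life_h: float = 20.0
    cv_bio: float = 0.35


@dataclass(frozen=True)
class BloodPrior:
    """Biexponential circulating-activity model.

    Terminal effective half-life is sampled lognormally around
    ``terminal_half_life_h`` with geometric CV ``geo_cv_pct`` (calibrated to
    published ^177Lu-PSMA-617 pharmacokinetics: 41.6 h, 68.8%).
    """

    terminal_half_life_h: float = 41.6
    geo_cv_pct: float = 68.8
    fast_half_life_h: float = 0.5
    slow_fraction: float = 0.02
    volume_mL: float = 5000.0
    #: circulatory mixing half-life; puts the observed peak ~20 min
    #: after the end of infusion rather than at t=0
    mixing_half_life_h: float = 0.12


#: Published cycle-1 mean doses per unit activity used as calibration targets.
_DEFAULT_ORGANS: dict[str, OrganPrior] = {
    "kidneys": OrganPrior(0.43, 120.0, 0.37),
    LACRIMAL: OrganPrior(2.1, 90.0, 0.22),
    "salivary_glands": OrganPrior(0.63, 80.0, 0.57),
    "liver": OrganPrior(0.090, 150.0, 0.49),
    "spleen": OrganPrior(0.067, 150.0, 0.40),
}


@dataclass(frozen=True)
class KineticPrior:
    organs: dict[str, OrganPrior] = field(default_factory=lambda: dict(_DEFAULT_ORGANS))
    remainder: RemainderPrior = field(default_factory=RemainderPrior)
    blood: BloodPrior = field(default_factory=BloodPrior)
    inter_cycle_cv: float = 0.20
    measurement_noise_cv: float = 0.10
    #: "kinetic": per-cycle multipliers on both uptake and washout rate;
    #: "amplitude": multipliers on uptake only (cycle curves stay exact
    #: scalar multiples of cycle 1).
    inter_cycle_mode: Literal["kinetic", "amplitude"] = "kinetic"

    def __post_init__(self) -> None:
        if self.inter_cycle_cv < 0 or self.measurement_noise_cv < 0:
            raise InvalidParameterError("CVs must be >= 0")

    def noiseless(self) -> "KineticPrior":
        """Copy with no measurement noise and identical kinetics across cycles."""
        return replace(self, inter_cycle_cv=0.0, measurement_noise_cv=0.0)


@dataclass(frozen=True)
class CohortDesign:
    """The study's sampling design."""

    n_patients: int = 30
    injected_GBq_per_cycle: float = 7.4
    cycles: int = 6
    imaging_times_c1: tuple[float, ...] = (2.0, 24.0, 48.0, 168.0)
    imaging_time_ck: float = 48.0
    blood_times_h: tuple[float, ...] = (0.0, 1 / 60, 1 / 3, 1.0, 2.0, 4.0, 24.0, 48.0, 72.0, 144.0)
    evaluable_per_cycle: tuple[int, ...] = (29, 21, 21, 19, 13, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.evaluable_per_cycle) != self.cycles:
            raise DesignError("need one evaluable count per cycle")
        if any(c > self.n_patients or c < 0 for c in self.evaluable_per_cycle):
            raise DesignError("evaluable counts must be within [0, n_patients]")
        tail = self.evaluable_per_cycle[1:]
        if any(tail[i] < tail[i + 1] for i in range(len(tail) - 1)):
            raise DesignError("evaluable counts must be non-increasing from cycle 2 on")
        if list(self.imaging_times_c1) != sorted(set(self.imaging_times_c1)):
            raise DesignError("cycle-1 imaging times must be strictly increasing")
        if list(self.blood_times_h) != sorted(set(self.blood_times_h)):
            raise DesignError("blood sampling times must be strictly increasing")
        if self.injected_GBq_per_cycle <= 0:
            raise DesignError("injected activity per cycle must be > 0")


@dataclass
class SyntheticCohort:
    design: CohortDesign
    measurements: list[ActivityMeasurement]
    truth: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": m.patient_id,
                    "cycle": m.cycle,
                    "region": m.region,
                    "time_h": m.time_h,
                    "value": m.value,
                    "unit": m.unit,
                }
                for m in self.measurements
            ]
        )


def _sigma_ln(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _mean_one_lognormal(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    s = _sigma_ln(cv)
    return float(np.exp(rng.normal(-0.5 * s * s, s)))


def calibrated_uptake_fractions(
    priors: KineticPrior,
    smatrix: SMatrix,
    sphere: SphereModelParams,
    nuclide: NuclideData,
) -> dict[str, float]:
    """Mean uptake fractions implied by the calibration dose targets.

    Self S-values come from the S-matrix diagonal (lacrimal glands from the
    sphere model); a one-pass correction subtracts the remainder-of-body
    cross-dose before inverting d = f * S_self / lambda_eff.
    """
    lam_phys = nuclide.lambda_phys

    def s_self(region: str) -> float:
        if region == LACRIMAL:
            # Gy/(MBq*h) -> mGy/(MBq*h)
            return sphere.absorbed_fraction * sphere.delta_local / sphere.mass_g * 1e3
        return smatrix.s(region, region)

    lam_eff = {
        r: lam_phys + LN2 / p.bio_half_life_h for r, p in priors.organs.items()
    }
    naive = {
        r: p.dose_per_gbq * lam_eff[r] / s_self(r) for r, p in priors.organs.items()
    }
    f_rem = max(1.0 - sum(naive.values()), 0.0)
    lam_rem = lam_phys + LN2 / priors.remainder.bio_half_life_h
    out = {}
    for r, p in priors.organs.items():
        cross = 0.0
        if r != LACRIMAL and REMAINDER in smatrix.sources and r in smatrix.targets:
            cross = f_rem * smatrix.s(r, REMAINDER) / lam_rem
        out[r] = max((p.dose_per_gbq - cross) * lam_eff[r] / s_self(r), 1e-12)
    return out


def _patient_truth_doses(
    organ_tias: dict[str, float],
    rob_tia: float,
    blood_conc_tia: float,
    smatrix: SMatrix,
    sphere: SphereModelParams,
    marrow: MarrowParams,
) -> dict[str, float]:
    sources = {r: t for r, t in organ_tias.items() if r != LACRIMAL and r in smatrix.sources}
    sources[REMAINDER] = rob_tia
    doses = {t: organ_dose(sources, smatrix, t) for t in smatrix.targets}
    doses[LACRIMAL] = sphere_self_dose(organ_tias[LACRIMAL], sphere)
    doses[RED_MARROW] = red_marrow_dose(blood_conc_tia, rob_tia, marrow)
    return doses


def generate_cohort(
    design: CohortDesign,
    priors: KineticPrior | None = None,
    nuclide: NuclideData = LU177,
    smatrix: SMatrix | None = None,
    sphere: SphereModelParams | None = None,
    marrow: MarrowParams | None = None,
) -> SyntheticCohort:
    """Generate one cohort: measurements plus hidden ground truth."""
    from .io import default_smatrix  # local import to avoid a cycle

    priors = priors or KineticPrior()
    smatrix = smatrix or default_smatrix()
    sphere = sphere or SphereModelParams()
    marrow = marrow or MarrowParams()
    rng = np.random.default_rng(design.seed)
    lam_phys = nuclide.lambda_phys
    inj_MBq = design.injected_GBq_per_cycle * 1e3
    f_mean = calibrated_uptake_fractions(priors, smatrix, sphere, nuclide)
    noise_sigma = _sigma_ln(priors.measurement_noise_cv)

    def noisy(v: float) -> float:
        if noise_sigma == 0 or v == 0:
            return v
        return v * float(np.exp(rng.normal(-0.5 * noise_sigma**2, noise_sigma)))

    measurements: list[ActivityMeasurement] = []
    truth_patients: dict[str, dict] = {}

    for idx in range(design.n_patients):
        pid = f"P{idx + 1:03d}"
        has_cycle = [idx < design.evaluable_per_cycle[k] for k in range(design.cycles)]
        n_completed = 0
        for k in range(design.cycles):
            if has_cycle[k]:
                n_completed = k + 1

        # --- sample cycle-1 kinetics (always sampled, for rng stability) ---
        organ_par: dict[str, tuple[float, float]] = {}  # region -> (f, lam_bio)
        for region, p in priors.organs.items():
            f = f_mean[region] * _mean_one_lognormal(rng, p.cv_uptake)
            t_bio = p.bio_half_life_h * _mean_one_lognormal(rng, p.cv_bio)
            organ_par[region] = (f, LN2 / t_bio)
        f_sum = sum(f for f, _ in organ_par.values())
        if f_sum >= 0.9:  # pathological tail draw; renormalize to keep mass balance
            organ_par = {r: (f * 0.9 / f_sum, lb) for r, (f, lb) in organ_par.items()}
            f_sum = 0.9
        f_rem = 1.0 - f_sum
        t_rem = priors.remainder.bio_half_life_h * _mean_one_lognormal(rng, priors.remainder.cv_bio)
        lam_rem_bio = LN2 / t_rem

        b = priors.blood
        t_term = b.terminal_half_life_h * math.exp(
            rng.normal(0.0, _sigma_ln(b.geo_cv_pct / 100.0))
        )
        lam_slow = LN2 / t_term  # effective (as measured in circulation)
        lam_fast = LN2 / b.fast_half_life_h + lam_phys
        lam_mix = LN2 / b.mixing_half_life_h
        c0 = inj_MBq / b.volume_mL

        def blood_curve(t: float, amp: float) -> float:
            # biexp decline times a (1 - e^{-lam_mix t}) mixing factor
            return (
                amp
                * ((1 - b.slow_fraction) * math.exp(-lam_fast * t)
                   + b.slow_fraction * math.exp(-lam_slow * t))
                * (1.0 - math.exp(-lam_mix * t))
            )

        def blood_tia(amp: float) -> float:
            return amp * (
                (1 - b.slow_fraction) * (1.0 / lam_fast - 1.0 / (lam_fast + lam_mix))
                + b.slow_fraction * (1.0 / lam_slow - 1.0 / (lam_slow + lam_mix))
            )

        # --- per-cycle multipliers ---
        cyc_mult: dict[int, dict[str, tuple[float, float]]] = {}
        blood_mult: dict[int, float] = {}
        rem_mult: dict[int, tuple[float, float]] = {}
        for k in range(1, design.cycles + 1):
            if k == 1 or priors.inter_cycle_cv == 0:
                cyc_mult[k] = {r: (1.0, 1.0) for r in organ_par}
                rem_mult[k] = (1.0, 1.0)
                blood_mult[k] = 1.0
            else:
                cv = priors.inter_cycle_cv
                amp_only = priors.inter_cycle_mode == "amplitude"
                cyc_mult[k] = {
                    r: (
                        _mean_one_lognormal(rng, cv),
                        1.0 if amp_only else _mean_one_lognormal(rng, cv),
                    )
                    for r in organ_par
                }
                rem_mult[k] = (
                    _mean_one_lognormal(rng, cv),
                    1.0 if amp_only else _mean_one_lognormal(rng, cv),
                )
                blood_mult[k] = _mean_one_lognormal(rng, cv)

        # --- truth kinetics, TIAs and doses per cycle ---
        p_truth: dict = {
            "n_cycles_completed": n_completed,
            "organs": {},
            "whole_body": {},
            "remainder": {},
            "blood": {"terminal_half_life_h": t_term, "conc_tia": {}},
            "doses": {},
        }
        # each region's curve is a list of (amplitude, rate) terms; organs
        # with an uptake-phase half-life get a matched negative fast term
        # normalized so the uptake fraction keeps its TIA meaning
        # (TIA = injected * f / lambda_eff)
        curves: dict[int, dict[str, list[tuple[float, float]]]] = {}
        for k in range(1, design.cycles + 1):
            ck: dict[str, list[tuple[float, float]]] = {}
            for region, (f, lam_bio) in organ_par.items():
                mf, ml = cyc_mult[k][region]
                lam = lam_phys + lam_bio * ml
                amp = inj_MBq * f * mf
                t_up = priors.organs[region].uptake_half_life_h
                if t_up:
                    lam_up = LN2 / t_up
                    a = amp * (lam + lam_up) / lam_up
                    ck[region] = [(a, lam), (-a, lam + lam_up)]
                else:
                    ck[region] = [(amp, lam)]
            mf, ml = rem_mult[k]
            ck[REMAINDER] = [(inj_MBq * f_rem * mf, lam_phys + lam_rem_bio * ml)]
            curves[k] = ck

            def _tia(terms):
                return sum(a / lam for a, lam in terms)

            organ_tias = {r: _tia(ts) for r, ts in ck.items() if r != REMAINDER}
            rob_tia = _tia(ck[REMAINDER])
            conc_tia = blood_tia(blood_mult[k] * c0)
            for r, terms in ck.items():
                store = p_truth["organs"].setdefault(r, {}) if r != REMAINDER else p_truth["remainder"]
                lam_terminal = min(lam for _, lam in terms)
                store[k] = {
                    "terms": [list(t) for t in terms],
                    "lambda_eff_per_h": lam_terminal,
                    "tia_MBq_h": _tia(terms),
                    "effective_half_life_h": LN2 / lam_terminal,
                }
            p_truth["whole_body"][k] = {
                "tia_MBq_h": sum(_tia(ts) for ts in ck.values())
            }
            p_truth["blood"]["conc_tia"][k] = conc_tia
            p_truth["doses"][k] = _patient_truth_doses(
                organ_tias, rob_tia, conc_tia, smatrix, sphere, marrow
            )

        d1 = p_truth["doses"][1]
        planned_total = design.cycles * design.injected_GBq_per_cycle
        p_truth["predicted_cumulative"] = {
            o: d / design.injected_GBq_per_cycle * planned_total for o, d in d1.items()
        }
        if n_completed == design.cycles:
            p_truth["observed_cumulative"] = {
                o: sum(p_truth["doses"][k][o] for k in range(1, design.cycles + 1))
                for o in d1
            }
        truth_patients[pid] = p_truth

        # --- measurements ---
        def eval_regions(ck):
            def make(terms):
                return lambda t: sum(a * math.exp(-lam * t) for a, lam in terms)

            vals = {r: make(terms) for r, terms in ck.items()}
            wb = lambda t: sum(v(t) for v in vals.values())
            return vals, wb

        if has_cycle[0]:
            vals, wb = eval_regions(curves[1])
            for t in design.imaging_times_c1:
                for region in organ_par:
                    measurements.append(
                        ActivityMeasurement(pid, 1, region, t, noisy(vals[region](t)))
                    )
                measurements.append(ActivityMeasurement(pid, 1, WHOLE_BODY, t, noisy(wb(t))))
            for t in design.blood_times_h:
                conc = 0.0 if t <= 0 else blood_curve(t, c0)  # pre-dose is zero
                measurements.append(
                    ActivityMeasurement(pid, 1, BLOOD, t, noisy(conc), unit="MBq_per_mL")
                )
        for k in range(2, design.cycles + 1):
            if not has_cycle[k - 1]:
                continue
            vals, wb = eval_regions(curves[k])
            t = design.imaging_time_ck
            for region in organ_par:
                measurements.append(
                    ActivityMeasurement(pid, k, region, t, noisy(vals[region](t)))
                )
            measurements.append(ActivityMeasurement(pid, k, WHOLE_BODY, t, noisy(wb(t))))

    truth = {
        "design": {
            "n_patients": design.n_patients,
            "injected_GBq_per_cycle": design.injected_GBq_per_cycle,
            "cycles": design.cycles,
            "seed": design.seed,
        },
        "uptake_fraction_means": f_mean,
        "patients": truth_patients,
    }
    return SyntheticCohort(design=design, measurements=measurements, truth=truth)


def recovery_report(truth: dict, estimates: pd.DataFrame) -> pd.DataFrame:
    """Bias and RMSE of pipeline estimates against the generator's truth.

    ``estimates`` must have columns patient_id, region, tia_MBq_h and
    (optionally) effective_half_life_h, one row per patient/region for
    cycle 1.  Returns one row per region plus an ``overall`` row with
    percent bias and percent RMSE.
    """
    required = {"patient_id", "region", "tia_MBq_h"}
    if not required.issubset(estimates.columns):
        raise AlignmentError(f"estimates must have columns {sorted(required)}")
    rows = []
    for _, r in estimates.iterrows():
        p = truth["patients"].get(r["patient_id"])
        if p is None:
            raise AlignmentError(f"unknown patient {r['patient_id']!r} in estimates")
        if r["region"] == WHOLE_BODY:
            true_tia = p["whole_body"][1]["tia_MBq_h"]
            true_hl = None
        elif r["region"] == REMAINDER:
            true_tia = p["remainder"][1]["tia_MBq_h"]
            true_hl = p["remainder"][1]["effective_half_life_h"]
        else:
            org = p["organs"].get(r["region"])
            if org is None:
                raise AlignmentError(f"unknown region {r['region']!r} for {r['patient_id']}")
            true_tia = org[1]["tia_MBq_h"]
            true_hl = org[1]["effective_half_life_h"]
        row = {
            "patient_id": r["patient_id"],
            "region": r["region"],
            "tia_rel_err": (r["tia_MBq_h"] - true_tia) / true_tia,
        }
        if true_hl is not None and "effective_half_life_h" in estimates.columns:
            row["half_life_rel_err"] = (r["effective_half_life_h"] - true_hl) / true_hl
        rows.append(row)
    err = pd.DataFrame(rows)

    def agg(g: pd.DataFrame) -> pd.Series:
        out = {
            "n": len(g),
            "tia_bias_pct": 100.0 * g["tia_rel_err"].mean(),
            "tia_rmse_pct": 100.0 * math.sqrt((g["tia_rel_err"] ** 2).mean()),
        }
        if "half_life_rel_err" in g and g["half_life_rel_err"].notna().any():
            h = g["half_life_rel_err"].dropna()
            out["half_life_bias_pct"] = 100.0 * h.mean()
            out["half_life_rmse_pct"] = 100.0 * math.sqrt((h**2).mean())
        return pd.Series(out)

    by_region = err.groupby("region", sort=True).apply(agg, include_groups=False)
    overall = agg(err)
    overall.name = "overall"
    return pd.concat([by_region, overall.to_frame().T])
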