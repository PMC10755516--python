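"""End-to-end orchestration: measurements -> fits -> doses -> cohort report.

The stages mirror the study's analysis order:

1. fit cycle-1 time-activity curves per patient/region and integrate them;
2. derive the blood concentration TIA and remainder-of-body TIA;
3. convert TIAs to organ absorbed doses (S-matrix sum, sphere-model
   lacrimal self-dose, blood-based red marrow);
4. scale cycles 2-6 from the single 48 h (or 24 h) measurement;
5. aggregate predicted and observed cumulative doses, compare them with
   paired Hotelling T^2 per cycle (Bonferroni over the cycle family), and
   summarize the blood pharmacokinetics.

Everything is deterministic given the inputs; fit model choices and
single-time-point scale factors are logged.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as cstats
from .dose import (
    organ_dose,
    red_marrow_dose,
    remainder_of_body_tia,
    sphere_self_dose,
)
from .errors import (
    DosimetryError,
    InconsistencyError,
    InsufficientDataError,
    UnscalableError,
)
from .io import RunConfig
from .kinetics import (
    ActivityMeasurement,
    effective_half_life,
    fit_tac,
    fit_tac_arrays,
    normalized_disintegrations,
    tia,
)
from .pk import ConcentrationMeasurement, geometric_summary, nca
from .simulate import BLOOD, LACRIMAL, RED_MARROW, REMAINDER, WHOLE_BODY
from .stp import STPMeasurement, scale_tia

__all__ = ["derive_doses", "cohort_tables", "pk_analysis", "run_pipeline"]

log = logging.getLogger("mirdose")


def _group_measurements(measurements: Sequence[ActivityMeasurement]):
    by_patient: dict[str, dict[int, dict[str, list[ActivityMeasurement]]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(list))
    )
    for m in measurements:
        by_patient[m.patient_id][m.cycle][m.region].append(m)
    return by_patient


def _blood_conc_tia(blood: list[ActivityMeasurement], config: RunConfig):
    """Analytic TIA of the fitted blood concentration decline (MBq*h/mL),
    together with the fit; returns ``(tia, fit)``.

    The fit uses the decline from the observed peak onward; the area before
    the peak (minutes) is negligible against a multi-day integral.
    """
    pts = sorted(blood, key=lambda m: m.time_h)
    concs = np.array([m.value for m in pts])
    times = np.array([m.time_h for m in pts])
    imax = int(np.argmax(concs))
    # fit the disposition curve from the first post-peak sample on (the peak
    # sample itself still sits in the mixing/distribution phase, which a sum
    # of decaying exponentials cannot represent)
    start = imax + 1 if concs[imax + 1 :].size >= 2 else imax
    keep = concs[start:] > 0
    if int(keep.sum()) < 2:
        raise InsufficientDataError("not enough positive blood samples for a decline fit")
    fit = fit_tac_arrays(times[start:][keep], concs[start:][keep], config.nuclide, region=BLOOD)
    # trapezoid head over the observed rise + analytic fitted integral beyond
    head = float(np.trapezoid(concs[: start + 1], times[: start + 1]))
    tail = float(sum(a / r * np.exp(-r * times[start]) for a, r in fit.terms))
    return head + tail, fit


def derive_doses(measurements: Sequence[ActivityMeasurement], config: RunConfig):
    """Per-patient, per-cycle organ absorbed doses.

    Returns ``(doses, estimates)``: ``doses`` has one row per
    patient/cycle/organ with dose_Gy and dose_per_GBq; ``estimates`` holds
    the cycle-1 fit diagnostics (TIA, effective half-life, model,
    normalized disintegrations) per patient/region.
    """
    smatrix = config.load_smatrix()
    inj_MBq = config.per_cycle_GBq * 1e3
    by_patient = _group_measurements(measurements)
    dose_rows: list[dict] = []
    est_rows: list[dict] = []

    for pid in sorted(by_patient):
        cycles = by_patient[pid]
        if 1 not in cycles:
            continue
        c1 = cycles[1]

        # The whole-body curve is a many-exponential mixture; rather than
        # force a biexponential through it, subtract the organ activities
        # per time point and fit the remainder of body as its own region.
        if WHOLE_BODY in c1:
            organs_by_time: dict[float, float] = defaultdict(float)
            for region, ms in c1.items():
                if region in (BLOOD, WHOLE_BODY):
                    continue
                for m in ms:
                    organs_by_time[m.time_h] += m.value
            rob_ms = []
            for m in sorted(c1[WHOLE_BODY], key=lambda x: x.time_h):
                organs_t = organs_by_time.get(m.time_h, 0.0)
                val = m.value - organs_t
                # non-positive residuals are noise-dominated (late times, when
                # the remainder has cleared) and carry no log-scale kinetic
                # information: drop them; gross excess is a real inconsistency
                if m.value < 0.5 * organs_t:
                    raise InconsistencyError(
                        f"{pid}: organ activity grossly exceeds whole body at t={m.time_h} h"
                    )
                if val > 0:
                    rob_ms.append(ActivityMeasurement(pid, 1, REMAINDER, m.time_h, val))
            c1 = {r: v for r, v in c1.items() if r != WHOLE_BODY}
            if len(rob_ms) >= 2:
                c1[REMAINDER] = rob_ms
            else:
                log.warning("%s: remainder of body not fittable (too few points)", pid)

        fits: dict[str, object] = {}
        tias: dict[str, float] = {}
        for region, ms in sorted(c1.items()):
            if region == BLOOD:
                continue
            fit = fit_tac(ms, config.nuclide)
            fits[region] = fit
            tias[region] = tia(fit, mode=config.tia_mode, measurements=ms)
            log.info("fit %s/%s: model=%s rss=%.3g", pid, region, fit.model, fit.fit_quality)
            est_rows.append(
                {
                    "patient_id": pid,
                    "region": region,
                    "model": fit.model,
                    "tia_MBq_h": tias[region],
                    "effective_half_life_h": effective_half_life(fit),
                    "normalized_disintegrations_h": normalized_disintegrations(
                        tias[region], inj_MBq
                    ),
                    "fit_quality": fit.fit_quality,
                }
            )
        organ_tias_1 = {r: v for r, v in tias.items() if r != REMAINDER}
        rob_1 = tias.get(REMAINDER)
        if rob_1 is not None:
            # consistency check of the mass balance (whole body >= organs)
            wb_tia_1 = rob_1 + sum(organ_tias_1.values())
            remainder_of_body_tia(wb_tia_1, organ_tias_1)
            est_rows.append(
                {
                    "patient_id": pid,
                    "region": WHOLE_BODY,
                    "model": "derived",
                    "tia_MBq_h": wb_tia_1,
                    "effective_half_life_h": None,
                    "normalized_disintegrations_h": normalized_disintegrations(
                        wb_tia_1, inj_MBq
                    ),
                    "fit_quality": None,
                }
            )
        blood_tia_1 = None
        if BLOOD in c1:
            blood_tia_1, blood_fit = _blood_conc_tia(c1[BLOOD], config)

        def cycle_doses(cyc: int, organ_tias: dict, rob, blood_tia) -> None:
            sources = {r: t for r, t in organ_tias.items() if r in smatrix.sources}
            if rob is not None and REMAINDER in smatrix.sources:
                sources[REMAINDER] = rob
            for target in smatrix.targets:
                d = organ_dose(sources, smatrix, target)
                dose_rows.append(
                    {"patient_id": pid, "cycle": cyc, "organ": target, "dose_Gy": d}
                )
            if LACRIMAL in organ_tias:
                dose_rows.append(
                    {
                        "patient_id": pid,
                        "cycle": cyc,
                        "organ": LACRIMAL,
                        "dose_Gy": sphere_self_dose(organ_tias[LACRIMAL], config.sphere),
                    }
                )
            if blood_tia is not None and rob is not None:
                dose_rows.append(
                    {
                        "patient_id": pid,
                        "cycle": cyc,
                        "organ": RED_MARROW,
                        "dose_Gy": red_marrow_dose(blood_tia, rob, config.marrow),
                    }
                )

        cycle_doses(1, organ_tias_1, rob_1, blood_tia_1)

        for cyc in sorted(c for c in cycles if c >= 2):
            ck = cycles[cyc]
            organ_tias_k: dict[str, float] = {}
            ratios: dict[str, float] = {}
            organ_meas_k: dict[float, float] = defaultdict(float)
            for region, ms in sorted(ck.items()):
                if region in (BLOOD, WHOLE_BODY) or region not in fits:
                    continue
                m = ms[0]
                organ_meas_k[m.time_h] += m.value
                stp = STPMeasurement(pid, cyc, region, m.time_h, m.value)
                organ_tias_k[region] = scale_tia(
                    fits[region], tias[region], stp, floor_MBq=config.stp_floor_MBq
                )
                ratios[region] = organ_tias_k[region] / tias[region] if tias[region] else 0.0
                log.info("stp %s/%s cycle %d: scale=%.4g", pid, region, cyc, ratios[region])
            rob_k = None
            blood_tia_k = None
            if WHOLE_BODY in ck and REMAINDER in fits:
                m = ck[WHOLE_BODY][0]
                organs_t = organ_meas_k.get(m.time_h, 0.0)
                rob_raw = m.value - organs_t
                if m.value < 0.5 * organs_t:
                    raise InconsistencyError(
                        f"{pid}: organ activity grossly exceeds whole body in cycle {cyc}"
                    )
                stp = STPMeasurement(pid, cyc, REMAINDER, m.time_h, max(rob_raw, 0.0))
                try:
                    rob_k = scale_tia(
                        fits[REMAINDER], tias[REMAINDER], stp, floor_MBq=config.stp_floor_MBq
                    )
                except UnscalableError as exc:
                    log.warning("%s cycle %d: %s", pid, cyc, exc)
                else:
                    rob_ratio = rob_k / tias[REMAINDER] if tias[REMAINDER] else 0.0
                    log.info("stp %s/rob cycle %d: scale=%.4g", pid, cyc, rob_ratio)
                    # blood sampled in cycle 1 only: its kinetics track the
                    # circulating/excreting compartment, so scale by the
                    # remainder-of-body factor
                    if blood_tia_1 is not None:
                        blood_tia_k = blood_tia_1 * rob_ratio
            cycle_doses(cyc, organ_tias_k, rob_k, blood_tia_k)

    doses = pd.DataFrame(dose_rows)
    if not doses.empty:
        doses["dose_per_GBq"] = doses["dose_Gy"] / config.per_cycle_GBq
    estimates = pd.DataFrame(est_rows)
    return doses, estimates


def cohort_tables(doses: pd.DataFrame, config: RunConfig) -> dict:
    """Per-cycle and cumulative cohort summaries plus Hotelling comparisons."""
    out: dict = {"per_cycle": {}, "cumulative": {}, "hotelling": {}}
    if doses.empty:
        return out
    planned = config.planned_total_GBq
    organs = sorted(doses["organ"].unique())

    for organ in organs:
        sub = doses[doses["organ"] == organ]
        block = {}
        c1 = sub[sub["cycle"] == 1]["dose_per_GBq"]
        if len(c1):
            block["cycle1"] = cstats.summarize(c1.tolist()).as_dict()
        later = sub[sub["cycle"] >= 2]["dose_per_GBq"]
        if len(later):
            block["cycles2_6"] = cstats.summarize(later.tolist()).as_dict()
        out["per_cycle"][organ] = block

    # cumulative: predicted for every cycle-1 patient, observed for completers
    wide = doses.pivot_table(index=["patient_id", "organ"], columns="cycle", values="dose_Gy")
    completed = doses.groupby("patient_id")["cycle"].max()
    completers = completed[completed == config.cycles].index

    for organ in organs:
        sub = doses[(doses["organ"] == organ) & (doses["cycle"] == 1)]
        predicted = {
            r["patient_id"]: cstats.predict_cumulative(r["dose_per_GBq"], planned)
            for _, r in sub.iterrows()
        }
        observed = {}
        for pid in completers:
            try:
                row = wide.loc[(pid, organ)]
            except KeyError:
                continue
            vals = row.dropna()
            if len(vals) == config.cycles:
                observed[pid] = cstats.observed_cumulative(vals.tolist())
        block = {"predicted": cstats.summarize(list(predicted.values())).as_dict()}
        if observed:
            obs_sum = cstats.summarize(list(observed.values()))
            block["observed"] = obs_sum.as_dict()
            block["relative_difference_pct"] = cstats.relative_difference(
                block["predicted"]["mean"], obs_sum.mean
            )
        out["cumulative"][organ] = block

    # Hotelling per cycle on the at-risk organs, cumulative through cycle k
    at_risk = [o for o in config.at_risk_organs if o in organs]
    for k in range(2, config.cycles + 1):
        pids = completed[completed >= k].index
        P, O, used = [], [], []
        for pid in pids:
            prow, orow = [], []
            ok = True
            for organ in at_risk:
                try:
                    row = wide.loc[(pid, organ)]
                except KeyError:
                    ok = False
                    break
                d1 = row.get(1)
                cyc_doses = [row.get(j) for j in range(1, k + 1)]
                if d1 is None or any(v is None or pd.isna(v) for v in cyc_doses):
                    ok = False
                    break
                prow.append(
                    cstats.predict_cumulative(d1 / config.per_cycle_GBq, k * config.per_cycle_GBq)
                )
                orow.append(cstats.observed_cumulative(cyc_doses))
            if ok:
                P.append(prow)
                O.append(orow)
                used.append(pid)
        try:
            res = cstats.hotelling_paired(
                np.array(P), np.array(O), m_comparisons=config.m_comparisons, organs=at_risk
            )
            out["hotelling"][k] = {"n": len(used), **res.as_dict()}
        except DosimetryError as exc:
            out["hotelling"][k] = {"n": len(used), "error": str(exc)}
    return out


def pk_analysis(measurements: Sequence[ActivityMeasurement]) -> dict:
    """Per-patient NCA of the cycle-1 blood curves and geometric summaries."""
    by_patient: dict[str, list[ConcentrationMeasurement]] = defaultdict(list)
    for m in measurements:
        if m.region == BLOOD and m.cycle == 1:
            by_patient[m.patient_id].append(
                ConcentrationMeasurement(m.patient_id, m.time_h, m.value)
            )
    results = {}
    for pid in sorted(by_patient):
        try:
            r = nca(by_patient[pid])
        except DosimetryError as exc:
            log.warning("pk %s: %s", pid, exc)
            continue
        results[pid] = r
    out: dict = {"n": len(results)}
    if len(results) >= 2:
        half_lives = [r.t_half_h for r in results.values()]
        gm, gcv = geometric_summary(half_lives)
        out["terminal_half_life_geomean_h"] = gm
        out["terminal_half_life_geo_cv_pct"] = gcv
        out["tmax_median_h"] = float(np.median([r.tmax_h for r in results.values()]))
    return out


def run_pipeline(config: RunConfig, measurements: Sequence[ActivityMeasurement]) -> dict:
    """Full analysis: doses, cohort tables, Hotelling comparisons, PK."""
    doses, estimates = derive_doses(measurements, config)

    def records(df: pd.DataFrame) -> list[dict]:
        # keep the report JSON-clean and comparable: NaN -> None
        return [
            {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]

    report = {
        "config": {
            "nuclide": config.nuclide.name,
            "half_life_h": config.nuclide.half_life_h,
            "cycles": config.cycles,
            "per_cycle_GBq": config.per_cycle_GBq,
            "planned_total_GBq": config.planned_total_GBq,
            "tia_mode": config.tia_mode,
        },
        "cohort": cohort_tables(doses, config),
        "pk": pk_analysis(measurements),
        "doses": records(doses),
        "cycle1_estimates": records(estimates),
    }
    return report


def report_to_markdown(report: dict) -> str:
    """Compact human-readable summary of a pipeline report."""
    lines = ["# Dosimetry report", ""]
    cfg = report["config"]
    lines.append(
        f"{cfg['nuclide']} | {cfg['cycles']} cycles x {cfg['per_cycle_GBq']:g} GBq "
        f"(planned total {cfg['planned_total_GBq']:.4g} GBq)"
    )
    lines.append("")
    lines.append("## Dose per unit activity (Gy/GBq)")
    lines.append("| organ | cycle 1 mean (SD) | cycles 2-6 mean (SD) |")
    lines.append("|---|---|---|")
    for organ, block in report["cohort"].get("per_cycle", {}).items():
        c1 = block.get("cycle1")
        c26 = block.get("cycles2_6")
        f = lambda b: f"{b['mean']:.3g} ({b['sd']:.2g})" if b else "-"
        lines.append(f"| {organ} | {f(c1)} | {f(c26)} |")
    lines.append("")
    lines.append("## Cumulative dose (Gy)")
    lines.append("| organ | predicted mean | observed mean | rel. diff |")
    lines.append("|---|---|---|---|")
    for organ, block in report["cohort"].get("cumulative", {}).items():
        pred = block["predicted"]["mean"]
        obs = block.get("observed", {}).get("mean")
        rd = block.get("relative_difference_pct")
        if obs is None:
            lines.append(f"| {organ} | {pred:.3g} | - | - |")
        else:
            lines.append(f"| {organ} | {pred:.3g} | {obs:.3g} | {rd:+.1f}% |")
    lines.append("")
    hot = report["cohort"].get("hotelling", {})
    if hot:
        lines.append("## Predicted vs observed (Hotelling T^2, Bonferroni-adjusted)")
        for k, h in hot.items():
            if "error" in h:
                lines.append(f"- cycle {k}: n={h['n']}, {h['error']}")
            else:
                lines.append(
                    f"- cycle {k}: n={h['n']}, T2={h['t2']:.3g}, p_adj={h['p_adjusted']:.3g}"
                )
    pk = report.get("pk", {})
    if "terminal_half_life_geomean_h" in pk:
        lines.append("")
        lines.append(
            f"Blood terminal half-life: geometric mean {pk['terminal_half_life_geomean_h']:.3g} h "
            f"(geo CV {pk['terminal_half_life_geo_cv_pct']:.3g}%), n={pk['n']}"
        )
    return "\n".join(lines) + "\n"
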