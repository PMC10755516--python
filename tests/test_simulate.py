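"""Synthetic cohort generator: determinism, design, ground truth, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import mirdose as md
from mirdose.errors import AlignmentError, DesignError
from mirdose.simulate import BLOOD, KineticPrior, WHOLE_BODY


class TestDesign:
    def test_default_matches_study_design(self):
        d = md.CohortDesign()
        assert d.n_patients == 30
        assert d.injected_GBq_per_cycle == 7.4
        assert d.evaluable_per_cycle == (29, 21, 21, 19, 13, 10)
        assert d.imaging_times_c1 == (2.0, 24.0, 48.0, 168.0)

    def test_evaluable_count_above_cohort_size_rejected(self):
        with pytest.raises(DesignError):
            md.CohortDesign(evaluable_per_cycle=(31, 21, 21, 19, 13, 10))

    def test_increasing_dropout_counts_rejected(self):
        with pytest.raises(DesignError):
            md.CohortDesign(evaluable_per_cycle=(29, 13, 21, 19, 13, 10))


class TestGenerateCohort:
    def test_same_seed_reproduces_identical_cohort(self):
        a = md.generate_cohort(md.CohortDesign(seed=9))
        b = md.generate_cohort(md.CohortDesign(seed=9))
        assert a.measurements == b.measurements
        assert a.truth == b.truth

    def test_different_seed_differs(self):
        a = md.generate_cohort(md.CohortDesign(seed=9))
        b = md.generate_cohort(md.CohortDesign(seed=10))
        assert a.measurements != b.measurements

    def test_evaluable_counts_respected(self, noisy_cohort):
        df = noisy_cohort.to_frame()
        counts = df.groupby("cycle")["patient_id"].nunique()
        assert tuple(counts[c] for c in range(1, 7)) == (29, 21, 21, 19, 13, 10)

    def test_noiseless_measurements_lie_on_true_curves(self, noiseless_cohort):
        truth = noiseless_cohort.truth["patients"]
        for m in noiseless_cohort.measurements:
            if m.region in (BLOOD, WHOLE_BODY):
                continue
            par = truth[m.patient_id]["organs"][m.region][m.cycle]
            expected = sum(a * math.exp(-lam * m.time_h) for a, lam in par["terms"])
            assert m.value == pytest.approx(expected, rel=1e-12)

    def test_whole_body_dominates_organ_sum(self, noisy_cohort):
        df = noisy_cohort.to_frame()
        imaging = df[df["unit"] == "MBq"]
        for (pid, cyc, t), g in imaging.groupby(["patient_id", "cycle", "time_h"]):
            wb = g[g.region == WHOLE_BODY]["value"]
            organs = g[g.region != WHOLE_BODY]["value"].sum()
            assert len(wb) == 1
            assert wb.iloc[0] > 0.5 * organs  # noise cannot flip the balance

    def test_truth_contains_predicted_and_observed_for_completers(self, noisy_cohort):
        truth = noisy_cohort.truth["patients"]
        completers = [p for p, t in truth.items() if t["n_cycles_completed"] == 6]
        assert len(completers) == 10
        for pid in completers:
            assert "observed_cumulative" in truth[pid]
            assert set(truth[pid]["observed_cumulative"]) == set(
                truth[pid]["predicted_cumulative"]
            )

    def test_noiseless_observed_equals_predicted_in_truth(self, noiseless_cohort):
        truth = noiseless_cohort.truth["patients"]
        for pid, t in truth.items():
            if "observed_cumulative" not in t:
                continue
            for organ, obs in t["observed_cumulative"].items():
                assert obs == pytest.approx(t["predicted_cumulative"][organ], rel=1e-12)


class TestRecoveryReport:
    def _estimates(self, truth, factor=1.0):
        rows = []
        for pid, t in truth["patients"].items():
            for region, cycles in t["organs"].items():
                rows.append(
                    {
                        "patient_id": pid,
                        "region": region,
                        "tia_MBq_h": factor * cycles[1]["tia_MBq_h"],
                        "effective_half_life_h": factor * cycles[1]["effective_half_life_h"],
                    }
                )
        return pd.DataFrame(rows)

    def test_perfect_estimates_have_zero_bias(self, noisy_cohort):
        rep = md.recovery_report(noisy_cohort.truth, self._estimates(noisy_cohort.truth))
        assert np.allclose(rep["tia_bias_pct"].astype(float), 0.0, atol=1e-9)
        assert np.allclose(rep["tia_rmse_pct"].astype(float), 0.0, atol=1e-9)

    def test_ten_percent_inflation_reports_ten_percent_bias(self, noisy_cohort):
        rep = md.recovery_report(noisy_cohort.truth, self._estimates(noisy_cohort.truth, 1.1))
        assert np.allclose(rep["tia_bias_pct"].astype(float), 10.0, atol=1e-9)

    def test_unknown_patient_raises_alignment_error(self, noisy_cohort):
        est = self._estimates(noisy_cohort.truth)
        est.loc[0, "patient_id"] = "P999"
        with pytest.raises(AlignmentError):
            md.recovery_report(noisy_cohort.truth, est)


class TestUptakePhase:
    def test_uptake_prior_produces_peaked_curve_with_calibrated_tia(self):
        from mirdose.simulate import _DEFAULT_ORGANS, OrganPrior
        import dataclasses
        organs = dict(_DEFAULT_ORGANS)
        organs["salivary_glands"] = dataclasses.replace(
            organs["salivary_glands"], uptake_half_life_h=1.5
        )
        priors = KineticPrior(organs=organs).noiseless()
        cohort = md.generate_cohort(md.CohortDesign(seed=2), priors)
        truth = cohort.truth["patients"]["P001"]["organs"]["salivary_glands"][1]
        terms = truth["terms"]
        assert len(terms) == 2 and terms[1][0] < 0
        # curve starts at zero, peaks, then washes out; TIA keeps the
        # closed-form value sum(a/lambda)
        assert sum(a for a, _ in terms) == pytest.approx(0.0, abs=1e-9)
        assert truth["tia_MBq_h"] == pytest.approx(
            sum(a / lam for a, lam in terms), rel=1e-12
        )
        vals = [m for m in cohort.measurements
                if m.patient_id == "P001" and m.region == "salivary_glands" and m.cycle == 1]
        assert all(v.value >= 0 for v in vals)


class TestCalibration:
    def test_single_cohort_kidney_dose_near_published_mean(self, noisy_cohort):
        truth = noisy_cohort.truth["patients"]
        d1 = [
            t["doses"][1]["kidneys"] / 7.4
            for t in truth.values()
            if t["n_cycles_completed"] >= 1
        ]
        assert abs(np.mean(d1) - 0.43) / 0.43 < 0.30
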