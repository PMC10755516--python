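"""Time-activity curve fitting and time-integrated activity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mirdose as md
from mirdose.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidActivityError,
    InvalidInputError,
    MissingInputError,
)
from mirdose.kinetics import TACFit

from conftest import mono_measurements

TIMES = [2.0, 24.0, 48.0, 168.0]


class TestFitTac:
    def test_noiseless_mono_recovery(self, lu177):
        ms = mono_measurements(10.0, 0.008, TIMES)
        fit = md.fit_tac(ms, lu177)
        assert fit.model == "mono"
        (a, r), = fit.terms
        assert abs(a - 10.0) / 10.0 < 1e-6
        assert abs(r - 0.008) / 0.008 < 1e-6

    def test_noiseless_biexp_reproduces_all_points(self, lu177):
        t = np.array(TIMES)
        y = 12 * np.exp(-0.01 * t) - 12 * np.exp(-0.3 * t)
        fit = md.fit_tac_arrays(t, y, lu177, "salivary_glands")
        assert fit.model == "biexp"
        rel = np.abs(fit.predict(t) - y) / y
        assert np.max(rel) < 1e-4

    def test_single_measurement_is_insufficient(self, lu177):
        with pytest.raises(InsufficientDataError):
            md.fit_tac(mono_measurements(10, 0.01, [48.0]), lu177)

    def test_all_zero_activities_are_degenerate(self, lu177):
        ms = [md.ActivityMeasurement("P", 1, "liver", t, 0.0) for t in TIMES]
        with pytest.raises(DegenerateInputError):
            md.fit_tac(ms, lu177)

    def test_mixed_regions_rejected(self, lu177):
        ms = mono_measurements(10, 0.01, [2.0, 24.0]) + mono_measurements(
            10, 0.01, [48.0], region="liver"
        )
        with pytest.raises(InvalidInputError):
            md.fit_tac(ms, lu177)

    def test_terminal_rate_clamped_at_physical_decay(self, lu177):
        # constant activity would imply an infinite effective half-life
        ms = [md.ActivityMeasurement("P", 1, "liver", t, 5.0) for t in TIMES]
        fit = md.fit_tac(ms, lu177)
        assert fit.terminal_rate >= lu177.lambda_phys * (1 - 1e-12)
        assert md.effective_half_life(fit) <= lu177.half_life_h * (1 + 1e-12)

    def test_two_point_data_fits_mono(self, lu177):
        fit = md.fit_tac(mono_measurements(8.0, 0.02, [24.0, 96.0]), lu177)
        assert fit.model == "mono"
        assert abs(md.effective_half_life(fit) - math.log(2) / 0.02) < 1e-6

    @given(c=st.floats(0.01, 100.0))
    def test_scaling_equivariance_of_fit_and_tia(self, c):
        lu = md.LU177
        t = np.array(TIMES)
        y = 50 * np.exp(-0.012 * t)
        f1 = md.fit_tac_arrays(t, y, lu, "r")
        f2 = md.fit_tac_arrays(t, c * y, lu, "r")
        assert md.tia(f2) == pytest.approx(c * md.tia(f1), rel=1e-9)

    def test_time_unit_consistency(self, lu177):
        # hours vs days: rates and TIA rescale by 24, dose-level results agree
        t_h = np.array(TIMES)
        y = 30 * np.exp(-0.01 * t_h)
        fit_h = md.fit_tac_arrays(t_h, y, lu177, "r")
        nuc_d = md.NuclideData("Lu-177", lu177.half_life_h / 24.0)
        fit_d = md.fit_tac_arrays(t_h / 24.0, y, nuc_d, "r")
        assert md.tia(fit_d) * 24.0 == pytest.approx(md.tia(fit_h), rel=1e-9)
        assert md.effective_half_life(fit_d) * 24.0 == pytest.approx(
            md.effective_half_life(fit_h), rel=1e-9
        )


class TestTia:
    @pytest.mark.parametrize(
        "terms,expected",
        [
            (((100.0, 0.01),), 10_000.0),
            (((12.0, 0.01), (-12.0, 0.3)), 12 / 0.01 - 12 / 0.3),
        ],
    )
    def test_analytic_closed_form(self, terms, expected):
        fit = TACFit("r", "mono" if len(terms) == 1 else "biexp", terms, 0.0, 4)
        assert md.tia(fit) == pytest.approx(expected, rel=1e-12)

    def test_hybrid_within_trapezoid_bound_of_analytic(self, lu177):
        a0, lam = 100.0, 0.01
        ms = mono_measurements(a0, lam, TIMES)
        fit = md.fit_tac(ms, lu177)
        analytic = md.tia(fit, "analytic")
        hybrid = md.tia(fit, "hybrid", ms)
        # head and tail are exact for noiseless mono; the only deviation is
        # the trapezoid excess, bounded by sum (dt^3/12) max|A''| per segment
        bound = 0.0
        for t0, t1 in zip(TIMES[:-1], TIMES[1:]):
            bound += (t1 - t0) ** 3 / 12.0 * a0 * lam**2 * math.exp(-lam * t0)
        assert hybrid >= analytic - 1e-9
        assert hybrid - analytic <= bound

    def test_hybrid_converges_to_analytic_with_dense_sampling(self, lu177):
        fit = TACFit("r", "mono", ((100.0, 0.01),), 0.0, 4)
        analytic = md.tia(fit)
        errs = []
        for n in (16, 256, 4096):
            times = np.linspace(0.01, 1200.0, n)
            ms = mono_measurements(100.0, 0.01, times)
            errs.append(abs(md.tia(fit, "hybrid", ms) - analytic) / analytic)
        assert errs[0] > errs[1] > errs[2]
        # trapezoid error ~ (h^2/12) * lambda^2 -> ~7e-7 at h = 0.29 h
        assert errs[-1] < 2e-6

    def test_hybrid_requires_measurements(self):
        fit = TACFit("r", "mono", ((1.0, 0.01),), 0.0, 4)
        with pytest.raises(MissingInputError):
            md.tia(fit, "hybrid")

    def test_unknown_mode_rejected(self):
        fit = TACFit("r", "mono", ((1.0, 0.01),), 0.0, 4)
        with pytest.raises(InvalidInputError):
            md.tia(fit, "simpson")

    @given(
        amps=st.lists(st.floats(0.5, 500.0), min_size=1, max_size=3),
        rates=st.lists(st.floats(0.005, 5.0), min_size=3, max_size=3),
    )
    def test_analytic_tia_finite_and_positive(self, amps, rates):
        terms = tuple((a, r) for a, r in zip(amps, rates))
        fit = TACFit("r", "biexp", terms, 0.0, 4)
        v = md.tia(fit)
        assert math.isfinite(v) and v > 0


class TestNormalizedDisintegrations:
    @pytest.mark.parametrize(
        "tia,inj,expected",
        [(10_000.0, 7_400.0, 10_000 / 7_400), (0.0, 7_400.0, 0.0), (7_400.0, 7_400.0, 1.0)],
    )
    def test_values(self, tia, inj, expected):
        assert md.normalized_disintegrations(tia, inj) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_injection_rejected(self):
        with pytest.raises(InvalidActivityError):
            md.normalized_disintegrations(100.0, 0.0)


class TestEffectiveHalfLife:
    def test_closed_form(self):
        fit = TACFit("r", "mono", ((10.0, 0.01),), 0.0, 4)
        assert md.effective_half_life(fit) == pytest.approx(math.log(2) / 0.01, rel=1e-12)

    def test_noiseless_fit_half_life(self, lu177):
        fit = md.fit_tac(mono_measurements(10, 0.008, TIMES), lu177)
        assert md.effective_half_life(fit) == pytest.approx(86.64, abs=0.01)

    def test_boundary_equals_physical(self, lu177):
        fit = TACFit("r", "mono", ((10.0, lu177.lambda_phys),), 0.0, 4)
        assert md.effective_half_life(fit) == pytest.approx(lu177.half_life_h, rel=1e-12)
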