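"""MIRD dose engine: S-matrix sum, sphere self-dose, blood-based marrow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mirdose as md
from mirdose.dose import MarrowParams, SMatrix, SphereModelParams
from mirdose.errors import (
    InconsistencyError,
    InvalidActivityError,
    InvalidInputError,
    InvalidParameterError,
    SchemaError,
)

ORGANS = ["a", "b", "c", "d", "e"]


def random_smatrix(rng):
    vals = rng.uniform(0.0, 1.0, size=(5, 5))
    return SMatrix(pd.DataFrame(vals, index=ORGANS, columns=ORGANS))


class TestOrganDose:
    def test_unit_case(self):
        S = SMatrix(pd.DataFrame([[1.0]], index=["t"], columns=["s"]))
        assert md.organ_dose({"s": 1000.0}, S, "t") == pytest.approx(1.0, rel=1e-12)

    def test_additive_over_sources(self):
        S = SMatrix(pd.DataFrame([[0.4, 0.4]], index=["t"], columns=["s1", "s2"]))
        split = md.organ_dose({"s1": 500.0, "s2": 500.0}, S, "t")
        merged = md.organ_dose({"s1": 1000.0, "s2": 0.0}, S, "t")
        assert split == pytest.approx(merged, rel=1e-12)

    def test_matches_bruteforce_sum_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            S = random_smatrix(rng)
            tias = {o: float(rng.uniform(0, 1e4)) for o in ORGANS}
            for target in ORGANS:
                # independent brute-force elementwise oracle
                expected = sum(tias[s] * S.values.at[target, s] for s in ORGANS) / 1e3
                assert md.organ_dose(tias, S, target) == pytest.approx(expected, rel=1e-12)

    def test_unknown_labels_raise_schema_error(self):
        S = SMatrix(pd.DataFrame([[1.0]], index=["t"], columns=["s"]))
        with pytest.raises(SchemaError, match="nope"):
            md.organ_dose({"s": 1.0}, S, "nope")
        with pytest.raises(SchemaError, match="ghost"):
            md.organ_dose({"ghost": 1.0}, S, "t")

    def test_negative_tia_rejected(self):
        S = SMatrix(pd.DataFrame([[1.0]], index=["t"], columns=["s"]))
        with pytest.raises(InvalidInputError):
            md.organ_dose({"s": -1.0}, S, "t")

    @given(c=st.floats(0.01, 100.0))
    def test_linearity_in_tia(self, c):
        rng = np.random.default_rng(1)
        S = random_smatrix(rng)
        tias = {o: float(rng.uniform(0, 1e3)) for o in ORGANS}
        scaled = {o: c * v for o, v in tias.items()}
        assert md.organ_dose(scaled, S, "a") == pytest.approx(
            c * md.organ_dose(tias, S, "a"), rel=1e-9
        )


class TestDosePerUnitActivity:
    @pytest.mark.parametrize(
        "dose,inj,expected",
        [(3.182, 7.4, 0.43), (0.0, 7.4, 0.0), (7.4, 7.4, 1.0)],
    )
    def test_values(self, dose, inj, expected):
        assert md.dose_per_unit_activity(dose, inj) == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_injection_rejected(self):
        with pytest.raises(InvalidActivityError):
            md.dose_per_unit_activity(1.0, -7.4)


class TestSphereSelfDose:
    def test_zero_tia_gives_zero(self):
        assert md.sphere_self_dose(0.0, SphereModelParams()) == 0.0

    def test_inverse_mass_law(self):
        p1 = SphereModelParams(mass_g=0.7)
        p2 = SphereModelParams(mass_g=1.4)
        assert md.sphere_self_dose(100.0, p1) == pytest.approx(
            2 * md.sphere_self_dose(100.0, p2), rel=1e-12
        )

    def test_energy_bookkeeping_oracle(self):
        # explicit hand computation from the mean electron energy per decay
        mean_E_MeV = 0.1479
        joules_per_decay = mean_E_MeV * 1.602176634e-13
        decays_per_MBq_h = 1e6 * 3600.0
        tia = 1000.0  # MBq*h
        mass_kg = 1e-3  # 1 g
        expected_Gy = tia * decays_per_MBq_h * joules_per_decay / mass_kg
        p = SphereModelParams(mass_g=1.0, absorbed_fraction=1.0)
        assert md.sphere_self_dose(tia, p) == pytest.approx(expected_Gy, rel=1e-9)

    def test_invalid_mass_rejected(self):
        with pytest.raises(InvalidParameterError):
            SphereModelParams(mass_g=0.0)


class TestRedMarrowDose:
    PARAMS = MarrowParams(rmblr=1.0, marrow_mass_g=1100.0, s_rm_rm=0.02, s_rm_rob=0.001)

    def test_two_term_hand_computation(self):
        # marrow TIA = 2 * 1100 = 2200; dose = (2200*0.02 + 50000*0.001)/1000
        total, self_term, cross_term = md.red_marrow_dose(
            2.0, 50_000.0, self.PARAMS, return_components=True
        )
        assert self_term == pytest.approx(0.044, rel=1e-12)
        assert cross_term == pytest.approx(0.050, rel=1e-12)
        assert total == pytest.approx(0.094, rel=1e-12)

    def test_zero_blood_leaves_cross_term_only(self):
        assert md.red_marrow_dose(0.0, 50_000.0, self.PARAMS) == pytest.approx(
            0.050, rel=1e-12
        )

    def test_zero_rmblr_equivalent_to_zero_blood(self):
        p0 = MarrowParams(rmblr=0.0, marrow_mass_g=1100.0, s_rm_rm=0.02, s_rm_rob=0.001)
        assert md.red_marrow_dose(2.0, 50_000.0, p0) == md.red_marrow_dose(
            0.0, 50_000.0, self.PARAMS
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            md.red_marrow_dose(-1.0, 0.0, self.PARAMS)


class TestRemainderOfBody:
    def test_subtraction(self):
        assert md.remainder_of_body_tia(10_000.0, {"a": 4_000.0, "b": 3_000.0}) == 3_000.0

    def test_no_organs_returns_whole_body(self):
        assert md.remainder_of_body_tia(10_000.0, {}) == 10_000.0

    def test_organ_excess_raises(self):
        with pytest.raises(InconsistencyError):
            md.remainder_of_body_tia(10_000.0, {"a": 10_001.0})


class TestSMatrixIO:
    def test_csv_round_trip(self, tmp_path, smatrix):
        p = tmp_path / "s.csv"
        smatrix.values.to_csv(p)
        again = md.SMatrix.from_csv(p)
        assert np.allclose(again.values.to_numpy(), smatrix.values.to_numpy())
        assert again.targets == smatrix.targets

    def test_negative_values_rejected(self):
        with pytest.raises(InvalidInputError):
            SMatrix(pd.DataFrame([[-1.0]], index=["t"], columns=["s"]))

    def test_packaged_fixture_covers_remainder_source(self, smatrix):
        assert "remainder_of_body" in smatrix.sources
        assert set(smatrix.targets) >= {"kidneys", "salivary_glands", "liver", "spleen"}
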