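"""MIRD-schema absorbed-dose engine.

D(target) = sum_sources TIA(source) * S(target <- source), with S in
mGy/(MBq*h) and TIA in MBq*h, giving dose in mGy (converted to Gy here).
Two special targets sit outside the S-matrix sum:

* small-gland (lacrimal) self-dose via the unit-density sphere model, where
  all locally absorbed emissions deposit in the gland mass;
* red marrow via the standard blood-based method: the marrow activity
  concentration is taken as RMBLR times the blood concentration, and the
  remainder of body contributes a photon cross-dose.

The engine is strictly linear in every TIA input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    InconsistencyError,
    InvalidActivityError,
    InvalidInputError,
    InvalidParameterError,
    SchemaError,
)
from .nuclide import (
    LU177_MEAN_ELECTRON_ENERGY_MEV,
    electron_dose_constant_Gy_g_per_MBq_h,
)

__all__ = [
    "SMatrix",
    "SphereModelParams",
    "MarrowParams",
    "DoseResult",
    "organ_dose",
    "dose_per_unit_activity",
    "sphere_self_dose",
    "red_marrow_dose",
    "remainder_of_body_tia",
]


@dataclass(frozen=True)
class SMatrix:
    """Target x source matrix of dose per unit time-integrated activity.

    ``values`` is a DataFrame indexed by target label with one column per
    source label, in mGy/(MBq*h).  The matrix need not be square.
    """

    values: pd.DataFrame
    phantom_label: str = ""

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidInputError("S-values must be finite and >= 0")

    @property
    def targets(self) -> list[str]:
        return list(self.values.index)

    @property
    def sources(self) -> list[str]:
        return list(self.values.columns)

    def s(self, target: str, source: str) -> float:
        if target not in self.values.index:
            raise SchemaError(f"unknown target organ {target!r}")
        if source not in self.values.columns:
            raise SchemaError(f"unknown source organ {source!r}")
        return float(self.values.at[target, source])

    @classmethod
    def from_csv(cls, path, phantom_label: str = "") -> "SMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(values=df, phantom_label=phantom_label or str(path))


@dataclass(frozen=True)
class SphereModelParams:
    """Unit-density sphere self-dose parameters for a small gland.

    ``delta_local`` is the equilibrium dose constant of the locally absorbed
    emissions in Gy*g/(MBq*h); the default is derived from the mean electron
    energy per decay of ^177Lu.  ``absorbed_fraction`` accounts for electron
    escape from very small masses (1.0 = full local absorption).
    """

    mass_g: float = 0.7
    delta_local: float = electron_dose_constant_Gy_g_per_MBq_h(
        LU177_MEAN_ELECTRON_ENERGY_MEV
    )
    absorbed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise InvalidParameterError(f"sphere mass must be > 0 g, got {self.mass_g}")
        if self.delta_local <= 0:
            raise InvalidParameterError("delta_local must be > 0")
        if not (0.0 < self.absorbed_fraction <= 1.0):
            raise InvalidParameterError(
                f"absorbed fraction must be in (0, 1], got {self.absorbed_fraction}"
            )


@dataclass(frozen=True)
class MarrowParams:
    """Blood-based red-marrow dose parameters.

    ``rmblr`` is the red-marrow-to-blood activity concentration ratio
    (1.0 for agents with no specific marrow binding); ``s_rm_rm`` and
    ``s_rm_rob`` are marrow self- and remainder-of-body cross S-values in
    mGy/(MBq*h).
    """

    rmblr: float = 1.0
    marrow_mass_g: float = 1100.0
    s_rm_rm: float = electron_dose_constant_Gy_g_per_MBq_h(
        LU177_MEAN_ELECTRON_ENERGY_MEV
    ) / 1100.0 * 1e3  # mGy/(MBq*h) for the 1100 g reference marrow
    s_rm_rob: float = 1.1e-4
    blood_density_g_per_mL: float = 1.0

    def __post_init__(self) -> None:
        if self.rmblr < 0:
            raise InvalidParameterError("rmblr must be >= 0")
        if self.marrow_mass_g <= 0:
            raise InvalidParameterError("marrow mass must be > 0 g")
        if self.s_rm_rm < 0 or self.s_rm_rob < 0:
            raise InvalidParameterError("marrow S-values must be >= 0")
        if self.blood_density_g_per_mL <= 0:
            raise InvalidParameterError("blood density must be > 0")


@dataclass(frozen=True)
class DoseResult:
    """Absorbed dose for one patient/cycle/organ."""

    patient_id: str
    cycle: int
    organ: str
    dose_Gy: float
    dose_per_activity_Gy_per_GBq: float

    def __post_init__(self) -> None:
        if self.dose_Gy < 0 or self.dose_per_activity_Gy_per_GBq < 0:
            raise InvalidInputError("doses must be >= 0")


def organ_dose(tia_by_source: Mapping[str, float], S: SMatrix, target: str) -> float:
    """MIRD sum over sources for one target organ, in Gy."""
    if target not in S.values.index:
        raise SchemaError(f"unknown target organ {target!r}")
    total_mGy = 0.0
    for source, t in tia_by_source.items():
        if source not in S.values.columns:
            raise SchemaError(f"unknown source organ {source!r}")
        if t < 0 or not math.isfinite(t):
            raise InvalidInputError(f"TIA for source {source!r} must be finite and >= 0, got {t}")
        total_mGy += t * float(S.values.at[target, source])
    return total_mGy / 1e3


def dose_per_unit_activity(dose_Gy: float, injected_GBq: float) -> float:
    """Absorbed dose normalized by injected activity (Gy/GBq)."""
    if injected_GBq <= 0:
        raise InvalidActivityError(f"injected activity must be > 0 GBq, got {injected_GBq}")
    if dose_Gy < 0:
        raise InvalidInputError("dose must be >= 0")
    return dose_Gy / injected_GBq


def sphere_self_dose(tia_MBq_h: float, params: SphereModelParams) -> float:
    """Self-dose of a small unit-density sphere, in Gy.

    dose = absorbed_fraction * delta_local * TIA / mass, with delta_local in
    Gy*g/(MBq*h).
    """
    if tia_MBq_h < 0:
        raise InvalidInputError("TIA must be >= 0")
    return params.absorbed_fraction * params.delta_local * tia_MBq_h / params.mass_g


def red_marrow_dose(
    blood_conc_tia_MBq_h_per_mL: float,
    rob_tia_MBq_h: float,
    params: MarrowParams,
    return_components: bool = False,
):
    """Blood-based red-marrow dose, in Gy.

    Marrow TIA = RMBLR * [blood concentration TIA] * marrow mass / density;
    dose = (marrow_TIA * S(rm<-rm) + ROB_TIA * S(rm<-rob)) / 1000.
    """
    if blood_conc_tia_MBq_h_per_mL < 0 or rob_tia_MBq_h < 0:
        raise InvalidInputError("marrow dose inputs must be >= 0")
    marrow_tia = (
        params.rmblr
        * blood_conc_tia_MBq_h_per_mL
        * params.marrow_mass_g
        / params.blood_density_g_per_mL
    )
    self_term = marrow_tia * params.s_rm_rm / 1e3
    cross_term = rob_tia_MBq_h * params.s_rm_rob / 1e3
    if return_components:
        return self_term + cross_term, self_term, cross_term
    return self_term + cross_term


def remainder_of_body_tia(
    whole_body_tia: float,
    organ_tias: Mapping[str, float],
    rel_tol: float = 1e-6,
) -> float:
    """Whole-body TIA minus the explicitly modelled source organs.

    Organ TIAs exceeding the whole body by more than ``rel_tol`` (relative)
    indicate inconsistent quantification and raise.
    """
    if whole_body_tia < 0 or any(v < 0 for v in organ_tias.values()):
        raise InvalidInputError("TIAs must be >= 0")
    organ_sum = float(sum(organ_tias.values()))
    if organ_sum > whole_body_tia * (1.0 + rel_tol):
        raise InconsistencyError(
            f"organ TIA sum {organ_sum:.6g} exceeds whole-body TIA {whole_body_tia:.6g}"
        )
    return max(whole_body_tia - organ_sum, 0.0)
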