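"""Radionuclide physical data.

The default nuclide is ^177Lu with the ICRP 107 half-life of 6.647 days.
``delta_local_Gy_g_per_MBq_h`` is the equilibrium dose constant of the locally
absorbed (electron) emissions: mean electron energy per decay converted to
Gy*g per MBq*h of time-integrated activity.  It drives the unit-density
sphere self-dose model and the synthetic S-value fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

LN2 = math.log(2.0)

#: J per MeV
_MEV_TO_J = 1.602176634e-13
#: decays per MBq*h
_DECAYS_PER_MBQ_H = 1e6 * 3600.0

#: Mean energy of electron emissions (beta + conversion + Auger) per decay of
#: ^177Lu, MeV (ICRP 107 nuclear data).
LU177_MEAN_ELECTRON_ENERGY_MEV = 0.1479


def electron_dose_constant_Gy_g_per_MBq_h(mean_energy_MeV: float) -> float:
    """Equilibrium dose constant for locally absorbed emissions.

    Gy*g/(MBq*h) = MeV/decay * J/MeV * decays/(MBq*h) * 1000 g/kg.
    """
    if mean_energy_MeV <= 0:
        raise InvalidParameterError("mean energy per decay must be > 0")
    return mean_energy_MeV * _MEV_TO_J * _DECAYS_PER_MBQ_H * 1e3


@dataclass(frozen=True)
class NuclideData:
    """Physical decay data for one radionuclide.

    ``lambda_phys`` is derived from the half-life (ln 2 / T_half); it is a
    field so serialized configs stay explicit, but the constructor always
    recomputes it to keep the invariant exact.
    """

    name: str
    half_life_h: float
    lambda_phys: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.half_life_h > 0 and math.isfinite(self.half_life_h)):
            raise InvalidParameterError(
                f"half-life must be a positive finite number of hours, got {self.half_life_h!r}"
            )
        object.__setattr__(self, "lambda_phys", LN2 / self.half_life_h)


#: Default nuclide: ^177Lu, T_half = 6.647 d (ICRP 107).
LU177 = NuclideData(name="Lu-177", half_life_h=6.647 * 24.0)
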