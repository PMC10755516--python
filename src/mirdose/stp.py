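"""Single-time-point (STP) dosimetry scaling for cycles 2-6.

After the first cycle, each organ is imaged once (nominally 48 h, 24 h
permitted).  The cycle-k time-integrated activity is obtained by scaling the
patient's *entire* cycle-1 curve by the ratio of the single measured
activity to the fitted cycle-1 activity at the same time:

    TIA_k = TIA_1 * A_k(t*) / A_1_fit(t*)

This activity-ratio method is exact whenever the cycle-k kinetics are a
scalar multiple of the cycle-1 kinetics, and uses the fitted (not raw)
cycle-1 value in the denominator so the 24-h fallback needs no raw
measurement at that time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError, UnscalableError
from .kinetics import TACFit

__all__ = ["STPMeasurement", "scale_tia"]


@dataclass(frozen=True)
class STPMeasurement:
    """The single post-administration measurement of a later cycle."""

    patient_id: str
    cycle: int
    region: str
    time_h: float
    activity_MBq: float

    def __post_init__(self) -> None:
        if not (2 <= int(self.cycle) <= 6):
            raise InvalidInputError(f"STP measurements belong to cycles 2-6, got {self.cycle}")
        if not (self.time_h > 0 and math.isfinite(self.time_h)):
            raise InvalidInputError(f"time_h must be > 0, got {self.time_h}")
        if self.activity_MBq < 0 or not math.isfinite(self.activity_MBq):
            raise InvalidInputError(f"activity must be >= 0, got {self.activity_MBq}")


def scale_tia(
    fit_c1: TACFit,
    tia_c1: float,
    m: STPMeasurement,
    floor_MBq: float = 1e-9,
) -> float:
    """Cycle-k TIA from the cycle-1 curve and one measurement.

    Raises :class:`UnscalableError` when the fitted cycle-1 activity at the
    measurement time is at or below ``floor_MBq`` (the ratio would be
    meaningless noise amplification).
    """
    if tia_c1 < 0:
        raise InvalidInputError("cycle-1 TIA must be >= 0")
    if fit_c1.region and m.region and fit_c1.region != m.region:
        raise InvalidInputError(
            f"region mismatch: fit is {fit_c1.region!r}, measurement is {m.region!r}"
        )
    ref = float(fit_c1.predict(m.time_h))
    if ref <= floor_MBq:
        raise UnscalableError(
            f"fitted cycle-1 activity at {m.time_h} h is {ref:.3g} MBq (<= floor {floor_MBq:g}) "
            f"for region {m.region!r}"
        )
    return tia_c1 * m.activity_MBq / ref
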