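"""File formats, organ-label vocabulary and run configuration.

Measurements travel as a flat CSV with columns
``patient_id, cycle, region, time_h, value, unit`` (unit ``MBq`` for imaging
regions, ``MBq_per_mL`` for blood).  Organ labels are normalized to a fixed
snake_case vocabulary at parse time through an alias map, so files written
by different tools ("Urinary bladder wall", "urinary-bladder-wall") land on
the same label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .dose import MarrowParams, SMatrix, SphereModelParams
from .errors import ConfigError, ParseError
from .kinetics import ActivityMeasurement
from .nuclide import LU177, NuclideData

__all__ = [
    "normalize_region",
    "read_measurements",
    "write_measurements",
    "read_smatrix",
    "default_smatrix",
    "RunConfig",
    "load_config",
]

_REQUIRED_COLUMNS = ("patient_id", "cycle", "region", "time_h", "value", "unit")

#: explicit aliases on top of mechanical snake_casing
_ALIASES = {
    "kidney": "kidneys",
    "lacrimal_gland": "lacrimal_glands",
    "salivary_gland": "salivary_glands",
    "whole_body": "whole_body",
    "total_body": "whole_body",
    "wb": "whole_body",
    "urinary_bladder": "urinary_bladder_wall",
    "bladder_wall": "urinary_bladder_wall",
    "marrow": "red_marrow",
    "rob": "remainder_of_body",
    "remainder": "remainder_of_body",
}


def normalize_region(label: str) -> str:
    """Normalize an organ label to the controlled snake_case vocabulary."""
    s = re.sub(r"[\s\-/]+", "_", str(label).strip().lower())
    s = re.sub(r"_+", "_", s).strip("_")
    return _ALIASES.get(s, s)


def read_measurements(path) -> list[ActivityMeasurement]:
    """Read and validate a measurements CSV.

    Raises :class:`ParseError` with row numbers (1-based, header = row 1)
    for missing columns, negative activities and duplicate
    (patient, cycle, region, time) keys.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {', '.join(missing)}")
    records: list[ActivityMeasurement] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = ActivityMeasurement(
                patient_id=str(row.patient_id),
                cycle=int(row.cycle),
                region=normalize_region(row.region),
                time_h=float(row.time_h),
                value=float(row.value),
                unit=str(row.unit),
            )
        except Exception as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
        key = (rec.patient_id, rec.cycle, rec.region, rec.time_h)
        if key in seen:
            raise ParseError(
                f"{path}: duplicate (patient, cycle, region, time) at rows {seen[key]} and {i}: {key}"
            )
        seen[key] = i
        records.append(rec)
    return records


def write_measurements(records: Iterable[ActivityMeasurement], path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "cycle": m.cycle,
                "region": m.region,
                "time_h": m.time_h,
                "value": m.value,
                "unit": m.unit,
            }
            for m in records
        ],
        columns=list(_REQUIRED_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_smatrix(path) -> SMatrix:
    """S-matrix CSV: first column target label, one column per source,
    values in mGy/(MBq*h)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        sm = SMatrix.from_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    sm.values.index = [normalize_region(t) for t in sm.values.index]
    sm.values.columns = [normalize_region(s) for s in sm.values.columns]
    return sm


def default_smatrix() -> SMatrix:
    """Packaged synthetic adult-male-like ^177Lu S-value subset."""
    ref = resources.files("mirdose.data").joinpath("s_matrix_lu177_adult_male_synthetic.csv")
    with resources.as_file(ref) as p:
        return read_smatrix(p)


AT_RISK_ORGANS = ("kidneys", "lacrimal_glands", "salivary_glands", "red_marrow")


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the measurements themselves."""

    nuclide: NuclideData = LU177
    cycles: int = 6
    per_cycle_GBq: float = 7.4
    smatrix_path: str | None = None
    organs: tuple[str, ...] = ("kidneys", "lacrimal_glands", "salivary_glands", "liver", "spleen")
    at_risk_organs: tuple[str, ...] = AT_RISK_ORGANS
    sphere: SphereModelParams = field(default_factory=SphereModelParams)
    marrow: MarrowParams = field(default_factory=MarrowParams)
    tia_mode: str = "analytic"
    stp_floor_MBq: float = 1e-9
    m_comparisons: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1 or self.per_cycle_GBq <= 0:
            raise ConfigError("cycles must be >= 1 and per-cycle activity > 0")
        if self.tia_mode not in ("analytic", "hybrid"):
            raise ConfigError(f"unknown TIA mode {self.tia_mode!r}")

    @property
    def planned_total_GBq(self) -> float:
        return self.cycles * self.per_cycle_GBq

    def load_smatrix(self) -> SMatrix:
        if self.smatrix_path:
            return read_smatrix(self.smatrix_path)
        return default_smatrix()


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        kwargs: dict = {}
        if "nuclide" in raw:
            n = raw["nuclide"]
            kwargs["nuclide"] = NuclideData(
                name=n.get("name", "Lu-177"), half_life_h=float(n["half_life_h"])
            )
        for key in ("cycles", "m_comparisons", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        for key in ("per_cycle_GBq", "stp_floor_MBq"):
            if key in raw:
                kwargs[key] = float(raw[key])
        for key in ("smatrix_path", "tia_mode"):
            if key in raw:
                kwargs[key] = raw[key]
        if "organs" in raw:
            kwargs["organs"] = tuple(normalize_region(o) for o in raw["organs"])
        if "at_risk_organs" in raw:
            kwargs["at_risk_organs"] = tuple(normalize_region(o) for o in raw["at_risk_organs"])
        if "sphere" in raw:
            s = raw["sphere"]
            defaults = SphereModelParams()
            kwargs["sphere"] = SphereModelParams(
                mass_g=float(s.get("mass_g", defaults.mass_g)),
                delta_local=float(s.get("delta_local", defaults.delta_local)),
                absorbed_fraction=float(s.get("absorbed_fraction", defaults.absorbed_fraction)),
            )
        if "marrow" in raw:
            m = raw["marrow"]
            defaults = MarrowParams()
            kwargs["marrow"] = MarrowParams(
                rmblr=float(m.get("rmblr", defaults.rmblr)),
                marrow_mass_g=float(m.get("mass_g", defaults.marrow_mass_g)),
                s_rm_rm=float(m.get("s_rm_rm", defaults.s_rm_rm)),
                s_rm_rob=float(m.get("s_rm_rob", defaults.s_rm_rob)),
            )
        cfg = RunConfig(**kwargs)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    unknown = set(cfg.at_risk_organs) - set(cfg.organs) - {"red_marrow"}
    if unknown:
        raise ConfigError(f"at-risk organs not in organ list: {sorted(unknown)}")
    return cfg
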