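"""Absorbance processing: raw cuvette readings -> temperature-corrected net OD.

A run consists of replicate irradiated cuvettes read at 304 nm, one control
cuvette (solution that sat in the vessel unirradiated) and a pure-water blank
for instrument QC.  The dose-induced optical-density increase is the
irradiated minus control absorbance, referred to a 25 C reference temperature
by a two-factor multiplicative correction:

    dOD = (OD_i - OD_c) / [(1 + c_irr*(T_i - 25)) * (1 + c_read*(T_r - 25))]

where c_irr accounts for the temperature dependence of the ferric yield
during irradiation and c_read for that of the molar absorption coefficient
during the spectrophotometer reading.  Both coefficients are configuration
(packaged literature defaults: 0.0012 and 0.0069 per degC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "ROLES",
    "TemperatureCoefficients",
    "CuvetteReading",
    "IrradiationRecord",
    "DeltaOD",
    "QCReport",
    "delta_od",
    "average_replicates",
    "blank_qc",
    "read_readings_csv",
    "read_irradiations_csv",
]

ROLES = ("irradiated", "control", "water_blank")

#: Plausibility bands; violations warn rather than fail.
_PATH_BAND_CM = (0.9, 1.1)
_TEMP_BAND_C = (10.0, 40.0)
_DOSE_BAND_GY = (5.0, 400.0)

REFERENCE_TEMP_C = 25.0


@dataclass(frozen=True)
class TemperatureCoefficients:
    """Per-degC coefficients of the two temperature correction factors."""

    irradiation: float = 0.0012
    reading: float = 0.0069


@dataclass(frozen=True)
class CuvetteReading:
    """One absorbance reading of one cuvette at 304 nm."""

    cuvette_id: str
    role: str
    od: float
    path_length: float = 1.0  # cm
    t_read: float = REFERENCE_TEMP_C  # degC

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.od < 0:
            raise ValueError(f"optical density must be >= 0, got {self.od}")
        if not _PATH_BAND_CM[0] <= self.path_length <= _PATH_BAND_CM[1]:
            warnings.warn(
                f"cuvette {self.cuvette_id}: path length {self.path_length} cm outside "
                f"plausibility band {_PATH_BAND_CM}", stacklevel=3,
            )
        if not _TEMP_BAND_C[0] <= self.t_read <= _TEMP_BAND_C[1]:
            raise ValueError(
                f"reading temperature {self.t_read} C outside {_TEMP_BAND_C}"
            )


@dataclass(frozen=True)
class IrradiationRecord:
    """Irradiation metadata for one run."""

    run_id: str
    t_irr: float  # degC, solution temperature during irradiation
    duration: float  # h
    nominal_dose: float  # Gy
    s_k: float | None = None  # air-kerma strength, U = cGy.cm^2/h

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0 h, got {self.duration}")
        if not _DOSE_BAND_GY[0] <= self.nominal_dose <= _DOSE_BAND_GY[1]:
            warnings.warn(
                f"run {self.run_id}: nominal dose {self.nominal_dose} Gy outside the "
                f"Fricke operating band {_DOSE_BAND_GY}", stacklevel=3,
            )


@dataclass(frozen=True)
class DeltaOD:
    """Net temperature-corrected OD increase, averaged over replicates."""

    value: float
    path_length: float  # cm, mean over replicates
    n_replicates: int
    type_a_percent: float | None = None  # % SD of the mean; absent for n = 1
    flagged: bool = False  # true when the corrected mean is <= 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.type_a_percent is not None and self.type_a_percent < 0:
            raise ValueError("type_a_percent must be >= 0")


@dataclass(frozen=True)
class QCReport:
    """Verdicts of the pre-run instrument/solution checks."""

    blank_od: float
    control_drift: float | None  # absent when no reference OD was supplied
    threshold: float
    blank_pass: bool
    control_pass: bool

    @property
    def passed(self) -> bool:
        return self.blank_pass and self.control_pass


def delta_od(
    od_i: float,
    od_c: float,
    t_irr: float,
    t_read: float,
    coeffs: TemperatureCoefficients = TemperatureCoefficients(),
) -> float:
    """Temperature-corrected net OD for a single irradiated/control pair.

    Equals ``od_i - od_c`` when both temperatures sit at the 25 C reference.
    """
    for name, t in (("irradiation", t_irr), ("reading", t_read)):
        if not _TEMP_BAND_C[0] <= t <= _TEMP_BAND_C[1]:
            raise ValueError(f"{name} temperature {t} C outside {_TEMP_BAND_C}")
    factor = (1.0 + coeffs.irradiation * (t_irr - REFERENCE_TEMP_C)) * (
        1.0 + coeffs.reading * (t_read - REFERENCE_TEMP_C)
    )
    if factor <= 0:
        raise ValueError(
            f"temperature correction factor {factor:.4g} <= 0: unphysical "
            "temperature/coefficient combination"
        )
    return (od_i - od_c) / factor


def average_replicates(
    readings: Sequence[CuvetteReading],
    control: CuvetteReading,
    irr: IrradiationRecord,
    coeffs: TemperatureCoefficients = TemperatureCoefficients(),
) -> DeltaOD:
    """Per-replicate temperature correction, then the mean and its Type A spread.

    ``type_a_percent`` is 100 * (sample SD of the mean) / mean for n >= 2 and
    absent for a single reading.  A non-positive mean is flagged, not raised,
    so downstream QC can catch swapped irradiated/control labels.
    """
    if not readings:
        raise ValueError("empty replicate set")
    if any(r.role != "irradiated" for r in readings):
        raise ValueError("all replicate readings must have role 'irradiated'")
    if control.role != "control":
        raise ValueError(f"control reading has role {control.role!r}")

    corrected = [
        delta_od(r.od, control.od, irr.t_irr, r.t_read, coeffs) for r in readings
    ]
    n = len(corrected)
    mean = sum(corrected) / n
    flagged = mean <= 0
    if flagged:
        warnings.warn(
            f"run {irr.run_id}: non-positive corrected delta-OD ({mean:.4g}); "
            "check irradiated/control labels", stacklevel=2,
        )
    type_a = None
    if n >= 2:
        sd = math.sqrt(sum((c - mean) ** 2 for c in corrected) / (n - 1))
        sdm = sd / math.sqrt(n)
        type_a = 100.0 * sdm / abs(mean) if mean != 0 else float("inf")
    path = sum(r.path_length for r in readings) / n
    return DeltaOD(mean, path, n, type_a, flagged)


def blank_qc(
    blank: CuvetteReading,
    control: CuvetteReading,
    threshold: float = 0.01,
    control_reference_od: float | None = None,
) -> QCReport:
    """Check the water blank and the control-solution drift against a threshold.

    The control drift is measured against ``control_reference_od`` (e.g. the
    freshly prepared solution's absorbance); without a reference the control
    check is skipped, since the control's absolute absorbance is dominated by
    the acid matrix baseline.  Passing requires strict inequality: a value
    equal to the threshold fails.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if blank.role != "water_blank":
        raise ValueError(f"blank reading has role {blank.role!r}")
    if control.role != "control":
        raise ValueError(f"control reading has role {control.role!r}")
    drift = (
        abs(control.od - control_reference_od)
        if control_reference_od is not None
        else None
    )
    return QCReport(
        blank_od=blank.od,
        control_drift=drift,
        threshold=threshold,
        blank_pass=blank.od < threshold,
        control_pass=(drift < threshold) if drift is not None else True,
    )


_READING_COLUMNS = ["run_id", "cuvette_id", "role", "od", "path_length_cm", "t_read_c"]
_IRRADIATION_COLUMNS = ["run_id", "t_irr_c", "duration_h", "nominal_dose_gy"]


def read_readings_csv(path) -> pd.DataFrame:
    """Load a cuvette-readings table, validating schema and roles.

    Required columns: run_id, cuvette_id, role, od, path_length_cm, t_read_c.
    Extra columns (e.g. a read timestamp for audit) are passed through.
    """
    df = pd.read_csv(path, dtype={"run_id": str, "cuvette_id": str})
    missing = set(_READING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"readings file missing columns: {sorted(missing)}")
    bad_roles = set(df["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles in readings file: {sorted(bad_roles)}")
    return df


def read_irradiations_csv(path) -> pd.DataFrame:
    """Load an irradiation-records table (s_k_u column optional)."""
    df = pd.read_csv(path, dtype={"run_id": str})
    missing = set(_IRRADIATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"irradiations file missing columns: {sorted(missing)}")
    if df["run_id"].duplicated().any():
        raise ValueError("duplicate run_id in irradiations file")
    return df


def readings_to_objects(df: pd.DataFrame, run_id: str):
    """Split one run's rows into (irradiated list, control, blank-or-None)."""
    rows = df[df["run_id"] == run_id]
    if rows.empty:
        raise ValueError(f"no readings for run {run_id!r}")

    def make(row) -> CuvetteReading:
        return CuvetteReading(
            cuvette_id=str(row.cuvette_id),
            role=row.role,
            od=float(row.od),
            path_length=float(row.path_length_cm),
            t_read=float(row.t_read_c),
        )

    irradiated = [make(r) for r in rows.itertuples() if r.role == "irradiated"]
    controls = [make(r) for r in rows.itertuples() if r.role == "control"]
    blanks = [make(r) for r in rows.itertuples() if r.role == "water_blank"]
    if not irradiated:
        raise ValueError(f"run {run_id!r} has no irradiated readings")
    if len(controls) != 1:
        raise ValueError(f"run {run_id!r} must have exactly one control, got {len(controls)}")
    return irradiated, controls[0], (blanks[0] if blanks else None)
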