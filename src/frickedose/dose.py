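"""Dose chain: corrected OD -> dose to Fricke solution -> dose to water,
plus the air-kerma-strength (TG-43 point) reference it is compared against.

Unit regime, fixed throughout: epsilon in L/(mol.cm), path length L in cm,
density rho in g/cm^3 (numerically equal to kg/L), G in mol/J.  Then

    D_F = dOD / (rho * L * epsilon * G)            [Gy]
    D_w = D_F * f * p_wall * F_h * k_dd            [Gy]

with f the Fricke->water medium conversion, p_wall the vessel-wall
perturbation, F_h the volume-averaging correction and k_dd the dose-profile
non-uniformity correction — calibrated constants carried with standard
uncertainties.  The ionometric reference is the point conversion

    D_w(TG-43) = S_k * Lambda * dt / 100           [Gy]

with S_k in U = cGy.cm^2/h, Lambda the dose rate constant in cGy/(h.U) at
1 cm from the source centre, and dt the irradiation time in hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .spectrophotometry import DeltaOD
from .yields import GValue

__all__ = [
    "Factor",
    "FrickeConstants",
    "CorrectionFactors",
    "SourceCalibration",
    "DoseResult",
    "MethodComparison",
    "dose_fricke",
    "dose_water_fricke",
    "dose_water_tg43",
    "compare_methods",
]


@dataclass(frozen=True)
class Factor:
    """A dimensionless multiplier with a standard uncertainty."""

    value: float
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass(frozen=True)
class FrickeConstants:
    """The constants entering the OD -> Fricke-dose conversion."""

    epsilon: float = 2174.0  # L/(mol.cm) at 304 nm
    rho: float = 1.023  # g/cm^3 at 25 C
    g_value: GValue = GValue(1.555e-6, 0.017e-6, method="energy_weighted")

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not 1.00 <= self.rho <= 1.05:
            raise ValueError(f"density {self.rho} g/cm^3 outside [1.00, 1.05]")

    @property
    def gy_per_unit_delta_od(self) -> float:
        """Sensitivity at unit path length: dose per unit corrected OD."""
        return 1.0 / (self.rho * self.epsilon * self.g_value.value)


@dataclass(frozen=True)
class CorrectionFactors:
    """The four multiplicative corrections taking Fricke dose to water dose."""

    f: Factor = Factor(1.004, 0.003)  # Fricke -> water medium conversion
    p_wall: Factor = Factor(0.999, 0.004)  # vessel wall perturbation
    f_h: Factor = Factor(0.996, 0.003)  # volume averaging
    k_dd: Factor = Factor(1.000, 0.002)  # dose-profile non-uniformity

    def __post_init__(self) -> None:
        for name in ("f", "p_wall", "f_h", "k_dd"):
            v = getattr(self, name).value
            if not 0.9 <= v <= 1.1:
                raise ValueError(f"correction factor {name} = {v} outside [0.9, 1.1]")

    @property
    def product(self) -> float:
        return self.f.value * self.p_wall.value * self.f_h.value * self.k_dd.value

    @property
    def product_rel_u(self) -> float:
        """Relative standard uncertainty of the product (quadrature)."""
        return math.sqrt(
            sum(
                (g.u / g.value) ** 2
                for g in (self.f, self.p_wall, self.f_h, self.k_dd)
            )
        )


@dataclass(frozen=True)
class SourceCalibration:
    """Air-kerma strength calibration for the ionometric reference dose."""

    s_k: float  # U = cGy.cm^2/h
    delta_t: float  # h
    lambda_const: float = 1.108  # cGy/(h.U)
    lambda_rel_u_percent: float = 0.13

    def __post_init__(self) -> None:
        if not self.s_k > 0:
            raise ValueError(f"air-kerma strength must be > 0, got {self.s_k}")
        if self.delta_t < 0:
            raise ValueError(f"irradiation time must be >= 0, got {self.delta_t}")
        if not self.lambda_const > 0:
            raise ValueError("dose rate constant must be > 0")


@dataclass(frozen=True)
class DoseResult:
    """Per-run outcome of the Fricke chain, optionally paired with TG-43."""

    run_id: str
    d_fricke: float  # Gy
    d_water: float  # Gy
    d_water_tg43: float | None = None  # Gy
    ratio: float | None = None  # d_water / d_water_tg43
    combined_u_percent: float | None = None
    type_a_percent: float | None = None
    flagged: bool = False


def dose_fricke(dod: DeltaOD, constants: FrickeConstants = FrickeConstants()) -> float:
    """Absorbed dose to the Fricke solution (Gy) from a corrected net OD.

    A non-positive OD yields a flagged non-positive dose with a warning,
    never an exception, so QC stages still see the run.
    """
    if not dod.path_length > 0:
        raise ValueError(f"path length must be > 0 cm, got {dod.path_length}")
    d = dod.value / (
        constants.rho * dod.path_length * constants.epsilon * constants.g_value.value
    )
    if dod.value <= 0 and dod.value != 0:
        warnings.warn(
            f"non-positive delta-OD {dod.value:.4g} gives dose {d:.4g} Gy", stacklevel=2
        )
    return d


def dose_water_fricke(d_fricke: float, cf: CorrectionFactors = CorrectionFactors()) -> float:
    """Absorbed dose to water (Gy): the Fricke dose times the four corrections."""
    if d_fricke < 0:
        warnings.warn(f"negative Fricke dose {d_fricke:.4g} Gy carried through", stacklevel=2)
    return d_fricke * cf.product


def dose_water_tg43(cal: SourceCalibration) -> float:
    """Ionometric reference dose to water at 1 cm (Gy) from S_k, Lambda, dt."""
    return cal.s_k * cal.lambda_const * cal.delta_t / 100.0  # cGy -> Gy


@dataclass(frozen=True)
class MethodComparison:
    """Summary of Fricke vs ionometric doses over paired runs."""

    mean_ratio: float
    sd_ratio: float | None  # absent for a single pair
    n: int
    table: pd.DataFrame  # per-run doses, ratio, residual


def compare_methods(results: Sequence[DoseResult]) -> MethodComparison:
    """Mean and spread of d_water / d_water_tg43 over runs with both doses."""
    paired = [r for r in results if r.d_water_tg43 is not None]
    if not paired:
        raise ValueError("no paired results (d_water_tg43 missing everywhere)")
    ratios = [r.d_water / r.d_water_tg43 for r in paired]
    n = len(ratios)
    mean = sum(ratios) / n
    sd = (
        math.sqrt(sum((x - mean) ** 2 for x in ratios) / (n - 1)) if n >= 2 else None
    )
    table = pd.DataFrame(
        {
            "run_id": [r.run_id for r in paired],
            "d_water_gy": [r.d_water for r in paired],
            "d_water_tg43_gy": [r.d_water_tg43 for r in paired],
            "ratio": ratios,
            "residual_gy": [r.d_water - r.d_water_tg43 for r in paired],
        }
    )
    return MethodComparison(mean_ratio=mean, sd_ratio=sd, n=n, table=table)
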