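"""Packaged constants and their TOML loader.

The defaults shipped in ``data/constants.toml`` hold the full parameter set
of the dose chain: the ferric-yield coefficients, the energy-weighted G
value, the interpolated LET endpoints, the Fricke solution constants, the
four correction factors, the TG-43 dose rate constant and the temperature
coefficients.  Users override any of them by supplying their own file.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .dose import CorrectionFactors, Factor, FrickeConstants
from .spectrophotometry import TemperatureCoefficients
from .yields import GValue, RadiolysisCoefficients

__all__ = ["Constants", "load_constants", "default_coefficients"]


@dataclass(frozen=True)
class Constants:
    """Everything the pipeline needs, bundled."""

    fricke: FrickeConstants
    correction_factors: CorrectionFactors
    temperature: TemperatureCoefficients
    coefficients: dict[str, RadiolysisCoefficients]
    let_linear_fit: float  # keV/um, first-order energy->LET fit
    let_quadratic_fit: float  # keV/um, second-order fit
    lambda_const: float  # cGy/(h.U)
    lambda_rel_u_percent: float
    blank_threshold: float  # AU


def _read_toml(path: str | Path | None) -> dict:
    if path is None:
        raw = (resources.files("frickedose") / "data" / "constants.toml").read_bytes()
        return tomllib.loads(raw.decode())
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def load_constants(path: str | Path | None = None) -> Constants:
    """Load the constants bundle from TOML; with no path, the packaged default."""
    data = _read_toml(path)
    coeffs = {
        row["species"]: RadiolysisCoefficients.from_scaled(
            row["species"], row["alpha"], row["scale"]
        )
        for row in data["yield_coefficients"]
    }
    cf = data["correction_factors"]
    return Constants(
        fricke=FrickeConstants(
            epsilon=float(data["fricke"]["epsilon"]),
            rho=float(data["fricke"]["rho"]),
            g_value=GValue(
                float(data["gvalue"]["value"]),
                float(data["gvalue"]["uncertainty"]),
                method="energy_weighted",
            ),
        ),
        correction_factors=CorrectionFactors(
            f=Factor(*cf["f"]),
            p_wall=Factor(*cf["p_wall"]),
            f_h=Factor(*cf["f_h"]),
            k_dd=Factor(*cf["k_dd"]),
        ),
        temperature=TemperatureCoefficients(
            irradiation=float(data["temperature"]["coeff_irradiation"]),
            reading=float(data["temperature"]["coeff_reading"]),
        ),
        coefficients=coeffs,
        let_linear_fit=float(data["let"]["linear_fit"]),
        let_quadratic_fit=float(data["let"]["quadratic_fit"]),
        lambda_const=float(data["tg43"]["lambda_cgy_per_h_per_u"]),
        lambda_rel_u_percent=float(data["tg43"]["lambda_rel_u_percent"]),
        blank_threshold=float(data["qc"]["blank_threshold_au"]),
    )


def default_coefficients() -> dict[str, RadiolysisCoefficients]:
    """The packaged primary-species coefficient set (expanded scales)."""
    return load_constants().coefficients
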