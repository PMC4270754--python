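"""Radiation chemical yields for the Fricke (ferrous sulfate) dosimeter.

The dosimeter's sensitivity is set by G(Fe3+), the radiation chemical yield of
ferric ions: how many Fe2+ ions are oxidised per unit of absorbed energy.  For
low-LET photons the yield varies slowly with linear energy transfer (LET), and
in aerated 0.4 M H2SO4 each primary water-radiolysis species contributes
through the stoichiometry of the oxidation chain:

    G(Fe3+) = 3*G_H + G_OH + 2*G_H2O2

Each primary yield G_s (molecules per 100 eV) is modelled as a quartic
polynomial in ln(LET), with LET in keV/um:

    G_s(LET) = sum_i alpha_i * (ln LET)**i ,  i = 0..4

The packaged coefficient set applies to aerated 0.4 M sulfuric acid at room
temperature.  This module also provides the unit conversion between
molecules/100 eV and mol/J, polynomial energy->LET interpolation from
literature anchors, and fluence-weighted averaging of a G(E) table over a
photon spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "LET_SUPPORTED_RANGE",
    "MOL_PER_JOULE_PER_MOLEC_100EV",
    "RadiolysisCoefficients",
    "LetValue",
    "LetEnergyAnchor",
    "LetEnergyModel",
    "GValue",
    "SpectrumWeight",
    "primary_yield",
    "ferric_yield",
    "to_mol_per_joule",
    "from_mol_per_joule",
    "fit_let_curve",
    "interpolate_let",
    "weighted_g_value",
]

#: Primary radiolysis species tracked by the ferric-yield combination.
SPECIES = ("H", "OH", "H2O2")

#: LET range (keV/um) over which the quartic parameterisation is trusted;
#: evaluation outside it warns but is not forbidden.
LET_SUPPORTED_RANGE = (0.2, 10.0)

# 1 molecule / 100 eV  ->  mol/J, via the elementary charge (J/eV) and
# Avogadro's number (both exact SI values).
_E_CHARGE = 1.602176634e-19
_N_AVOGADRO = 6.02214076e23
MOL_PER_JOULE_PER_MOLEC_100EV = 1.0 / (100.0 * _E_CHARGE * _N_AVOGADRO)


class DomainError(ValueError):
    """A physically meaningless input (non-positive LET, negative yield...)."""


@dataclass(frozen=True)
class RadiolysisCoefficients:
    """Quartic ln(LET) coefficients for one primary species.

    ``alpha`` is stored fully expanded (no residual column scales); use
    :meth:`from_scaled` when loading values published on mixed scales.
    """

    species: str
    alpha: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if len(self.alpha) != 5:
            raise ValueError(f"exactly 5 coefficients required, got {len(self.alpha)}")
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))

    @classmethod
    def from_scaled(
        cls, species: str, alpha: Sequence[float], scale: Sequence[float]
    ) -> "RadiolysisCoefficients":
        """Expand coefficients published on per-column scales (alpha_i * scale_i)."""
        if len(alpha) != len(scale):
            raise ValueError("alpha and scale must have equal length")
        return cls(species, tuple(a * s for a, s in zip(alpha, scale)))


@dataclass(frozen=True)
class LetValue:
    """Linear energy transfer in keV/um; strictly positive (its log is taken)."""

    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise DomainError(f"LET must be > 0 keV/um, got {self.value}")


@dataclass(frozen=True)
class LetEnergyAnchor:
    """A literature (photon energy, LET) point used to fit the energy->LET curve."""

    energy: float  # MeV
    let: LetValue
    label: str = ""

    def __post_init__(self) -> None:
        if not self.energy > 0:
            raise ValueError(f"anchor energy must be > 0 MeV, got {self.energy}")
        if not isinstance(self.let, LetValue):
            object.__setattr__(self, "let", LetValue(float(self.let)))


@dataclass(frozen=True)
class GValue:
    """A ferric yield in mol/J with optional standard uncertainty."""

    value: float
    uncertainty: float | None = None
    method: str = "user"  # one of {"energy_weighted", "let_formalism", "user"}

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"G value must be > 0 mol/J, got {self.value}")
        if self.uncertainty is not None and self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")
        if self.method not in ("energy_weighted", "let_formalism", "user"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class SpectrumWeight:
    """Relative photon-fluence weight at one energy (e.g. fluence/MeV/100 decays)."""

    energy: float  # MeV
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")


def _as_let(let: LetValue | float) -> LetValue:
    return let if isinstance(let, LetValue) else LetValue(float(let))


def _warn_if_outside_range(let: LetValue) -> None:
    lo, hi = LET_SUPPORTED_RANGE
    if not lo <= let.value <= hi:
        warnings.warn(
            f"LET {let.value} keV/um outside supported range [{lo}, {hi}]; "
            "extrapolating the quartic parameterisation",
            stacklevel=3,
        )


def primary_yield(
    species: str,
    let: LetValue | float,
    coeffs: RadiolysisCoefficients,
) -> float:
    """Yield of one primary species at the given LET, in molecules per 100 eV.

    Evaluates the quartic sum_i alpha_i*(ln LET)**i with the fully expanded
    coefficients.  Raises :class:`DomainError` for non-positive LET and
    ``ValueError`` on a species/coefficient mismatch.
    """
    let = _as_let(let)
    if coeffs.species != species:
        raise ValueError(
            f"coefficients are for {coeffs.species!r}, not requested species {species!r}"
        )
    _warn_if_outside_range(let)
    x = math.log(let.value)
    return float(sum(a * x**i for i, a in enumerate(coeffs.alpha)))


def ferric_yield(
    let: LetValue | float,
    coeff_set: Mapping[str, RadiolysisCoefficients] | Iterable[RadiolysisCoefficients],
) -> float:
    """Ferric-ion yield G(Fe3+) at the given LET, in molecules per 100 eV.

    Combines the primary yields with the aerated-Fricke stoichiometry
    3*G_H + G_OH + 2*G_H2O2.  ``coeff_set`` must cover exactly the species
    H, OH and H2O2.
    """
    if not isinstance(coeff_set, Mapping):
        coeff_set = {c.species: c for c in coeff_set}
    if set(coeff_set) != set(SPECIES):
        raise ValueError(f"coefficient set must cover exactly {set(SPECIES)}, got {set(coeff_set)}")
    g = {s: primary_yield(s, let, coeff_set[s]) for s in SPECIES}
    return 3.0 * g["H"] + g["OH"] + 2.0 * g["H2O2"]


def to_mol_per_joule(g_molecules_per_100ev: float) -> float:
    """Convert a yield from molecules per 100 eV to mol/J."""
    if g_molecules_per_100ev < 0:
        raise DomainError(f"yield must be >= 0, got {g_molecules_per_100ev}")
    return g_molecules_per_100ev * MOL_PER_JOULE_PER_MOLEC_100EV


def from_mol_per_joule(g_mol_per_joule: float) -> float:
    """Inverse of :func:`to_mol_per_joule`."""
    if g_mol_per_joule < 0:
        raise DomainError(f"yield must be >= 0, got {g_mol_per_joule}")
    return g_mol_per_joule / MOL_PER_JOULE_PER_MOLEC_100EV


@dataclass(frozen=True)
class LetEnergyModel:
    """Least-squares polynomial mapping photon energy (MeV) to LET (keV/um)."""

    coefficients: tuple[float, ...]  # ascending powers of energy
    degree: int
    energy_range: tuple[float, float]
    anchors: tuple[LetEnergyAnchor, ...] = field(default=(), repr=False)

    def __call__(self, energy: float) -> float:
        return float(np.polynomial.polynomial.polyval(energy, np.asarray(self.coefficients)))


def fit_let_curve(anchors: Sequence[LetEnergyAnchor], degree: int) -> LetEnergyModel:
    """Fit an energy->LET polynomial of degree 1 or 2 to literature anchors.

    With exactly ``degree + 1`` anchors the fit interpolates them exactly;
    with more it is the ordinary least-squares polynomial.
    """
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    if len(anchors) < degree + 1:
        raise ValueError(f"need at least {degree + 1} anchors for degree {degree}, got {len(anchors)}")
    energies = np.array([a.energy for a in anchors], dtype=float)
    if len(np.unique(energies)) != len(energies):
        raise ValueError("anchor energies must be distinct")
    lets = np.array([a.let.value for a in anchors], dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(energies, lets, degree)
    return LetEnergyModel(
        coefficients=tuple(float(c) for c in coeffs),
        degree=degree,
        energy_range=(float(energies.min()), float(energies.max())),
        anchors=tuple(anchors),
    )


def interpolate_let(model: LetEnergyModel, energy: float) -> LetValue:
    """Evaluate the fitted energy->LET model, warning on extrapolation."""
    lo, hi = model.energy_range
    if not lo <= energy <= hi:
        warnings.warn(
            f"energy {energy} MeV outside anchor range [{lo}, {hi}] MeV; extrapolating",
            stacklevel=2,
        )
    predicted = model(energy)
    if predicted <= 0:
        raise DomainError(
            f"fitted model predicts non-positive LET ({predicted:.4g} keV/um) at "
            f"{energy} MeV; check anchors / fit degree"
        )
    return LetValue(predicted)


def weighted_g_value(
    g_table: Sequence[tuple[float, float]],
    weights: Sequence[SpectrumWeight],
    energy_tol: float = 0.025,
) -> GValue:
    """Photon-fluence-weighted mean of a G(E) table, in mol/J.

    Each spectrum weight is matched to the nearest table energy; a weight whose
    nearest bin lies further than ``energy_tol`` (MeV; default half of a 50 keV
    grid step) is an error.  Returns sum(w_i*G_i)/sum(w_i) tagged as
    ``energy_weighted``.
    """
    if not g_table:
        raise ValueError("empty G table")
    if not weights:
        raise ValueError("empty spectrum weights")
    table_e = np.array([e for e, _ in g_table], dtype=float)
    table_g = np.array([g for _, g in g_table], dtype=float)
    total_w = 0.0
    total_wg = 0.0
    for w in weights:
        idx = int(np.argmin(np.abs(table_e - w.energy)))
        if abs(table_e[idx] - w.energy) > energy_tol:
            raise ValueError(
                f"no table energy within {energy_tol} MeV of spectrum energy {w.energy} MeV"
            )
        total_w += w.weight
        total_wg += w.weight * table_g[idx]
    if total_w <= 0:
        raise ValueError("spectrum weights sum to zero")
    return GValue(total_wg / total_w, method="energy_weighted")
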