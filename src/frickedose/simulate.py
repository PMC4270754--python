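"""Synthetic spectrophotometry experiments for end-to-end pipeline testing.

The generator inverts the dose chain: from a true dose to water it computes
the noiseless corrected OD (dividing out the four correction factors, then
the Fricke sensitivity), re-applies the temperature factors at sampled
irradiation/reading temperatures, and emits schema-valid replicate cuvette
readings with a shared control baseline plus per-reading instrument noise.
Noise therefore enters at the reading level, so the Type A statistics the
pipeline computes downstream are exercised honestly.

Default noise magnitudes emulate the measurement conditions of an HDR
Ir-192 Fricke campaign: per-reading absorbance repeatability of 3e-4 AU
(about 0.45% of the 20 Gy signal), cuvette path lengths known to 0.0005 cm,
and solution temperatures stabilised to a 0.2 degC drift around 25 C.
Recorded temperatures are exact — no thermometer error is modelled — so
temperature drift exercises the correction code path but cancels in
recovery.  Every stream of randomness derives from one explicit seed;
equal seeds give byte-identical campaigns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import Constants, load_constants
from .spectrophotometry import REFERENCE_TEMP_C, CuvetteReading, IrradiationRecord

__all__ = [
    "GENERATOR_VERSION",
    "DEFAULT_DOSE_GRID_GY",
    "DEFAULT_SK_U",
    "NoiseModel",
    "SyntheticExperiment",
    "simulate_run",
    "simulate_campaign",
    "experiments_to_frames",
    "write_campaign",
]

GENERATOR_VERSION = "1.0"

#: Default campaign grid: the operating doses of an HDR Ir-192 Fricke campaign.
DEFAULT_DOSE_GRID_GY = (14.0, 20.0, 30.0, 40.0)

#: Default air-kerma strength, U (a fresh ~10 Ci HDR source).
DEFAULT_SK_U = 40000.0

_OPERATING_BAND_GY = (5.0, 400.0)


@dataclass(frozen=True)
class NoiseModel:
    """Reading-level noise magnitudes; all standard deviations."""

    od_read_sd: float = 3.0e-4  # AU, per-reading repeatability
    path_sd: float = 0.0005  # cm, cuvette path tolerance
    t_irr_drift_sd: float = 0.2  # degC around the 25 C reference
    t_read_drift_sd: float = 0.2  # degC
    control_od_mean: float = 0.050  # AU, unirradiated-solution baseline
    control_od_sd: float = 0.002  # AU, batch-to-batch baseline variation
    blank_od_mean: float = 0.002  # AU, pure-water blank
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("od_read_sd", "path_sd", "t_irr_drift_sd", "t_read_drift_sd",
                     "control_od_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def zero_noise(self) -> "NoiseModel":
        """A copy with every stochastic magnitude set to zero."""
        return NoiseModel(
            od_read_sd=0.0, path_sd=0.0, t_irr_drift_sd=0.0, t_read_drift_sd=0.0,
            control_od_mean=self.control_od_mean, control_od_sd=0.0,
            blank_od_mean=self.blank_od_mean, seed=self.seed,
        )


@dataclass(frozen=True)
class SyntheticExperiment:
    """One simulated irradiation run with its readings and ground truth."""

    true_dose: float  # Gy, dose to water
    readings: tuple[CuvetteReading, ...]
    irradiation: IrradiationRecord
    provenance: dict = field(repr=False)


def _require_valid_dose(true_dose: float) -> None:
    import warnings

    lo, hi = _OPERATING_BAND_GY
    if not lo <= true_dose <= hi:
        warnings.warn(
            f"true dose {true_dose} Gy outside the Fricke operating band [{lo}, {hi}]",
            stacklevel=3,
        )


def simulate_run(
    true_dose: float,
    constants: Constants | None = None,
    noise: NoiseModel = NoiseModel(),
    run_id: str = "run-1",
    n_replicates: int = 2,
    s_k: float = DEFAULT_SK_U,
    rng: np.random.Generator | None = None,
) -> SyntheticExperiment:
    """Simulate one irradiation: replicate cuvettes + control + water blank.

    The irradiation time is chosen so the ionometric (TG-43 point) reference
    reproduces ``true_dose`` exactly, giving downstream comparisons a
    consistent pairing.  With all noise SDs at zero and temperatures pinned
    at 25 C the pipeline recovers ``true_dose`` exactly.
    """
    _require_valid_dose(true_dose)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    constants = constants or load_constants()
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    fk = constants.fricke
    cf = constants.correction_factors
    tc = constants.temperature

    # Invert the chain: dose to water -> Fricke dose -> corrected OD per cm.
    d_fricke = true_dose / cf.product
    dod_per_cm = d_fricke * fk.rho * fk.epsilon * fk.g_value.value

    t_irr = REFERENCE_TEMP_C + rng.normal(0.0, noise.t_irr_drift_sd)
    baseline = noise.control_od_mean + rng.normal(0.0, noise.control_od_sd)

    readings: list[CuvetteReading] = []
    for j in range(n_replicates):
        path = 1.0 + rng.normal(0.0, noise.path_sd)
        t_read = REFERENCE_TEMP_C + rng.normal(0.0, noise.t_read_drift_sd)
        dod_actual = (
            dod_per_cm
            * path
            * (1.0 + tc.irradiation * (t_irr - REFERENCE_TEMP_C))
            * (1.0 + tc.reading * (t_read - REFERENCE_TEMP_C))
        )
        od = baseline + dod_actual + rng.normal(0.0, noise.od_read_sd)
        readings.append(
            CuvetteReading(f"{run_id}-irr{j + 1}", "irradiated", max(od, 0.0), path, t_read)
        )
    # Control: same solution batch, never irradiated.
    path_c = 1.0 + rng.normal(0.0, noise.path_sd)
    t_read_c = REFERENCE_TEMP_C + rng.normal(0.0, noise.t_read_drift_sd)
    od_c = baseline + rng.normal(0.0, noise.od_read_sd)
    readings.append(CuvetteReading(f"{run_id}-ctl", "control", max(od_c, 0.0), path_c, t_read_c))
    # Water blank for instrument QC.
    od_b = noise.blank_od_mean + rng.normal(0.0, noise.od_read_sd)
    readings.append(
        CuvetteReading(f"{run_id}-blk", "water_blank", max(od_b, 0.0), 1.0, REFERENCE_TEMP_C)
    )

    # Irradiation time that delivers true_dose per the ionometric reference.
    delta_t = true_dose * 100.0 / (s_k * constants.lambda_const)
    irr = IrradiationRecord(
        run_id=run_id, t_irr=t_irr, duration=delta_t, nominal_dose=true_dose, s_k=s_k
    )
    provenance = {"noise": asdict(noise), "generator_version": GENERATOR_VERSION}
    return SyntheticExperiment(true_dose, tuple(readings), irr, provenance)


def simulate_campaign(
    dose_grid: Sequence[float] = DEFAULT_DOSE_GRID_GY,
    n_runs_per_dose: int = 3,
    constants: Constants | None = None,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 2,
    s_k: float = DEFAULT_SK_U,
    seed: int | None = None,
) -> list[SyntheticExperiment]:
    """Simulate a full campaign: ``n_runs_per_dose`` runs at every grid dose.

    Per-run random substreams are derived deterministically from the campaign
    seed and the run index (``seed`` defaults to ``noise.seed``).
    """
    if not dose_grid:
        raise ValueError("dose grid must be non-empty")
    if n_runs_per_dose < 1:
        raise ValueError("n_runs_per_dose must be >= 1")
    constants = constants or load_constants()
    campaign_seed = noise.seed if seed is None else seed
    experiments = []
    idx = 0
    for dose in dose_grid:
        for rep in range(n_runs_per_dose):
            rng = np.random.default_rng(np.random.SeedSequence([campaign_seed, idx]))
            experiments.append(
                simulate_run(
                    dose,
                    constants,
                    noise,
                    run_id=f"d{dose:g}-r{rep + 1}",
                    n_replicates=n_replicates,
                    s_k=s_k,
                    rng=rng,
                )
            )
            idx += 1
    return experiments


def experiments_to_frames(
    experiments: Sequence[SyntheticExperiment],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CSV-ready (readings, irradiations) tables for the pipeline readers."""
    readings = pd.DataFrame(
        [
            {
                "run_id": e.irradiation.run_id,
                "cuvette_id": r.cuvette_id,
                "role": r.role,
                "od": r.od,
                "path_length_cm": r.path_length,
                "t_read_c": r.t_read,
            }
            for e in experiments
            for r in e.readings
        ]
    )
    irradiations = pd.DataFrame(
        [
            {
                "run_id": e.irradiation.run_id,
                "t_irr_c": e.irradiation.t_irr,
                "duration_h": e.irradiation.duration,
                "nominal_dose_gy": e.irradiation.nominal_dose,
                "s_k_u": e.irradiation.s_k,
            }
            for e in experiments
        ]
    )
    return readings, irradiations


def write_campaign(experiments: Sequence[SyntheticExperiment], outdir: str | Path) -> None:
    """Write readings.csv, irradiations.csv and truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    readings, irradiations = experiments_to_frames(experiments)
    readings.to_csv(outdir / "readings.csv", index=False)
    irradiations.to_csv(outdir / "irradiations.csv", index=False)
    truth = {
        e.irradiation.run_id: {"true_dose_gy": e.true_dose} for e in experiments
    }
    truth["_provenance"] = experiments[0].provenance if experiments else {}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
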