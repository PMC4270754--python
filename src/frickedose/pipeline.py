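"""End-to-end processing: readings + irradiation records -> per-run doses.

Ties the other modules together: per-run replicate averaging with
temperature correction, the OD -> Fricke-dose -> water-dose chain, the
optional ionometric (air-kerma-strength) reference, and the uncertainty
budget with the measured Type A repeatability injected into its
dose-determination row.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .budget import Budget, combine, inject_type_a, load_budget
from .config import Constants, load_constants
from .dose import (
    DoseResult,
    SourceCalibration,
    compare_methods,
    dose_fricke,
    dose_water_fricke,
    dose_water_tg43,
)
from .spectrophotometry import (
    IrradiationRecord,
    average_replicates,
    blank_qc,
    read_irradiations_csv,
    read_readings_csv,
    readings_to_objects,
)

__all__ = ["process_run", "process_campaign", "process_files", "results_to_frame"]

#: Budget row that receives the measured replicate repeatability.
DOSE_DETERMINATION_LABEL = "Dose determination"


def process_run(
    readings_df: pd.DataFrame,
    irr: IrradiationRecord,
    constants: Constants | None = None,
    budget: Budget | None = None,
) -> DoseResult:
    """Process one run's readings into a :class:`~frickedose.dose.DoseResult`.

    When the run carries an air-kerma strength, the ionometric reference dose
    and the Fricke/ionometric ratio are attached.  The combined uncertainty
    uses the default budget with the run's measured Type A repeatability
    substituted into the dose-determination row (when replicates exist).
    """
    constants = constants or load_constants()
    budget = budget or load_budget()
    irradiated, control, blank = readings_to_objects(readings_df, irr.run_id)
    if blank is not None:
        blank_qc(blank, control, threshold=constants.blank_threshold)
    dod = average_replicates(irradiated, control, irr, constants.temperature)
    d_f = dose_fricke(dod, constants.fricke)
    d_w = dose_water_fricke(d_f, constants.correction_factors)

    d_tg43 = ratio = None
    if irr.s_k is not None:
        cal = SourceCalibration(
            s_k=irr.s_k,
            delta_t=irr.duration,
            lambda_const=constants.lambda_const,
            lambda_rel_u_percent=constants.lambda_rel_u_percent,
        )
        d_tg43 = dose_water_tg43(cal)
        ratio = d_w / d_tg43 if d_tg43 > 0 else None

    run_budget = budget
    if dod.type_a_percent is not None:
        run_budget = inject_type_a(budget, DOSE_DETERMINATION_LABEL, dod.type_a_percent)
    combined = combine(run_budget).combined_percent

    return DoseResult(
        run_id=irr.run_id,
        d_fricke=d_f,
        d_water=d_w,
        d_water_tg43=d_tg43,
        ratio=ratio,
        combined_u_percent=combined,
        type_a_percent=dod.type_a_percent,
        flagged=dod.flagged,
    )


def process_campaign(
    readings_df: pd.DataFrame,
    irradiations_df: pd.DataFrame,
    constants: Constants | None = None,
    budget: Budget | None = None,
) -> list[DoseResult]:
    """Process every run listed in the irradiations table, in order."""
    constants = constants or load_constants()
    budget = budget or load_budget()
    results = []
    for row in irradiations_df.itertuples():
        s_k = getattr(row, "s_k_u", None)
        irr = IrradiationRecord(
            run_id=str(row.run_id),
            t_irr=float(row.t_irr_c),
            duration=float(row.duration_h),
            nominal_dose=float(row.nominal_dose_gy),
            s_k=None if s_k is None or pd.isna(s_k) else float(s_k),
        )
        results.append(process_run(readings_df, irr, constants, budget))
    return results


def process_files(
    readings_path,
    irradiations_path,
    constants_path=None,
    budget_path=None,
) -> list[DoseResult]:
    """File-level convenience wrapper around :func:`process_campaign`."""
    return process_campaign(
        read_readings_csv(readings_path),
        read_irradiations_csv(irradiations_path),
        load_constants(constants_path),
        load_budget(budget_path),
    )


def results_to_frame(results: Sequence[DoseResult]) -> pd.DataFrame:
    """Tabulate per-run results (machine precision; round only for display)."""
    return pd.DataFrame(
        {
            "run_id": [r.run_id for r in results],
            "d_fricke_gy": [r.d_fricke for r in results],
            "d_water_gy": [r.d_water for r in results],
            "d_water_tg43_gy": [r.d_water_tg43 for r in results],
            "ratio": [r.ratio for r in results],
            "combined_u_percent": [r.combined_u_percent for r in results],
            "type_a_percent": [r.type_a_percent for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
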