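"""End-to-end glue: measurements + urine + demographics -> residence -> doses."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .biodist_io import CU64, NuclideConstants, phantom_for_sex
from .bladder_model import VoidingSchedule, bladder_residence, fit_bladder_filling
from .dose_engine import (
    SValueSet,
    compute_doses,
    effective_dose,
    effective_dose_equivalent,
    load_svalue_set,
)
from .residence_accounting import ResidenceTable, assemble_residence
from .tac_kinetics import (
    fit_tac,
    heart_content_residence,
    integrate_fit,
)

__all__ = ["ParticipantResult", "run_participant", "run_cohort"]

_FITTED_REGIONS = ("liver", "kidneys", "spleen", "red_marrow")


@dataclass(frozen=True)
class ParticipantResult:
    participant_id: str
    sex: str
    residence: ResidenceTable
    organ_doses: dict[str, float]
    effective_dose: float
    effective_dose_equivalent: float


def run_participant(
    pid: str,
    sex: str,
    measurements: pd.DataFrame,
    urine: pd.DataFrame,
    model: str = "auto",
    void_interval: float = 2.0,
    nuclide: NuclideConstants = CU64,
    svals: SValueSet | None = None,
) -> ParticipantResult:
    """Fit one participant's TACs and urine, assemble residence, compute doses.

    ``measurements`` columns: region, t, value (concentration per gram, blood
    pool per mL); ``urine`` columns: t, cumulative_fraction.
    """
    phantom = phantom_for_sex(sex)
    taus: dict[str, float] = {}
    for region in _FITTED_REGIONS:
        sub = measurements[measurements["region"] == region]
        if sub.empty:
            raise ValueError(f"{pid}: no measurements for {region}")
        organ_frac = sub["value"].to_numpy() * phantom.organ_masses[region]
        fit = fit_tac(sub["t"].to_numpy(), organ_frac, model=model, region=region)
        taus[region] = integrate_fit(fit, nuclide).tau

    blood = measurements[measurements["region"] == "blood_pool"]
    if blood.empty:
        raise ValueError(f"{pid}: no blood-pool measurements")
    blood_frac = blood["value"].to_numpy() * phantom.total_blood_volume
    blood_fit = fit_tac(blood["t"].to_numpy(), blood_frac, model=model, region="blood_pool")
    blood_tau = integrate_fit(blood_fit, nuclide).tau
    taus["heart_content"] = heart_content_residence(blood_tau, phantom).tau

    bfit = fit_bladder_filling(urine["t"].to_numpy(), urine["cumulative_fraction"].to_numpy())
    retained, excreted = bladder_residence(bfit, VoidingSchedule(void_interval), nuclide)

    residence = assemble_residence(pid, taus, (retained, excreted), nuclide)
    if svals is None:
        svals = load_svalue_set(sex)
    organ_doses = compute_doses(residence.dose_source_taus(), svals)
    return ParticipantResult(
        participant_id=pid,
        sex=sex,
        residence=residence,
        organ_doses=organ_doses,
        effective_dose=effective_dose(organ_doses, sex),
        effective_dose_equivalent=effective_dose_equivalent(organ_doses, sex),
    )


def run_cohort(
    participants: pd.DataFrame,
    measurements: pd.DataFrame,
    urine: pd.DataFrame,
    model: str = "auto",
    void_interval: float = 2.0,
    nuclide: NuclideConstants = CU64,
) -> dict[str, ParticipantResult]:
    """Run the full dosimetry pipeline for every participant in a cohort."""
    svals = {sex: load_svalue_set(sex) for sex in ("male", "female")}
    results: dict[str, ParticipantResult] = {}
    for row in participants.itertuples(index=False):
        pid, sex = str(row.participant_id), str(row.sex)
        results[pid] = run_participant(
            pid,
            sex,
            measurements[measurements["participant_id"] == pid],
            urine[urine["participant_id"] == pid],
            model=model,
            void_interval=void_interval,
            nuclide=nuclide,
            svals=svals[sex],
        )
    return results
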