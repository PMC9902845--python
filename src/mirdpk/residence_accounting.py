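"""Per-participant residence-time table with remainder-of-body mass balance.

The six explicit source regions are liver, kidneys, bladder content, spleen,
red marrow, and heart content.  The bladder-content row is the sum of the
retained (voiding-model) and excreted components; the remainder of body
closes the balance against the no-excretion total-body TIA 1/lambda:

    total     = sum of the six source-region residence times
    remainder = half_life/ln2 - total

so total + remainder = half_life/ln2 always, which for Cu-64 is
12.7/ln2 = 18.32 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .biodist_io import CU64, SOURCE_REGIONS, NuclideConstants

__all__ = ["ResidenceTable", "assemble_residence"]

_ORGAN_REGIONS = ("liver", "kidneys", "spleen", "red_marrow", "heart_content")


@dataclass(frozen=True)
class ResidenceTable:
    """Residence times (hours) for one participant, with accounting rows."""

    participant_id: str
    taus: Mapping[str, float]  # the six source regions
    mird_void: float  # retained bladder-content component
    excreted: float  # voided, non-irradiating component
    nuclide: NuclideConstants = CU64

    @property
    def total(self) -> float:
        return sum(self.taus[r] for r in SOURCE_REGIONS)

    @property
    def remainder(self) -> float:
        return 1.0 / self.nuclide.lambda_phys - self.total

    def dose_source_taus(self) -> dict[str, float]:
        """Source residence times that actually irradiate tissue.

        The bladder-content entry is the retained component only (the voided
        urine leaves the body); the remainder row is added as its own source.
        """
        taus = {r: self.taus[r] for r in _ORGAN_REGIONS}
        taus["bladder_content"] = self.mird_void
        taus["remainder"] = self.remainder
        return taus


def assemble_residence(
    participant_id: str,
    organ_taus: Mapping[str, float],
    bladder: tuple[float, float],
    nuclide: NuclideConstants = CU64,
) -> ResidenceTable:
    """Assemble the residence table from organ fits and the bladder model.

    Parameters
    ----------
    organ_taus
        Residence times for liver, kidneys, spleen, red_marrow, heart_content.
    bladder
        ``(tau_bladder_retained, tau_excreted)`` from the voiding model; the
        bladder-content row is their sum.

    Raises when a region is missing, any residence time is negative, or the
    remainder would be negative (activity balance violated).
    """
    missing = [r for r in _ORGAN_REGIONS if r not in organ_taus]
    if missing:
        raise KeyError(f"missing source region(s): {missing}")
    retained, excreted = bladder
    taus = {r: float(organ_taus[r]) for r in _ORGAN_REGIONS}
    taus["bladder_content"] = float(retained) + float(excreted)
    for region, tau in {**taus, "mird_void": retained, "excreted": excreted}.items():
        if tau < 0:
            raise ValueError(f"{participant_id}: residence time {region} is negative ({tau})")
    table = ResidenceTable(
        participant_id=participant_id,
        taus=taus,
        mird_void=float(retained),
        excreted=float(excreted),
        nuclide=nuclide,
    )
    if table.remainder < -1e-9:
        raise ValueError(
            f"{participant_id}: total residence time {table.total:.3f} h exceeds the "
            f"total-body TIA {1.0 / nuclide.lambda_phys:.3f} h (activity balance violated)"
        )
    return table
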