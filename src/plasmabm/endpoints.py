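"""Response endpoints and blood-count indices.

Durable clinical benefit (DCB) is survival without disease progression —
best response CR, PR or SD — at 24 weeks; everything else observed is
non-durable benefit (NDB).  Patients with rapid progression (progression
and death before the first response assessment) are NDB by definition.
The 24-week landmark is converted to months at 30.44 days/month and is
boundary-inclusive: progression exactly at 24 weeks still meets the
landmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import CohortValidationError
from .types import PatientRecord

DAYS_PER_MONTH = 30.44
LANDMARK_MONTHS = 24 * 7 / DAYS_PER_MONTH  # ~5.52 months
_EPS = 1e-9

DCB = "DCB"
NDB = "NDB"
NOT_EVALUABLE = "not_evaluable"


def classify_dcb(record: PatientRecord) -> str:
    """Classify one patient as DCB / NDB / not_evaluable."""
    if record.rapid_progression_flag:
        return NDB
    if record.best_response == "PD":
        return NDB
    if record.best_response == "NE":
        if record.pfs_months is not None and record.pfs_event \
                and record.pfs_months < LANDMARK_MONTHS - _EPS:
            return NDB
        return NOT_EVALUABLE
    # CR / PR / SD
    if record.pfs_months is None:
        # fall back on the recorded SD duration when no survival time exists
        if record.best_response == "SD" and record.sd_duration_weeks is not None:
            return DCB if record.sd_duration_weeks >= 24 else NDB
        return NOT_EVALUABLE
    if record.pfs_months >= LANDMARK_MONTHS - _EPS:
        return DCB
    if record.pfs_event:
        return NDB
    return NOT_EVALUABLE  # censored before the landmark


@dataclass
class CohortRates:
    """Response bookkeeping over the intention-to-treat denominator."""

    n: int
    orr: float                 # percent, CR + PR
    dcb_rate: float            # percent
    response_counts: dict
    dcb_counts: dict

    @property
    def cbr_components(self) -> dict:
        return {
            "CR": self.response_counts.get("CR", 0),
            "PR": self.response_counts.get("PR", 0),
            "DCB": self.dcb_counts.get(DCB, 0),
        }


def cohort_rates(records: Sequence[PatientRecord]) -> CohortRates:
    """ORR and DCB rate over the full (ITT) denominator."""
    if not records:
        raise CohortValidationError("cohort_rates requires a non-empty cohort")
    n = len(records)
    response_counts: dict[str, int] = {}
    dcb_counts: dict[str, int] = {}
    for r in records:
        response_counts[r.best_response] = response_counts.get(r.best_response, 0) + 1
        cls = classify_dcb(r)
        dcb_counts[cls] = dcb_counts.get(cls, 0) + 1
    responders = response_counts.get("CR", 0) + response_counts.get("PR", 0)
    return CohortRates(
        n=n,
        orr=100.0 * responders / n,
        dcb_rate=100.0 * dcb_counts.get(DCB, 0) / n,
        response_counts=response_counts,
        dcb_counts=dcb_counts,
    )


def blood_indices(record: PatientRecord) -> tuple[float, float, float]:
    """(NLR, dNLR, PLR) from absolute blood counts.

    NLR = ANC / lymphocytes; dNLR = ANC / (WBC - ANC); PLR = platelets /
    lymphocytes.
    """
    for name in ("anc", "wbc", "lymphocytes", "platelets"):
        value = getattr(record, name)
        if value is None or value <= 0:
            raise CohortValidationError(
                f"patient {record.patient_id}: {name} must be present and > 0"
            )
    if record.wbc <= record.anc:
        raise CohortValidationError(
            f"patient {record.patient_id}: WBC must exceed ANC for dNLR"
        )
    nlr = record.anc / record.lymphocytes
    dnlr = record.anc / (record.wbc - record.anc)
    plr = record.platelets / record.lymphocytes
    return nlr, dnlr, plr


def summarize_characteristics(records: Sequence[PatientRecord]) -> dict:
    """Cohort characteristic percentages among tested patients.

    Marker status ``None`` means untested; percentages use the tested
    denominator, as clinical baseline tables do.
    """
    def _tested_rate(attr: str, positive: str) -> tuple[int, int, Optional[float]]:
        tested = [r for r in records if getattr(r, attr) is not None]
        pos = sum(1 for r in tested if getattr(r, attr) == positive)
        pct = 100.0 * pos / len(tested) if tested else None
        return len(tested), pos, pct

    egfr_n, egfr_pos, egfr_pct = _tested_rate("egfr_status", "positive")
    alk_n, alk_pos, alk_pct = _tested_rate("alk_status", "positive")
    pdl1_n, pdl1_high, pdl1_pct = _tested_rate("pd_l1_class", "high")
    return {
        "n": len(records),
        "egfr_tested": egfr_n, "egfr_positive": egfr_pos, "egfr_positive_pct": egfr_pct,
        "alk_tested": alk_n, "alk_positive": alk_pos, "alk_positive_pct": alk_pct,
        "pd_l1_tested": pdl1_n, "pd_l1_high": pdl1_high, "pd_l1_high_pct": pdl1_pct,
    }
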