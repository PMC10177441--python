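"""Core record types for the plasma biomarker pipeline.

Each record corresponds to one row of the three input tables: an annotated
somatic variant candidate at one blood-draw timepoint, one plasma assay
(cfDNA draw), and one patient's clinical outcome row.  VAFs are stored as
fractions in [0, 1] throughout; reporting layers convert to percent where
the convention demands it (hVAF).  Genomic coordinates are 1-based, fully
closed (MAF convention).  Survival times are always in months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import CohortValidationError

TIMEPOINTS = ("C0", "C4", "EOT")
VARIANT_TYPES = ("SNV", "insertion", "deletion")
CONSEQUENCES = ("synonymous", "nonsynonymous", "other")
RESPONSES = ("CR", "PR", "SD", "PD", "NE")


@dataclass
class VariantCall:
    """One annotated somatic variant candidate at one timepoint.

    Population allele-frequency annotations (dbSNP / ExAC / KRGDB) and the
    panel-of-normals flag are pre-joined upstream; ``None`` means the
    variant is absent from that database.
    """

    patient_id: str
    sample_id: str
    timepoint: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    consequence: str
    vaf: float
    dbsnp_af: Optional[float] = None
    exac_af: Optional[float] = None
    krgdb_af: Optional[float] = None
    pon_flag: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise CohortValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.variant_type not in VARIANT_TYPES:
            raise CohortValidationError(
                f"variant_type must be one of {VARIANT_TYPES}, got {self.variant_type!r}"
            )
        if self.consequence not in CONSEQUENCES:
            raise CohortValidationError(
                f"consequence must be one of {CONSEQUENCES}, got {self.consequence!r}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise CohortValidationError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.pos < 1:
            raise CohortValidationError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref == self.alt:
            raise CohortValidationError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple:
        """Variant identity across timepoints: (patient, chrom, pos, ref, alt)."""
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple:
        """Patient-agnostic genomic key, used by the manual-review blocklist."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleAssay:
    """One plasma draw: cfDNA yield, QC state and ctDNA positivity."""

    patient_id: str
    sample_id: str
    timepoint: str
    cfdna_conc_ng_ml: Optional[float] = None
    qc_pass: bool = True
    ctdna_positive: bool = False
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise CohortValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.cfdna_conc_ng_ml is not None and self.cfdna_conc_ng_ml < 0:
            raise CohortValidationError("cfDNA concentration must be >= 0 ng/mL")


@dataclass
class PatientRecord:
    """Clinical covariates, best response and survival endpoints for one patient.

    Times are months; event flags are booleans.  Blood counts (cells/uL) feed
    the NLR / dNLR / PLR indices.
    """

    patient_id: str
    best_response: str
    pfs_months: Optional[float] = None
    pfs_event: bool = False
    os_months: Optional[float] = None
    os_event: bool = False
    sd_duration_weeks: Optional[float] = None
    rapid_progression_flag: bool = False
    response_onset_months: Optional[float] = None
    anc: Optional[float] = None
    wbc: Optional[float] = None
    lymphocytes: Optional[float] = None
    platelets: Optional[float] = None
    pd_l1_class: Optional[str] = None  # "high" / "low_neg"
    egfr_status: Optional[str] = None  # "positive" / "negative"
    alk_status: Optional[str] = None   # "positive" / "negative"

    def __post_init__(self) -> None:
        if self.best_response not in RESPONSES:
            raise CohortValidationError(
                f"best_response must be one of {RESPONSES}, got {self.best_response!r}"
            )
        for name in ("pfs_months", "os_months", "sd_duration_weeks",
                     "response_onset_months"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise CohortValidationError(f"{name} must be >= 0, got {value}")
        if self.pfs_event and self.pfs_months is None:
            raise CohortValidationError(
                f"patient {self.patient_id}: pfs_event=True requires pfs_months"
            )
        if self.os_event and self.os_months is None:
            raise CohortValidationError(
                f"patient {self.patient_id}: os_event=True requires os_months"
            )
        if self.best_response == "NE" and self.response_onset_months is not None:
            raise CohortValidationError(
                f"patient {self.patient_id}: NE response cannot have a response onset"
            )


DYNAMICS_CLASSES = ("increased", "nc_or_decreased", "undefined")


@dataclass
class BiomarkerProfile:
    """Per-patient biomarker values at baseline (C0) and on-treatment (C4/EOT).

    bTMB in Mut/Mb, cfDNA in ng/mL, hVAF in percent, VAFSD as a fraction.
    Ratios are on-treatment / baseline, present only when both values exist
    and the baseline is positive; a ratio strictly above 1 is classed
    "increased", anything else "nc_or_decreased".
    """

    patient_id: str
    btmb_c0: Optional[float] = None
    btmb_on: Optional[float] = None
    cfdna_c0: Optional[float] = None
    cfdna_on: Optional[float] = None
    hvaf_c0: Optional[float] = None
    hvaf_on: Optional[float] = None
    vafsd_c0: Optional[float] = None
    vafsd_on: Optional[float] = None
    ratio_btmb: Optional[float] = None
    ratio_cfdna: Optional[float] = None
    ratio_hvaf: Optional[float] = None
    ratio_vafsd: Optional[float] = None
    dynamics_btmb: str = "undefined"
    dynamics_cfdna: str = "undefined"
    dynamics_hvaf: str = "undefined"
    dynamics_vafsd: str = "undefined"
    group_btmb: Optional[str] = None   # "high" / "low" at C0
    group_cfdna: Optional[str] = None
    group_hvaf: Optional[str] = None
    group_vafsd: Optional[str] = None
    on_timepoint: Optional[str] = None  # which draw filled the on-treatment slot
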