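"""Readers and writers for the variant, assay and clinical tables.

The variant dialect is a minimal MAF-inspired tab-separated table with
pre-joined population-frequency annotations; assay and clinical tables
are plain CSV.  VAF columns must already be fractions in [0, 1] — there
is deliberately no percent auto-detection, since a table of low-VAF
plasma variants is ambiguous between the two conventions.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .config import PanelDefinition, PipelineConfig
from .errors import CohortValidationError, SchemaError
from .types import PatientRecord, SampleAssay, VariantCall

PathLike = Union[str, Path]

# MAF-dialect column -> VariantCall field
MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample_id",
    "Patient_ID": "patient_id",
    "Timepoint": "timepoint",
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Type": "variant_type",
    "Consequence": "consequence",
    "VAF": "vaf",
}
OPTIONAL_MAF_COLUMNS = {
    "dbSNP_AF": "dbsnp_af",
    "ExAC_AF": "exac_af",
    "KRGDB_AF": "krgdb_af",
    "PoN_Flag": "pon_flag",
}
# MAF uses SNP/INS/DEL; internally we say SNV/insertion/deletion
_VTYPE_IN = {"SNP": "SNV", "INS": "insertion", "DEL": "deletion"}
_VTYPE_OUT = {v: k for k, v in _VTYPE_IN.items()}

CLINICAL_COLUMNS = [
    "patient_id", "best_response", "pfs_months", "pfs_event", "os_months",
    "os_event", "sd_duration_weeks", "rapid_progression", "response_onset_months",
    "anc", "wbc", "lymphocytes", "platelets", "pd_l1_class", "egfr_status",
    "alk_status",
]
ASSAY_COLUMNS = [
    "patient_id", "sample_id", "timepoint", "cfdna_conc_ng_ml", "qc_pass",
    "ctdna_positive", "evaluable",
]


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes", "t")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return bool(value)


def read_variant_table(path: PathLike, dialect: str = "maf_min") -> list[VariantCall]:
    """Read a MAF-dialect TSV into :class:`VariantCall` records.

    Raises :class:`SchemaError` naming the first missing mandatory column and
    :class:`CohortValidationError` with the offending row index for bad values.
    """
    if dialect != "maf_min":
        raise ValueError(f"unknown variant dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str},
                     float_precision="round_trip")
    for col in MAF_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"variant table is missing mandatory column {col!r}")
    records: list[VariantCall] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        vaf = float(row["VAF"])
        if not 0.0 <= vaf <= 1.0:
            raise CohortValidationError(
                f"row {idx}: VAF {vaf} outside [0, 1]; VAFs must be fractions"
            )
        try:
            records.append(VariantCall(
                patient_id=str(row["Patient_ID"]),
                sample_id=str(row["Tumor_Sample_Barcode"]),
                timepoint=str(row["Timepoint"]),
                gene=str(row["Hugo_Symbol"]),
                chrom=str(row["Chromosome"]),
                pos=int(row["Start_Position"]),
                ref=str(row["Reference_Allele"]),
                alt=str(row["Tumor_Seq_Allele2"]),
                variant_type=_VTYPE_IN.get(str(row["Variant_Type"]),
                                           str(row["Variant_Type"])),
                consequence=str(row["Consequence"]),
                vaf=vaf,
                dbsnp_af=_opt_float(row.get("dbSNP_AF")),
                exac_af=_opt_float(row.get("ExAC_AF")),
                krgdb_af=_opt_float(row.get("KRGDB_AF")),
                pon_flag=_as_bool(row.get("PoN_Flag")),
            ))
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {idx}: {exc}") from None
    return records


def variants_to_frame(variants: Sequence[VariantCall]) -> pd.DataFrame:
    """Render variants in the MAF dialect (fractions kept as fractions)."""
    rows = []
    for v in variants:
        rows.append({
            "Tumor_Sample_Barcode": v.sample_id,
            "Patient_ID": v.patient_id,
            "Timepoint": v.timepoint,
            "Hugo_Symbol": v.gene,
            "Chromosome": v.chrom,
            "Start_Position": v.pos,
            "Reference_Allele": v.ref,
            "Tumor_Seq_Allele2": v.alt,
            "Variant_Type": _VTYPE_OUT[v.variant_type],
            "Consequence": v.consequence,
            "VAF": v.vaf,
            "dbSNP_AF": v.dbsnp_af,
            "ExAC_AF": v.exac_af,
            "KRGDB_AF": v.krgdb_af,
            "PoN_Flag": v.pon_flag,
        })
    columns = list(MAF_COLUMNS) + list(OPTIONAL_MAF_COLUMNS)
    return pd.DataFrame(rows, columns=columns)


def write_variant_table(variants: Sequence[VariantCall], path: PathLike) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_assay_table(path: PathLike) -> list[SampleAssay]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("patient_id", "sample_id", "timepoint"):
        if col not in df.columns:
            raise SchemaError(f"assay table is missing mandatory column {col!r}")
    records = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        key = (str(row["patient_id"]), str(row["timepoint"]))
        if key in seen:
            raise CohortValidationError(
                f"duplicate assay for patient {key[0]} timepoint {key[1]}"
            )
        seen.add(key)
        records.append(SampleAssay(
            patient_id=str(row["patient_id"]),
            sample_id=str(row["sample_id"]),
            timepoint=str(row["timepoint"]),
            cfdna_conc_ng_ml=_opt_float(row.get("cfdna_conc_ng_ml")),
            qc_pass=_as_bool(row.get("qc_pass", True)),
            ctdna_positive=_as_bool(row.get("ctdna_positive", False)),
            evaluable=_as_bool(row.get("evaluable", True)),
        ))
    return records


def assays_to_frame(assays: Sequence[SampleAssay]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(a, c) for c in ASSAY_COLUMNS} for a in assays],
        columns=ASSAY_COLUMNS,
    )


def write_assay_table(assays: Sequence[SampleAssay], path: PathLike) -> None:
    assays_to_frame(assays).to_csv(path, index=False)


def read_clinical_table(path: PathLike) -> list[PatientRecord]:
    """Read the per-patient clinical CSV.

    Survival times must be months; tables exposing ``*_days`` columns are
    rejected rather than converted, to avoid silent unit errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    day_cols = [c for c in df.columns if c.endswith("_days")]
    if day_cols:
        raise SchemaError(
            f"survival times must be in months; found day-unit columns {day_cols}"
        )
    for col in ("patient_id", "best_response"):
        if col not in df.columns:
            raise SchemaError(f"clinical table is missing mandatory column {col!r}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortValidationError(f"duplicate patient ID {dup!r} in clinical table")

    def _opt_str(value) -> Optional[str]:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return str(value)

    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            best_response=str(row["best_response"]),
            pfs_months=_opt_float(row.get("pfs_months")),
            pfs_event=_as_bool(row.get("pfs_event")),
            os_months=_opt_float(row.get("os_months")),
            os_event=_as_bool(row.get("os_event")),
            sd_duration_weeks=_opt_float(row.get("sd_duration_weeks")),
            rapid_progression_flag=_as_bool(row.get("rapid_progression")),
            response_onset_months=_opt_float(row.get("response_onset_months")),
            anc=_opt_float(row.get("anc")),
            wbc=_opt_float(row.get("wbc")),
            lymphocytes=_opt_float(row.get("lymphocytes")),
            platelets=_opt_float(row.get("platelets")),
            pd_l1_class=_opt_str(row.get("pd_l1_class")),
            egfr_status=_opt_str(row.get("egfr_status")),
            alk_status=_opt_str(row.get("alk_status")),
        ))
    return records


def clinical_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "best_response": r.best_response,
            "pfs_months": r.pfs_months,
            "pfs_event": r.pfs_event,
            "os_months": r.os_months,
            "os_event": r.os_event,
            "sd_duration_weeks": r.sd_duration_weeks,
            "rapid_progression": r.rapid_progression_flag,
            "response_onset_months": r.response_onset_months,
            "anc": r.anc,
            "wbc": r.wbc,
            "lymphocytes": r.lymphocytes,
            "platelets": r.platelets,
            "pd_l1_class": r.pd_l1_class,
            "egfr_status": r.egfr_status,
            "alk_status": r.alk_status,
        })
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def write_clinical_table(records: Sequence[PatientRecord], path: PathLike) -> None:
    clinical_to_frame(records).to_csv(path, index=False)


def read_config(path: PathLike) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "panel" in data and isinstance(data["panel"], dict):
        data["panel"] = PanelDefinition(**data["panel"])
    if "blocklist" in data:
        data["blocklist"] = tuple(tuple(entry) for entry in data["blocklist"])
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path: PathLike) -> None:
    data = config.model_dump()
    data["panel"]["gene_symbols"] = list(data["panel"]["gene_symbols"])
    data["blocklist"] = [list(entry) for entry in data["blocklist"]]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
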