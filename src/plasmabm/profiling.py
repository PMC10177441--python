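"""Gene-level mutation frequencies and baseline/on-treatment variant overlap.

Feeds oncoplot-style frequency tables and sunburst-style overlap
summaries.  Variant identity across timepoints keys on
(patient, chrom, pos, ref, alt); the gene symbol is deliberately left out
of the key so annotation drift between calls cannot split one variant in
two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import VariantCall

logger = logging.getLogger(__name__)

ON_TIMEPOINTS = ("C4", "EOT")


def gene_frequency(
    variants: Sequence[VariantCall],
    patients: Sequence[str],
    groups: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Fraction of patients mutated per gene, overall and per group.

    ``patients`` is the denominator population (typically the
    ctDNA-positive baseline patients); ``groups`` maps patient -> group
    label.  Only baseline (C0) variants count.  Rows are sorted by overall
    frequency, descending; genes with no mutated patient are omitted.
    """
    patients = list(patients)
    denominator = len(patients)
    patient_set = set(patients)
    mutated: dict[str, set[str]] = {}
    for v in variants:
        if v.timepoint != "C0" or v.patient_id not in patient_set:
            continue
        mutated.setdefault(v.gene, set()).add(v.patient_id)

    group_names = sorted(set(groups.values())) if groups else []
    group_members = {
        g: {p for p in patients if groups.get(p) == g} for g in group_names
    } if groups else {}

    rows = []
    for gene, carriers in mutated.items():
        row = {
            "gene": gene,
            "n_mutated": len(carriers),
            "frequency": len(carriers) / denominator if denominator else 0.0,
        }
        for g in group_names:
            members = group_members[g]
            row[f"frequency_{g}"] = (
                len(carriers & members) / len(members) if members else 0.0
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        ["frequency", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass
class OverlapSummary:
    """Baseline/on-treatment partition of one group's distinct variant keys."""

    group: str
    total_variants: int
    c0_only: int
    shared: int
    c4_only: int

    def __post_init__(self) -> None:
        assert self.c0_only + self.shared + self.c4_only == self.total_variants

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.total_variants if self.total_variants else 0.0

    @property
    def pct_c0_only(self) -> float:
        return self._pct(self.c0_only)

    @property
    def pct_shared(self) -> float:
        return self._pct(self.shared)

    @property
    def pct_c4_only(self) -> float:
        return self._pct(self.c4_only)


def timepoint_overlap(
    variants: Sequence[VariantCall],
    paired_patients: Iterable[str],
    group: str = "all",
) -> OverlapSummary:
    """Classify one group's distinct variant keys as C0-only / shared / C4-only.

    Only patients with draws at both timepoints (``paired_patients``)
    enter; variants of unpaired patients are excluded with a log entry.
    Percent denominators are distinct variant keys over the whole group.
    """
    paired = set(paired_patients)
    c0_keys: set[tuple] = set()
    on_keys: set[tuple] = set()
    excluded: set[str] = set()
    for v in variants:
        if v.patient_id not in paired:
            excluded.add(v.patient_id)
            continue
        if v.timepoint == "C0":
            c0_keys.add(v.key)
        elif v.timepoint in ON_TIMEPOINTS:
            on_keys.add(v.key)
    if excluded:
        logger.info("timepoint_overlap(%s): excluded unpaired patients %s",
                    group, sorted(excluded))
    shared = c0_keys & on_keys
    c0_only = c0_keys - on_keys
    c4_only = on_keys - c0_keys
    return OverlapSummary(
        group=group,
        total_variants=len(shared) + len(c0_only) + len(c4_only),
        c0_only=len(c0_only),
        shared=len(shared),
        c4_only=len(c4_only),
    )


def overlap_to_frame(summaries: Sequence[OverlapSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.group,
        "total_variants": s.total_variants,
        "c0_only": s.c0_only,
        "shared": s.shared,
        "c4_only": s.c4_only,
        "pct_c0_only": s.pct_c0_only,
        "pct_shared": s.pct_shared,
        "pct_c4_only": s.pct_c4_only,
    } for s in summaries])


def oncoplot_long_frame(
    variants: Sequence[VariantCall],
    patients: Sequence[str],
) -> pd.DataFrame:
    """Long-format patient x gene x status table for oncoplot rendering."""
    rows = []
    patient_set = set(patients)
    seen = set()
    for v in variants:
        if v.timepoint != "C0" or v.patient_id not in patient_set:
            continue
        key = (v.patient_id, v.gene, v.variant_type)
        if key in seen:
            continue
        seen.add(key)
        rows.append({"patient_id": v.patient_id, "gene": v.gene,
                     "status": v.variant_type})
    return pd.DataFrame(rows, columns=["patient_id", "gene", "status"])
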