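"""Somatic-variant filtering cascade.

Candidate variants carry pre-joined population allele frequencies from
dbSNP, ExAC and a Korean reference database (KRGDB), plus a
panel-of-normals flag.  A candidate is removed iff any rule fires:

* dbSNP AF strictly above 1% ("common" variants),
* ExAC AF at or above 0.001,
* KRGDB AF at or above the same threshold (unpublished; ExAC's reused),
* flagged by the panel of normals,
* listed on the manual-review blocklist.

Absence from a database is evidence of absence and never removes.  The
removal log records the *first* rule that fires in the fixed order
dbSNP -> ExAC -> KRGDB -> PoN -> blocklist; kept-set membership itself
is order-independent.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .config import PipelineConfig
from .types import VariantCall

RULE_DBSNP = "dbSNP"
RULE_EXAC = "ExAC"
RULE_KRGDB = "KRGDB"
RULE_PON = "PoN"
RULE_BLOCKLIST = "blocklist"
RULE_ORDER = (RULE_DBSNP, RULE_EXAC, RULE_KRGDB, RULE_PON, RULE_BLOCKLIST)


def removal_rule(variant: VariantCall, config: PipelineConfig) -> Optional[str]:
    """First filtering rule that removes ``variant``, or None if it is kept."""
    if variant.dbsnp_af is not None and variant.dbsnp_af > config.dbsnp_max_af:
        return RULE_DBSNP
    if variant.exac_af is not None and variant.exac_af >= config.exac_max_af:
        return RULE_EXAC
    if variant.krgdb_af is not None and variant.krgdb_af >= config.krgdb_max_af:
        return RULE_KRGDB
    if variant.pon_flag:
        return RULE_PON
    if variant.site in set(config.blocklist):
        return RULE_BLOCKLIST
    return None


def filter_somatic(
    candidates: Sequence[VariantCall], config: Optional[PipelineConfig] = None
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Apply the cascade; return (kept, removal log) with input order preserved."""
    config = config or PipelineConfig()
    kept: list[VariantCall] = []
    removed: list[tuple[VariantCall, str]] = []
    for v in candidates:
        rule = removal_rule(v, config)
        if rule is None:
            kept.append(v)
        else:
            removed.append((v, rule))
    return kept, removed


def removal_log_frame(removed: Sequence[tuple[VariantCall, str]]) -> pd.DataFrame:
    """Removal log as a CSV-ready frame: variant key plus the rule that fired."""
    rows = [{
        "patient_id": v.patient_id,
        "sample_id": v.sample_id,
        "timepoint": v.timepoint,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "rule": rule,
    } for v, rule in removed]
    return pd.DataFrame(rows, columns=[
        "patient_id", "sample_id", "timepoint", "chrom", "pos", "ref", "alt", "rule",
    ])


def eligible_for_btmb(variant: VariantCall) -> bool:
    """Whether a filtered variant counts toward bTMB.

    bTMB counts whole-exonic SNVs and InDels, synonymous and non-synonymous
    alike; calls annotated "other" (non-exonic, e.g. intronic
    rearrangement-region reads) are excluded.
    """
    return (
        variant.consequence in ("synonymous", "nonsynonymous")
        and variant.variant_type in ("SNV", "insertion", "deletion")
    )
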