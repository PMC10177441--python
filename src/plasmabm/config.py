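"""Panel and pipeline configuration.

The effective exonic footprint of the 118-gene panel is not published;
the default of 0.26 Mb is the value consistent with the anchor that two
eligible variants correspond to a bTMB of 7.7 Mut/Mb (2 / 7.7 = 0.2597 Mb)
and cross-checks against three variants giving 11.5 Mut/Mb.  All bTMB
values scale inversely with this number, so it is exposed here rather
than buried in the arithmetic.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, field_validator

# Synthetic 118-gene lung-cancer panel: the handful of genes the assay is
# known to cover, padded with standard pan-cancer panel genes to the
# documented panel size.  Not the proprietary target list.
DEFAULT_PANEL_GENES: tuple[str, ...] = (
    "TP53", "EGFR", "KRAS", "ALK", "ROS1", "BRAF", "MET", "ERBB2", "ERBB3",
    "ERBB4", "RET", "NTRK1", "NTRK2", "NTRK3", "PIK3CA", "PIK3CB", "PTEN",
    "AKT1", "AKT2", "MTOR", "TSC1", "TSC2", "STK11", "KEAP1", "NFE2L2",
    "NF1", "NF2", "RB1", "CDKN2A", "CDKN2B", "CDK4", "CDK6", "CCND1",
    "CCND2", "CCND3", "CCNE1", "MDM2", "MDM4", "MYC", "MYCN", "MYCL",
    "FGFR1", "FGFR2", "FGFR3", "FGFR4", "FGF3", "FGF4", "FGF19", "IGF1R",
    "KIT", "PDGFRA", "PDGFRB", "VEGFA", "KDR", "FLT1", "FLT3", "FLT4",
    "JAK1", "JAK2", "JAK3", "STAT3", "SMAD4", "SMAD2", "TGFBR1", "TGFBR2",
    "ARID1A", "ARID1B", "ARID2", "SMARCA4", "SMARCB1", "PBRM1", "ATM",
    "ATR", "BRCA1", "BRCA2", "PALB2", "CHEK1", "CHEK2", "RAD51", "MLH1",
    "MSH2", "MSH6", "PMS2", "POLE", "POLD1", "APC", "CTNNB1", "AXIN1",
    "AXIN2", "NOTCH1", "NOTCH2", "NOTCH3", "FBXW7", "PTCH1", "SMO", "GNAS",
    "GNAQ", "GNA11", "HRAS", "NRAS", "RIT1", "MAP2K1", "MAP2K2", "MAPK1",
    "RAF1", "ARAF", "SOS1", "PTPN11", "CBL", "DDR2", "EPHA2", "ESR1", "AR",
    "IDH1", "IDH2", "TERT", "VHL", "KMT2A",
)

DEFAULT_FOOTPRINT_MB = 0.26


class PanelDefinition(BaseModel):
    """Targeted sequencing panel: gene list plus effective exonic footprint."""

    gene_symbols: tuple[str, ...] = DEFAULT_PANEL_GENES
    footprint_mb: float = Field(default=DEFAULT_FOOTPRINT_MB, gt=0.0)

    @field_validator("gene_symbols")
    @classmethod
    def _genes_nonempty_unique(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) == 0:
            raise ValueError("panel gene list must be non-empty")
        if len(set(v)) != len(v):
            raise ValueError("panel gene list must be unique")
        return v


class PipelineConfig(BaseModel):
    """Thresholds, units and rounding rules shared across the pipeline.

    Population-frequency semantics: dbSNP removes strictly above 1% (the
    "common" definition), ExAC removes at or above 0.001, and KRGDB — whose
    threshold is not published — reuses the ExAC threshold.  All three are
    overridable here.
    """

    panel: PanelDefinition = Field(default_factory=PanelDefinition)
    dbsnp_max_af: float = Field(default=0.01, gt=0.0, lt=1.0)
    exac_max_af: float = Field(default=0.001, gt=0.0, lt=1.0)
    krgdb_max_af: float = Field(default=0.001, gt=0.0, lt=1.0)
    # manual-review blocklist of (chrom, pos, ref, alt) sites; empty by default
    blocklist: tuple[tuple[str, int, str, str], ...] = ()
    # sample (n-1) standard deviation for VAFSD by default
    vafsd_ddof: int = Field(default=1, ge=0, le=1)
    # reporting precision: Mut/Mb and percent to 1 decimal, VAFSD to 3
    btmb_decimals: int = 1
    hvaf_decimals: int = 1
    vafsd_decimals: int = 3
    # cutpoint criterion for ROC-derived dichotomization
    cutpoint_criterion: str = "youden"  # or "closest_topleft"
    # covariate entry rule for the multivariate Cox model
    multivariate_entry_p: float = Field(default=0.05, gt=0.0, le=1.0)
    seed: int = 0

    @field_validator("cutpoint_criterion")
    @classmethod
    def _known_criterion(cls, v: str) -> str:
        if v not in ("youden", "closest_topleft"):
            raise ValueError("cutpoint_criterion must be 'youden' or 'closest_topleft'")
        return v
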