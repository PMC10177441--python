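"""The four plasma biomarkers and their on-treatment dynamics.

* bTMB — somatic whole-exonic SNV/InDel count per megabase of panel
  footprint (Mut/Mb).
* cfDNA concentration — ng/mL, straight from the assay table.
* hVAF — the highest variant allele frequency in the sample, in percent;
  a proxy for circulating tumor content.
* VAFSD — the standard deviation of the sample's VAFs (fraction units);
  a surrogate for intratumoral heterogeneity.  Needs at least two
  variants, i.e. bTMB >= 2 / footprint.

Dynamics compare the on-treatment draw (cycle 4, or end of treatment when
treatment stopped earlier) with baseline: ratio = on / C0, classed
"increased" iff the ratio is strictly above 1, otherwise
"nc_or_decreased"; missing values or a zero baseline leave the class
"undefined" and the patient out of dynamics analyses.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .errors import CohortValidationError
from .filtering import eligible_for_btmb
from .types import BiomarkerProfile, SampleAssay, VariantCall

logger = logging.getLogger(__name__)

MARKERS = ("btmb", "cfdna", "hvaf", "vafsd")


def compute_btmb(variants: Sequence[VariantCall], footprint_mb: float) -> float:
    """Mutations per megabase for one sample's eligible variants."""
    if footprint_mb <= 0:
        raise CohortValidationError(f"footprint_mb must be > 0, got {footprint_mb}")
    return len(variants) / footprint_mb


def compute_hvaf(variants: Sequence[VariantCall]) -> Optional[float]:
    """Highest VAF in the sample, in percent; None when no variant exists."""
    if not variants:
        return None
    return 100.0 * max(v.vaf for v in variants)


def compute_vafsd(variants: Sequence[VariantCall], ddof: int = 1) -> Optional[float]:
    """Standard deviation of the sample's VAFs (fraction units).

    Defined only for samples with two or more variants; the default is the
    sample (n-1) standard deviation.
    """
    if len(variants) < 2:
        return None
    return float(np.std([v.vaf for v in variants], ddof=ddof))


def classify_dynamics(
    c0_value: Optional[float], on_value: Optional[float]
) -> tuple[Optional[float], str]:
    """On-treatment / baseline ratio and its class.

    Returns ``(ratio, class)``; ratio is None and the class "undefined"
    when either value is missing or the baseline is zero (a ratio of
    exactly 1 is "nc_or_decreased" — "increased" requires ratio > 1).
    """
    if c0_value is None or on_value is None or c0_value <= 0:
        return None, "undefined"
    ratio = on_value / c0_value
    return ratio, ("increased" if ratio > 1 else "nc_or_decreased")


def round_profile(profile: BiomarkerProfile, config: PipelineConfig) -> BiomarkerProfile:
    """Apply the reporting precision (raw values are kept upstream)."""
    def _r(value, nd):
        return None if value is None else round(value, nd)

    profile.btmb_c0 = _r(profile.btmb_c0, config.btmb_decimals)
    profile.btmb_on = _r(profile.btmb_on, config.btmb_decimals)
    profile.hvaf_c0 = _r(profile.hvaf_c0, config.hvaf_decimals)
    profile.hvaf_on = _r(profile.hvaf_on, config.hvaf_decimals)
    profile.vafsd_c0 = _r(profile.vafsd_c0, config.vafsd_decimals)
    profile.vafsd_on = _r(profile.vafsd_on, config.vafsd_decimals)
    return profile


def _sample_markers(
    assay: SampleAssay,
    variants: Sequence[VariantCall],
    config: PipelineConfig,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(btmb, hvaf, vafsd) for one draw; all None when ctDNA-negative."""
    if not assay.ctdna_positive:
        return None, None, None
    eligible = [v for v in variants if eligible_for_btmb(v)]
    btmb = compute_btmb(eligible, config.panel.footprint_mb)
    hvaf = compute_hvaf(variants)
    vafsd = compute_vafsd(variants, ddof=config.vafsd_ddof)
    return btmb, hvaf, vafsd


def build_profiles(
    variants: Sequence[VariantCall],
    assays: Sequence[SampleAssay],
    config: Optional[PipelineConfig] = None,
) -> list[BiomarkerProfile]:
    """One profile per patient in the cfDNA biomarker-evaluable population.

    A patient enters the BEP when the baseline draw passed QC and is
    evaluable.  Variant-derived markers are populated only for
    ctDNA-positive draws, so the eligibility sets nest: VAFSD-evaluable
    (>= 2 variants) within hVAF/bTMB-evaluable (ctDNA-positive) within
    cfDNA-evaluable.  The on-treatment slot prefers the cycle-4 draw and
    falls back to end-of-treatment.
    """
    config = config or PipelineConfig()

    by_sample: dict[tuple[str, str], SampleAssay] = {}
    for a in assays:
        key = (a.patient_id, a.timepoint)
        if key in by_sample:
            raise CohortValidationError(
                f"duplicate sample for patient {a.patient_id} timepoint {a.timepoint}"
            )
        by_sample[key] = a

    variants_by_sample: dict[str, list[VariantCall]] = {}
    for v in variants:
        variants_by_sample.setdefault(v.sample_id, []).append(v)

    patients = sorted({a.patient_id for a in assays})
    profiles: list[BiomarkerProfile] = []
    for pid in patients:
        c0 = by_sample.get((pid, "C0"))
        if c0 is None or not c0.qc_pass or not c0.evaluable:
            continue  # outside the cfDNA BEP
        profile = BiomarkerProfile(patient_id=pid)
        profile.cfdna_c0 = c0.cfdna_conc_ng_ml
        (profile.btmb_c0, profile.hvaf_c0, profile.vafsd_c0) = _sample_markers(
            c0, variants_by_sample.get(c0.sample_id, []), config)

        on = by_sample.get((pid, "C4")) or by_sample.get((pid, "EOT"))
        if on is not None and on.qc_pass and on.evaluable:
            profile.on_timepoint = on.timepoint
            profile.cfdna_on = on.cfdna_conc_ng_ml
            (profile.btmb_on, profile.hvaf_on, profile.vafsd_on) = _sample_markers(
                on, variants_by_sample.get(on.sample_id, []), config)

        for marker in MARKERS:
            c0_val = getattr(profile, f"{marker}_c0")
            on_val = getattr(profile, f"{marker}_on")
            ratio, cls = classify_dynamics(c0_val, on_val)
            if c0_val is not None and on_val is not None and ratio is None:
                logger.info("patient %s: %s ratio undefined (baseline 0)", pid, marker)
            setattr(profile, f"ratio_{marker}", ratio)
            setattr(profile, f"dynamics_{marker}", cls)
        profiles.append(profile)
    return profiles


def assign_baseline_groups(
    profiles: Iterable[BiomarkerProfile],
    cutoffs: dict[str, float],
) -> None:
    """Label each profile high/low per marker at baseline, in place.

    ``cutoffs`` maps marker name -> threshold; a value at or above the
    threshold is "high" (ties to the high group), missing values stay
    unlabelled.
    """
    for profile in profiles:
        for marker, cutoff in cutoffs.items():
            value = getattr(profile, f"{marker}_c0")
            if value is None:
                continue
            setattr(profile, f"group_{marker}", "high" if value >= cutoff else "low")


def profiles_to_frame(profiles: Sequence[BiomarkerProfile]):
    """Biomarker table: one row per BEP patient."""
    import pandas as pd

    columns = ["patient_id"]
    for m in MARKERS:
        columns += [f"{m}_c0", f"{m}_on", f"ratio_{m}", f"dynamics_{m}", f"group_{m}"]
    columns.append("on_timepoint")
    return pd.DataFrame(
        [{c: getattr(p, c) for c in columns} for p in profiles], columns=columns
    )
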