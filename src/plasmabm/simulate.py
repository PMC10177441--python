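"""Synthetic cohort generator.

Emulates the statistical structure of a second-line immunotherapy trial
cohort with paired baseline (C0) and on-treatment (C4, or EOT when
treatment stopped early) plasma draws:

* each patient carries a latent benefit class (DCB / NDB) with configured
  prevalence;
* somatic variants follow a clonal model — VAF = clone fraction x tumor
  fraction / 2 (diploid heterozygous variants) plus Gaussian read noise —
  so VAF dispersion (VAFSD) grows with clonal heterogeneity;
* on-treatment VAFs are the baseline VAFs scaled by a per-class shrinkage
  factor (below 1 for DCB, above 1 for NDB by default), with variants
  falling under the detection limit dropping out and NDB patients gaining
  emergent on-treatment-only variants;
* germline/artifact contaminants carry population-database annotations or
  panel-of-normals flags on the removal side of each threshold, so the
  filtering cascade has real work to do;
* progression-free and overall survival come from an exponential
  proportional-hazards model with configurable hazard ratios on the truth
  factors, under administrative (uniform follow-up) plus light random
  dropout censoring;
* the best RECIST response is assigned consistently with the *realized*
  progression time, so the observed DCB classification agrees with the
  landmark definition while the hazard model stays strictly proportional.

QC-failed and non-evaluable baseline draws are assigned by count, not
rate, to mirror exclusion bookkeeping exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import DEFAULT_PANEL_GENES
from .endpoints import DAYS_PER_MONTH, LANDMARK_MONTHS
from .errors import CohortValidationError
from .types import PatientRecord, SampleAssay, VariantCall

_BASES = ("A", "C", "G", "T")


def default_gene_weights() -> dict[str, float]:
    """TP53-dominant mutation probabilities over the default panel."""
    named = {
        "TP53": 0.30, "EGFR": 0.05, "KRAS": 0.05, "CDKN2A": 0.03,
        "ARID1A": 0.03, "NF1": 0.025, "PIK3CA": 0.025, "JAK2": 0.015,
        "NFE2L2": 0.015, "RB1": 0.015,
    }
    rest = [g for g in DEFAULT_PANEL_GENES if g not in named]
    remaining = 1.0 - sum(named.values())
    weights = dict(named)
    for g in rest:
        weights[g] = remaining / len(rest)
    return weights


class GroupValue(BaseModel):
    """A per-class (DCB / NDB) parameter pair."""

    dcb: float
    ndb: float

    def get(self, latent_class: str) -> float:
        return self.dcb if latent_class == "DCB" else self.ndb


class LogNormalParams(BaseModel):
    """Lognormal parameters on the natural-log scale."""

    mu: float
    sigma: float = Field(gt=0.0)


class SimulationConfig(BaseModel):
    """Generator parameters; defaults emulate the study conditions.

    Sample-size bookkeeping (100 patients, 11 QC failures, 3 non-evaluable
    draws, 25% benefit prevalence, ~75% ctDNA detection and on-treatment
    pairing) follows the trial's reported flow; distributional parameters
    (cfDNA lognormals, tumor fractions, shrinkage, emergent-variant rates)
    are free choices documented in the methods note, not study claims.
    """

    n_patients: int = Field(default=100, ge=1)
    dcb_prevalence: float = Field(default=0.25, ge=0.0, le=1.0)
    qc_fail_n: int = Field(default=11, ge=0)
    non_evaluable_n: int = Field(default=3, ge=0)
    c4_sample_prob: float = Field(default=0.75, ge=0.0, le=1.0)
    eot_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    ctdna_detect_prob: GroupValue = GroupValue(dcb=0.65, ndb=0.78)
    cfdna_lognormal_dcb: LogNormalParams = LogNormalParams(mu=math.log(5.5), sigma=0.55)
    cfdna_lognormal_ndb: LogNormalParams = LogNormalParams(mu=math.log(12.0), sigma=0.65)
    cfdna_c4_factor: GroupValue = GroupValue(dcb=0.85, ndb=1.35)
    cfdna_c4_noise_sigma: float = Field(default=0.2, ge=0.0)
    n_clones_range: tuple[int, int] = (1, 6)
    tumor_fraction_dcb: LogNormalParams = LogNormalParams(mu=math.log(0.05), sigma=0.7)
    tumor_fraction_ndb: LogNormalParams = LogNormalParams(mu=math.log(0.15), sigma=0.8)
    tumor_fraction_max: float = Field(default=0.6, gt=0.0, le=1.0)
    c4_shrinkage_factor: GroupValue = GroupValue(dcb=0.4, ndb=1.5)
    emergent_variant_rate: GroupValue = GroupValue(dcb=0.1, ndb=0.8)
    vaf_noise_sd: float = Field(default=0.002, ge=0.0)
    detection_limit_vaf: float = Field(default=0.005, gt=0.0)
    gene_weights: Optional[dict[str, float]] = None
    contaminant_rate: float = Field(default=1.0, ge=0.0)
    # hazard multipliers on truth factors; absent factor = no effect
    hazard_ratios: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "ndb": {"pfs": 15.0, "os": 2.5},
            "cfdna_high": {"pfs": 1.5, "os": 1.5},
        }
    )
    baseline_pfs_median_months: float = Field(default=24.0, gt=0.0)
    baseline_os_residual_median_months: float = Field(default=30.0, gt=0.0)
    cfdna_high_threshold: float = Field(default=8.6, gt=0.0)
    censoring_rate: float = Field(default=0.1, ge=0.0, lt=1.0)
    followup_months_range: tuple[float, float] = (6.0, 24.0)
    pr_prob_dcb: float = Field(default=0.4, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.qc_fail_n + self.non_evaluable_n >= self.n_patients:
            raise ValueError(
                "qc_fail_n + non_evaluable_n must be smaller than n_patients"
            )
        lo, hi = self.n_clones_range
        if not (1 <= lo <= hi):
            raise ValueError("n_clones_range must satisfy 1 <= lo <= hi")
        if self.followup_months_range[0] > self.followup_months_range[1]:
            raise ValueError("followup_months_range must be ordered")
        if self.gene_weights is not None:
            total = sum(self.gene_weights.values())
            if not math.isclose(total, 1.0, rel_tol=1e-6):
                raise ValueError("gene_weights must sum to 1")
        return self


class CohortTables(NamedTuple):
    variants: list[VariantCall]
    assays: list[SampleAssay]
    clinical: list[PatientRecord]
    truth: pd.DataFrame


def _random_site(rng: np.random.Generator, used: set) -> tuple[str, int, str, str, str]:
    """A fresh (chrom, pos, ref, alt, variant_type) not colliding in ``used``."""
    while True:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1, 200_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        break
    if rng.random() < 0.85:
        vtype = "SNV"
        ref, alt = rng.choice(_BASES, size=2, replace=False)
    elif rng.random() < 0.5:
        vtype = "insertion"
        ref = str(rng.choice(_BASES))
        alt = ref + str(rng.choice(_BASES))
    else:
        vtype = "deletion"
        alt = str(rng.choice(_BASES))
        ref = alt + str(rng.choice(_BASES))
    return chrom, pos, str(ref), str(alt), vtype


def _consequence(rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.70:
        return "nonsynonymous"
    if u < 0.95:
        return "synonymous"
    return "other"


def generate_cohort(config: SimulationConfig) -> CohortTables:
    """Draw one full synthetic cohort; all randomness flows from config.seed."""
    rng = np.random.default_rng(config.seed)
    weights = config.gene_weights or default_gene_weights()
    genes = np.array(list(weights))
    gene_p = np.array([weights[g] for g in genes], dtype=float)
    gene_p = gene_p / gene_p.sum()

    n = config.n_patients
    pids = [f"P{i + 1:04d}" for i in range(n)]
    latent = np.where(rng.random(n) < config.dcb_prevalence, "DCB", "NDB")

    flagged = rng.choice(n, size=config.qc_fail_n + config.non_evaluable_n,
                         replace=False)
    qc_fail = set(flagged[:config.qc_fail_n].tolist())
    non_eval = set(flagged[config.qc_fail_n:].tolist())

    ln2 = math.log(2.0)
    lam_pfs0 = ln2 / config.baseline_pfs_median_months
    lam_os0 = ln2 / config.baseline_os_residual_median_months
    dropout_lam = 0.0
    if config.censoring_rate > 0:
        # dropout hazard sized so roughly censoring_rate of patients drop
        # out within a year, on top of administrative follow-up limits
        dropout_lam = -math.log(1.0 - config.censoring_rate) / 12.0

    variants: list[VariantCall] = []
    assays: list[SampleAssay] = []
    clinical: list[PatientRecord] = []
    truth_rows: list[dict] = []

    for i, pid in enumerate(pids):
        g = str(latent[i])
        glabel = "DCB" if g == "DCB" else "NDB"
        used_sites: set = set()

        # --- baseline assay ---------------------------------------------
        cf_params = (config.cfdna_lognormal_dcb if glabel == "DCB"
                     else config.cfdna_lognormal_ndb)
        cfdna_c0 = float(rng.lognormal(cf_params.mu, cf_params.sigma))
        cfdna_high = cfdna_c0 > config.cfdna_high_threshold
        ctdna_pos = bool(rng.random() < config.ctdna_detect_prob.get(glabel))

        # --- clonal structure and baseline variants ---------------------
        tf_params = (config.tumor_fraction_dcb if glabel == "DCB"
                     else config.tumor_fraction_ndb)
        tumor_fraction = min(float(rng.lognormal(tf_params.mu, tf_params.sigma)),
                             config.tumor_fraction_max)
        lo, hi = config.n_clones_range
        n_clones = int(rng.integers(lo, hi + 1))
        clone_fracs = rng.dirichlet(np.ones(n_clones))

        c0_sample = f"{pid}-C0"
        c0_vafs: list[tuple] = []  # (site record, baseline vaf)
        if ctdna_pos:
            for frac in clone_fracs:
                vaf = frac * tumor_fraction / 2.0
                vaf += rng.normal(0.0, config.vaf_noise_sd)
                vaf = float(np.clip(vaf, config.detection_limit_vaf, 1.0))
                site = _random_site(rng, used_sites)
                gene = str(rng.choice(genes, p=gene_p))
                c0_vafs.append((site, gene, vaf))
                variants.append(VariantCall(
                    patient_id=pid, sample_id=c0_sample, timepoint="C0",
                    gene=gene, chrom=site[0], pos=site[1], ref=site[2],
                    alt=site[3], variant_type=site[4],
                    consequence=_consequence(rng), vaf=vaf,
                ))

        # --- on-treatment draw ------------------------------------------
        has_on = bool(rng.random() < config.c4_sample_prob)
        on_tp = None
        on_somatic: list[tuple] = []
        cfdna_on = None
        if has_on:
            on_tp = "EOT" if rng.random() < config.eot_fraction else "C4"
            on_sample = f"{pid}-{on_tp}"
            cfdna_on = cfdna_c0 * config.cfdna_c4_factor.get(glabel) * float(
                rng.lognormal(0.0, config.cfdna_c4_noise_sigma))
            shrink = config.c4_shrinkage_factor.get(glabel)
            for site, gene, vaf0 in c0_vafs:
                vaf = vaf0 * shrink + rng.normal(0.0, config.vaf_noise_sd)
                if vaf < config.detection_limit_vaf:
                    continue  # fell under the detection limit: C0-only
                on_somatic.append((site, gene, float(min(vaf, 1.0))))
            n_emergent = int(rng.poisson(config.emergent_variant_rate.get(glabel)))
            for _ in range(n_emergent):
                site = _random_site(rng, used_sites)
                gene = str(rng.choice(genes, p=gene_p))
                vaf = float(np.clip(rng.lognormal(math.log(0.01), 0.5),
                                    config.detection_limit_vaf, 0.3))
                on_somatic.append((site, gene, vaf))
            for site, gene, vaf in on_somatic:
                variants.append(VariantCall(
                    patient_id=pid, sample_id=on_sample, timepoint=on_tp,
                    gene=gene, chrom=site[0], pos=site[1], ref=site[2],
                    alt=site[3], variant_type=site[4],
                    consequence=_consequence(rng), vaf=vaf,
                ))

        # --- contaminants (germline / artifact candidates) --------------
        n_contam = int(rng.poisson(config.contaminant_rate))
        for _ in range(n_contam):
            site = _random_site(rng, used_sites)
            gene = str(rng.choice(genes, p=gene_p))
            vaf = float(rng.uniform(0.3, 0.6))
            kind = int(rng.integers(0, 4))
            ann = dict(dbsnp_af=None, exac_af=None, krgdb_af=None, pon_flag=False)
            if kind == 0:
                ann["dbsnp_af"] = float(rng.uniform(0.011, 0.5))
            elif kind == 1:
                ann["exac_af"] = float(rng.uniform(0.001, 0.05))
            elif kind == 2:
                ann["krgdb_af"] = float(rng.uniform(0.001, 0.05))
            else:
                ann["pon_flag"] = True
            consequence = _consequence(rng)
            for tp, sample in ([("C0", c0_sample)]
                               + ([(on_tp, f"{pid}-{on_tp}")] if has_on else [])):
                variants.append(VariantCall(
                    patient_id=pid, sample_id=sample, timepoint=tp, gene=gene,
                    chrom=site[0], pos=site[1], ref=site[2], alt=site[3],
                    variant_type=site[4], consequence=consequence, vaf=vaf, **ann,
                ))

        # --- assays ------------------------------------------------------
        assays.append(SampleAssay(
            patient_id=pid, sample_id=c0_sample, timepoint="C0",
            cfdna_conc_ng_ml=cfdna_c0, qc_pass=i not in qc_fail,
            ctdna_positive=ctdna_pos and len(c0_vafs) > 0,
            evaluable=i not in non_eval,
        ))
        if has_on:
            assays.append(SampleAssay(
                patient_id=pid, sample_id=f"{pid}-{on_tp}", timepoint=on_tp,
                cfdna_conc_ng_ml=cfdna_on, qc_pass=True,
                ctdna_positive=len(on_somatic) > 0, evaluable=True,
            ))

        # --- survival under exponential proportional hazards -------------
        factors = {"ndb": glabel == "NDB", "cfdna_high": cfdna_high}
        hr_pfs = hr_os = 1.0
        for name, hrs in config.hazard_ratios.items():
            if factors.get(name, False):
                hr_pfs *= hrs.get("pfs", 1.0)
                hr_os *= hrs.get("os", 1.0)
        t_pfs = float(rng.exponential(1.0 / (lam_pfs0 * hr_pfs)))
        t_os = t_pfs + float(rng.exponential(1.0 / (lam_os0 * hr_os)))
        censor = float(rng.uniform(*config.followup_months_range))
        if dropout_lam > 0:
            censor = min(censor, float(rng.exponential(1.0 / dropout_lam)))
        pfs_months = min(t_pfs, censor)
        pfs_event = t_pfs <= censor
        os_months = min(t_os, censor)
        os_event = t_os <= censor

        # --- best response consistent with the realized progression time -
        rapid = False
        sd_weeks = None
        onset = None
        if pfs_months < 2.0 and not pfs_event:
            response = "NE"  # lost before the first assessment, no event
        elif t_pfs >= LANDMARK_MONTHS and pfs_months >= LANDMARK_MONTHS:
            pr_prob = config.pr_prob_dcb if glabel == "DCB" else 0.1
            if rng.random() < pr_prob:
                response = "PR"
                onset = 2.1
            else:
                response = "SD"
                sd_weeks = t_pfs * DAYS_PER_MONTH / 7.0
        elif not pfs_event:
            # censored before the landmark with no progression seen: the
            # last assessment showed stable disease
            response = "SD"
            sd_weeks = pfs_months * DAYS_PER_MONTH / 7.0
        else:
            if t_pfs < 1.0 and os_event and rng.random() < 0.5:
                response = "PD"
                rapid = True
            elif rng.random() < 0.75:
                response = "PD"
            else:
                response = "SD"
                sd_weeks = t_pfs * DAYS_PER_MONTH / 7.0

        wbc = float(rng.normal(7500.0, 1500.0))
        wbc = max(wbc, 2500.0)
        anc_frac = float(rng.uniform(0.45, 0.75))
        lym_frac = float(rng.uniform(0.12, min(0.35, 0.9 - anc_frac)))
        pd_l1 = None
        if rng.random() < 0.95:
            pd_l1 = "high" if rng.random() < 0.368 else "low_neg"
        egfr = None
        if rng.random() < 0.80:
            egfr = "positive" if rng.random() < 0.138 else "negative"
        alk = None
        if rng.random() < 0.74:
            alk = "positive" if rng.random() < 0.014 else "negative"

        clinical.append(PatientRecord(
            patient_id=pid, best_response=response,
            pfs_months=pfs_months, pfs_event=pfs_event,
            os_months=os_months, os_event=os_event,
            sd_duration_weeks=sd_weeks, rapid_progression_flag=rapid,
            response_onset_months=onset,
            anc=wbc * anc_frac, wbc=wbc, lymphocytes=wbc * lym_frac,
            platelets=max(float(rng.normal(280_000.0, 60_000.0)), 30_000.0),
            pd_l1_class=pd_l1, egfr_status=egfr, alk_status=alk,
        ))

        truth_rows.append({
            "patient_id": pid, "latent_class": glabel,
            "tumor_fraction": tumor_fraction, "n_clones": n_clones,
            "cfdna_c0": cfdna_c0, "cfdna_high": cfdna_high,
            "ctdna_positive_c0": ctdna_pos and len(c0_vafs) > 0,
            "has_on_sample": has_on, "on_timepoint": on_tp,
            "t_pfs": t_pfs, "t_os": t_os, "censor_time": censor,
            "qc_fail": i in qc_fail, "non_evaluable": i in non_eval,
        })

    truth = pd.DataFrame(truth_rows)
    return CohortTables(variants=variants, assays=assays, clinical=clinical,
                        truth=truth)


def make_filter_fixture(
    n_somatic: int,
    n_dbsnp: int,
    n_exac: int,
    n_krgdb: int,
    n_pon: int,
    seed: int = 0,
) -> list[VariantCall]:
    """Variant table with exactly the requested count per removal category.

    Annotations sit strictly on the removal side of each threshold
    (dbSNP AF > 1%, ExAC/KRGDB AF >= 0.001, PoN flag set); categories are
    mutually exclusive, so the first ``n_somatic`` rows survive the
    filtering cascade and the rest are each removed by exactly one rule.
    """
    for name, count in (("n_somatic", n_somatic), ("n_dbsnp", n_dbsnp),
                        ("n_exac", n_exac), ("n_krgdb", n_krgdb),
                        ("n_pon", n_pon)):
        if count < 0:
            raise CohortValidationError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    used: set = set()
    out: list[VariantCall] = []

    def _make(idx: int, **ann) -> VariantCall:
        site = _random_site(rng, used)
        return VariantCall(
            patient_id="PFIX", sample_id="PFIX-C0", timepoint="C0",
            gene="TP53", chrom=site[0], pos=site[1], ref=site[2], alt=site[3],
            variant_type=site[4], consequence="nonsynonymous",
            vaf=float(rng.uniform(0.01, 0.3)), **ann,
        )

    idx = 0
    for _ in range(n_somatic):
        # below every threshold: annotated but on the keep side
        out.append(_make(idx, dbsnp_af=float(rng.uniform(0.0, 0.01)),
                         exac_af=float(rng.uniform(0.0, 0.0009)),
                         krgdb_af=None, pon_flag=False))
        idx += 1
    for _ in range(n_dbsnp):
        out.append(_make(idx, dbsnp_af=float(rng.uniform(0.011, 0.5))))
        idx += 1
    for _ in range(n_exac):
        out.append(_make(idx, exac_af=float(rng.uniform(0.001, 0.05))))
        idx += 1
    for _ in range(n_krgdb):
        out.append(_make(idx, krgdb_af=float(rng.uniform(0.001, 0.05))))
        idx += 1
    for _ in range(n_pon):
        out.append(_make(idx, pon_flag=True))
        idx += 1
    return out
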