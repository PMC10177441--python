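"""Statsmodels-style entry point: a study object fitted to the three tables.

``BiomarkerStudy`` bundles the variant, assay and clinical tables with a
:class:`~plasmabm.config.PipelineConfig`; ``fit()`` runs the whole
analysis — filtering cascade, biomarker profiles, response endpoints,
ROC/median cutpoints, group comparisons, Kaplan-Meier / Cox survival
models and the two-factor risk stratification — and returns a
``StudyResults`` object with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .biomarkers import (MARKERS, assign_baseline_groups, build_profiles,
                         profiles_to_frame)
from .config import PipelineConfig
from .endpoints import DCB, NDB, CohortRates, classify_dcb, cohort_rates
from .errors import CohortValidationError
from .filtering import filter_somatic, removal_log_frame
from .profiling import (OverlapSummary, gene_frequency, overlap_to_frame,
                        timepoint_overlap)
from .stats import (ComparisonResult, RocResult, SurvivalFit, fit_survival,
                    median_split, roc_optimal_cutoff, stratify_two_factor)
from .types import BiomarkerProfile, PatientRecord, SampleAssay, VariantCall

logger = logging.getLogger(__name__)

# markers where a low baseline value is the favorable side
LOW_FAVORABLE = ("cfdna", "hvaf", "vafsd")


@dataclass
class StudyResults:
    """Fitted study: estimates, cutpoints, survival fits, diagnostics."""

    config: PipelineConfig
    profiles: list[BiomarkerProfile]
    removal_log: pd.DataFrame
    rates: CohortRates
    dcb_class: dict[str, str]
    cutoffs: dict[str, float]
    roc: dict[str, Optional[RocResult]]
    baseline_tests: dict[str, Optional[ComparisonResult]]
    ratio_tests: dict[str, Optional[ComparisonResult]]
    survival_pfs: dict[str, Optional[SurvivalFit]]
    survival_os: dict[str, Optional[SurvivalFit]]
    multivariate_pfs: Optional[pd.DataFrame]
    multivariate_os: Optional[pd.DataFrame]
    stratification: pd.DataFrame
    stratification_fits: dict[int, SurvivalFit]
    gene_frequencies: pd.DataFrame
    overlaps: list[OverlapSummary]

    @property
    def profile_frame(self) -> pd.DataFrame:
        return profiles_to_frame(self.profiles)

    @property
    def overlap_frame(self) -> pd.DataFrame:
        return overlap_to_frame(self.overlaps)

    def summary(self) -> str:
        """Human-readable report of the main estimates."""
        lines = [
            "Plasma biomarker study summary",
            "=" * 34,
            f"Patients (ITT): {self.rates.n}",
            f"cfDNA BEP profiles: {len(self.profiles)}",
            f"ORR: {self.rates.orr:.1f}%   DCB rate: {self.rates.dcb_rate:.1f}%",
            "",
            "Baseline cutoffs (C0):",
        ]
        for marker, cutoff in self.cutoffs.items():
            roc = self.roc.get(marker)
            if roc is not None:
                lines.append(f"  {marker:6s} {cutoff:8.3f}  (ROC AUC {roc.auc:.3f})")
            else:
                lines.append(f"  {marker:6s} {cutoff:8.3f}  (median split)")
        lines.append("")
        lines.append("DCB vs NDB comparisons (Mann-Whitney p):")
        for marker in MARKERS:
            t0 = self.baseline_tests.get(marker)
            tr = self.ratio_tests.get(marker)
            c0 = f"{t0.p_value:.4f}" if t0 else "  --  "
            rr = f"{tr.p_value:.4f}" if tr else "  --  "
            lines.append(f"  {marker:6s} C0 p={c0}   C4/C0 ratio p={rr}")
        lines.append("")
        for label, fits in (("PFS", self.survival_pfs), ("OS", self.survival_os)):
            lines.append(f"Univariate Cox ({label}):")
            for factor, fit in fits.items():
                if fit is None or fit.cox is None:
                    continue
                row = fit.cox.iloc[0]
                lines.append(
                    f"  {factor:22s} HR {row['hr']:6.2f} "
                    f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}) "
                    f"p={row['p']:.4f}"
                )
            lines.append("")
        if self.multivariate_pfs is not None and not self.multivariate_pfs.empty:
            lines.append("Multivariate Cox (PFS):")
            for factor, row in self.multivariate_pfs.iterrows():
                lines.append(
                    f"  {factor:22s} HR {row['hr']:6.2f} "
                    f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}) "
                    f"p={row['p']:.4f}"
                )
            lines.append("")
        if not self.stratification.empty:
            lines.append("Two-factor stratification (increased bTMB + high C0 cfDNA):")
            counts = self.stratification["risk_factors"].value_counts().sort_index()
            for k, v in counts.items():
                lines.append(f"  {k} risk factor(s): {v} patients")
        return "\n".join(lines)

    def plot_km(self, endpoint: str = "pfs", factor: str = "cfdna_high", ax=None):
        """Kaplan-Meier step curves for one dichotomized factor."""
        import matplotlib.pyplot as plt

        fits = self.survival_pfs if endpoint == "pfs" else self.survival_os
        fit = fits.get(factor)
        if fit is None:
            raise CohortValidationError(f"no survival fit for factor {factor!r}")
        if ax is None:
            _, ax = plt.subplots()
        ax.step(fit.km["time"], fit.km["survival"], where="post", label=factor)
        ax.fill_between(fit.km["time"], fit.km["ci_low"], fit.km["ci_high"],
                        step="post", alpha=0.2)
        ax.set_xlabel("months")
        ax.set_ylabel(f"{endpoint.upper()} probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


class BiomarkerStudy:
    """The study model: three input tables plus a pipeline configuration."""

    def __init__(
        self,
        variants: Sequence[VariantCall],
        assays: Sequence[SampleAssay],
        clinical: Sequence[PatientRecord],
        config: Optional[PipelineConfig] = None,
    ) -> None:
        self.variants = list(variants)
        self.assays = list(assays)
        self.clinical = list(clinical)
        self.config = config or PipelineConfig()
        ids = [r.patient_id for r in self.clinical]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate patient IDs in clinical table")

    @classmethod
    def from_tables(cls, variant_path, assay_path, clinical_path,
                    config: Optional[PipelineConfig] = None) -> "BiomarkerStudy":
        return cls(
            variants=pio.read_variant_table(variant_path),
            assays=pio.read_assay_table(assay_path),
            clinical=pio.read_clinical_table(clinical_path),
            config=config,
        )

    @classmethod
    def from_cohort(cls, cohort, config: Optional[PipelineConfig] = None):
        """Build directly from a :func:`plasmabm.simulate.generate_cohort` result."""
        return cls(cohort.variants, cohort.assays, cohort.clinical, config=config)

    # ------------------------------------------------------------------
    def fit(self) -> StudyResults:
        config = self.config
        kept, removed = filter_somatic(self.variants, config)
        profiles = build_profiles(kept, self.assays, config)
        rates = cohort_rates(self.clinical)
        dcb_class = {r.patient_id: classify_dcb(r) for r in self.clinical}

        # -- cutpoints: ROC for the low-favorable markers, median for bTMB
        cutoffs: dict[str, float] = {}
        roc: dict[str, Optional[RocResult]] = {}
        for marker in MARKERS:
            pairs = [(getattr(p, f"{marker}_c0"), dcb_class[p.patient_id])
                     for p in profiles
                     if getattr(p, f"{marker}_c0") is not None
                     and dcb_class.get(p.patient_id) in (DCB, NDB)]
            if not pairs:
                continue
            values = np.array([v for v, _ in pairs])
            labels = np.array([c == DCB for _, c in pairs])
            if marker in LOW_FAVORABLE and labels.any() and not labels.all():
                res = roc_optimal_cutoff(values, labels,
                                         criterion=config.cutpoint_criterion)
                roc[marker] = res
                cutoffs[marker] = res.cutoff
            else:
                cutoff, _ = median_split(values)
                roc[marker] = None
                cutoffs[marker] = cutoff
        assign_baseline_groups(profiles, cutoffs)

        # -- DCB vs NDB comparisons at baseline and on the dynamics ratio
        baseline_tests: dict[str, Optional[ComparisonResult]] = {}
        ratio_tests: dict[str, Optional[ComparisonResult]] = {}
        for marker in MARKERS:
            baseline_tests[marker] = self._group_test(
                profiles, dcb_class, f"{marker}_c0")
            ratio_tests[marker] = self._group_test(
                profiles, dcb_class, f"ratio_{marker}")

        # -- survival: univariate Cox per dichotomized factor ------------
        factor_values = self._binary_factors(profiles)
        survival_pfs = self._univariate_cox(factor_values, endpoint="pfs")
        survival_os = self._univariate_cox(factor_values, endpoint="os")
        multivariate_pfs = self._multivariate_cox(factor_values, survival_pfs, "pfs")
        multivariate_os = self._multivariate_cox(factor_values, survival_os, "os")

        # -- two-factor stratification: increased bTMB + high C0 cfDNA ---
        strat_fits: dict[int, SurvivalFit] = {}
        strat = self._stratify(profiles, factor_values)
        clin_by_id = {r.patient_id: r for r in self.clinical}
        for k in sorted(strat["risk_factors"].dropna().unique()):
            sub = strat[strat["risk_factors"] == k]
            recs = [clin_by_id[p] for p in sub["patient_id"]]
            times = [r.pfs_months for r in recs if r.pfs_months is not None]
            events = [r.pfs_event for r in recs if r.pfs_months is not None]
            if times:
                strat_fits[int(k)] = fit_survival(times, events)

        # -- mutation profiling ------------------------------------------
        ctdna_pos_c0 = [a.patient_id for a in self.assays
                        if a.timepoint == "C0" and a.qc_pass and a.evaluable
                        and a.ctdna_positive]
        groups = {pid: dcb_class[pid] for pid in ctdna_pos_c0
                  if dcb_class.get(pid) in (DCB, NDB)}
        freqs = gene_frequency(kept, ctdna_pos_c0, groups)
        paired = {p.patient_id for p in profiles if p.on_timepoint is not None}
        overlaps = []
        for label in (DCB, NDB):
            members = {pid for pid, g in groups.items() if g == label} & paired
            group_variants = [v for v in kept if v.patient_id in members]
            overlaps.append(timepoint_overlap(group_variants, members, group=label))

        return StudyResults(
            config=config, profiles=profiles,
            removal_log=removal_log_frame(removed),
            rates=rates, dcb_class=dcb_class, cutoffs=cutoffs, roc=roc,
            baseline_tests=baseline_tests, ratio_tests=ratio_tests,
            survival_pfs=survival_pfs, survival_os=survival_os,
            multivariate_pfs=multivariate_pfs, multivariate_os=multivariate_os,
            stratification=strat, stratification_fits=strat_fits,
            gene_frequencies=freqs, overlaps=overlaps,
        )

    # ------------------------------------------------------------------
    def _group_test(self, profiles, dcb_class, attr) -> Optional[ComparisonResult]:
        from .stats import compare_groups

        dcb_vals, ndb_vals = [], []
        for p in profiles:
            value = getattr(p, attr)
            if value is None:
                continue
            cls = dcb_class.get(p.patient_id)
            if cls == DCB:
                dcb_vals.append(value)
            elif cls == NDB:
                ndb_vals.append(value)
        if not dcb_vals or not ndb_vals:
            return None
        return compare_groups(dcb_vals, ndb_vals)

    def _binary_factors(self, profiles) -> pd.DataFrame:
        """Per-patient boolean risk factors (None = undefined)."""
        rows = []
        for p in profiles:
            row = {"patient_id": p.patient_id}
            for marker in MARKERS:
                g = getattr(p, f"group_{marker}")
                row[f"{marker}_high"] = None if g is None else g == "high"
                dyn = getattr(p, f"dynamics_{marker}")
                row[f"{marker}_increased"] = (
                    None if dyn == "undefined" else dyn == "increased")
            rows.append(row)
        return pd.DataFrame(rows)

    def _endpoint_arrays(self, patient_ids, endpoint):
        clin = {r.patient_id: r for r in self.clinical}
        times, events, keep = [], [], []
        for pid in patient_ids:
            r = clin.get(pid)
            t = getattr(r, f"{endpoint}_months") if r else None
            if t is None:
                continue
            times.append(t)
            events.append(getattr(r, f"{endpoint}_event"))
            keep.append(pid)
        return np.array(times), np.array(events, dtype=bool), keep

    def _univariate_cox(self, factors: pd.DataFrame, endpoint: str):
        out: dict[str, Optional[SurvivalFit]] = {}
        for col in factors.columns:
            if col == "patient_id":
                continue
            sub = factors[["patient_id", col]].dropna()
            if sub.empty or sub[col].nunique() < 2:
                out[col] = None
                continue
            times, events, keep = self._endpoint_arrays(sub["patient_id"], endpoint)
            if len(times) == 0 or not events.any():
                out[col] = None
                continue
            cov = sub.set_index("patient_id").loc[keep, [col]].astype(float)
            try:
                out[col] = fit_survival(times, events, covariates=cov)
            except Exception as exc:  # singular fits on tiny strata
                logger.warning("Cox fit failed for %s (%s): %s", col, endpoint, exc)
                out[col] = None
        return out

    def _multivariate_cox(self, factors, univariate, endpoint):
        """Covariates entering: univariate p below the configured threshold."""
        entry = [f for f, fit in univariate.items()
                 if fit is not None and fit.cox is not None
                 and fit.cox["p"].iloc[0] < self.config.multivariate_entry_p]
        if len(entry) < 2:
            return None
        sub = factors[["patient_id"] + entry].dropna()
        if sub.empty:
            return None
        times, events, keep = self._endpoint_arrays(sub["patient_id"], endpoint)
        if len(times) < len(entry) + 2 or not events.any():
            return None
        cov = sub.set_index("patient_id").loc[keep, entry].astype(float)
        if any(cov[c].nunique() < 2 for c in entry):
            return None
        try:
            fit = fit_survival(times, events, covariates=cov)
        except Exception as exc:
            logger.warning("multivariate Cox failed (%s): %s", endpoint, exc)
            return None
        return fit.cox

    def _stratify(self, profiles, factors: pd.DataFrame) -> pd.DataFrame:
        f = factors.set_index("patient_id")
        a = [f.loc[p.patient_id, "btmb_increased"] for p in profiles]
        b = [f.loc[p.patient_id, "cfdna_high"] for p in profiles]
        labels = stratify_two_factor(a, b)
        return pd.DataFrame({
            "patient_id": [p.patient_id for p in profiles],
            "btmb_increased": a,
            "cfdna_high": b,
            "risk_factors": labels,
        })
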