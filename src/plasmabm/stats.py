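"""Cutpoint selection, group comparison, survival estimation, stratification.

ROC cutpoints, median splits, and the two-factor risk stratification are
authored here; rank/exact tests come from scipy and the Kaplan-Meier /
Cox machinery from lifelines (exponential-Greenwood log-log confidence
bands, Brookmeyer-Crowley median intervals, Efron handling of tied event
times).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .errors import CohortValidationError

HIGH_UNFAVORABLE = "high_unfavorable"
LOW_UNFAVORABLE = "low_unfavorable"


@dataclass
class RocResult:
    """ROC-derived optimal cutpoint for a favorable-outcome indicator.

    ``orientation`` records which side of the cutoff is unfavorable; the
    AUC is reported after orientation, so it is always >= 0.5 and measures
    discriminative magnitude.
    """

    auc: float
    cutoff: float
    orientation: str
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]


def roc_optimal_cutoff(
    values: Sequence[float],
    labels: Sequence[bool],
    criterion: str = "youden",
) -> RocResult:
    """Optimal dichotomization cutoff for predicting the positive label.

    Candidate cutoffs are midpoints between adjacent distinct sample
    values (plus the extremes); the default criterion maximizes Youden's
    J = sensitivity + specificity - 1, with ties broken toward the cutoff
    with higher specificity.  Sensitivity/specificity/PPV/NPV are reported
    for the positive (favorable) label at the chosen cutoff.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise CohortValidationError("values and labels must align")
    if np.isnan(values).any():
        raise CohortValidationError("values must not contain missing entries")
    if labels.all() or not labels.any():
        raise CohortValidationError("both classes must be present")

    auc_highpos = roc_auc_score(labels, values)
    if auc_highpos >= 0.5:
        orientation = LOW_UNFAVORABLE  # high values go with the favorable label
        auc = auc_highpos
        positive_side_high = True
    else:
        orientation = HIGH_UNFAVORABLE
        auc = 1.0 - auc_highpos
        positive_side_high = False

    unique = np.unique(values)
    mids = (unique[:-1] + unique[1:]) / 2.0
    candidates = np.concatenate(([unique[0] - 1.0], mids, [unique[-1] + 1.0]))

    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for c in candidates:
        pred_pos = values > c if positive_side_high else values < c
        tp = int((pred_pos & labels).sum())
        tn = int((~pred_pos & ~labels).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        if criterion == "youden":
            score = sens + spec - 1.0
        elif criterion == "closest_topleft":
            score = -math.hypot(1.0 - sens, 1.0 - spec)
        else:
            raise ValueError(f"unknown cutpoint criterion {criterion!r}")
        key = (score, spec)
        if best is None or key > best[0]:
            fp = int(pred_pos.sum()) - tp
            fn = int(n_pos) - tp
            ppv = tp / (tp + fp) if (tp + fp) else None
            npv = tn / (tn + fn) if (tn + fn) else None
            best = (key, RocResult(auc=float(auc), cutoff=float(c),
                                   orientation=orientation, sensitivity=sens,
                                   specificity=spec, ppv=ppv, npv=npv))
    return best[1]


def median_split(values: Sequence[float]) -> tuple[float, np.ndarray]:
    """Median dichotomization: cutoff = sample median, ties to "high".

    Returns (cutoff, boolean array with True = high group).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise CohortValidationError("median_split requires a non-empty sample")
    cutoff = float(np.median(values))
    return cutoff, values >= cutoff


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    estimate: Optional[float] = None  # odds ratio for Fisher


def compare_groups(
    x: Optional[Sequence[float]] = None,
    y: Optional[Sequence[float]] = None,
    *,
    table: Optional[Sequence[Sequence[int]]] = None,
) -> ComparisonResult:
    """Two-group comparison: Mann-Whitney U for values, Fisher's exact for 2x2.

    The U test uses the exact null distribution when both sides have at
    most 8 observations and there are no ties, and the tie-corrected
    normal approximation otherwise.
    """
    if table is not None:
        table = np.asarray(table, dtype=int)
        if table.shape != (2, 2):
            raise CohortValidationError("Fisher's exact test needs a 2x2 table")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return ComparisonResult(statistic=float(odds), p_value=float(p),
                                method="fisher_exact", estimate=float(odds))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortValidationError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(statistic=float(u), p_value=float(p),
                            method=f"mannwhitney_{method}")


@dataclass
class SurvivalFit:
    """Kaplan-Meier estimate plus optional Cox proportional-hazards table.

    ``km`` has columns time / at_risk / survival / ci_low / ci_high;
    ``median_months`` is None when the curve never crosses 0.5 ("not
    reached"); ``cox`` indexes covariates with columns hr / ci_low /
    ci_high / p.
    """

    km: pd.DataFrame
    median_months: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]
    cox: Optional[pd.DataFrame] = None
    n: int = 0
    n_events: int = 0

    @property
    def median_reached(self) -> bool:
        return self.median_months is not None


def _finite_or_none(value: float) -> Optional[float]:
    return None if value is None or not np.isfinite(value) else float(value)


def fit_survival(
    times: Sequence[float],
    events: Sequence[bool],
    covariates: Optional[pd.DataFrame] = None,
) -> SurvivalFit:
    """Kaplan-Meier product-limit fit, with a Cox model when covariates given.

    The KM bands are exponential-Greenwood (log-log) 95% intervals; the
    median interval is Brookmeyer-Crowley.  The Cox fit uses Efron's
    approximation for tied event times and Wald intervals, and is refused
    with a diagnostic when no events occurred.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise CohortValidationError("fit_survival requires observations")
    if (times < 0).any():
        raise CohortValidationError("survival times must be >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    km = pd.DataFrame({
        "time": kmf.survival_function_.index.values,
        "survival": kmf.survival_function_.iloc[:, 0].values,
        "ci_low": kmf.confidence_interval_.iloc[:, 0].values,
        "ci_high": kmf.confidence_interval_.iloc[:, 1].values,
        "at_risk": kmf.event_table["at_risk"].reindex(
            kmf.survival_function_.index).values,
    })
    median = _finite_or_none(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    median_ci = (_finite_or_none(ci.iloc[0, 0]), _finite_or_none(ci.iloc[0, 1]))

    cox_table = None
    if covariates is not None:
        if not events.any():
            raise CohortValidationError(
                "Cox model refused: no events observed (all observations censored)"
            )
        df = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        df["_time"] = times
        df["_event"] = events.astype(int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        summary = cph.summary
        cox_table = pd.DataFrame({
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        })
    return SurvivalFit(km=km, median_months=median, median_ci=median_ci,
                       cox=cox_table, n=int(times.size),
                       n_events=int(events.sum()))


def stratify_two_factor(
    factor_a: Sequence[Optional[bool]],
    factor_b: Sequence[Optional[bool]],
) -> list[Optional[int]]:
    """Risk-factor count per patient: 0, 1 or 2; None when either is undefined.

    Patients carrying both risk factors (label 2) are the worst-prognosis
    stratum.
    """
    out: list[Optional[int]] = []
    for a, b in zip(factor_a, factor_b, strict=True):
        out.append(None if a is None or b is None else int(bool(a)) + int(bool(b)))
    return out
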