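"""Differential tests and survival comparison of responder groups.

Overall survival (OS) runs from diagnosis to death or last follow-up;
progression-free survival (PFS) from diagnosis to progression or last
follow-up; both in months with an event flag (1 = observed, 0 = censored).
Group differences in feature values use the two-tailed unpaired Welch t
test; survival groups are summarised by the Kaplan–Meier median (the first
time the product-limit curve drops to 0.5 or below), compared by the
log-rank test, and modelled by Cox proportional-hazards regression
(univariate per covariate or one joint multivariate fit).

The headline comparison mirrors how a response classifier is judged as a
prognostic tool: the cohort is split into four groups — actual and
predicted responders and nonresponders (the predicted split coming from
one CV repetition's merged out-of-sample classes) — and the KM medians and
pairwise log-rank tests are reported for both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .metrics import UNDEFINED, is_defined


def welch_t(group_a, group_b) -> Tuple[float, float, float]:
    """Two-tailed unpaired Welch t test: (t, Satterthwaite df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both groups are constant with different means")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def km_median(times, events):
    """Kaplan–Meier median survival: first time the curve is <= 0.5.

    Returns the undefined sentinel when the product-limit curve never
    reaches 0.5 (e.g., heavy censoring).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no records")
    km = KaplanMeierFitter().fit(times, events)
    median = km.median_survival_time_
    return UNDEFINED if np.isinf(median) else float(median)


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival curve as a (time, survival) table."""
    km = KaplanMeierFitter().fit(np.asarray(times, float), np.asarray(events, int))
    curve = km.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return curve


def logrank(times, events, groups) -> Tuple[object, object]:
    """Two-group log-rank test: (chi-square statistic, p), 1 df.

    Undefined when no events occurred in either group.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(uniq)}")
    if events.sum() == 0:
        return UNDEFINED, UNDEFINED
    mask = groups == uniq[0]
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    model_type: str


def _standardize_continuous(frame: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Z-score covariates with more than two distinct values; binary
    indicators are left on their natural scale so their HR stays a group
    contrast."""
    frame = frame.copy()
    for cov in covariates:
        col = frame[cov].astype(float)
        if col.nunique() > 2:
            sd = col.std(ddof=1)
            if sd > 0:
                frame[cov] = (col - col.mean()) / sd
    return frame


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    model_type: str = "univariate",
    standardize: bool = True,
) -> List[CoxResult]:
    """Cox proportional-hazards regression with Wald 95% CIs.

    ``univariate`` fits one model per covariate; ``multivariate`` one joint
    model over all of them (requiring a full-rank covariate matrix —
    duplicated or collinear covariates raise a diagnostic before fitting).
    Continuous covariates are standardized by default so hazard ratios are
    per standard deviation.
    """
    if model_type not in ("univariate", "multivariate"):
        raise ValueError("model_type must be 'univariate' or 'multivariate'")
    covariates = list(covariates)
    data = records[[duration_col, event_col, *covariates]].dropna().copy()
    if standardize:
        data = _standardize_continuous(data, covariates)
    if model_type == "multivariate":
        mat = data[covariates].to_numpy(dtype=float)
        centered = mat - mat.mean(axis=0)
        if np.linalg.matrix_rank(centered) < len(covariates):
            raise ValueError(
                "rank-deficient covariate matrix: some covariates are "
                "collinear or duplicated"
            )
        groups = [covariates]
    else:
        groups = [[c] for c in covariates]
    results: List[CoxResult] = []
    for cols in groups:
        fitter = CoxPHFitter()
        try:
            fitter.fit(
                data[[duration_col, event_col, *cols]],
                duration_col=duration_col,
                event_col=event_col,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"Cox fit failed for covariates {cols}: {exc}") from exc
        summary = fitter.summary
        for cov in cols:
            row = summary.loc[cov]
            results.append(
                CoxResult(
                    covariate=cov,
                    hr=float(row["exp(coef)"]),
                    ci_low=float(row["exp(coef) lower 95%"]),
                    ci_high=float(row["exp(coef) upper 95%"]),
                    p_value=float(row["p"]),
                    model_type=model_type,
                )
            )
    return results


@dataclass
class GroupComparison:
    """Four-group survival summary (actual/predicted x responder/nonresponder)."""

    groups: pd.DataFrame  # group, endpoint, n, km_median
    comparisons: pd.DataFrame  # endpoint, group_a, group_b, logrank_chi2, logrank_p
    n_dropped: int = 0


_PAIRS = (
    ("actual_responder", "actual_nonresponder"),
    ("predicted_responder", "predicted_nonresponder"),
    ("actual_responder", "predicted_responder"),
    ("actual_nonresponder", "predicted_nonresponder"),
)


def compare_predicted_groups(
    predictions: pd.DataFrame,
    survival_records: pd.DataFrame,
    actual_labels: pd.DataFrame,
) -> GroupComparison:
    """KM medians and log-rank tests for actual vs predicted response groups.

    *predictions* holds one row per patient (``patient_id``,
    ``predicted_class`` with 1 = responder) from a chosen CV repetition's
    merged out-of-sample classes; *actual_labels* maps ``patient_id`` to
    ``response_label``; *survival_records* carries ``patient_id``,
    ``os_time``, ``os_event``, ``pfs_time``, ``pfs_event``. Patients absent
    from any input are dropped and counted. Note the actual-vs-predicted
    pairs compare overlapping groups — the point is whether the predicted
    split loses prognostic separation relative to the actual one.
    """
    merged = (
        predictions[["patient_id", "predicted_class"]]
        .merge(actual_labels[["patient_id", "response_label"]], on="patient_id")
        .merge(survival_records, on="patient_id")
    )
    n_dropped = len(predictions) - len(merged)
    membership = {
        "actual_responder": merged["response_label"] == "responder",
        "actual_nonresponder": merged["response_label"] == "nonresponder",
        "predicted_responder": merged["predicted_class"] == 1,
        "predicted_nonresponder": merged["predicted_class"] == 0,
    }
    endpoints = {"OS": ("os_time", "os_event"), "PFS": ("pfs_time", "pfs_event")}
    group_rows = []
    for group, mask in membership.items():
        sub = merged[mask]
        for endpoint, (tcol, ecol) in endpoints.items():
            med = km_median(sub[tcol], sub[ecol]) if len(sub) else UNDEFINED
            group_rows.append(
                {
                    "group": group,
                    "endpoint": endpoint,
                    "n": int(mask.sum()),
                    "km_median": med if is_defined(med) else np.nan,
                    "median_undefined": not is_defined(med),
                }
            )
    comp_rows = []
    for endpoint, (tcol, ecol) in endpoints.items():
        for ga, gb in _PAIRS:
            a, b = merged[membership[ga]], merged[membership[gb]]
            times = np.concatenate([a[tcol], b[tcol]])
            events = np.concatenate([a[ecol], b[ecol]])
            labels = np.array([0] * len(a) + [1] * len(b))
            if len(a) == 0 or len(b) == 0:
                chi2 = p = UNDEFINED
            else:
                chi2, p = logrank(times, events, labels)
            comp_rows.append(
                {
                    "endpoint": endpoint,
                    "group_a": ga,
                    "group_b": gb,
                    "logrank_chi2": chi2 if is_defined(chi2) else np.nan,
                    "logrank_p": p if is_defined(p) else np.nan,
                }
            )
    return GroupComparison(
        groups=pd.DataFrame(group_rows),
        comparisons=pd.DataFrame(comp_rows),
        n_dropped=n_dropped,
    )
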