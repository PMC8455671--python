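"""Survival evaluation of biomarker groups.

Kaplan-Meier medians, log-rank tests and univariate Cox hazard ratios for
progression-free survival across biomarker-defined and clinical groups.
Estimation is delegated to lifelines (Efron handling of tied event times,
Wald confidence intervals on the log hazard ratio); this module adds the
input validation, the flagged-failure contract for degenerate covariates,
and the forest-table convenience over many univariate fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "GroupComparison",
    "km_median",
    "logrank",
    "cox_univariate",
    "forest_univariate",
]


@dataclass(frozen=True)
class GroupComparison:
    """One univariate comparison: hazard ratio, CI, p, per-group medians."""

    label: str
    hr: float
    hr_ci95: tuple[float, float]
    p: float
    n: int
    n_events: int
    medians: dict[str, float]
    flag: str | None = None


def _validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("no survival times supplied")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("survival times must be finite and non-negative")
    return t


def km_median(times, events) -> float:
    """Kaplan-Meier median survival: earliest t with S(t) <= 0.5.

    NaN when the product-limit curve never reaches 0.5 (e.g. everything
    censored early). Invariant under rescaling of the time unit.
    """
    t = _validate_times(times)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    med = kmf.median_survival_time_
    return float("nan") if np.isinf(med) else float(med)


def logrank(times, events, groups) -> tuple[float, float]:
    """K-group log-rank test; returns (chi-square statistic, p-value)."""
    t = _validate_times(times)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if not (t.shape == e.shape == g.shape):
        raise ValueError("times, events and groups must have equal length")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def _group_medians(t: np.ndarray, e: np.ndarray, x: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    levels = np.unique(x)
    if levels.size > 4:  # continuous covariate: per-level medians are noise
        return out
    for lv in levels:
        m = x == lv
        out[str(lv)] = km_median(t[m], e[m])
    return out


def cox_univariate(times, events, covariate, label: str = "covariate") -> GroupComparison:
    """Univariate Cox proportional-hazards fit for one covariate.

    Returns the partial-likelihood hazard ratio per unit of the covariate
    with Wald 95% CI and p-value. Non-convergence (including the monotone
    likelihood of complete separation) yields a *flagged* result with NaN
    estimates rather than a silently unstable one; a constant covariate is
    rejected outright.
    """
    t = _validate_times(times)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if not (t.shape == e.shape == x.shape):
        raise ValueError("times, events and covariate must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant; hazard ratio undefined")

    df = pd.DataFrame({"T": t, "E": e.astype(int), "x": x})
    cph = CoxPHFitter()
    flag = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(df, duration_col="T", event_col="E")
    except (ConvergenceError, ConvergenceWarning, Warning) as exc:
        return GroupComparison(
            label=label,
            hr=float("nan"),
            hr_ci95=(float("nan"), float("nan")),
            p=float("nan"),
            n=int(t.size),
            n_events=int(e.sum()),
            medians=_group_medians(t, e, x),
            flag=f"no_convergence: {type(exc).__name__}",
        )
    summ = cph.summary.loc["x"]
    return GroupComparison(
        label=label,
        hr=float(summ["exp(coef)"]),
        hr_ci95=(float(summ["exp(coef) lower 95%"]), float(summ["exp(coef) upper 95%"])),
        p=float(summ["p"]),
        n=int(t.size),
        n_events=int(e.sum()),
        medians=_group_medians(t, e, x),
        flag=flag,
    )


def forest_univariate(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "pfs_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Univariate Cox fits for each covariate, one forest-plot row apiece.

    No multiplicity adjustment is applied (each row is its own marginal
    analysis). Rows whose fit fails carry the failure in ``flag`` instead of
    aborting the table; patients with a missing covariate value are dropped
    from that row only.
    """
    rows = []
    for cov in covariates:
        sub = records[[time_col, event_col, cov]].dropna()
        try:
            gc = cox_univariate(sub[time_col], sub[event_col], sub[cov], label=cov)
        except ValueError as exc:
            gc = GroupComparison(
                label=cov,
                hr=float("nan"),
                hr_ci95=(float("nan"), float("nan")),
                p=float("nan"),
                n=int(len(sub)),
                n_events=int(sub[event_col].sum()),
                medians={},
                flag=f"invalid: {exc}",
            )
        rows.append(
            {
                "covariate": gc.label,
                "hr": gc.hr,
                "ci_low": gc.hr_ci95[0],
                "ci_high": gc.hr_ci95[1],
                "p": gc.p,
                "n": gc.n,
                "n_events": gc.n_events,
                "flag": gc.flag,
            }
        )
    return pd.DataFrame(rows, columns=["covariate", "hr", "ci_low", "ci_high", "p", "n", "n_events", "flag"])
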