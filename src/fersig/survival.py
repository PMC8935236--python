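"""Kaplan-Meier estimation, log-rank tests, univariate Cox fits, median split.

Cox fits use the Efron approximation for tied event times, the sensible
default for day-granularity survival data.  All routines accept plain
vectors so they compose with any upstream scoring.
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
    "CoxFit",
    "KmCurve",
    "MedianSplit",
    "cox_univariate",
    "km_estimate",
    "logrank_test",
    "median_split",
]


@dataclass
class CoxFit:
    beta: float        # log hazard ratio per covariate unit
    hr: float
    se: float
    z: float
    p: float
    n: int
    n_events: int
    converged: bool
    separation_flag: bool = False
    ties: str = "efron"


@dataclass
class KmCurve:
    times: np.ndarray            # event times (step locations)
    survival: np.ndarray         # S(t) at those times
    at_risk: np.ndarray
    censor_times: np.ndarray
    truncated_at: float | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
        })


def cox_univariate(x, time, event) -> CoxFit:
    """Univariate Cox proportional-hazards fit (Efron ties).

    Raises on constant covariates (non-identifiable) and on data without
    events; monotone likelihood / perfect separation is flagged rather than
    raised, with the capped coefficient returned.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (x.size == time.size == event.size):
        raise ValueError("covariate, time and event must align")
    if event.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: non-identifiable")
    df = pd.DataFrame({"x": x, "time": time, "event": event})
    fitter = CoxPHFitter()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(df, duration_col="time", event_col="event",
                       fit_options={"precision": 1e-9, "max_steps": 500})
        except ConvergenceError as exc:
            raise ValueError(f"Cox fit failed to converge: {exc}") from exc
        separation = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if separation:
        warnings.warn("possible monotone likelihood (perfect separation); "
                      "coefficient may be capped")
    s = fitter.summary.loc["x"]
    return CoxFit(
        beta=float(s["coef"]),
        hr=float(np.exp(s["coef"])),
        se=float(s["se(coef)"]),
        z=float(s["z"]),
        p=float(s["p"]),
        n=int(x.size),
        n_events=int(event.sum()),
        converged=True,
        separation_flag=separation,
    )


def km_estimate(time, event, truncate_days: float | None = None) -> KmCurve:
    """Product-limit survival estimate with censoring marks.

    ``truncate_days`` restricts the returned curve for display; values before
    the truncation point are unchanged.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need >= 1 subject")
    if (time < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    values = surv.to_numpy(dtype=float)
    at_risk = tbl["at_risk"].reindex(surv.index).to_numpy(dtype=float)
    censor_times = np.sort(time[event == 0])
    if truncate_days is not None:
        keep = times <= truncate_days
        times, values, at_risk = times[keep], values[keep], at_risk[keep]
        censor_times = censor_times[censor_times <= truncate_days]
    return KmCurve(times=times, survival=values, at_risk=at_risk,
                   censor_times=censor_times, truncated_at=truncate_days)


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), len(uniq) - 1, float(res.p_value)


@dataclass
class MedianSplit:
    labels: pd.Series        # "high" / "low"
    threshold: float
    n_high: int
    n_low: int


def median_split(scores: pd.Series) -> MedianSplit:
    """Split samples at the median score; ties at the median go to "low"."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need >= 2 samples")
    if scores.nunique() == 1:
        raise ValueError("degenerate split: all scores identical")
    thr = float(scores.median())
    labels = pd.Series(np.where(scores > thr, "high", "low"),
                       index=scores.index, name="fersig_group")
    return MedianSplit(
        labels=labels,
        threshold=thr,
        n_high=int((labels == "high").sum()),
        n_low=int((labels == "low").sum()),
    )
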