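"""Cox risk scores from top-ranked genes, median stratification, and
Kaplan–Meier / log-rank separation testing.

The Cox model is fitted by partial likelihood (Breslow tie handling) on
the selected gene covariates; the risk score is the linear predictor.
Patients above the median risk form the high-risk group (ties go low).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

__all__ = ["cox_risk", "median_stratify", "km_logrank"]


def _check_table(table: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in table.columns:
            raise ValueError(f"survival table needs a '{col}' column")
    if (table["time"] < 0).any():
        raise ValueError("negative survival times")
    if not table["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0/1")


def cox_risk(table: pd.DataFrame, genes: list[str]
             ) -> tuple[np.ndarray, pd.Series, CoxPHFitter]:
    """Fit a Cox proportional-hazards model on the given gene covariates.

    Returns (per-patient risk scores = linear predictor, fitted log-hazard
    coefficients, the fitted model).  Constant covariates are dropped with
    a warning (their coefficient is reported as 0).
    """
    _check_table(table)
    if int(table["event"].sum()) < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    missing = [g for g in genes if g not in table.columns]
    if missing:
        raise ValueError(f"genes absent from the table: {missing}")
    kept = [g for g in genes if table[g].nunique() > 1]
    dropped = [g for g in genes if g not in kept]
    if dropped:
        warnings.warn(f"constant covariates dropped from the Cox fit: {dropped}")
    coefs = pd.Series(0.0, index=list(genes))
    if kept:
        cph = CoxPHFitter(penalizer=1e-6)
        try:
            cph.fit(table[["time", "event"] + kept], duration_col="time",
                    event_col="event")
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
        coefs[kept] = cph.params_.values
        risk = table[kept].to_numpy() @ cph.params_.values
    else:
        cph = None
        risk = np.zeros(len(table))
    return np.asarray(risk, float), coefs, cph


def median_stratify(risk: np.ndarray) -> np.ndarray:
    """Split at the median: risk > median -> 'high', <= median -> 'low'."""
    risk = np.asarray(risk, float)
    if risk.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    med = np.median(risk)
    groups = np.where(risk > med, "high", "low")
    if (groups == "low").all():
        warnings.warn("all risks at or below the median; single 'low' group")
    return groups


def km_logrank(table: pd.DataFrame, groups: np.ndarray
               ) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per group and the two-sample log-rank test.

    Returns ({group: step-function frame with columns time/survival/at_risk},
    chi-square statistic, p-value).
    """
    _check_table(table)
    groups = np.asarray(groups)
    names = [g for g in ("high", "low") if (groups == g).any()] or \
            list(pd.unique(groups))
    curves: dict[str, pd.DataFrame] = {}
    for name in names:
        mask = groups == name
        sub = table.loc[mask]
        if sub["event"].sum() == 0:
            warnings.warn(f"group {name!r} has zero events")
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        ev = km.event_table
        curves[name] = pd.DataFrame({
            "time": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": ev["at_risk"].reindex(km.survival_function_.index).to_numpy(),
        })
    if len(names) != 2:
        raise ValueError("log-rank comparison needs exactly two nonempty groups")
    m0, m1 = groups == names[0], groups == names[1]
    res = logrank_test(table.loc[m0, "time"], table.loc[m1, "time"],
                       event_observed_A=table.loc[m0, "event"],
                       event_observed_B=table.loc[m1, "event"])
    return curves, float(res.test_statistic), float(res.p_value)
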