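"""Subtype survival evaluation: Kaplan–Meier curves, horizon mortality,
log-rank tests, and covariate-adjusted Cox proportional-hazards models.

Conventions: time is in days and the standard 3-year horizon converts at
365.25 days/year; Cox ties use the Efron approximation; confidence
intervals use exp(coef +/- 1.96 * SE); gender and pathologic stage enter as
treatment contrasts against the (configurable) reference levels female and
Stage I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "CoxFit",
    "km_estimate",
    "mortality_at",
    "logrank_test",
    "cox_fit",
    "cox_arithmetic",
    "DAYS_PER_YEAR",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
STAGE_LEVELS = ("I", "II", "III", "IV")
Z_95 = 1.96


@dataclass
class CoxFit:
    """Cox regression summary, one row per model term.

    ``table`` columns: coefficient, se, wald_z, p, hr, ci_lower, ci_upper.
    The internal arithmetic is exact by construction: hr = exp(coefficient),
    wald_z = coefficient / se, ci = exp(coefficient +/- 1.96 se).
    """

    table: pd.DataFrame
    n_samples: int
    n_events: int


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative survival times")
    return times


def km_estimate(times, events):
    """Product-limit (Kaplan–Meier) survival estimator.

    Returns
    -------
    callable
        ``S(t)`` evaluating the right-continuous step function at scalar or
        array query times. The fitted lifelines object is attached as
        ``.fitter``.
    """
    times = _validate_times(times)
    events = np.asarray(events, dtype=int)
    if len(times) < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)

    def survival(t):
        out = kmf.predict(np.atleast_1d(np.asarray(t, dtype=float)))
        arr = np.atleast_1d(np.asarray(out, dtype=float))
        return float(arr[0]) if np.isscalar(t) or np.ndim(t) == 0 else arr

    survival.fitter = kmf
    return survival


def mortality_at(times, events, horizon: float) -> float:
    """KM-based mortality percentage at a horizon: 100 * (1 - S(horizon)).

    A horizon past the last observed time is evaluated at the last time
    (the KM curve is flat beyond it) with a logged caveat.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    times = _validate_times(times)
    if horizon > times.max():
        logger.warning(
            "horizon %.1f beyond last observed time %.1f; reporting the value there",
            horizon, times.max(),
        )
        horizon = float(times.max())
    return 100.0 * (1.0 - km_estimate(times, events)(horizon))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Unweighted log-rank chi-square across 2+ groups ((G-1) df).

    Returns (statistic, p_value).
    """
    times = _validate_times(times)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank requires at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, np.asarray(events, dtype=int))
    return float(res.test_statistic), float(res.p_value)


def _design_matrix(
    surv: pd.DataFrame,
    subtype_col: str,
    reference_gender: str,
    reference_stage: str,
) -> pd.DataFrame:
    df = pd.DataFrame(index=surv.index)
    subs = pd.Categorical(surv[subtype_col])
    for lvl in subs.categories[1:]:
        name = f"subtype_{lvl}" if len(subs.categories) > 2 else "subtype"
        df[name] = (subs == lvl).astype(float)
    if "age" in surv:
        df["age"] = surv["age"].astype(float)
    if "gender" in surv:
        levels = [g for g in pd.unique(surv["gender"]) if g != reference_gender]
        for lvl in sorted(map(str, levels)):
            name = "gender" if len(levels) == 1 else f"gender_{lvl}"
            df[name] = (surv["gender"].astype(str) == lvl).astype(float)
    if "stage" in surv:
        stages = pd.Categorical(surv["stage"], categories=STAGE_LEVELS, ordered=True)
        if stages.isna().any():
            bad = surv.loc[np.asarray(stages.isna()), "stage"].unique()
            raise ValueError(f"unknown stage levels: {list(bad)}")
        for lvl in STAGE_LEVELS:
            if lvl == reference_stage:
                continue
            col = (stages == lvl).astype(float)
            if col.sum() > 0:
                df[f"stage_{lvl}"] = np.asarray(col)
    return df


def cox_fit(
    surv: pd.DataFrame,
    subtype_col: str = "subtype",
    reference_gender: str = "female",
    reference_stage: str = "I",
) -> CoxFit:
    """Covariate-adjusted Cox model: subtype + age + gender + stage.

    Uses the Efron partial likelihood for ties. ``surv`` needs columns
    ``time``, ``event``, the subtype column, and whichever of
    ``age``/``gender``/``stage`` are available.
    """
    for col in ("time", "event", subtype_col):
        if col not in surv:
            raise ValueError(f"survival table missing column {col!r}")
    if surv[[c for c in ("time", "event", "age") if c in surv]].isna().any().any():
        raise ValueError("missing covariate values; complete cases required")
    design = _design_matrix(surv, subtype_col, reference_gender, reference_stage)
    data = design.copy()
    data["time"] = _validate_times(surv["time"].to_numpy())
    data["event"] = surv["event"].astype(int).to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except Exception as err:  # lifelines raises ConvergenceError and warns per-term
        raise RuntimeError(f"Cox fit failed: {err}") from err
    coef = cph.params_
    se = cph.standard_errors_
    table = pd.DataFrame(
        {
            "coefficient": coef,
            "se": se,
            "wald_z": coef / se,
            "p": cph.summary["p"],
            "hr": np.exp(coef),
            "ci_lower": np.exp(coef - Z_95 * se),
            "ci_upper": np.exp(coef + Z_95 * se),
        }
    )
    return CoxFit(table=table, n_samples=len(data), n_events=int(data["event"].sum()))


def cox_arithmetic(coefficient: float, se: float) -> dict:
    """Derived Cox-report quantities from a coefficient and its SE:
    hazard ratio, Wald Z and the 95% CI bounds (normal approximation)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return {
        "hr": float(np.exp(coefficient)),
        "wald_z": float(coefficient / se),
        "ci_lower": float(np.exp(coefficient - Z_95 * se)),
        "ci_upper": float(np.exp(coefficient + Z_95 * se)),
    }
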