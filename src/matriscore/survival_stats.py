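"""Percentile group assignment, log-rank screening, Cox hazard ratios and the
percentage-affected breadth statistic.

Samples are stratified by a gene's expression: strictly above the high-cutoff
empirical percentile = "high", strictly below the low-cutoff percentile =
"low", the middle band excluded (with equal cutoffs the split is two-way and
ties at the cut go low). Groups are then compared by the two-sample log-rank
test, and hazard ratios come from a Cox proportional-hazards fit with the
Efron tie correction, with Wald 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .data_io import MISSING

logger = logging.getLogger("matriscore")

HIGH, LOW, EXCLUDED = "high", "low", "excluded"


def assign_groups(values, high_cut: float = 0.75, low_cut: float = 0.25) -> pd.Series:
    """Label each sample high / low / excluded by empirical expression percentiles.

    ``high``: strictly above the ``high_cut`` quantile; ``low``: strictly below
    the ``low_cut`` quantile; everything else ``excluded``. When the two
    cutoffs coincide the split is two-way: ties at the cut go low.
    """
    values = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if len(values) < 4:
        raise ValueError("need at least 4 samples to assign groups")
    arr = values.to_numpy()
    if np.all(arr == arr[0]):
        raise ValueError("cannot assign groups: values are constant")
    if not 0 <= low_cut <= high_cut <= 1:
        raise ValueError("need 0 <= low_cut <= high_cut <= 1")
    q_high = np.quantile(arr, high_cut)
    labels = pd.Series(EXCLUDED, index=values.index, dtype=object)
    if high_cut == low_cut:
        labels[arr > q_high] = HIGH
        labels[arr <= q_high] = LOW
    else:
        q_low = np.quantile(arr, low_cut)
        labels[arr > q_high] = HIGH
        labels[arr < q_low] = LOW
    return labels


def logrank_test(times, events, groups: pd.Series) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) over pooled event times.

    ``groups`` carries high/low/excluded labels aligned with ``times`` and
    ``events``; excluded samples are ignored. With no events in either group
    the test is undefined and (0.0, 1.0) is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    hi, lo = g == HIGH, g == LOW
    if not hi.any() or not lo.any():
        raise ValueError("both groups must be non-empty")
    if events[hi | lo].sum() == 0:
        logger.warning("logrank_test: no events in either group; returning p = 1")
        return 0.0, 1.0
    res = _lifelines_logrank(times[hi], times[lo], event_observed_A=events[hi], event_observed_B=events[lo])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalResult:
    """One fitted survival comparison (overall or within a subgroup level)."""

    gene: str | None = None
    cancer_type: str | None = None
    subgroup: str = "overall"
    n_high: int = 0
    n_low: int = 0
    logrank_statistic: float = math.nan
    logrank_p: float = math.nan
    hazard_ratio: float = math.nan
    hr_ci_low: float = math.nan
    hr_ci_high: float = math.nan
    hr_p: float = math.nan
    log_hr: float = math.nan
    evaluable: bool = True
    note: str = ""


def cox_univariate(times, events, covariate) -> SurvivalResult:
    """Univariate Cox proportional-hazards fit (Efron ties).

    ``covariate`` may be a binary group indicator or a continuous value.
    Non-convergence or complete separation yields a flagged (non-evaluable)
    result with missing CI rather than an exception.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cov = np.asarray(covariate, dtype=float)
    if events.sum() < 2:
        return SurvivalResult(evaluable=False, note="fewer than 2 events")
    if np.all(cov == cov[0]):
        raise ValueError("covariate is constant")
    df = pd.DataFrame({"time": times, "event": events, "x": cov})
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure / separation
        return SurvivalResult(evaluable=False, note=f"fit failed: {type(exc).__name__}")
    coef = float(fitter.params_["x"])
    summary = fitter.summary.loc["x"]
    return SurvivalResult(
        hazard_ratio=math.exp(coef),
        log_hr=coef,
        hr_ci_low=math.exp(float(summary["coef lower 95%"])),
        hr_ci_high=math.exp(float(summary["coef upper 95%"])),
        hr_p=float(summary["p"]),
    )


def survival_screen(
    times, events, values, high_cut: float = 0.75, low_cut: float = 0.25,
    gene: str | None = None, cancer_type: str | None = None,
) -> SurvivalResult:
    """Full high/low screen for one gene: assign groups, log-rank, Cox HR."""
    groups = assign_groups(pd.Series(values), high_cut, low_cut)
    stat, p = logrank_test(times, events, groups)
    mask = groups != EXCLUDED
    indicator = (groups[mask] == HIGH).astype(float)
    times = np.asarray(times, dtype=float)[mask.to_numpy()]
    events = np.asarray(events, dtype=int)[mask.to_numpy()]
    if indicator.nunique() > 1 and events.sum() >= 2:
        res = cox_univariate(times, events, indicator.to_numpy())
    else:
        res = SurvivalResult(evaluable=False, note="degenerate groups")
    res.gene = gene
    res.cancer_type = cancer_type
    res.n_high = int((groups == HIGH).sum())
    res.n_low = int((groups == LOW).sum())
    res.logrank_statistic = stat
    res.logrank_p = p
    return res


def cox_subgroup(
    times, events, groups: pd.Series, stratifier: Sequence[str]
) -> dict[str, SurvivalResult]:
    """Cox HR of high-vs-low expression fitted separately within each stratifier level.

    Levels (e.g. race or gender values) with fewer than 2 events in either
    expression group are reported as not-evaluable; the missing token is
    skipped entirely.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    strat = np.asarray(stratifier)
    g = np.asarray(groups)
    out: dict[str, SurvivalResult] = {}
    for level in sorted(set(strat) - {MISSING}):
        sel = (strat == level) & ((g == HIGH) | (g == LOW))
        hi = sel & (g == HIGH)
        lo = sel & (g == LOW)
        if events[hi].sum() < 2 or events[lo].sum() < 2:
            out[level] = SurvivalResult(subgroup=level, evaluable=False, note="fewer than 2 events per group")
            continue
        res = cox_univariate(times[sel], events[sel], (g[sel] == HIGH).astype(float))
        res.subgroup = level
        res.n_high = int(hi.sum())
        res.n_low = int(lo.sum())
        res.logrank_statistic, res.logrank_p = logrank_test(times[sel], events[sel], pd.Series(g[sel]))
        out[level] = res
    return out


def percent_affected(k: int, n: int) -> float:
    """Breadth statistic: 100 * k / n, reported to two decimals.

    ``k`` = number of cancers significantly affected, ``n`` = total cancers
    analysed (study denominator 30).
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return round(100.0 * k / n, 2)
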