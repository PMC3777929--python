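"""Survival statistics for cohort comparisons: Kaplan-Meier curves,
logrank tests between predicted survivor groups, and chi-square tests of
independence (e.g. survivor group vs molecular subtype).

Estimation and testing are delegated to lifelines and scipy behind a small
stable surface; the chi-square uses the plain Pearson statistic
sum (O - E)^2 / E without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class SurvivalCurve:
    """Product-limit estimate of a survival function."""

    timeline: np.ndarray  # event/censor times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each timeline point
    label: str | None = None

    def survival_at(self, t: float) -> float:
        """Step-function lookup: S(t), right-continuous."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier_estimate(times, event_flags, label: str | None = None) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.  ``event_flags`` True marks an
    observed event (death); False marks right-censoring, which reduces the
    risk set without a step."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and event_flags must be 1-D and aligned")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table[kmf.event_table["removed"] > 0]  # observation times only
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    return SurvivalCurve(
        timeline=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        survival=surv,
        label=label,
    )


def logrank_test(groups) -> tuple[float, float]:
    """Logrank comparison of >= 2 survival distributions.

    ``groups``: mapping label -> (times, event_flags), or a sequence of
    such pairs.  Returns (chi-square statistic, p-value) with
    ``len(groups) - 1`` degrees of freedom.  Simultaneous (tied) event
    times are handled by the standard hypergeometric convention.
    Applying the test to uncensored data (e.g. age distributions) is
    supported by passing all-True event flags.
    """
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(str(i), g) for i, g in enumerate(groups)]
    if len(items) < 2:
        raise ValueError("need >= 2 groups")
    durations, events, labels = [], [], []
    for label, (t, e) in items:
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        durations.append(t)
        events.append(e)
        labels.append(np.full(len(t), label, dtype=object))
    durations = np.concatenate(durations)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("logrank test undefined with zero events")
    res = multivariate_logrank_test(durations, labels, events)
    return float(res.test_statistic), float(res.p_value)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, degrees of freedom, p-value); df = (r-1)(c-1).
    Warns when any expected count is below 5 (asymptotic approximation
    questionable).  Zero row or column margins are an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(obs, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("expected count < 5 in some cell; chi-square approximation is rough")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def logrank_groups_from_predictions(
    predictions: pd.Series, survival_days: pd.Series, event_flags: pd.Series | None = None
) -> tuple[float, float]:
    """Convenience: logrank test between predicted survivor groups.  All
    patients are treated as events unless flags are given."""
    groups = {}
    for cls in sorted(predictions.unique()):
        idx = predictions.index[predictions == cls]
        t = survival_days.loc[idx].to_numpy(dtype=float)
        e = (
            np.ones(len(idx), dtype=bool)
            if event_flags is None
            else event_flags.loc[idx].to_numpy(dtype=bool)
        )
        groups[str(cls)] = (t, e)
    return logrank_test(groups)
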