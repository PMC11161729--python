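"""Recurrence-free survival: response groups, Kaplan-Meier, log-rank, splits.

Response groups discretize recurrence-free survival (RFS, months from first
chemotherapy — or resection for the untreated arm — to recurrence or death):
poor response/survival (PRG) at RFS <= 16 months, good response/survival
(GRG) at RFS > 24 months, and an intermediate band (16, 24] that is excluded
from differential comparisons but retained everywhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import CountMatrix

logger = logging.getLogger(__name__)

PRG_MAX_RFS = 16.0
GRG_MIN_RFS = 24.0


def assign_response_groups(annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``response_group`` column derived from RFS.

    PRG iff rfs <= 16 months; GRG iff rfs > 24 months; otherwise
    ``intermediate``.  Returns a copy.
    """
    rfs = annotation["rfs_months"].to_numpy(dtype=float)
    if np.isnan(rfs).any():
        raise ValueError("rfs_months contains missing values")
    if (rfs < 0).any():
        raise ValueError("rfs_months must be non-negative")
    group = np.where(rfs <= PRG_MAX_RFS, "PRG", np.where(rfs > GRG_MIN_RFS, "GRG", "intermediate"))
    out = annotation.copy()
    out["response_group"] = group
    return out


@dataclass
class KMCurve:
    """Product-limit estimate: event times, survival, at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored samples leave the risk set without stepping the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # timeline excluding the t=0 anchor row lifelines prepends (unless a real event at 0)
    sf = kmf.survival_function_["KM_estimate"]
    ev = kmf.event_table
    times_out = ev.index.to_numpy(dtype=float)
    surv = sf.loc[ev.index].to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    return KMCurve(times=times_out, survival=surv, at_risk=at_risk)


@dataclass
class SurvivalComparison:
    group_labels: tuple[str, str]
    curves: dict = field(repr=False)
    chi2: float = 0.0
    p_value: float = 1.0


def logrank_test(group_a, group_b, labels: tuple[str, str] = ("A", "B")) -> SurvivalComparison:
    """Two-group log-rank test (1 df, two-sided).

    ``group_a`` and ``group_b`` are (times, events) pairs.  With no events in
    either group the comparison is degenerate and p = 1 is returned.
    """
    tA, eA = (np.asarray(v) for v in group_a)
    tB, eB = (np.asarray(v) for v in group_b)
    if tA.size == 0 or tB.size == 0:
        raise ValueError("both groups must be non-empty")
    curves = {labels[0]: km_estimate(tA, eA), labels[1]: km_estimate(tB, eB)}
    if eA.sum() + eB.sum() == 0:
        logger.debug("log-rank degenerate: no events observed")
        return SurvivalComparison(labels, curves, chi2=0.0, p_value=1.0)
    res = _ll_logrank(tA, tB, event_observed_A=eA.astype(bool), event_observed_B=eB.astype(bool))
    return SurvivalComparison(labels, curves, chi2=float(res.test_statistic), p_value=float(res.p_value))


def abundance_split(
    norm: CountMatrix, protein: str, quantile: float = 0.75
) -> tuple[list[str], list[str]]:
    """Split samples at a protein's abundance quantile.

    Returns (high, low): samples strictly above the linearly interpolated
    ``quantile`` of the protein's normalized abundance, and the rest (ties at
    the quantile fall into the low group).
    """
    if protein not in norm.data.index:
        raise KeyError(f"protein {protein!r} not in matrix")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    values = norm.data.loc[protein]
    if values.nunique() <= 1:
        raise ValueError(f"protein {protein!r} has constant abundance; no split possible")
    cut = float(np.quantile(values.to_numpy(dtype=float), quantile))
    high = list(values.index[values > cut])
    low = list(values.index[values <= cut])
    return high, low
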