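"""Kaplan-Meier estimation, log-rank testing and marker-based stratification.

Overall-survival analyses mirror the clinical workflow: estimate per-group
survival curves with the product-limit method, compare groups with the
(k-group) log-rank chi-square test, and stratify samples either by a gene's
expression level (median/tertile/custom quantile split) or by promoter
methylation calls obtained from a beta-value cutoff (default 0.3, strictly
greater = methylated).  Two markers' calls combine into four joint strata,
e.g. MGMT x PRKCG, whose survival-at-t values summarize the stratification.

Estimation and testing are delegated to lifelines; this module owns the
stratification rules and the step-function evaluation conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

DEFAULT_BETA_CUTOFF = 0.3


@dataclass
class KMCurve:
    """Product-limit survival estimate as step-function arrays: distinct
    observed times (ascending), S(t) just after each time, subjects at risk
    and events at each time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self):
        assert np.all(np.diff(self.times) > 0), "times must be strictly increasing"
        assert np.all(np.diff(self.survival) <= 1e-12), "survival must be non-increasing"


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    group_sizes: dict


@dataclass(frozen=True)
class MethylationCall:
    sample_id: str
    marker: str
    status: str  # methylated | unmethylated
    beta_used: float


def km_curve(os_months, os_event) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Subjects censored at an event time are counted at risk at that time
    (standard convention).  If every subject is censored the curve never
    drops; this is valid and flagged in the log.
    """
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(os_event, dtype=int)
    if len(t) == 0:
        raise ValueError("no subjects")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    if e.sum() == 0:
        logger.info("all %d subjects censored: survival curve never drops", len(t))
    kmf = KaplanMeierFitter().fit(t, event_observed=e)
    # keep only distinct observed times (lifelines inserts a bookkeeping t=0 row)
    tab = kmf.event_table[kmf.event_table["removed"] > 0]
    times = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(tab.index).to_numpy()
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        n_events=tab["observed"].to_numpy(dtype=int),
    )


def survival_at(curve: KMCurve, t_months: float) -> float:
    """Right-continuous evaluation S(t) of a KM step function.

    A query beyond the last observed time returns the last value and is
    flagged as extrapolation in the log.
    """
    if t_months < 0:
        raise ValueError("t must be >= 0")
    if len(curve.times) == 0 or t_months < curve.times[0]:
        return 1.0
    if t_months > curve.times[-1]:
        logger.warning("S(%g) extrapolated beyond last observed time %g",
                       t_months, curve.times[-1])
    idx = np.searchsorted(curve.times, t_months, side="right") - 1
    return float(curve.survival[idx])


def logrank_test(os_months, os_event, group_labels) -> LogRankResult:
    """k-group log-rank test (chi-square approximation, df = k - 1)."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(os_event, dtype=int)
    g = np.asarray(group_labels)
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("log-rank test requires at least 2 non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(uniq) - 1,
        p_value=float(res.p_value),
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )


def split_by_expression(values, scheme: str = "median",
                        quantiles=None) -> pd.Series:
    """Assign samples to expression subgroups.

    ``scheme`` is ``median`` (labels low/high), ``tertile`` (low/mid/high)
    or ``custom_quantiles`` (interior quantiles in (0,1); labels q1..qk+1).
    Ties at a cutpoint go to the lower group.  Constant values cannot be
    split and raise an error.
    """
    s = pd.Series(values, dtype=float)
    if s.nunique() < 2:
        raise ValueError("constant values: no split possible")
    if scheme == "median":
        cuts, labels = [0.5], ["low", "high"]
    elif scheme == "tertile":
        cuts, labels = [1 / 3, 2 / 3], ["low", "mid", "high"]
    elif scheme == "custom_quantiles":
        if not quantiles:
            raise ValueError("custom_quantiles scheme requires quantiles")
        cuts = sorted(float(q) for q in quantiles)
        if any(not 0 < q < 1 for q in cuts):
            raise ValueError("quantiles must lie strictly in (0,1)")
        labels = [f"q{i + 1}" for i in range(len(cuts) + 1)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    cutpoints = np.quantile(s.to_numpy(), cuts)
    idx = np.searchsorted(cutpoints, s.to_numpy(), side="left")  # v <= cut -> lower
    out = pd.Series([labels[i] for i in idx], index=s.index, name="subgroup")
    if out.nunique() < 2:
        raise ValueError("split produced a single non-empty group")
    return out


def call_methylation(beta_value: float, marker: str = "marker",
                     sample_id: str = "", cutoff: float = DEFAULT_BETA_CUTOFF):
    """Dichotomize a beta value: methylated iff beta strictly exceeds the
    cutoff (boundary = unmethylated).  A missing beta yields no call (None)."""
    if beta_value is None or (isinstance(beta_value, float) and np.isnan(beta_value)):
        return None
    if not 0 <= beta_value <= 1:
        raise ValueError(f"beta outside [0,1]: {beta_value}")
    status = "methylated" if beta_value > cutoff else "unmethylated"
    return MethylationCall(sample_id=sample_id, marker=marker,
                           status=status, beta_used=float(beta_value))


def call_methylation_series(betas, marker: str = "marker",
                            cutoff: float = DEFAULT_BETA_CUTOFF) -> dict[str, MethylationCall]:
    """Per-sample methylation calls for one marker; samples with missing
    beta are omitted."""
    calls = {}
    for sample_id, b in pd.Series(betas).items():
        c = call_methylation(b, marker=marker, sample_id=str(sample_id), cutoff=cutoff)
        if c is not None:
            calls[str(sample_id)] = c
    return calls


def stratum_labels(name_a: str = "A", name_b: str = "B") -> list[str]:
    """The fixed order of the four joint strata, from double-unmethylated
    (worst prognosis in the motivating signature) to double-methylated."""
    return [
        f"{name_a}_unmeth+{name_b}_unmeth",
        f"{name_a}_unmeth+{name_b}_meth",
        f"{name_a}_meth+{name_b}_unmeth",
        f"{name_a}_meth+{name_b}_meth",
    ]


def joint_strata(calls_marker_a: dict[str, MethylationCall],
                 calls_marker_b: dict[str, MethylationCall],
                 name_a: str = "A", name_b: str = "B") -> pd.Series:
    """Combine two markers' methylation calls into four joint strata.

    Only samples called for both markers are retained (dropped count
    logged); an empty intersection is an error.  Returns a Series mapping
    sample id to one of the four labels from :func:`stratum_labels`.
    """
    common = [s for s in calls_marker_a if s in calls_marker_b]
    dropped = (len(calls_marker_a) - len(common)) + (len(calls_marker_b) - len(common))
    if dropped:
        logger.info("joint strata: dropped %d sample(s) lacking a call for both markers",
                    dropped)
    if not common:
        raise ValueError("no sample has calls for both markers")
    short = {"methylated": "meth", "unmethylated": "unmeth"}
    labels = {
        s: f"{name_a}_{short[calls_marker_a[s].status]}+{name_b}_{short[calls_marker_b[s].status]}"
        for s in common
    }
    return pd.Series(labels, name="stratum")
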