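"""Nonparametric two-group comparisons with starred significance coding.

All compared groups (diagnosis classes, glioma grades, anatomic regions,
primary vs recurrent tumors) are independent samples, so "Wilcoxon test"
means the two-sample rank-sum (Mann-Whitney) test.  With at most 8
observations per side (or at most 10 pooled) the null distribution of the
rank-sum statistic is enumerated exhaustively over all C(n_a+n_b, n_a)
label assignments (valid under ties, since ranks are fixed by the pooled
data); larger groups use
the tie-corrected normal approximation with continuity correction.

Significance codes follow the convention ns p > 0.05, * p < 0.05,
** p < 0.01, *** p < 0.001; a p-value exactly at a threshold takes the
weaker code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from omniscreen.io import ClinicalTable

_EXACT_MAX_PER_SIDE = 8
_EXACT_MAX_TOTAL = 10  # exact also whenever the pooled sample is this small
_EPS = 1e-9  # rank sums are multiples of 0.5; guards float comparison only


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # rank-sum W of group a
    p_value: float
    direction: str  # a_higher | b_higher | none, by median difference
    code: str  # ns | * | ** | ***


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float, alternative: str) -> float:
    n = len(ranks)
    mu = n_a * (n + 1) / 2.0
    total = comb(n, n_a)
    count = 0
    for idx in combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        if alternative == "two_sided":
            if abs(w - mu) >= abs(w_obs - mu) - _EPS:
                count += 1
        elif alternative == "a_greater":
            if w >= w_obs - _EPS:
                count += 1
        else:  # a_less
            if w <= w_obs + _EPS:
                count += 1
    return count / total


def wilcoxon_compare(x, y, alternative: str = "two_sided",
                     group_a: str = "a", group_b: str = "b") -> ComparisonResult:
    """Rank-sum comparison of two independent samples.

    ``alternative`` is ``two_sided``, ``a_greater`` (values in ``x`` tend to
    be larger) or ``a_less``.  Missing values are dropped per group; a group
    left empty is an error.
    """
    if alternative not in ("two_sided", "a_greater", "a_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group is empty after dropping missing values")

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: len(x)].sum())

    n_total = len(x) + len(y)
    if (len(x) <= _EXACT_MAX_PER_SIDE and len(y) <= _EXACT_MAX_PER_SIDE) \
            or n_total <= _EXACT_MAX_TOTAL:
        p = _exact_ranksum_p(ranks, len(x), w_obs, alternative)
    else:
        scipy_alt = {"two_sided": "two-sided", "a_greater": "greater",
                     "a_less": "less"}[alternative]
        p = float(stats.mannwhitneyu(x, y, alternative=scipy_alt,
                                     method="asymptotic").pvalue)

    med_diff = float(np.median(x) - np.median(y))
    direction = "a_higher" if med_diff > 0 else ("b_higher" if med_diff < 0 else "none")
    return ComparisonResult(
        group_a=group_a, group_b=group_b, n_a=len(x), n_b=len(y),
        statistic=w_obs, p_value=min(p, 1.0), direction=direction,
        code=code_significance(min(p, 1.0)),
    )


def code_significance(p_value: float) -> str:
    """Starred significance code: ns for p > 0.05, then * / ** / *** at
    0.05 / 0.01 / 0.001.  A boundary value (exactly 0.05, 0.01 or 0.001)
    takes the weaker code."""
    if not 0 <= p_value <= 1:
        raise ValueError(f"p-value outside [0,1]: {p_value}")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def compare_across_labels(values_by_sample, clinical: ClinicalTable,
                          label_field: str, pairs=None,
                          alternative: str = "two_sided") -> list[ComparisonResult]:
    """One rank-sum comparison per requested label pair.

    ``values_by_sample`` maps sample id to a numeric value (e.g. one gene's
    expression or one probe's beta).  Default pairs are all unordered pairs
    of observed labels, in first-appearance order.
    """
    if label_field not in clinical.table.columns:
        raise ValueError(f"clinical table has no field {label_field!r}")
    labels = clinical.table[label_field]
    observed = list(dict.fromkeys(labels.dropna()))
    if pairs is None:
        pairs = list(combinations(observed, 2))
    else:
        known = set(observed)
        for a, b in pairs:
            if a not in known or b not in known:
                raise ValueError(f"unknown label in pair ({a!r}, {b!r})")
    values = dict(values_by_sample)
    results = []
    for a, b in pairs:
        xa = [values[s] for s in clinical.table.index[labels == a] if s in values]
        xb = [values[s] for s in clinical.table.index[labels == b] if s in values]
        results.append(wilcoxon_compare(xa, xb, alternative=alternative,
                                        group_a=str(a), group_b=str(b)))
    return results
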