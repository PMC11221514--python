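"""Cohort-level statistics: set-overlap significance, rank-sum tests,
median-split stratification, and Kaplan-Meier survival comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "OverlapTest",
    "hypergeometric_overlap_test",
    "rank_sum_test",
    "stratify_by_median",
    "km_logrank",
    "overrepresentation_test",
]

EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric test of the overlap k between a set of
    size K and a set of size n drawn from a universe of size N."""

    k: int
    K: int
    n: int
    N: int
    p_value: float

    @property
    def expected_overlap(self) -> float:
        return self.K * self.n / self.N


def hypergeometric_overlap_test(k: int, K: int, n: int, N: int) -> OverlapTest:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n), evaluated by
    the survival function (log-space internally).
    """
    if K > N or n > N:
        raise ValueError("set sizes cannot exceed the universe")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min({K},{n})]")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(k=k, K=K, n=n, N=N, p_value=min(p, 1.0))


def rank_sum_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact enumeration when the combined sample size is <= 12 and there
    are no cross-sample ties; otherwise the normal approximation with
    continuity and tie correction.  ``alternative`` tests whether x is
    stochastically 'less' or 'greater' than y, or 'two-sided'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    small = x.size + y.size <= EXACT_RANKSUM_MAX_N
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)


def stratify_by_median(values) -> pd.Series:
    """Split subjects into 'high' / 'low' at the median feature value.

    Values above the median are high, below are low; values equal to
    the median go to low.  If that leaves one side empty (heavy ties),
    the median-tied subjects move to the empty side.  All-identical
    values are an error — no informative split exists.
    """
    v = pd.Series(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 subjects")
    if v.nunique() == 1:
        raise ValueError("all values identical: no informative median split")
    med = v.median()
    group = pd.Series(np.where(v > med, "high", "low"), index=v.index)
    if (group == "high").sum() == 0:
        group[v == med] = "high"
    elif (group == "low").sum() == 0:
        group[v == med] = "low"
    return group


def km_logrank(time, event, group) -> dict:
    """Two-group Kaplan-Meier comparison.

    Returns per-group survival curves (product-limit), median survival
    (smallest time with S(t) <= 0.5, NA if never reached), and the
    two-group log-rank chi-square statistic and p-value.
    """
    df = pd.DataFrame({"time": pd.Series(time, dtype=float),
                       "event": pd.Series(event, dtype=int),
                       "group": pd.Series(group)})
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if df["event"].sum() == 0:
        raise ValueError("no events in either group")

    curves, medians = {}, {}
    for lab in labels:
        sub = df[df["group"] == lab]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(lab))
        curves[lab] = kmf.survival_function_
        med = kmf.median_survival_time_
        medians[lab] = float(med) if np.isfinite(med) else float("nan")

    a, b = (df[df["group"] == lab] for lab in labels)
    lr = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return {
        "curves": curves,
        "median_survival": medians,
        "logrank_statistic": float(lr.test_statistic),
        "p_value": float(lr.p_value),
    }


def overrepresentation_test(query, annotated_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set in each
    annotated set, BH-corrected across sets.

    Annotated sets are intersected with the universe; the query must be
    a subset of the universe.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = frozenset(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, members in annotated_sets.items():
        members = frozenset(members) & universe
        k = len(query & members)
        test = hypergeometric_overlap_test(k, len(members), len(query), len(universe))
        rows.append({"set": name, "set_size": len(members), "overlap": k,
                     "expected": test.expected_overlap, "p_value": test.p_value})
    df = pd.DataFrame(rows).set_index("set")
    df["q_value"] = bh_adjust(df["p_value"])
    return df.sort_values("p_value")
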