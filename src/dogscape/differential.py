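"""Minimal negative-binomial differential expression.

The engine is deliberately small: median-of-ratios size factors,
method-of-moments dispersion (variance = mu + alpha * mu^2), a Wald-style
statistic on the log2 fold change with a delta-method standard error,
and Benjamini-Hochberg correction.  No shrinkage, no outlier filtering —
it is validated by type-I-error and power properties rather than by
equivalence with any particular heavyweight implementation.

Calls use the thresholds |log2FC| > 0.58 (1.5-fold) at q < 0.05:
``up`` / ``down`` when both hold, ``unchanged`` otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LFC_THRESHOLD",
    "ALPHA_Q",
    "estimate_size_factors",
    "nb_test",
    "bh_adjust",
    "classify_calls",
    "classify_concordance",
]

LFC_THRESHOLD = 0.58
ALPHA_Q = 0.05

_DISPERSION_FLOOR = 1e-8


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-feature geometric mean across samples,
    taken over features positive in every sample; each sample's factor
    is the median ratio of its counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature is positive in all samples; add a pseudocount "
            "or filter samples"
        )
    log_ref = np.log(mat[all_pos]).mean(axis=1)
    factors = np.exp(np.median(np.log(mat[all_pos]) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p_values) -> pd.Series:
    """Benjamini-Hochberg step-up q-values; NAs pass through as NA."""
    p = pd.Series(p_values, dtype=float)
    valid = p.notna()
    pv = p[valid].to_numpy()
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = pd.Series(np.nan, index=p.index)
    if valid.any():
        q[valid] = multipletests(pv, method="fdr_bh")[1]
    return q


def classify_calls(log2fc, q_value,
                   lfc_threshold: float = LFC_THRESHOLD,
                   alpha: float = ALPHA_Q) -> pd.Series:
    """Categorical up/down/unchanged call from fold change and q."""
    lfc = pd.Series(log2fc, dtype=float)
    q = pd.Series(q_value, dtype=float)
    call = pd.Series("unchanged", index=lfc.index, dtype=object)
    sig = q < alpha
    call[sig & (lfc > lfc_threshold)] = "up"
    call[sig & (lfc < -lfc_threshold)] = "down"
    return call


def nb_test(
    counts: pd.DataFrame,
    groups,
    size_factors: pd.Series | None = None,
    pseudocount: float = 1.0,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA_Q,
) -> pd.DataFrame:
    """Two-group NB differential test on a feature x sample count matrix.

    ``groups`` maps each sample (column) to one of two levels; the fold
    change is level B over level A in sorted level order.  Per feature:
    counts are normalized by size factors (estimated if not given), the
    dispersion alpha is fit by method of moments on the pooled
    within-group variance and floored at 1e-8, and the Wald statistic
    log2fc / SE(log2fc) is referred to a t distribution with n-2 df
    (small-sample correction; the normal reference is anticonservative
    at the sample sizes this engine targets).  Features with zero counts
    everywhere get NA p-values and are excluded from BH.
    """
    groups = pd.Series(groups)
    if not groups.index.equals(pd.Index(counts.columns)):
        groups = groups.reindex(counts.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    a_cols = groups[groups == levels[0]].index
    b_cols = groups[groups == levels[1]].index
    n_a, n_b = len(a_cols), len(b_cols)
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least two samples per group")

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    norm = counts / size_factors

    xa = norm[a_cols].to_numpy(dtype=float)
    xb = norm[b_cols].to_numpy(dtype=float)
    mu_a = xa.mean(axis=1)
    mu_b = xb.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # pooled within-group variance -> method-of-moments dispersion
    ss = ((xa - mu_a[:, None]) ** 2).sum(axis=1) + ((xb - mu_b[:, None]) ** 2).sum(axis=1)
    var_pooled = ss / (n_a + n_b - 2)
    mu_bar = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_pooled - mu_bar) / np.square(mu_bar)
    disp = np.where(np.isfinite(disp), disp, _DISPERSION_FLOOR)
    disp = np.maximum(disp, _DISPERSION_FLOOR)

    log2fc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))

    ln2 = np.log(2.0)
    var_mu_a = (mu_a + disp * mu_a**2) / n_a
    var_mu_b = (mu_b + disp * mu_b**2) / n_b
    se = np.sqrt(
        var_mu_a / np.square(mu_a + pseudocount)
        + var_mu_b / np.square(mu_b + pseudocount)
    ) / ln2

    df = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    zero = base_mean == 0
    p = np.where(zero, np.nan, p)
    # nonzero fold change with zero SE (e.g. identical nonzero constants)
    p = np.where(~zero & (se == 0) & (log2fc != 0), 0.0, p)
    p = np.where(~zero & (se == 0) & (log2fc == 0), 1.0, p)

    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=counts.index,
    )
    res["q_value"] = bh_adjust(res["p_value"])
    res["call"] = classify_calls(res["log2fc"], res["q_value"], lfc_threshold, alpha)
    res.loc[res["p_value"].isna(), "call"] = "unchanged"
    return res


def _host_class(log2fc: float, q: float,
                lfc_threshold: float = LFC_THRESHOLD,
                alpha: float = ALPHA_Q) -> str:
    # grid: silenced / activated need both the fold-change and the
    # q-value bound; every uncovered (FC, q) combination is conservative
    # "not_changed"
    if q < alpha and log2fc > lfc_threshold:
        return "activated"
    if q < alpha and log2fc < -lfc_threshold:
        return "silenced"
    return "not_changed"


def classify_concordance(
    dog_results: pd.DataFrame,
    host_results: pd.DataFrame,
    host_of=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair differentially expressed readthrough regions with their host
    gene's expression class.

    ``dog_results``/``host_results`` are ``nb_test`` outputs; only DoGs
    called up or down enter the grid.  ``host_of`` maps a DoG feature id
    to its host gene id (identity by default).  Returns the per-DoG pair
    table and a 2x3 contingency table whose ``*_pct`` columns are row
    percentages.
    """
    if host_of is None:
        host_of = lambda fid: fid  # noqa: E731
    de = dog_results[dog_results["call"].isin(["up", "down"])]
    rows = []
    for fid, r in de.iterrows():
        host_id = host_of(fid)
        if host_id not in host_results.index:
            warnings.warn(f"no host result for {fid}; dropped")
            continue
        h = host_results.loc[host_id]
        rows.append(
            {
                "host_gene_id": host_id,
                "dog_call": r["call"],
                "host_class": _host_class(h["log2fc"], h["q_value"]),
            }
        )
    pairs = pd.DataFrame(rows, columns=["host_gene_id", "dog_call", "host_class"])
    table = concordance_table(pairs)
    return pairs, table


def concordance_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """2x3 contingency of dog_call (up/down) vs host_class, with row
    percentages (rounded to integer percent for reporting)."""
    classes = ["silenced", "not_changed", "activated"]
    table = pd.DataFrame(0, index=["up", "down"], columns=classes, dtype=int)
    if len(pairs):
        ct = pd.crosstab(pairs["dog_call"], pairs["host_class"])
        table = table.add(ct.reindex(index=table.index, columns=classes, fill_value=0),
                          fill_value=0).astype(int)
    totals = table.sum(axis=1)
    for c in classes:
        with np.errstate(invalid="ignore"):
            table[c + "_pct"] = np.where(
                totals > 0, 100.0 * table[c] / totals.replace(0, np.nan), np.nan
            )
    table["n"] = totals
    return table
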