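"""Two-sided Wilcoxon rank-sum comparisons and grouped summary tables.

The exact test enumerates the null distribution of the rank-sum statistic W
over all C(n_a + n_b, n_a) equally likely rank assignments (via a
subset-sum count, so no explicit enumeration is needed) and reports the
proportion of assignments at least as extreme as observed,
p = P(|W - E[W]| >= |w - E[W]|).  With n = 4 vs 4 and complete separation
this gives p = 2/70 ~ 0.0286, the smallest attainable two-sided value at
those sample sizes.  Ties fall back to midranks with the tie-corrected
normal approximation (flagged in the result).

Mixed-model (GLMM) comparisons — gamma family, log link, sequential
Bonferroni — are deliberately not reimplemented here; feed the tidy output of
:func:`group_summary`/:func:`metric_table` to statsmodels ``MixedLM``/GEE or
R ``lme4``/``glmmTMB`` as the study design requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import ConfigError

EXACT_MAX_N = 10  # exact method guaranteed for both n <= this (and no ties)


@dataclass
class GroupComparison:
    statistic: float        # rank-sum W of the first sample
    p_two_sided: float
    method: str             # "exact" | "normal-approx"
    n_a: int
    n_b: int
    tie_flag: bool = False


def _ranksum_null_counts(n_a: int, n_total: int) -> np.ndarray:
    """counts[w] = number of n_a-subsets of ranks 1..n_total summing to w."""
    max_w = n_a * n_total
    # dp[k][w] over items added one at a time (Gaussian-binomial recurrence)
    dp = np.zeros((n_a + 1, max_w + 1), dtype=object)
    dp[0][0] = 1
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_a), 0, -1):
            dp[k][rank:] = dp[k][rank:] + dp[k - 1][: max_w + 1 - rank]
    return dp[n_a]


def exact_ranksum_p(sample_a, sample_b, exact_max_n: int = EXACT_MAX_N) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two samples.

    Exact whenever both samples have at most ``exact_max_n`` values and the
    pooled data has no ties; otherwise midranks + normal approximation with
    tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)  # midranks
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    has_ties = np.unique(pooled).size < n

    if np.unique(pooled).size == 1:
        return GroupComparison(w, 1.0, "exact", n_a, n_b, tie_flag=True)

    if not has_ties and n_a <= exact_max_n and n_b <= exact_max_n:
        counts = _ranksum_null_counts(n_a, n)
        total = sum(counts)
        e_w = n_a * (n + 1) / 2.0
        dev = abs(w - e_w)
        extreme = sum(
            c for wv, c in enumerate(counts) if abs(wv - e_w) >= dev - 1e-9
        )
        return GroupComparison(w, min(extreme / total, 1.0), "exact", n_a, n_b)

    e_w = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n * (n - 1)) or 1)
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return GroupComparison(w, 1.0, "normal-approx", n_a, n_b, tie_flag=True)
    # continuity correction, as rank-sum normal approximations conventionally use
    z = (w - e_w - 0.5 * np.sign(w - e_w)) / np.sqrt(var_w)
    p = min(2.0 * sstats.norm.sf(abs(z)), 1.0)
    return GroupComparison(w, float(p), "normal-approx", n_a, n_b, tie_flag=has_ties)


def attainable_p_values(n_a: int, n_b: int) -> np.ndarray:
    """The finite set of two-sided p-values reachable without ties."""
    counts = _ranksum_null_counts(n_a, n_a + n_b)
    total = sum(counts)
    e_w = n_a * (n_a + n_b + 1) / 2.0
    ps = set()
    for wv, c in enumerate(counts):
        if c == 0:
            continue
        dev = abs(wv - e_w)
        extreme = sum(
            c2 for w2, c2 in enumerate(counts) if abs(w2 - e_w) >= dev - 1e-9
        )
        ps.add(extreme / total)
    return np.array(sorted(ps))


def group_summary(metric_table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Per-DIV, per-condition mean/SD/median/n of a longitudinal metric.

    Expects tidy rows ``(network_id, div, condition, value)``.  SD is 0 and
    flagged for n = 1 groups.
    """
    required = {"network_id", "div", "condition", value_col}
    missing = required - set(metric_table.columns)
    if missing:
        raise ConfigError(f"metric table missing columns: {sorted(missing)}")
    if len(metric_table) == 0:
        raise ConfigError("metric table is empty")
    g = metric_table.groupby(["div", "condition"])[value_col]
    out = g.agg(mean="mean", sd="std", median="median", n="size").reset_index()
    single = out["n"] == 1
    out.loc[single, "sd"] = 0.0
    out["single_observation"] = single
    return out
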