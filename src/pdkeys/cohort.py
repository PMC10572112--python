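"""Group comparisons and severity correlations.

Cohort tables compare each feature across the three groups (controls,
de novo PD, early PD) with a nonparametric ANOVA — Kruskal-Wallis with tie
correction — followed by a Tukey-type rank post hoc (Nemenyi, studentized-
range reference; Dunn with Holm adjustment available behind a flag).
Descriptive cells are mean ± SD over non-missing values.

Severity correlations are Spearman rank correlations of each feature with
the UPDRS-III motor score within a patient group, with exact permutation
p-values at very small n and the t approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "spearman",
    "group_compare",
    "comparison_table",
    "correlation_table",
]

EXACT_PERMUTATION_MAX_N = 9
ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    feature_name: str
    group_stats: dict  # group -> (n, mean, sd)
    h_statistic: float
    p_omnibus: float
    pairwise: dict  # (group_a, group_b) -> p-value (nan when not computable)

    def significant_pairs(self, alpha: float = ALPHA) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise.items()
                if not math.isnan(p) and p < alpha]


@dataclass(frozen=True)
class CorrelationResult:
    feature_name: str
    group: str
    rho: float
    p_value: float
    n: int
    reason: str = ""  # why rho is missing, when it is


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with tie-aware ranks.

    rho is the product-moment correlation of average ranks.  The two-sided
    p-value is exact (full permutation enumeration) for n <= 9 and the t
    approximation with n - 2 degrees of freedom otherwise.  Missing values
    are excluded pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return CorrelationResult("", "", math.nan, math.nan, n, reason="n < 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult("", "", math.nan, math.nan, n,
                                 reason="zero variance in ranks")
    rho = _rank_corr(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc @ rxc) * (ryc @ ryc))
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0:
        p = 0.0 if n > 2 else math.nan
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult("", "", rho, min(p, 1.0) if not math.isnan(p) else p, n)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _nemenyi(groups: list[np.ndarray]) -> dict[int, dict[int, float]]:
    """Tukey-type rank post hoc on mean ranks, studentized-range reference."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    a = n_tot * (n_tot + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_tot - 1))
    out: dict[int, dict[int, float]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(a * (1.0 / sizes[i] + 1.0 / sizes[j]) / 2.0)
            q = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = float(stats.studentized_range.sf(q, k, np.inf))
            out.setdefault(i, {})[j] = min(max(p, 0.0), 1.0)
    return out


def _dunn_holm(groups: list[np.ndarray]) -> dict[int, dict[int, float]]:
    """Dunn z tests on mean ranks with Holm step-down adjustment."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    a = n_tot * (n_tot + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_tot - 1))
    raw, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(a * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            raw.append(float(2 * stats.norm.sf(z)))
            pairs.append((i, j))
    order = np.argsort(raw)
    m = len(raw)
    adj = [0.0] * m
    running = 0.0
    for rank_pos, idx in enumerate(order):
        running = max(running, (m - rank_pos) * raw[idx])
        adj[idx] = min(running, 1.0)
    out: dict[int, dict[int, float]] = {}
    for (i, j), p in zip(pairs, adj):
        out.setdefault(i, {})[j] = p
    return out


def group_compare(
    records: pd.DataFrame,
    feature: str,
    group_col: str = "group",
    groups: tuple[str, ...] = GROUPS,
    posthoc: str = "nemenyi",
) -> GroupComparison:
    """Omnibus Kruskal-Wallis plus pairwise rank post hoc for one feature.

    Groups with fewer than 2 non-missing values are excluded from the tests
    (their pairwise entries are reported missing); descriptive mean ± SD is
    still reported wherever at least one value exists.
    """
    if posthoc not in ("nemenyi", "dunn_holm"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    data: dict[str, np.ndarray] = {}
    group_stats: dict[str, tuple[int, float, float]] = {}
    for g in groups:
        v = records.loc[records[group_col] == g, feature].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        data[g] = v
        group_stats[g] = (
            len(v),
            float(v.mean()) if len(v) else math.nan,
            float(v.std(ddof=1)) if len(v) > 1 else math.nan,
        )
    usable = [g for g in groups if len(data[g]) >= 2]
    if len(usable) < 2:
        raise ValueError(f"feature {feature!r}: need >= 2 groups with >= 2 values")
    h, p = stats.kruskal(*[data[g] for g in usable])

    method = _nemenyi if posthoc == "nemenyi" else _dunn_holm
    pp = method([data[g] for g in usable]) if len(usable) >= 2 else {}
    pairwise: dict[tuple[str, str], float] = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            if ga in usable and gb in usable:
                ia, ib = usable.index(ga), usable.index(gb)
                pairwise[(ga, gb)] = pp[min(ia, ib)][max(ia, ib)]
            else:
                pairwise[(ga, gb)] = math.nan
    return GroupComparison(
        feature_name=feature,
        group_stats=group_stats,
        h_statistic=float(h),
        p_omnibus=float(p),
        pairwise=pairwise,
    )


def comparison_table(
    records: pd.DataFrame,
    features: list[str],
    groups: tuple[str, ...] = GROUPS,
    posthoc: str = "nemenyi",
) -> pd.DataFrame:
    """Group-comparison summary, one row per feature (cohort-table analog)."""
    rows = []
    for feat in features:
        gc = group_compare(records, feat, groups=groups, posthoc=posthoc)
        row: dict = {"feature": feat, "H": gc.h_statistic, "p_omnibus": gc.p_omnibus}
        for g in groups:
            n, mean, sd = gc.group_stats[g]
            row[f"{g}_n"] = n
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
        for (ga, gb), p in gc.pairwise.items():
            row[f"p_{ga}_vs_{gb}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(
    records: pd.DataFrame,
    features: list[str],
    group: str,
    target: str = "updrs3",
    group_col: str = "group",
) -> list[CorrelationResult]:
    """Spearman correlation of each feature with ``target`` within one group."""
    sub = records[records[group_col] == group]
    target_vals = sub[target].to_numpy(dtype=float)
    if (~np.isnan(target_vals)).sum() < 3:
        raise ValueError(f"group {group!r}: fewer than 3 subjects with {target}")
    out = []
    for feat in features:
        r = spearman(sub[feat].to_numpy(dtype=float), target_vals)
        out.append(CorrelationResult(feat, group, r.rho, r.p_value, r.n, r.reason))
    return out
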