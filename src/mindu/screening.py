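"""Three-stage metric screening: sensitivity, seasonal stability, redundancy.

Candidate metrics enter the index only if they

1. *discriminate* the least-impacted stations (LIS) from the impaired
   ones — a box-plot criterion on interquartile ranges confirmed by a
   two-sided Mann-Whitney U test at ``alpha``;
2. are *seasonally stable* — no significant wet/dry difference at the
   LIS (Kruskal-Wallis), so index changes track pollution, not season;
3. are *non-redundant* — among metrics whose absolute Spearman rank
   correlation reaches the cutoff (default .78, inclusive) only one per
   connected redundancy group is kept.

All hypothesis testing is nonparametric; a Kolmogorov-Smirnov normality
check is computed for the record but never gates the pipeline.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RunConfig, ValidationError, quantile
from .metrics import MetricDefinition

__all__ = [
    "boxplot_discrimination",
    "mann_whitney_confirm",
    "normality_gate",
    "seasonality_screen",
    "redundancy_screen",
    "select_final_metrics",
    "screen_metrics",
]

#: Exact-permutation Kruskal-Wallis is used up to this many observations.
_KW_EXACT_MAX_N = 12


def boxplot_discrimination(values_lis, values_impaired):
    """Box-plot discrimination between reference and impaired samples.

    PASS with criterion ``"IQR-disjoint"`` when the [Q1, Q3] boxes do not
    overlap; else PASS with ``"median-outside"`` when each group's median
    falls strictly outside the other group's box; else FAIL.  Fewer than
    four values in either group is inconclusive (never a pass).

    Returns (pass: bool, criterion: str).
    """
    a = np.asarray(values_lis, dtype=float)
    b = np.asarray(values_impaired, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 4 or len(b) < 4:
        return False, "inconclusive"
    aq1, amed, aq3 = quantile(a, [25, 50, 75])
    bq1, bmed, bq3 = quantile(b, [25, 50, 75])
    if aq3 < bq1 or bq3 < aq1:
        return True, "IQR-disjoint"
    if (amed < bq1 or amed > bq3) and (bmed < aq1 or bmed > aq3):
        return True, "median-outside"
    return False, "fail"


def mann_whitney_confirm(values_lis, values_impaired, alpha: float = 0.05):
    """Two-sided Mann-Whitney U with tie correction.

    ``sensitive`` holds when p < alpha (strict).  Exact p-values are used
    for small tie-free samples (scipy's automatic policy); when every
    value across both groups is tied the test is vacuous and p = 1.

    Returns (U: float, p: float, sensitive: bool).
    """
    a = np.asarray(values_lis, dtype=float)
    b = np.asarray(values_impaired, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0, False
    # exact null distribution for small tie-free samples, otherwise the
    # tie-corrected normal approximation
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and max(len(a), len(b)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(res.statistic), p, p < alpha


def normality_gate(values, alpha: float = 0.05):
    """Kolmogorov-Smirnov check against a normal with the sample moments.

    Informational only: the pipeline always proceeds nonparametrically,
    this merely records whether it had to.

    Returns (D: float, p: float, normal: bool).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ValidationError(f"need n >= 5 for the normality check, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0:
        return math.nan, 0.0, False
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue), float(res.pvalue) >= alpha


def _kw_statistic(groups) -> float:
    return float(stats.kruskal(*groups).statistic)


def seasonality_screen(values_by_season: dict, alpha: float = 0.05):
    """Kruskal-Wallis across seasons on reference-station values only.

    ``stable`` holds when p >= alpha.  For small samples (total n <= 12)
    the p-value is computed by exact enumeration of all group
    assignments of the pooled values; otherwise by the usual chi-square
    approximation with tie correction.

    Returns (H: float, p: float, stable: bool).
    """
    seasons = sorted(values_by_season)
    groups = []
    for s in seasons:
        g = np.asarray(values_by_season[s], dtype=float)
        g = g[~np.isnan(g)]
        if len(g) == 0:
            raise ValidationError(f"season {s!r} has no values")
        groups.append(g)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 seasons with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, True
    h_obs = _kw_statistic(groups)
    n = len(pooled)
    if n <= _KW_EXACT_MAX_N:
        p = _kw_exact_p(pooled, [len(g) for g in groups], h_obs)
    else:
        p = float(stats.kruskal(*groups).pvalue)
    return h_obs, p, p >= alpha


def _kw_exact_p(pooled: np.ndarray, sizes: list[int], h_obs: float) -> float:
    """P(H >= h_obs) over all assignments of the pooled values to groups."""
    n = len(pooled)
    idx = range(n)
    count = total = 0
    for first in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in set(first)]
        # two groups dominate in practice; recurse for more
        for assign in _assignments(rest, sizes[1:]):
            groups = [pooled[list(first)]] + [pooled[list(g)] for g in assign]
            total += 1
            if _kw_statistic(groups) >= h_obs - 1e-12:
                count += 1
    return count / total


def _assignments(indices, sizes):
    if len(sizes) == 1:
        yield [list(indices)]
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in set(first)]
        for tail in _assignments(rest, sizes[1:]):
            yield [list(first)] + tail


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def redundancy_screen(
    matrix: pd.DataFrame,
    cutoff: float = 0.78,
    alpha: float = 0.05,
    min_pairs: int = 5,
):
    """Group metrics into redundancy classes by Spearman rank correlation.

    An edge joins two metrics when |rho| >= cutoff (inclusive) and
    p < alpha over their complete joint observations; redundancy groups
    are the connected components of that graph.  Zero-variance metrics
    are excluded with a warning.

    Returns (groups: Series metric -> int group id, pairs: DataFrame of
    tested pairs with rho, p and the redundant flag).
    """
    cols = []
    for c in matrix.columns:
        v = matrix[c].dropna()
        if len(v) and v.nunique() > 1:
            cols.append(c)
        else:
            warnings.warn(f"metric {c!r} has zero variance; excluded", stacklevel=2)
    if len(cols) < 2:
        raise ValidationError("need >= 2 usable metrics for redundancy screening")
    uf = _UnionFind(cols)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        sub = matrix[[a, b]].dropna()
        if len(sub) < min_pairs:
            warnings.warn(
                f"pair ({a!r}, {b!r}): only {len(sub)} joint observations; skipped",
                stacklevel=2,
            )
            continue
        rho, p = stats.spearmanr(sub[a], sub[b])
        redundant = abs(rho) >= cutoff - 1e-12 and p < alpha
        rows.append({"metric_a": a, "metric_b": b, "rho": float(rho),
                     "p": float(p), "redundant": bool(redundant)})
        if redundant:
            uf.union(a, b)
    roots = {}
    group = {}
    for c in cols:
        r = uf.find(c)
        roots.setdefault(r, len(roots))
        group[c] = roots[r]
    return pd.Series(group, name="redundancy_group"), pd.DataFrame(rows)


def select_final_metrics(report: pd.DataFrame, preferences=()) -> list[str]:
    """Pick one metric per redundancy group among sensitive, stable metrics.

    Preference order wins when it names a group member; otherwise the
    member with the smallest Mann-Whitney p (alphabetical on ties).
    Metrics in singleton groups are kept outright.
    """
    known = set(report.index)
    unknown = [p for p in preferences if p not in known]
    if unknown:
        warnings.warn(f"preferences name unknown metrics: {unknown}", stacklevel=2)
    prefs = [p for p in preferences if p in known]
    eligible = report[(report["sensitive"]) & (report["seasonally_stable"])]
    chosen = []
    for _, members in eligible.groupby("redundancy_group"):
        names = sorted(members.index)
        pick = next((p for p in prefs if p in names), None)
        if pick is None:
            pick = members.loc[names].sort_values(
                ["mw_p"], kind="mergesort"
            ).index[0]
        chosen.append(pick)
    return sorted(chosen)


def screen_metrics(
    matrix: pd.DataFrame,
    categories: pd.Series,
    config: RunConfig | None = None,
    pairwise: bool = False,
    preferences=(),
) -> pd.DataFrame:
    """Run the full screening cascade on a metric matrix.

    Parameters
    ----------
    matrix
        Occasion x metric frame indexed by (station, date, season).
    categories
        Station -> impact category (1/2/3 or LIS/MIS/HIS labels).
    pairwise
        Test LIS against MIS and HIS separately, requiring both
        comparisons to pass, instead of against the pooled impaired set.

    Returns a per-metric report with every stage's statistics and flags,
    including the final ``retained`` column.
    """
    config = config or RunConfig()
    cats = categories.map(
        lambda v: {"LIS": 1, "MIS": 2, "HIS": 3}.get(v, v)
    ).astype(int)
    st = matrix.index.get_level_values("station")
    station_cat = st.map(cats)
    lis_mask = np.asarray(station_cat == 1)
    seasons = matrix.index.get_level_values("season")

    rows = {}
    for m in matrix.columns:
        v = matrix[m].to_numpy(dtype=float)
        lis = v[lis_mask]
        comparators = (
            [v[np.asarray(station_cat == k)] for k in (2, 3)]
            if pairwise
            else [v[~lis_mask]]
        )
        passes, crits, us, ps = [], [], [], []
        for imp in comparators:
            ok, crit = boxplot_discrimination(lis, imp)
            passes.append(ok)
            crits.append(crit)
            if ok:
                u, p, _ = mann_whitney_confirm(lis, imp, config.alpha)
            else:
                u, p = math.nan, math.nan
            us.append(u)
            ps.append(p)
        box_pass = all(passes)
        mw_p = max(ps) if box_pass else math.nan
        mw_u = us[0]
        sensitive = box_pass and mw_p < config.alpha

        finite = matrix[m].dropna().to_numpy(dtype=float)
        if len(finite) >= 5:
            ks_d, ks_p, normal = normality_gate(finite, config.alpha)
        else:
            ks_d = ks_p = math.nan
            normal = False

        kw_h = kw_p = math.nan
        stable = False
        if sensitive:
            by_season = {
                s: matrix[m].to_numpy(dtype=float)[lis_mask & (seasons == s)]
                for s in sorted(set(seasons[lis_mask]))
            }
            by_season = {
                s: g[~np.isnan(g)] for s, g in by_season.items()
            }
            if len(by_season) >= 2 and all(len(g) >= 2 for g in by_season.values()):
                kw_h, kw_p, stable = seasonality_screen(by_season, config.alpha)

        rows[m] = {
            "boxplot_pass": box_pass,
            "boxplot_criterion": ";".join(crits),
            "mw_U": mw_u,
            "mw_p": mw_p,
            "sensitive": sensitive,
            "ks_D": ks_d,
            "ks_p": ks_p,
            "normal": normal,
            "kw_H": kw_h,
            "kw_p": kw_p,
            "seasonally_stable": stable,
        }

    report = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    report.index.name = "metric"

    candidates = report.index[report["sensitive"] & report["seasonally_stable"]]
    report["redundancy_group"] = -1
    if len(candidates) >= 2:
        groups, _pairs = redundancy_screen(
            matrix[list(candidates)], config.spearman_cutoff, config.alpha
        )
        report.loc[groups.index, "redundancy_group"] = groups
    elif len(candidates) == 1:
        report.loc[candidates, "redundancy_group"] = 0

    retained = set(select_final_metrics(report, preferences)) if len(candidates) else set()
    report["retained"] = [m in retained for m in report.index]
    return report
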