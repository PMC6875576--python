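import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mindu.io import RunConfig, ValidationError
from mindu.metrics import MINDU_METRICS, default_registry, compute_metric_matrix
from mindu.screening import (
    boxplot_discrimination,
    mann_whitney_confirm,
    normality_gate,
    redundancy_screen,
    screen_metrics,
    seasonality_screen,
    select_final_metrics,
)

# ---------------------------------------------------------------------------
# independent oracles


def _quartiles_oracle(values):
    """Inclusive linear-interpolation quartiles, written out longhand."""
    v = sorted(values)
    out = []
    for q in (0.25, 0.5, 0.75):
        h = (len(v) - 1) * q
        lo = math.floor(h)
        hi = math.ceil(h)
        out.append(v[lo] + (h - lo) * (v[hi] - v[lo]))
    return out


def _boxplot_oracle(a, b):
    aq1, amed, aq3 = _quartiles_oracle(a)
    bq1, bmed, bq3 = _quartiles_oracle(b)
    if aq3 < bq1 or bq3 < aq1:
        return True, "IQR-disjoint"
    a_out = amed < bq1 or amed > bq3
    b_out = bmed < aq1 or bmed > aq3
    if a_out and b_out:
        return True, "median-outside"
    return False, "fail"


def _mw_u(x, y):
    """U statistic of x by direct pairwise counting."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += (xi > yi) + 0.5 * (xi == yi)
    return u


def _mw_exact_p(x, y):
    """Two-sided exact p by enumerating every group assignment."""
    pooled = list(x) + list(y)
    n1 = len(x)
    m = n1 * len(y) / 2.0
    u_obs = abs(_mw_u(x, y) - m)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in comb]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in set(comb)]
        total += 1
        if abs(_mw_u(g1, g2) - m) >= u_obs - 1e-12:
            count += 1
    return count / total


def _kw_h(groups):
    """Tie-corrected Kruskal-Wallis H from first principles."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


def _kw_exact_p(groups):
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = _kw_h(groups)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), sizes[0]):
        rest = [i for i in range(len(pooled)) if i not in set(comb)]
        g1 = pooled[list(comb)]
        g2 = pooled[rest]
        total += 1
        if _kw_h([g1, g2]) >= h_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------


class TestBoxplotDiscrimination:
    def test_separated_samples_are_iqr_disjoint(self):
        ok, crit = boxplot_discrimination([10, 11, 12, 13], [1, 2, 3, 4])
        assert ok and crit == "IQR-disjoint"

    def test_identical_distributions_fail(self):
        v = [1, 2, 3, 4, 5]
        ok, crit = boxplot_discrimination(v, v)
        assert not ok and crit == "fail"

    def test_overlapping_iqrs_with_mutual_outside_medians(self):
        a = [0, 1, 2, 6, 10]
        b = [0, 4, 8, 9, 10]
        ok, crit = boxplot_discrimination(a, b)
        assert ok and crit == "median-outside"

    def test_too_few_values_is_inconclusive(self):
        ok, crit = boxplot_discrimination([1, 2, 3], [4, 5, 6, 7])
        assert not ok and crit == "inconclusive"

    @given(
        a=st.lists(st.integers(0, 40), min_size=4, max_size=12),
        b=st.lists(st.integers(0, 40), min_size=4, max_size=12),
    )
    @settings(max_examples=1000, deadline=None)
    def test_agrees_with_brute_force_oracle(self, a, b):
        assert boxplot_discrimination(a, b) == _boxplot_oracle(a, b)


class TestMannWhitney:
    def test_identical_groups_not_sensitive(self):
        u, p, sens = mann_whitney_confirm([3, 3, 3, 3], [3, 3, 3, 3])
        assert p == 1.0 and not sens

    def test_fully_separated_8v8_exact_enumeration(self):
        a = [1, 2, 3, 4, 5, 6, 7, 8]
        b = [11, 12, 13, 14, 15, 16, 17, 18]
        u, p, sens = mann_whitney_confirm(a, b)
        assert sens and p < 1e-3
        assert p == pytest.approx(_mw_exact_p(a, b), abs=1e-12)

    @given(data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_small_tie_free_samples_match_enumeration(self, data):
        n1 = data.draw(st.integers(4, 6))
        n2 = data.draw(st.integers(4, 6))
        pool = data.draw(
            st.lists(
                st.integers(0, 1000),
                min_size=n1 + n2,
                max_size=n1 + n2,
                unique=True,
            )
        )
        a, b = pool[:n1], pool[n1:]
        _, p, _ = mann_whitney_confirm(a, b)
        assert p == pytest.approx(_mw_exact_p(a, b), abs=1e-9)

    def test_alpha_boundary_is_strict(self):
        a = [1, 2, 3, 4, 5]
        b = [4.5, 5.5, 6.5, 7.5, 8.5]
        _, p, _ = mann_whitney_confirm(a, b)
        assert not mann_whitney_confirm(a, b, alpha=p)[2]
        assert mann_whitney_confirm(a, b, alpha=p + 1e-9)[2]


class TestNormalityGate:
    def test_large_normal_sample_flagged_normal(self):
        rng = np.random.default_rng(7)
        d, p, normal = normality_gate(rng.normal(0, 1, 200))
        assert normal

    def test_exponential_sample_flagged_non_normal(self):
        rng = np.random.default_rng(7)
        d, p, normal = normality_gate(rng.exponential(1.0, 200))
        assert not normal

    def test_constant_vector_not_normal(self):
        d, p, normal = normality_gate([2.0] * 10)
        assert not normal and p == 0.0


class TestSeasonality:
    def test_identical_seasonal_distributions_stable(self):
        h, p, stable = seasonality_screen(
            {"wet": [1, 2, 3, 4], "dry": [1, 2, 3, 4]}
        )
        assert stable

    def test_disjoint_seasons_unstable_with_exact_p(self):
        wet = [1.0, 2.0, 3.0, 4.0]
        dry = [10.0, 11.0, 12.0, 13.0]
        h, p, stable = seasonality_screen({"wet": wet, "dry": dry})
        assert not stable
        assert p == pytest.approx(_kw_exact_p([np.array(wet), np.array(dry)]),
                                  abs=1e-12)
        # fully separated 4v4: only the two extreme assignments reach H_obs
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_h_statistic_matches_rank_formula_for_two_seasons(self):
        wet = [3.0, 9.0, 1.0, 7.0, 5.0, 11.0, 2.0]
        dry = [4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 13.0]
        h, _, _ = seasonality_screen({"wet": wet, "dry": dry})
        assert h == pytest.approx(_kw_h([np.array(wet), np.array(dry)]), abs=1e-9)

    def test_empty_season_named_in_error(self):
        with pytest.raises(ValidationError, match="dry"):
            seasonality_screen({"wet": [1, 2, 3], "dry": []})


class TestRedundancy:
    def test_monotone_transform_is_redundant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        m = pd.DataFrame({"a": x, "b": np.exp(x), "c": rng.normal(size=40)})
        groups, pairs = redundancy_screen(m)
        assert groups["a"] == groups["b"]
        assert groups["c"] != groups["a"]

    def test_independent_noise_gives_singletons(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(100, 5)),
                         columns=list("abcde"))
        groups, _ = redundancy_screen(m)
        assert groups.nunique() == 5

    def test_cutoff_is_inclusive_at_exactly_078(self):
        # permutation of 0..24 with sum of squared rank differences 572:
        # rho = 1 - 6*572/(25*624) = 0.78 exactly
        x = list(range(25))
        y = list(range(25))
        for i, j in [(0, 16), (1, 6), (2, 4), (7, 8)]:
            y[i], y[j] = y[j], y[i]
        rho, p = stats.spearmanr(x, y)
        assert rho == pytest.approx(0.78, abs=1e-12)
        m = pd.DataFrame({"a": x, "b": y})
        groups, pairs = redundancy_screen(m)
        assert groups["a"] == groups["b"]
        assert bool(pairs.loc[0, "redundant"])

    def test_zero_variance_metric_excluded_with_warning(self):
        m = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 2, 2, 2, 2],
                          "c": [5, 4, 3, 2, 1]})
        with pytest.warns(UserWarning, match="'b'"):
            groups, _ = redundancy_screen(m)
        assert "b" not in groups.index


class TestFinalSelection:
    def _report(self):
        return pd.DataFrame(
            {
                "sensitive": [True, True, True, True],
                "seasonally_stable": [True, True, True, True],
                "mw_p": [0.01, 0.001, 0.02, 0.03],
                "redundancy_group": [0, 0, 0, 1],
            },
            index=["m1", "m2", "m3", "solo"],
        ).rename_axis("metric")

    def test_preference_wins_within_group(self):
        assert select_final_metrics(self._report(), ["m3"]) == ["m3", "solo"]

    def test_smallest_p_wins_without_preferences(self):
        assert select_final_metrics(self._report()) == ["m2", "solo"]

    def test_unknown_preferences_warn_and_are_ignored(self):
        with pytest.warns(UserWarning, match="ghost"):
            out = select_final_metrics(self._report(), ["ghost"])
        assert out == ["m2", "solo"]

    def test_p_tie_broken_alphabetically(self):
        rep = self._report()
        rep["mw_p"] = [0.01, 0.01, 0.01, 0.03]
        assert select_final_metrics(rep) == ["m1", "solo"]


class TestScreenPipeline:
    def test_invariant_to_metric_column_order(self, small_survey):
        matrix = compute_metric_matrix(
            small_survey.abundance, default_registry(), small_survey.traits
        )
        rep1 = screen_metrics(matrix, small_survey.categories)
        rep2 = screen_metrics(matrix[matrix.columns[::-1]],
                              small_survey.categories)
        pd.testing.assert_frame_equal(
            rep1.drop(columns="redundancy_group").sort_index(),
            rep2.drop(columns="redundancy_group").sort_index(),
        )
        # group partitions must match even if ids differ
        g1 = rep1["redundancy_group"]
        g2 = rep2["redundancy_group"]
        part1 = {frozenset(g1.index[g1 == g]) for g in g1.unique() if g >= 0}
        part2 = {frozenset(g2.index[g2 == g]) for g in g2.unique() if g >= 0}
        assert part1 == part2

    def test_planted_gradient_flags_index_metrics_sensitive(self, survey):
        matrix = compute_metric_matrix(
            survey.abundance, default_registry(), survey.traits
        )
        rep = screen_metrics(matrix, survey.categories,
                             preferences=MINDU_METRICS)
        assert rep.loc[list(MINDU_METRICS), "sensitive"].all()
        assert rep.loc[list(MINDU_METRICS), "seasonally_stable"].all()
        assert rep["retained"].sum() >= 1
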