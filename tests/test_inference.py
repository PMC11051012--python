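"""Kruskal-Wallis, rank eta-squared and Dunn's post hoc tests."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from swallowseq import (
    compare_groups,
    comparison_table,
    dunn_posthoc,
    eta_squared,
    kruskal_wallis,
)


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        H, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert H == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_hand_computed_midrank_example(self):
        # ranks 1..6, rank sums 3/7/11 -> H = 12/(6*7) * sum(R^2/n) - 3*7 = 32/7
        H, df, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert df == 2
        assert H == pytest.approx(float(Fraction(32, 7)), rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(32 / 7, 2)), rel=1e-12)

    def test_all_values_identical_degenerates_to_h0_p1(self):
        H, df, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (H, p) == (0.0, 1.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])

    def test_tie_heavy_data_matches_reference_implementations(self):
        """Cross-implementation oracle on random tie-heavy data."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        for _ in range(10):
            groups = [rng.integers(0, 4, size=rng.integers(5, 15)).astype(float)
                      for _ in range(3)]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            H, df, p = kruskal_wallis(groups)
            long = pd.DataFrame(
                {
                    "value": np.concatenate(groups),
                    "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
                }
            )
            ref = pingouin.kruskal(data=long, dv="value", between="g")
            assert H == pytest.approx(float(ref["H"].iloc[0]), rel=1e-9)
            assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=12), rng.normal(1, 1, size=10), rng.normal(size=8)]
        H1, _, _ = kruskal_wallis(groups)
        H2, _, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert H1 == pytest.approx(H2, rel=1e-12)


class TestEtaSquared:
    @pytest.mark.parametrize(
        "H, k, n, expected",
        [
            (622.7, 3, 1451, 0.429),    # HB-GH init concurrency
            (526.413, 3, 1451, 0.362),  # TB-HB init
            (456.167, 3, 1451, 0.314),  # HB-GH sus
            (571.85, 3, 1451, 0.394),   # TB-HB sus
            (99.907, 3, 1451, 0.068),   # TB-GH init
            (78.472, 3, 345, 0.224),    # entropy, all bolus types
        ],
    )
    def test_reproduces_published_effect_sizes_to_3dp(self, H, k, n, expected):
        assert round(eta_squared(H, k, n), 3) == expected

    def test_null_expectation_h_gives_zero(self):
        assert eta_squared(2.0, 3, 100) == pytest.approx(0.0)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            eta_squared(1.0, 3, 3)
        with pytest.raises(ValueError):
            eta_squared(1.0, 1, 10)


def _dunn_oracle(groups):
    """Independent hand computation: midranks by explicit sorting, pooled
    tie correction, normal z per pair."""
    pooled = [v for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for idx in order[i:j]:
            ranks[idx] = mid
        i = j
    N = len(pooled)
    from collections import Counter

    ties = Counter(pooled)
    tie_sum = sum(t**3 - t for t in ties.values())
    var = N * (N + 1) / 12 - tie_sum / (12 * (N - 1))
    sizes = [len(g) for g in groups]
    starts = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[starts[i]:starts[i + 1]])) for i in range(len(groups))
    ]
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            out[(i, j)] = (z, 2 * stats.norm.sf(abs(z)))
    return out


class TestDunn:
    def test_identical_pair_has_p_near_one(self):
        table = dunn_posthoc([[1, 2, 3], [1, 2, 3], [10, 11, 12]], adjust="none")
        row = table[(table["group1"] == "group1") & (table["group2"] == "group2")]
        assert row["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_adjust_none_returns_raw(self):
        table = dunn_posthoc([[1, 2], [3, 4], [5, 6]], adjust="none")
        assert np.allclose(table["p_raw"], table["p_adj"])

    def test_holm_and_bonferroni_are_at_least_raw(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc, 1, 9) for loc in (0, 0.5, 1.5)]
        for method in ("holm", "bonferroni"):
            table = dunn_posthoc(groups, adjust=method)
            assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()
            assert (table["p_adj"] <= 1.0).all()

    def test_matches_hand_rank_oracle_on_tied_data(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            groups = [list(map(float, rng.integers(0, 5, rng.integers(4, 10))))
                      for _ in range(3)]
            if len(set(v for g in groups for v in g)) < 2:
                continue
            table = dunn_posthoc(groups, adjust="none")
            oracle = _dunn_oracle(groups)
            for _, row in table.iterrows():
                i = int(row["group1"][-1]) - 1
                j = int(row["group2"][-1]) - 1
                z, p = oracle[(i, j)]
                assert row["z"] == pytest.approx(z, rel=1e-9)
                assert row["p_raw"] == pytest.approx(p, rel=1e-9)

    def test_pairwise_table_has_k_choose_2_rows(self):
        table = dunn_posthoc([[1, 2], [2, 3], [3, 4], [4, 5]])
        assert len(table) == 6

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1, 2], []])


def test_compare_groups_bundles_everything():
    rng = np.random.default_rng(4)
    samples = {
        "young": rng.normal(1.0, 0.1, 30),
        "older": rng.normal(0.6, 0.2, 25),
        "dysphagic": list(rng.normal(0.4, 0.2, 20)) + [float("nan")],
    }
    comp = compare_groups("HB-GH_init", samples)
    assert comp.ns == (30, 25, 20)  # NaN dropped listwise
    assert comp.df == 2
    assert len(comp.dunn) == 3
    assert 0 <= comp.eta_squared <= 1
    table = comparison_table([comp])
    assert table.loc[0, "feature"] == "HB-GH_init"
    assert "young vs older p" in table.columns
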