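"""MLCS enumeration, adherence matrices and obligatory-chain extraction."""

from __future__ import annotations

import itertools
import random

import hypothesis.strategies as st
import pytest
from hypothesis import given, settings

from swallowseq import (
    SequenceSet,
    adherence_matrix,
    expand_permutations,
    extract_obligatory_chains,
    mlcs,
    mlcs_bruteforce,
    pool,
)
from swallowseq.obligatory import AdherenceMatrix, chains_report

from .conftest import make_swallow

TOY_STRINGS = ["ABCDEF", "FBADEC", "FABDCE"]


def seqset(strings: list[str]) -> SequenceSet:
    ss = SequenceSet(n_trials=len(strings))
    for i, s in enumerate(strings):
        ss.provenance[(f"t{i}", s)] += 1
    return ss


class TestMLCS:
    def test_toy_example_contains_the_named_lcs(self):
        assert "BDE" in mlcs(TOY_STRINGS)

    def test_toy_example_full_set_certified_by_oracle(self):
        # The brute-force oracle enumerates every subsequence: the complete
        # length-3 common set is {ADE, BDE}, not just the named B-D-E.
        oracle = mlcs_bruteforce(TOY_STRINGS)
        assert oracle == ["ADE", "BDE"]
        assert mlcs(TOY_STRINGS) == oracle

    def test_identical_sequences_return_themselves(self):
        assert mlcs(["ADGBEHCFI", "ADGBEHCFI"]) == ["ADGBEHCFI"]
        assert mlcs_bruteforce(["XY"]) == ["XY"]

    def test_no_shared_symbol_yields_empty_string(self):
        assert mlcs(["ABC", "XYZ"]) == [""]

    def test_crossing_pair(self):
        assert mlcs(["AB", "BA"]) == ["A", "B"] == mlcs_bruteforce(["AB", "BA"])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            mlcs([])
        with pytest.raises(ValueError):
            mlcs_bruteforce([])

    def test_bruteforce_guard(self):
        with pytest.raises(ValueError, match="guard"):
            mlcs_bruteforce(["A" * 20, "A" * 20])

    def test_repeated_symbols_within_strings(self):
        # general strings, not only 9-event permutations
        strings = ["ABAB", "BABA"]
        assert mlcs(strings) == mlcs_bruteforce(strings)

    @settings(max_examples=500, derandomize=True)
    @given(
        strings=st.lists(
            st.text(alphabet="ABCDEF", min_size=0, max_size=8),
            min_size=1,
            max_size=5,
        )
    )
    def test_mlcs_equals_bruteforce_on_random_instances(self, strings):
        result = mlcs(strings)
        assert result == mlcs_bruteforce(strings)
        # every answer is a common subsequence of maximal length
        for answer in result:
            for s in strings:
                it = iter(s)
                assert all(c in it for c in answer)

    def test_deduplication_invariance(self):
        assert mlcs(TOY_STRINGS * 3) == mlcs(TOY_STRINGS)


class TestAdherence:
    def test_unanimous_pair_and_complement(self):
        m = adherence_matrix(seqset(["ABC", "ACB", "BAC"]))
        assert m.n_sequences == 3
        assert m.probabilities.at["A", "C"] == 1.0  # A precedes C in all three
        assert m.is_unanimous("A", "C")
        assert m.probabilities.at["A", "B"] == pytest.approx(2 / 3)
        assert m.probabilities.at["B", "A"] == pytest.approx(1 / 3)

    def test_tied_pair_pool_gives_half_each_way(self):
        sw = make_swallow(tb=(0, 8, 12), hb=(0, 7, 11), gh=(3, 6, 10))  # A/D tied
        m = adherence_matrix(expand_permutations(sw))
        assert m.probabilities.at["A", "D"] == 0.5
        assert m.probabilities.at["D", "A"] == 0.5

    def test_complement_on_random_pools(self):
        rng = random.Random(3)
        for _ in range(25):
            strings = ["".join(rng.sample("ABCDE", 5)) for _ in range(rng.randint(1, 12))]
            m = adherence_matrix(seqset(strings))
            for a, b in itertools.combinations(m.labels, 2):
                assert m.probabilities.at[a, b] + m.probabilities.at[b, a] == pytest.approx(1.0)

    def test_unanimity_uses_exact_integer_counting(self):
        # 9999 of 10000 sequences: a float ratio would be 0.9999, never 1.0,
        # and exact counting must not round up.
        ss = SequenceSet(n_trials=2)
        ss.provenance[("t0", "AB")] = 9999
        ss.provenance[("t1", "BA")] = 1
        m = adherence_matrix(ss)
        assert not m.is_unanimous("A", "B")
        assert m.counts.at["A", "B"] == 9999

    def test_csv_roundtrip(self, tmp_path):
        m = adherence_matrix(seqset(["ABC", "ACB"]))
        path = tmp_path / "adherence.csv"
        m.to_csv(path)
        back = AdherenceMatrix.from_csv(path, n_sequences=m.n_sequences)
        assert back.probabilities.equals(m.probabilities)


class TestObligatoryChains:
    def test_published_matrix_recovers_the_four_nontrivial_chains(
        self, published_adherence_matrix
    ):
        chains = extract_obligatory_chains(
            published_adherence_matrix, nontrivial_only=True, longest_only=True
        )
        assert sorted(c.symbols for c in chains) == ["AEF", "AHI", "DHI", "GEF"]
        humans = {c.human for c in chains}
        assert "TB_on → GH_max → GH_off" in humans
        assert "HB_on → GH_max → GH_off" in humans
        assert "GH_on → HB_max → HB_off" in humans
        assert "TB_on → HB_max → HB_off" in humans
        assert not any(c.trivial for c in chains)

    def test_published_matrix_trivial_chains_kept_without_filter(
        self, published_adherence_matrix
    ):
        chains = extract_obligatory_chains(
            published_adherence_matrix, longest_only=True
        )
        symbols = {c.symbols for c in chains}
        assert {"ABC", "DEF", "GHI"} <= symbols  # the within-structure chains
        assert len(symbols) == 7

    def test_published_matrix_has_one_extension_maximal_pair_below_mlcs_length(
        self, published_adherence_matrix
    ):
        """HB_on → TB_off is unanimous yet extends into no 3-event chain; it
        is extension-maximal but, being shorter than the longest chains, is
        not an obligatory sequence under longest-common-subsequence
        semantics."""
        all_maximal = extract_obligatory_chains(published_adherence_matrix)
        assert "DC" in {c.symbols for c in all_maximal}
        longest = extract_obligatory_chains(
            published_adherence_matrix, longest_only=True
        )
        assert "DC" not in {c.symbols for c in longest}

    def test_only_within_structure_unanimity_yields_only_trivial_chains(self):
        # Two mirrored sequences: every cross-structure pair flips, only each
        # structure's own on<max<off order is unanimous.
        s1 = "ABC" + "DEF" + "GHI"
        s2 = "GHI" + "DEF" + "ABC"
        s3 = "DEF" + "GHI" + "ABC"
        m = adherence_matrix(seqset([s1, s2, s3]))
        all_chains = extract_obligatory_chains(m)
        assert sorted(c.symbols for c in all_chains) == ["ABC", "DEF", "GHI"]
        assert extract_obligatory_chains(m, nontrivial_only=True) == []

    def test_forced_global_order_yields_single_full_chain(self):
        m = adherence_matrix(seqset(["ADGBEHCFI"] * 5))
        chains = extract_obligatory_chains(m)
        assert [c.symbols for c in chains] == ["ADGBEHCFI"]
        assert not chains[0].trivial

    def test_chains_match_mlcs_on_pools(self):
        """Cross-validation: unanimous chains are common subsequences of every
        pooled sequence; the longest returned chains appear in the MLCS set
        restricted to pairwise-unanimous events."""
        rng = random.Random(17)
        for _ in range(10):
            base = "ADGBEHCFI"
            strings = []
            for _ in range(rng.randint(2, 6)):
                s = list(base)
                i = rng.randrange(8)
                s[i], s[i + 1] = s[i + 1], s[i]
                strings.append("".join(s))
            m = adherence_matrix(seqset(strings))
            chains = extract_obligatory_chains(m)
            for chain in chains:
                for s in strings:
                    it = iter(s)
                    assert all(c in it for c in chain.symbols)
            longest = max(len(c) for c in chains)
            mlcs_set = set(mlcs(strings))
            for chain in chains:
                if len(chain) == longest:
                    # a maximal unanimous chain of maximal length is an MLCS
                    assert any(chain.symbols == m_ for m_ in mlcs_set)

    def test_report_lists_both_symbol_and_human_forms(self, published_adherence_matrix):
        chains = extract_obligatory_chains(published_adherence_matrix, nontrivial_only=True)
        report = chains_report(chains)
        assert "AEF" in report and "TB_on → HB_max → HB_off" in report
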