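"""Obligatory event orders: multiple longest common subsequences and adherence.

An obligatory sequence is an event chain that every possible sequence of a
pool adheres to, i.e. a (multiple) longest common subsequence of the pool.
Two complementary routes are implemented:

* :func:`mlcs` — a leveled DAG search that enumerates the *full* set of
  longest common subsequences of arbitrarily many strings.  Level k of the
  DAG holds every length-k common subsequence, keyed by its greedy leftmost
  embedding into each input; edges append one symbol via per-string successor
  tables.  The deepest non-empty level is the MLCS set.
* :func:`adherence_matrix` / :func:`extract_obligatory_chains` — pairwise
  event-order probabilities (the fraction of sequences in which one event
  precedes another) and the maximal chains of pairs with unanimous (1.0)
  adherence.

For event pools the two routes agree: chains of unanimously ordered events
are exactly the common subsequences over those events (cross-validated in the
test suite).  Unanimity is decided by exact integer counting whenever counts
are available — 1.0 means literally every sequence.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .events import SYMBOL_TO_EVENT
from .expansion import SequenceSet

BRUTEFORCE_GUARD = 2**12


def _successor_table(s: str, alphabet: Sequence[str]) -> list[dict[str, int]]:
    """succ[i][c] = smallest j >= i with s[j] == c, or len(s) if none."""
    n = len(s)
    table: list[dict[str, int]] = [dict() for _ in range(n + 1)]
    nxt = {c: n for c in alphabet}
    table[n] = dict(nxt)
    for i in range(n - 1, -1, -1):
        nxt = dict(nxt)
        nxt[s[i]] = i
        table[i] = nxt
    return table


def mlcs(sequences: Iterable[str]) -> list[str]:
    """All longest common subsequences of a set of strings, lexicographic.

    Input multiplicity is irrelevant (sequences are deduplicated); symbols may
    repeat within a string.  Returns ``[""]`` when the inputs share no symbol.
    """
    seqs = sorted(set(sequences))
    if not seqs:
        raise ValueError("mlcs() requires at least one sequence")
    alphabet = sorted(set.intersection(*(set(s) for s in seqs)))
    succ = [_successor_table(s, alphabet) for s in seqs]

    # Leveled BFS: each node is a common subsequence, keyed by the end
    # positions of its greedy leftmost embedding in every input string.
    level: dict[str, tuple[int, ...]] = {"": tuple(0 for _ in seqs)}
    last = level
    while level:
        nxt: dict[str, tuple[int, ...]] = {}
        for prefix, pos in level.items():
            for c in alphabet:
                ends = tuple(succ[i][p][c] for i, p in enumerate(pos))
                if any(e >= len(seqs[i]) for i, e in enumerate(ends)):
                    continue
                nxt[prefix + c] = tuple(e + 1 for e in ends)
        if nxt:
            last = nxt
        level = nxt
    return sorted(last)


def _is_subsequence(sub: str, s: str) -> bool:
    it = iter(s)
    return all(c in it for c in sub)


def mlcs_bruteforce(sequences: Iterable[str]) -> list[str]:
    """Exhaustive-enumeration reference for :func:`mlcs` on tiny instances."""
    seqs = sorted(set(sequences))
    if not seqs:
        raise ValueError("mlcs_bruteforce() requires at least one sequence")
    shortest = min(seqs, key=len)
    if 2 ** len(shortest) > BRUTEFORCE_GUARD:
        raise ValueError(
            f"subsequence space 2^{len(shortest)} exceeds guard; use mlcs()"
        )
    candidates = {
        "".join(shortest[i] for i in range(len(shortest)) if mask >> i & 1)
        for mask in range(2 ** len(shortest))
    }
    common = [c for c in candidates if all(_is_subsequence(c, s) for s in seqs)]
    best = max(len(c) for c in common)
    return sorted(c for c in common if len(c) == best)


@dataclass
class AdherenceMatrix:
    """Pairwise event-order probabilities over a pool of sequences.

    ``probabilities[a][b]`` (wide DataFrame: row = first event, column =
    second) is the fraction of sequences in which a precedes b; complements
    sum to 1 for every ordered pair.  When built from a pool, integer
    precedence counts are kept so unanimity is exact.
    """

    probabilities: pd.DataFrame
    n_sequences: int
    counts: pd.DataFrame | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.probabilities.index)

    def is_unanimous(self, a: str, b: str, tol: float = 1e-12) -> bool:
        """True iff event a precedes event b in every sequence of the pool."""
        if a == b:
            return False
        if self.counts is not None:
            return int(self.counts.at[a, b]) == self.n_sequences
        return float(self.probabilities.at[a, b]) >= 1.0 - tol

    @classmethod
    def from_probabilities(
        cls, probabilities: pd.DataFrame, n_sequences: int = 0
    ) -> "AdherenceMatrix":
        """Wrap an externally reported probability table (no exact counts)."""
        return cls(probabilities=probabilities.astype(float), n_sequences=n_sequences)

    def to_csv(self, path) -> None:
        self.probabilities.to_csv(path, index_label="first_event")

    @classmethod
    def from_csv(cls, path, n_sequences: int = 0) -> "AdherenceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index.name = None
        return cls.from_probabilities(df, n_sequences=n_sequences)


def adherence_matrix(pool: SequenceSet | Iterable[str]) -> AdherenceMatrix:
    """Event-order probability matrix over the full permuted multiset."""
    if isinstance(pool, SequenceSet):
        weighted = list(pool.counts.items())
    else:
        weighted = list(Counter(pool).items())
    if not weighted:
        raise ValueError("adherence_matrix() requires a non-empty pool")

    labels = sorted({c for seq, _ in weighted for c in seq})
    idx = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    total = 0
    for seq, mult in weighted:
        total += mult
        order = [idx[c] for c in seq]
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                counts[a, b] += mult

    counts_df = pd.DataFrame(counts, index=labels, columns=labels)
    probs = counts_df.astype(float) / total
    np.fill_diagonal(probs.values, np.nan)
    return AdherenceMatrix(probabilities=probs, n_sequences=total, counts=counts_df)


@dataclass(frozen=True)
class ObligatoryChain:
    """A maximal chain of events whose pairwise order is unanimous."""

    events: tuple[str, ...]  # symbols, in order

    def __len__(self) -> int:
        return len(self.events)

    @property
    def symbols(self) -> str:
        return "".join(self.events)

    @property
    def trivial(self) -> bool:
        """True iff every event belongs to a single structure."""
        structures = {
            SYMBOL_TO_EVENT[s].structure for s in self.events if s in SYMBOL_TO_EVENT
        }
        return len(structures) <= 1

    @property
    def human(self) -> str:
        parts = [
            SYMBOL_TO_EVENT[s].label if s in SYMBOL_TO_EVENT else s for s in self.events
        ]
        return " → ".join(parts)


def extract_obligatory_chains(
    matrix: AdherenceMatrix,
    nontrivial_only: bool = False,
    tol: float = 1e-12,
    longest_only: bool = False,
) -> list[ObligatoryChain]:
    """Maximal chains of unanimously ordered events in an adherence matrix.

    A chain is maximal when no further event can be inserted (at either end or
    inside) while keeping every pairwise adherence at 1.0.  Unanimous
    precedence is transitive on real pools, so maximal chains coincide with
    maximal cliques of the comparability graph; each clique is ordered by its
    within-clique precedence.  Singleton "chains" are not reported.

    With ``longest_only`` the result keeps only chains of the maximum length
    found.  This mirrors longest-common-subsequence semantics: an obligatory
    sequence is a *longest* chain every pooled sequence adheres to, so a
    shorter unanimous pair that extends into no longer chain is not reported
    as an obligatory sequence even though it is extension-maximal.
    """
    labels = matrix.labels
    comp = nx.Graph()
    comp.add_nodes_from(labels)
    unanimous: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(labels, 2):
        if matrix.is_unanimous(a, b, tol):
            unanimous.add((a, b))
            comp.add_edge(a, b)
        elif matrix.is_unanimous(b, a, tol):
            unanimous.add((b, a))
            comp.add_edge(a, b)

    chains = []
    for clique in nx.find_cliques(comp):
        if len(clique) < 2:
            continue
        ordered = sorted(
            clique, key=lambda e: sum((e, other) in unanimous for other in clique),
            reverse=True,
        )
        # Sanity: consecutive members must really be unanimously ordered.
        if all((a, b) in unanimous for a, b in itertools.combinations(ordered, 2)):
            chains.append(ObligatoryChain(tuple(ordered)))
    if longest_only and chains:
        top = max(len(c) for c in chains)
        chains = [c for c in chains if len(c) == top]
    if nontrivial_only:
        chains = [c for c in chains if not c.trivial]
    return sorted(chains, key=lambda c: c.symbols)


def chains_report(chains: Sequence[ObligatoryChain]) -> str:
    """Plain-text report listing chains in symbol and human-readable form."""
    lines = [f"{len(chains)} maximal obligatory chain(s):"]
    for c in chains:
        tag = " [trivial]" if c.trivial else ""
        lines.append(f"  {c.symbols}: {c.human}{tag}")
    return "\n".join(lines)
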