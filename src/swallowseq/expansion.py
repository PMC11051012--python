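"""Permutation expansion of tied event timestamps into pseudo-DNA sequences.

At 15 Hz two or more event states frequently land on the same frame.  A trial
with tied timestamps does not determine a single total order of its nine
events; instead every maximal block of k tied events contributes all k!
orderings, so one trial expands into Π(kᵢ!) equally likely *possible
sequences*.  Each possible sequence is a permutation of the fixed 9-letter
alphabet and is handled as a 9-character string.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Iterator, Sequence

from .events import (
    ALPHABET,
    EVENTS,
    EVENT_TO_SYMBOL,
    SYMBOL_TO_EVENT,
    AnnotatedSwallow,
    EventState,
    State,
    Structure,
)

#: Guard against pathological expansion (e.g. a record with all nine frames
#: tied, which is legal input but expands to 9! = 362880 sequences).
MAX_SEQUENCES_PER_TRIAL = 10_000


class ExpansionOverflowError(RuntimeError):
    """Raised when a single trial would expand beyond the sequence cap."""


@dataclass(frozen=True)
class EventSequence:
    """A total ordering of the nine event states, stored as its symbol string."""

    symbols: str

    def __post_init__(self) -> None:
        if sorted(self.symbols) != sorted(ALPHABET):
            raise ValueError(
                f"sequence must be a permutation of {ALPHABET!r}, got {self.symbols!r}"
            )

    @property
    def events(self) -> tuple[EventState, ...]:
        return tuple(SYMBOL_TO_EVENT[s] for s in self.symbols)

    def respects_structure_order(self) -> bool:
        """True if every structure reads on, max, off by position.

        Sequences expanded from tied frames may positionally swap a
        structure's own tied states; on the underlying (equal) times the
        on ≤ max ≤ off relation still holds.
        """
        for s in Structure:
            pos = [self.symbols.index(EVENT_TO_SYMBOL[EventState(s, st)]) for st in State]
            if not pos[0] < pos[1] < pos[2]:
                return False
        return True

    def __str__(self) -> str:
        return self.symbols


def encode(sequence: EventSequence) -> str:
    """Pseudo-DNA string of a sequence (inverse of :func:`decode`)."""
    return sequence.symbols


def decode(string: str) -> EventSequence:
    """Parse a 9-letter pseudo-DNA string; rejects unknown or repeated symbols."""
    unknown = sorted(set(string) - set(ALPHABET))
    if unknown:
        raise ValueError(f"unknown symbol(s) {unknown} in {string!r}")
    repeated = sorted(s for s, c in Counter(string).items() if c > 1)
    if repeated:
        raise ValueError(f"repeated symbol(s) {repeated} in {string!r}")
    return EventSequence(string)


@dataclass
class SequenceSet:
    """Multiset of possible sequences with per-trial provenance.

    ``provenance`` maps (trial_id, sequence string) to its multiplicity; each
    permuted sequence occurrence carries equal probability mass, so
    multiplicities matter for the entropy downstream.
    """

    provenance: Counter = field(default_factory=Counter)
    n_trials: int = 0

    @property
    def counts(self) -> Counter:
        """Multiplicity of each unique sequence string, pooled over trials."""
        pooled: Counter = Counter()
        for (_, seq), k in self.provenance.items():
            pooled[seq] += k
        return pooled

    @property
    def size(self) -> int:
        """Total multiset size (number of possible-sequence occurrences)."""
        return sum(self.provenance.values())

    @property
    def unique_sequences(self) -> tuple[str, ...]:
        return tuple(sorted({seq for _, seq in self.provenance}))

    @property
    def n_unique(self) -> int:
        return len({seq for _, seq in self.provenance})

    def occurrences(self) -> Iterator[tuple[str, str]]:
        """Yield (trial_id, sequence) once per occurrence, deterministically."""
        for (trial_id, seq), k in sorted(self.provenance.items()):
            for _ in range(k):
                yield trial_id, seq

    def trial_counts(self, trial_id: str) -> Counter:
        return Counter({seq: k for (t, seq), k in self.provenance.items() if t == trial_id})

    @property
    def trial_ids(self) -> tuple[str, ...]:
        return tuple(sorted({t for t, _ in self.provenance}))


def expand_permutations(
    swallow: AnnotatedSwallow, max_sequences: int = MAX_SEQUENCES_PER_TRIAL
) -> SequenceSet:
    """Expand one trial into the multiset of all possible event sequences.

    Timestamps are sorted ascending; every maximal block of tied frames
    contributes all permutations of its members, so the total count is the
    product of the factorials of the tied-block sizes.
    """
    items = sorted(
        ((swallow.timestamps[e], EVENT_TO_SYMBOL[e]) for e in EVENTS),
        key=lambda fs: (fs[0], fs[1]),
    )
    blocks: list[list[str]] = []
    for frame, grp in itertools.groupby(items, key=lambda fs: fs[0]):
        blocks.append([sym for _, sym in grp])

    total = 1
    for b in blocks:
        total *= factorial(len(b))
    if total > max_sequences:
        raise ExpansionOverflowError(
            f"trial {swallow.trial_id} expands to {total} sequences "
            f"(cap {max_sequences})"
        )

    seqs = SequenceSet(n_trials=1)
    for combo in itertools.product(*(itertools.permutations(b) for b in blocks)):
        seq = "".join(itertools.chain.from_iterable(combo))
        seqs.provenance[(swallow.trial_id, seq)] += 1
    return seqs


def expand_all(swallows: Iterable[AnnotatedSwallow]) -> SequenceSet:
    """Expand and pool a collection of trials."""
    return pool(expand_permutations(s) for s in swallows)


def pool(sequence_sets: Iterable[SequenceSet]) -> SequenceSet:
    """Multiset union preserving provenance; trial counts are summed."""
    out = SequenceSet()
    n = 0
    for ss in sequence_sets:
        out.provenance.update(ss.provenance)
        out.n_trials += ss.n_trials
        n += 1
    if n == 0:
        raise ValueError("pool() requires a non-empty collection of SequenceSets")
    return out


def write_fasta(seqset: SequenceSet, path) -> None:
    """FASTA-like export: one record per possible-sequence occurrence.

    Headers read ``participant|consistency|volume|trial|perm_k`` so the file
    round-trips back into an identical multiset.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    per_trial: Counter = Counter()
    for trial_id, seq in seqset.occurrences():
        per_trial[trial_id] += 1
        records.append(
            SeqRecord(Seq(seq), id=f"{trial_id}|perm_{per_trial[trial_id]}", description="")
        )
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> SequenceSet:
    """Read a FASTA-like sequence export back into a :class:`SequenceSet`."""
    from Bio.SeqIO import parse as seqio_parse

    out = SequenceSet()
    trials: set[str] = set()
    for record in seqio_parse(str(path), "fasta"):
        trial_id, _, _ = record.id.rpartition("|perm_")
        seq = decode(str(record.seq)).symbols
        out.provenance[(trial_id, seq)] += 1
        trials.add(trial_id)
    out.n_trials = len(trials)
    return out
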