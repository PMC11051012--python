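"""Sequence variability as Shannon entropy of possible-sequence distributions.

Each participant's swallowing sequencing system, for one bolus condition, is
treated as a probability distribution over event sequences.  Trials of the
same participant, bolus volume and consistency are pooled; permutation
expansion makes every possible sequence occurrence equally likely, so
p(sequence) = multiplicity / pooled multiset size and the variability of the
system is the plug-in Shannon entropy H = −Σ p log p (bits by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .events import AnnotatedSwallow, Consistency, Group
from .expansion import SequenceSet, expand_permutations, pool

#: The bolus conditions common to every cohort: dry plus 5 mL of IDDSI 0–4.
MATCHED_CONDITIONS: frozenset[tuple[float | None, Consistency]] = frozenset(
    [(None, Consistency.DRY)]
    + [
        (5.0, c)
        for c in (
            Consistency.IDDSI0,
            Consistency.IDDSI1,
            Consistency.IDDSI2,
            Consistency.IDDSI3,
            Consistency.IDDSI4,
        )
    ]
)

GroupKey = tuple[str, float | None, str]


@dataclass
class AggregationGroup:
    """All trials of one participant for one bolus volume and consistency."""

    key: GroupKey  # (participant_id, bolus_volume_ml, consistency)
    group_label: Group
    pooled: SequenceSet

    @property
    def n_trials(self) -> int:
        return self.pooled.n_trials

    @property
    def n_unique_sequences(self) -> int:
        return self.pooled.n_unique


@dataclass(frozen=True)
class EntropyResult:
    key: GroupKey
    group_label: Group
    entropy: float
    probabilities: Mapping[str, float]
    n_trials: int
    pooled_size: int

    @property
    def n_unique(self) -> int:
        return len(self.probabilities)


def group_trials(
    swallows: Iterable[AnnotatedSwallow], matched_only: bool = False
) -> list[AggregationGroup]:
    """Partition trials into participant × bolus-condition aggregation groups.

    With ``matched_only`` only the six conditions shared by all cohorts
    (dry and 5 mL of IDDSI levels 0–4) are retained.
    """
    buckets: dict[GroupKey, list[AnnotatedSwallow]] = {}
    labels: dict[GroupKey, Group] = {}
    for sw in swallows:
        if matched_only and (sw.bolus_volume_ml, sw.consistency) not in MATCHED_CONDITIONS:
            continue
        key = (sw.participant_id, sw.bolus_volume_ml, sw.consistency.value)
        buckets.setdefault(key, []).append(sw)
        labels[key] = sw.group

    groups = []
    for key in sorted(buckets, key=lambda k: (k[0], k[2], k[1] if k[1] is not None else -1.0)):
        pooled = pool(expand_permutations(sw) for sw in buckets[key])
        groups.append(AggregationGroup(key=key, group_label=labels[key], pooled=pooled))
    return groups


def shannon_entropy(
    group: AggregationGroup,
    base: float = 2.0,
    weighting: Literal["pooled", "per-trial"] = "pooled",
) -> EntropyResult:
    """Plug-in Shannon entropy of one aggregation group's sequence distribution.

    ``pooled`` weighting (default): every possible-sequence occurrence in the
    pooled multiset is equally likely.  ``per-trial``: each trial carries total
    mass 1/n_trials, split uniformly over its own permutations, so trials with
    many ties do not dominate the distribution.
    """
    if group.pooled.size == 0:
        raise ValueError(f"empty aggregation group {group.key}")
    probs: dict[str, float] = {}
    if weighting == "pooled":
        total = group.pooled.size
        for seq, k in group.pooled.counts.items():
            probs[seq] = k / total
    elif weighting == "per-trial":
        trial_ids = group.pooled.trial_ids
        for tid in trial_ids:
            counts = group.pooled.trial_counts(tid)
            tsize = sum(counts.values())
            for seq, k in counts.items():
                probs[seq] = probs.get(seq, 0.0) + k / (tsize * len(trial_ids))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    h = -sum(p * math.log(p, base) for p in probs.values() if p > 0)
    return EntropyResult(
        key=group.key,
        group_label=group.group_label,
        entropy=max(h, 0.0),
        probabilities=probs,
        n_trials=group.n_trials,
        pooled_size=group.pooled.size,
    )


def entropy_table(
    groups: Iterable[AggregationGroup],
    base: float = 2.0,
    weighting: Literal["pooled", "per-trial"] = "pooled",
) -> pd.DataFrame:
    """One row per aggregation group with its entropy and bookkeeping counts."""
    rows = []
    for g in groups:
        res = shannon_entropy(g, base=base, weighting=weighting)
        rows.append(
            {
                "participant_id": g.key[0],
                "bolus_volume_ml": g.key[1],
                "consistency": g.key[2],
                "group": g.group_label.value,
                "n_trials": res.n_trials,
                "pooled_size": res.pooled_size,
                "n_unique": res.n_unique,
                "entropy_bits" if base == 2.0 else "entropy": res.entropy,
            }
        )
    return pd.DataFrame(rows)
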