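"""Shared fixtures: hand-built trials and the published adherence table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from swallowseq import (
    AnnotatedSwallow,
    Consistency,
    EventState,
    Group,
    State,
    Structure,
)
from swallowseq.obligatory import AdherenceMatrix


def make_swallow(
    tb: tuple[int, int, int],
    hb: tuple[int, int, int],
    gh: tuple[int, int, int],
    participant_id: str = "P01",
    group: Group = Group.HEALTHY_YOUNG,
    bolus_volume_ml: float | None = 5.0,
    consistency: Consistency = Consistency.IDDSI0,
    trial_index: int = 1,
) -> AnnotatedSwallow:
    """Build a validated trial from (on, max, off) frames per structure."""
    frames = {Structure.TB: tb, Structure.HB: hb, Structure.GH: gh}
    timestamps = {
        EventState(s, st): frames[s][i]
        for s in Structure
        for i, st in enumerate(State)
    }
    return AnnotatedSwallow(
        participant_id=participant_id,
        group=group,
        bolus_volume_ml=bolus_volume_ml,
        consistency=consistency,
        trial_index=trial_index,
        timestamps=timestamps,
    )


@pytest.fixture
def worked_example_swallow() -> AnnotatedSwallow:
    """The published worked-example frames: HB 173/180/182, GH 176/180/182.

    The tongue-base frames are not printed for that extract; the values here
    are synthetic, chosen so TB nests the other periods like the Gantt chart
    shows (TB_init ⊇ HB_init ⊇ GH_init, equal sustaining spans).
    """
    return make_swallow(tb=(172, 180, 182), hb=(173, 180, 182), gh=(176, 180, 182))


# Published event-order probability table for the healthy young cohort
# (upper triangle as printed; lower triangle by complement).  Symbol order:
# A=TB_on D=HB_on G=GH_on B=TB_max E=HB_max H=GH_max C=TB_off F=HB_off I=GH_off.
_PUBLISHED_UPPER: dict[tuple[str, str], float] = {
    ("A", "D"): 0.3838, ("A", "G"): 0.4963, ("A", "B"): 1.0, ("A", "E"): 1.0,
    ("A", "H"): 1.0, ("A", "C"): 1.0, ("A", "F"): 1.0, ("A", "I"): 1.0,
    ("D", "G"): 0.6162, ("D", "B"): 0.9998, ("D", "E"): 1.0, ("D", "H"): 1.0,
    ("D", "C"): 1.0, ("D", "F"): 1.0, ("D", "I"): 1.0,
    ("G", "B"): 0.9992, ("G", "E"): 1.0, ("G", "H"): 1.0, ("G", "C"): 0.9998,
    ("G", "F"): 1.0, ("G", "I"): 1.0,
    ("B", "E"): 0.4755, ("B", "H"): 0.5181, ("B", "C"): 1.0, ("B", "F"): 0.9858,
    ("B", "I"): 0.9793,
    ("E", "H"): 0.6105, ("E", "C"): 0.9529, ("E", "F"): 1.0, ("E", "I"): 0.9733,
    ("H", "C"): 0.9309, ("H", "F"): 0.9917, ("H", "I"): 1.0,
    ("C", "F"): 0.4804, ("C", "I"): 0.4904,
    ("F", "I"): 0.5302,
}


@pytest.fixture(scope="session")
def published_adherence_matrix() -> AdherenceMatrix:
    """The printed healthy-young event-order probability matrix."""
    labels = list("ABCDEFGHI")
    df = pd.DataFrame(np.nan, index=labels, columns=labels)
    for (a, b), p in _PUBLISHED_UPPER.items():
        df.at[a, b] = p
        df.at[b, a] = round(1.0 - p, 4)
    return AdherenceMatrix.from_probabilities(df, n_sequences=8309)
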