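"""Synthetic annotated swallow trials with controllable temporal structure.

The generator is a test scaffold, not a physiological simulator: each cohort
is described by a :class:`GroupProfile` whose *nesting factor* blends a fully
nested canonical timing template (every shorter period inside its longer
counterpart, as in highly concurrent healthy young swallows) with a
dissociated template (hyoid and geniohyoid periods pulled apart).  Gaussian
frame jitter is added, frames are rounded to the 15 Hz grid, each structure's
onset/maximum/offset triple is re-sorted to restore on ≤ max ≤ off, and a
tie-snap pass pulls events onto a neighbour's frame so permutation expansion
is exercised at realistic rates.  Identical seeds yield bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .events import (
    AnnotatedSwallow,
    Consistency,
    EventState,
    Group,
    State,
    Structure,
)

# Canonical event times (frames at 15 Hz, relative to trial start).  The
# nested template mirrors the concurrent Gantt profile of a healthy young
# swallow: onsets ascend TB < HB < GH, maxima descend GH < HB < TB and
# offsets ascend TB < HB < GH, so for every structure pair one initiating
# period nests inside the other and likewise for the sustaining periods
# (all six overlap coefficients are exactly 1), while all nine frames stay
# distinct — a zero-jitter trial expands to a single sequence.  The
# dissociated template pulls the hyoid period early and the geniohyoid
# period late, breaking the HB/GH and TB-sustain overlaps.
NESTED_TEMPLATE: dict[tuple[Structure, State], float] = {
    (Structure.TB, State.ON): 0.0,
    (Structure.TB, State.MAX): 9.0,
    (Structure.TB, State.OFF): 12.0,
    (Structure.HB, State.ON): 1.0,
    (Structure.HB, State.MAX): 8.0,
    (Structure.HB, State.OFF): 13.0,
    (Structure.GH, State.ON): 3.0,
    (Structure.GH, State.MAX): 7.0,
    (Structure.GH, State.OFF): 14.0,
}
DISSOCIATED_TEMPLATE: dict[tuple[Structure, State], float] = {
    (Structure.TB, State.ON): 0.0,
    (Structure.TB, State.MAX): 9.0,
    (Structure.TB, State.OFF): 12.0,
    (Structure.HB, State.ON): 1.0,
    (Structure.HB, State.MAX): 4.0,
    (Structure.HB, State.OFF): 6.0,
    (Structure.GH, State.ON): 8.0,
    (Structure.GH, State.MAX): 11.0,
    (Structure.GH, State.OFF): 14.0,
}

#: Trial protocol bolus menu: dry plus {5, 10} mL of IDDSI levels 0–4.
FULL_BOLUS_MENU: tuple[tuple[float | None, Consistency], ...] = (
    (None, Consistency.DRY),
) + tuple(
    (vol, cons)
    for vol in (5.0, 10.0)
    for cons in (
        Consistency.IDDSI0,
        Consistency.IDDSI1,
        Consistency.IDDSI2,
        Consistency.IDDSI3,
        Consistency.IDDSI4,
    )
)
#: The six conditions common to all cohorts (dry + 5 mL IDDSI 0–4).
MATCHED_BOLUS_MENU: tuple[tuple[float | None, Consistency], ...] = tuple(
    (vol, cons) for vol, cons in FULL_BOLUS_MENU if vol is None or vol == 5.0
)


@dataclass
class GroupProfile:
    """Generative description of one cohort's swallow timing."""

    label: Group
    n_participants: int
    nesting: float = 1.0        # 1 ⇒ fully nested periods, 0 ⇒ dissociated
    jitter_sd: float = 1.0      # Gaussian SD on each event time, in frames
    tie_snap: float = 0.2       # per-event chance of snapping onto the
                                # previous event's frame after rounding
    trials_per_bolus: int = 5
    bolus_menu: Sequence[tuple[float | None, Consistency]] = FULL_BOLUS_MENU
    participant_prefix: str = "P"
    frame_rate_hz: float = 15.0
    start_frame: float = 30.0   # nominal trial onset within the recording

    def canonical_times(self) -> dict[tuple[Structure, State], float]:
        """Nesting-blended canonical event times (before jitter)."""
        w = self.nesting
        return {
            key: w * NESTED_TEMPLATE[key] + (1.0 - w) * DISSOCIATED_TEMPLATE[key]
            for key in NESTED_TEMPLATE
        }

    def validate(self) -> None:
        if not 0.0 <= self.nesting <= 1.0:
            raise ValueError(f"nesting must lie in [0, 1], got {self.nesting}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not 0.0 <= self.tie_snap <= 1.0:
            raise ValueError("tie_snap must lie in [0, 1]")
        if self.n_participants < 1 or self.trials_per_bolus < 1:
            raise ValueError("n_participants and trials_per_bolus must be >= 1")
        times = self.canonical_times()
        for s in Structure:
            on, mx, off = (times[(s, st)] for st in State)
            if not on <= mx <= off:
                raise ValueError(f"infeasible profile: {s.value} canonical order broken")
        if self.start_frame - 6.0 * max(self.jitter_sd, 1.0) < 0:
            raise ValueError("infeasible profile: jitter can reach negative frames")


def _simulate_timestamps(
    profile: GroupProfile, rng: np.random.Generator
) -> dict[EventState, int]:
    times = profile.canonical_times()
    raw: dict[tuple[Structure, State], int] = {}
    for key, t in times.items():
        jittered = profile.start_frame + t + rng.normal(0.0, profile.jitter_sd)
        raw[key] = max(int(round(jittered)), 0)

    # Tie-snap: walk events in temporal order; with probability tie_snap pull
    # an event that already lies within one frame of its predecessor onto the
    # predecessor's frame.  Only near-coincident events can snap — at 15 Hz a
    # tie means two states fell inside the same 67 ms window, not that distant
    # events collapsed together.
    order = sorted(raw, key=lambda k: (raw[k], k[0].value, k[1].value))
    for prev, cur in zip(order, order[1:]):
        gap = raw[cur] - raw[prev]
        if gap == 1 and rng.random() < profile.tie_snap:
            raw[cur] = raw[prev]

    # Restore on <= max <= off within each structure.
    out: dict[EventState, int] = {}
    for s in Structure:
        vals = sorted(raw[(s, st)] for st in State)
        for st, v in zip(State, vals):
            out[EventState(s, st)] = v
    return out


def simulate_trials(
    profiles: Iterable[GroupProfile], seed: int | np.random.Generator = 0
) -> list[AnnotatedSwallow]:
    """Generate annotated trials for each profile, deterministically under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    swallows: list[AnnotatedSwallow] = []
    for profile in profiles:
        profile.validate()
        for p in range(1, profile.n_participants + 1):
            pid = f"{profile.participant_prefix}{p:02d}"
            for volume, consistency in profile.bolus_menu:
                for trial in range(1, profile.trials_per_bolus + 1):
                    swallows.append(
                        AnnotatedSwallow(
                            participant_id=pid,
                            group=profile.label,
                            bolus_volume_ml=volume,
                            consistency=consistency,
                            trial_index=trial,
                            timestamps=_simulate_timestamps(profile, rng),
                            frame_rate_hz=profile.frame_rate_hz,
                        )
                    )
    return swallows


def three_cohort_profiles() -> list[GroupProfile]:
    """Three cohort profiles (17/15/11 participants) with graded temporality.

    Nesting, jitter and tie rates all decrease from healthy young through
    healthy older to dysphagic, so by construction mean concurrency and mean
    sequence entropy both follow the young > older > dysphagic ordering.  The
    dysphagic cohort performs only three trials of the six matched bolus
    conditions (dry + 5 mL IDDSI 0–4).
    """
    return [
        GroupProfile(
            label=Group.HEALTHY_YOUNG,
            n_participants=17,
            nesting=1.0,
            jitter_sd=1.1,
            tie_snap=0.30,
            trials_per_bolus=5,
            participant_prefix="Y",
        ),
        GroupProfile(
            label=Group.HEALTHY_OLDER,
            n_participants=15,
            nesting=0.5,
            jitter_sd=0.8,
            tie_snap=0.20,
            trials_per_bolus=5,
            participant_prefix="O",
        ),
        GroupProfile(
            label=Group.DYSPHAGIC,
            n_participants=11,
            nesting=0.35,
            jitter_sd=0.5,
            tie_snap=0.08,
            trials_per_bolus=3,
            bolus_menu=MATCHED_BOLUS_MENU,
            participant_prefix="D",
        ),
    ]


def three_cohort_dataset(seed: int = 0) -> list[AnnotatedSwallow]:
    """End-to-end demo dataset: three cohorts with graded temporal structure."""
    return simulate_trials(three_cohort_profiles(), seed=seed)
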