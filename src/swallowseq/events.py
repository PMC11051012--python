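"""Event-state data model for annotated swallow trials.

A swallow trial is annotated with nine frame indices: the onset, maximum and
offset of three structures of interest (SOIs) — tongue base retraction (TB),
hyoid bone displacement (HB) and geniohyoid muscle contraction (GH).  Each
(structure, state) combination is one *event state* and carries a fixed
single-letter symbol so that a totally ordered trial can be written as a
9-letter pseudo-DNA string.

The span from onset up to (but excluding) the maximum frame is the
*initiating* period; the span from the maximum through the offset frame is the
*sustaining* period.  Frame indices are opaque non-negative integers — only
order and set membership matter, no 0/1-base is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping


class Structure(str, Enum):
    """Structure of interest tracked in the submental ultrasound view."""

    TB = "TB"  # tongue base retraction
    HB = "HB"  # hyoid bone displacement
    GH = "GH"  # geniohyoid muscle contraction


class State(str, Enum):
    """Movement state of one structure: onset, maximum, offset."""

    ON = "on"
    MAX = "max"
    OFF = "off"


class Phase(str, Enum):
    """Derived period of one structure's movement."""

    INIT = "init"  # onset .. maximum-1
    SUS = "sus"    # maximum .. offset


class Group(str, Enum):
    """Participant cohort."""

    HEALTHY_YOUNG = "healthy_young"
    HEALTHY_OLDER = "healthy_older"
    DYSPHAGIC = "dysphagic"


class Consistency(str, Enum):
    """Bolus consistency: dry swallow or IDDSI fluid level 0 (thin) .. 4."""

    DRY = "dry"
    IDDSI0 = "IDDSI0"
    IDDSI1 = "IDDSI1"
    IDDSI2 = "IDDSI2"
    IDDSI3 = "IDDSI3"
    IDDSI4 = "IDDSI4"


@dataclass(frozen=True)
class EventState:
    """One of the nine (structure, state) combinations."""

    structure: Structure
    state: State

    @property
    def symbol(self) -> str:
        return EVENT_TO_SYMBOL[self]

    @property
    def label(self) -> str:
        """Human-readable name, e.g. ``"HB_on"``."""
        return f"{self.structure.value}_{self.state.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


# Fixed bijective symbol mapping (pseudo-DNA alphabet).
ALPHABET = "ABCDEFGHI"
EVENTS: tuple[EventState, ...] = tuple(
    EventState(structure, state)
    for structure in (Structure.TB, Structure.HB, Structure.GH)
    for state in (State.ON, State.MAX, State.OFF)
)
EVENT_TO_SYMBOL: dict[EventState, str] = dict(zip(EVENTS, ALPHABET))
SYMBOL_TO_EVENT: dict[str, EventState] = {s: e for e, s in EVENT_TO_SYMBOL.items()}

#: Column names of the nine timestamps in the annotation CSV, in symbol order.
TIMESTAMP_COLUMNS: tuple[str, ...] = tuple(
    f"{e.structure.value.lower()}_{e.state.value}" for e in EVENTS
)


class AnnotationError(ValueError):
    """Structured rejection of a raw annotation record.

    ``violations`` lists every violated invariant, each tagged with the
    offending structure or field.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class AnnotatedSwallow:
    """One validated swallow trial: nine event-state frames plus metadata."""

    participant_id: str
    group: Group
    bolus_volume_ml: float | None
    consistency: Consistency
    trial_index: int
    timestamps: Mapping[EventState, int]
    frame_rate_hz: float = 15.0

    @property
    def trial_id(self) -> str:
        vol = "NA" if self.bolus_volume_ml is None else f"{self.bolus_volume_ml:g}"
        return (
            f"{self.participant_id}|{self.consistency.value}|{vol}"
            f"|t{self.trial_index}"
        )

    def frame(self, structure: Structure, state: State) -> int:
        return self.timestamps[EventState(structure, state)]

    @property
    def degenerate_structures(self) -> tuple[Structure, ...]:
        """Structures with a coincident onset/maximum or maximum/offset frame.

        Legal at 15 Hz (two states can fall in one frame) but flagged because
        an empty initiating period makes the overlap coefficient undefined.
        """
        out = []
        for s in Structure:
            on, mx, off = (self.frame(s, st) for st in State)
            if on == mx or mx == off:
                out.append(s)
        return tuple(out)


@dataclass(frozen=True)
class EventPeriod:
    """Contiguous frame set of one structure's initiating or sustaining phase."""

    structure: Structure
    phase: Phase
    frames: frozenset[int]

    def __post_init__(self) -> None:
        if self.frames:
            lo, hi = min(self.frames), max(self.frames)
            if len(self.frames) != hi - lo + 1:
                raise ValueError("period frames must be contiguous")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def name(self) -> str:
        return f"{self.structure.value}_{self.phase.value}"


def structure_periods(on: int, max_: int, off: int, structure: Structure = Structure.HB
                      ) -> tuple[EventPeriod, EventPeriod]:
    """Build (init, sus) periods from one structure's three frames.

    init = {on .. max-1} (empty iff on == max), sus = {max .. off}.
    """
    if not on <= max_ <= off:
        raise ValueError(f"frames must satisfy on <= max <= off, got {on},{max_},{off}")
    init = EventPeriod(structure, Phase.INIT, frozenset(range(on, max_)))
    sus = EventPeriod(structure, Phase.SUS, frozenset(range(max_, off + 1)))
    return init, sus


def build_periods(swallow: AnnotatedSwallow) -> dict[tuple[Structure, Phase], EventPeriod]:
    """Derive the six event periods (init and sus per structure) of a trial.

    For each structure init ∪ sus = {on .. off} and init ∩ sus = ∅; an empty
    init (on == max) is legal and simply yields an empty frame set.
    """
    periods: dict[tuple[Structure, Phase], EventPeriod] = {}
    for s in Structure:
        init, sus = structure_periods(
            swallow.frame(s, State.ON),
            swallow.frame(s, State.MAX),
            swallow.frame(s, State.OFF),
            structure=s,
        )
        periods[(s, Phase.INIT)] = init
        periods[(s, Phase.SUS)] = sus
    return periods


def _parse_frame(value: object) -> int:
    iv = int(value)  # type: ignore[arg-type]
    if float(value) != iv:  # type: ignore[arg-type]
        raise ValueError(f"frame index {value!r} is not an integer")
    if iv < 0:
        raise ValueError(f"frame index {iv} is negative")
    return iv


def validate_annotation(raw: Mapping[str, object]) -> AnnotatedSwallow:
    """Validate a raw field map into an :class:`AnnotatedSwallow`.

    Collects *every* violated invariant before rejecting, so a malformed row
    produces a complete diagnosis rather than the first failure.

    Raises
    ------
    AnnotationError
        With one tagged message per violation: ``missing SOI`` for absent
        timestamps, the structure name for an ``on <= max <= off`` breach, and
        field tags for metadata problems.
    """
    violations: list[str] = []

    timestamps: dict[EventState, int] = {}
    for event, col in zip(EVENTS, TIMESTAMP_COLUMNS):
        value = raw.get(col)
        if value is None or (isinstance(value, float) and value != value) or value == "":
            violations.append(f"missing SOI: {event.label} ({col})")
            continue
        try:
            timestamps[event] = _parse_frame(value)
        except (TypeError, ValueError) as exc:
            violations.append(f"{col}: {exc}")

    for s in Structure:
        frames = [timestamps.get(EventState(s, st)) for st in State]
        if any(f is None for f in frames):
            continue
        on, mx, off = frames  # type: ignore[misc]
        if not on <= mx <= off:
            violations.append(
                f"{s.value} monotonicity: on={on}, max={mx}, off={off}"
            )

    try:
        group = Group(str(raw.get("group")))
    except ValueError:
        violations.append(f"group: unknown label {raw.get('group')!r}")
        group = None  # type: ignore[assignment]
    try:
        consistency = Consistency(str(raw.get("consistency")))
    except ValueError:
        violations.append(f"consistency: unknown label {raw.get('consistency')!r}")
        consistency = None  # type: ignore[assignment]

    vol_raw = raw.get("bolus_volume_ml")
    volume: float | None
    if vol_raw is None or vol_raw == "" or (isinstance(vol_raw, float) and vol_raw != vol_raw):
        volume = None
        if consistency is not None and consistency != Consistency.DRY:
            violations.append("bolus_volume_ml: empty volume allowed only for dry swallows")
    else:
        try:
            volume = float(vol_raw)  # type: ignore[arg-type]
            if volume < 0:
                violations.append(f"bolus_volume_ml: negative volume {volume}")
        except (TypeError, ValueError):
            violations.append(f"bolus_volume_ml: unparseable {vol_raw!r}")
            volume = None

    try:
        trial_index = int(raw.get("trial_index"))  # type: ignore[arg-type]
        if trial_index < 1:
            violations.append(f"trial_index: must be positive, got {trial_index}")
    except (TypeError, ValueError):
        violations.append(f"trial_index: unparseable {raw.get('trial_index')!r}")
        trial_index = 0

    frame_rate = raw.get("frame_rate_hz", 15.0)
    try:
        frame_rate = float(frame_rate)  # type: ignore[arg-type]
        if frame_rate <= 0:
            violations.append(f"frame_rate_hz: must be positive, got {frame_rate}")
    except (TypeError, ValueError):
        violations.append(f"frame_rate_hz: unparseable {frame_rate!r}")
        frame_rate = 15.0

    if violations:
        raise AnnotationError(violations)

    return AnnotatedSwallow(
        participant_id=str(raw.get("participant_id")),
        group=group,
        bolus_volume_ml=volume,
        consistency=consistency,
        trial_index=trial_index,
        timestamps=timestamps,
        frame_rate_hz=frame_rate,
    )
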