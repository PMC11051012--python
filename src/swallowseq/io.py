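"""Annotation CSV reading/writing with row-level rejection accounting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .events import (
    EVENTS,
    TIMESTAMP_COLUMNS,
    AnnotatedSwallow,
    AnnotationError,
    Consistency,
    validate_annotation,
)

#: Fixed annotation-table header.
COLUMNS: tuple[str, ...] = (
    "participant_id",
    "group",
    "bolus_volume_ml",
    "consistency",
    "trial_index",
    "frame_rate_hz",
) + TIMESTAMP_COLUMNS


@dataclass(frozen=True)
class RejectedRow:
    row: int  # 0-based data-row index
    reasons: tuple[str, ...]


def swallows_to_frame(swallows: Iterable[AnnotatedSwallow]) -> pd.DataFrame:
    """Annotation table with the documented header, one row per trial."""
    rows = []
    for sw in swallows:
        row: dict[str, object] = {
            "participant_id": sw.participant_id,
            "group": sw.group.value,
            "bolus_volume_ml": "" if sw.bolus_volume_ml is None else sw.bolus_volume_ml,
            "consistency": sw.consistency.value,
            "trial_index": sw.trial_index,
            "frame_rate_hz": sw.frame_rate_hz,
        }
        for event, col in zip(EVENTS, TIMESTAMP_COLUMNS):
            row[col] = sw.timestamps[event]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_annotations(swallows: Iterable[AnnotatedSwallow], path) -> None:
    swallows_to_frame(swallows).to_csv(path, index=False)


def parse_annotations(
    df: pd.DataFrame,
) -> tuple[list[AnnotatedSwallow], list[RejectedRow]]:
    """Validate a DataFrame of raw annotation rows.

    Unknown extra columns are ignored with a warning.  A dry trial carrying a
    bolus volume gets the volume nulled with a warning.  Each rejected row is
    reported with every violated invariant.
    """
    missing = [c for c in COLUMNS if c not in df.columns and c != "frame_rate_hz"]
    if missing:
        raise ValueError(f"annotation table is missing required column(s): {missing}")
    extras = [c for c in df.columns if c not in COLUMNS]
    if extras:
        warnings.warn(f"ignoring unknown column(s): {extras}", stacklevel=2)

    accepted: list[AnnotatedSwallow] = []
    rejected: list[RejectedRow] = []
    for i, raw in enumerate(df.to_dict(orient="records")):
        vol = raw.get("bolus_volume_ml")
        has_vol = vol is not None and vol == vol and vol != ""
        if raw.get("consistency") == Consistency.DRY.value and has_vol:
            warnings.warn(
                f"row {i}: dry trial with bolus volume {vol!r}; volume nulled",
                stacklevel=2,
            )
            raw["bolus_volume_ml"] = None
        try:
            accepted.append(validate_annotation(raw))
        except AnnotationError as exc:
            rejected.append(RejectedRow(row=i, reasons=tuple(exc.violations)))
    return accepted, rejected


def read_annotations(path) -> tuple[list[AnnotatedSwallow], list[RejectedRow]]:
    """Read the annotation CSV; returns (accepted swallows, rejected rows)."""
    df = pd.read_csv(path)
    return parse_annotations(df)
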