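"""Pairwise movement concurrency via the Szymkiewicz–Simpson overlap coefficient.

For two event periods with frame sets P and Q the overlap coefficient is
SSC(P, Q) = |P ∩ Q| / min(|P|, |Q|); it equals 1 exactly when the shorter
period nests inside the longer, which is the physiological reading of "fully
concurrent".  An empty operand (a degenerate period with onset == maximum)
makes the coefficient undefined; such pairs are flagged and excluded from
group aggregation rather than coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .events import AnnotatedSwallow, Phase, Structure, build_periods

#: Structure pairs × phases, in reporting order.
PAIRS: tuple[tuple[Structure, Structure], ...] = (
    (Structure.HB, Structure.GH),
    (Structure.TB, Structure.GH),
    (Structure.TB, Structure.HB),
)
PAIR_NAMES: tuple[str, ...] = tuple(
    f"{a.value}-{b.value}_{phase.value}"
    for phase in (Phase.INIT, Phase.SUS)
    for a, b in PAIRS
)


def overlap_coefficient(P: AbstractSet[int], Q: AbstractSet[int]) -> float | None:
    """SSC of two finite frame sets; ``None`` when either set is empty."""
    m = min(len(P), len(Q))
    if m == 0:
        return None
    return len(set(P) & set(Q)) / m


@dataclass(frozen=True)
class ConcurrencyResult:
    """The six named overlap coefficients of one swallow (None = undefined)."""

    swallow_id: str
    group: str
    coefficients: Mapping[str, float | None]

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in self.coefficients.items() if v is not None}


def pairwise_concurrency(swallow: AnnotatedSwallow) -> ConcurrencyResult:
    """Compute the three structure-pair overlap coefficients per phase."""
    periods = build_periods(swallow)
    coeffs: dict[str, float | None] = {}
    for phase in (Phase.INIT, Phase.SUS):
        for a, b in PAIRS:
            name = f"{a.value}-{b.value}_{phase.value}"
            coeffs[name] = overlap_coefficient(
                periods[(a, phase)].frames, periods[(b, phase)].frames
            )
    return ConcurrencyResult(swallow.trial_id, swallow.group.value, coeffs)


def concurrency_table(swallows: Iterable[AnnotatedSwallow]) -> pd.DataFrame:
    """One row per swallow: the six coefficients plus undefined flags."""
    rows = []
    for sw in swallows:
        res = pairwise_concurrency(sw)
        row: dict[str, object] = {
            "swallow_id": res.swallow_id,
            "participant_id": sw.participant_id,
            "group": res.group,
        }
        row.update(res.coefficients)
        row["n_undefined"] = sum(v is None for v in res.coefficients.values())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_concurrency(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean, SD and 95% CI of each coefficient over defined values."""
    records = []
    for group, sub in table.groupby("group", sort=True):
        for name in PAIR_NAMES:
            vals = sub[name].dropna().to_numpy(dtype=float)
            n = len(vals)
            mean = float(np.mean(vals)) if n else np.nan
            sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
            if n > 1 and sd > 0:
                half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
            else:
                half = 0.0 if n else np.nan
            records.append(
                {
                    "group": group,
                    "pair": name,
                    "n": n,
                    "n_undefined": int(sub[name].isna().sum()),
                    "mean": mean,
                    "sd": sd,
                    "ci95_low": mean - half,
                    "ci95_high": mean + half,
                }
            )
    return pd.DataFrame(records)
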