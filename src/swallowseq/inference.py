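"""Nonparametric group comparison of sequence-derived features.

Kruskal–Wallis H (tie-corrected midranks, chi-square reference with k−1 df),
a rank-based eta-squared effect size η² = (H − k + 1)/(n − k), and Dunn's
post hoc z tests on pooled midranks with tie correction and Holm (default),
Bonferroni or no p-value adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ADJUST_METHODS = ("holm", "bonferroni", "none")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal–Wallis H test over k ≥ 2 non-empty groups.

    Returns (H, df, p).  When every pooled value is identical, H = 0 and
    p = 1 (the tie-degenerate convention).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis() requires at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis() groups must be non-empty")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), df, float(p)


def eta_squared(H: float, k: int, n: int) -> float:
    """Rank-based eta-squared effect size, (H − k + 1)/(n − k)."""
    if k < 2:
        raise ValueError("eta_squared() requires k >= 2 groups")
    if n <= k:
        raise ValueError(f"eta_squared() requires n > k, got n={n}, k={k}")
    return (H - k + 1) / (n - k)


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals.copy()
    if method == "bonferroni":
        return np.minimum(pvals * len(pvals), 1.0)
    if method == "holm":
        m = len(pvals)
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * pvals[i])
            adj[i] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}; options: {ADJUST_METHODS}")


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled midranks with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j))
    where ΣT = Σ (t³ − t) over tied value groups; two-sided normal p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("dunn_posthoc() groups must be non-empty")
    k = len(groups)
    if k < 2:
        raise ValueError("dunn_posthoc() requires at least two groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]

    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[bounds[i]:bounds[i + 1]])) for i in range(k)
    ]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {"group1": labels[i], "group2": labels[j], "z": float(z), "p_raw": p}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = _adjust(table["p_raw"].to_numpy(), adjust)
    return table


@dataclass
class GroupComparison:
    """Full nonparametric comparison of one feature across cohorts."""

    feature: str
    labels: tuple[str, ...]
    ns: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    H: float
    df: int
    pvalue: float
    eta_squared: float
    dunn: pd.DataFrame
    adjust: str

    @property
    def n_total(self) -> int:
        return sum(self.ns)

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {"feature": self.feature}
        for lab, n, m, sd in zip(self.labels, self.ns, self.means, self.sds):
            row[f"{lab}_n"] = n
            row[f"{lab}_mean"] = m
            row[f"{lab}_sd"] = sd
        row.update(
            {"df": self.df, "H": self.H, "p": self.pvalue, "eta2": self.eta_squared}
        )
        for _, r in self.dunn.iterrows():
            row[f"{r['group1']} vs {r['group2']} p"] = r["p_adj"]
        return row


def compare_groups(
    feature: str,
    samples: Mapping[str, Iterable[float]],
    adjust: str = "holm",
) -> GroupComparison:
    """Kruskal–Wallis + η² + Dunn post hoc for one feature.

    ``samples`` maps cohort label to that cohort's observed values; NaNs are
    dropped listwise per feature (their counts show up in the reported ns).
    """
    labels = tuple(samples.keys())
    groups = [
        np.asarray([v for v in vals if v == v], dtype=float)
        for vals in samples.values()
    ]
    if any(len(g) == 0 for g in groups):
        raise ValueError(f"feature {feature!r}: every cohort needs defined values")
    H, df, p = kruskal_wallis(groups)
    n = sum(len(g) for g in groups)
    eta2 = eta_squared(H, len(groups), n)
    dunn = dunn_posthoc(groups, labels=list(labels), adjust=adjust)
    return GroupComparison(
        feature=feature,
        labels=labels,
        ns=tuple(len(g) for g in groups),
        means=tuple(float(np.mean(g)) for g in groups),
        sds=tuple(float(np.std(g, ddof=1)) if len(g) > 1 else float("nan") for g in groups),
        H=H,
        df=df,
        pvalue=p,
        eta_squared=eta2,
        dunn=dunn,
        adjust=adjust,
    )


def comparison_table(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Wide report table: one row per feature (means, SD, H, df, p, η², Dunn)."""
    return pd.DataFrame([c.to_row() for c in comparisons])
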