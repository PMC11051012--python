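"""Top-level model/results interface tying the pipeline together.

:class:`SwallowSequenceAnalysis` is built from validated trials (or a
DataFrame / CSV in the standard annotation layout) plus analysis options;
``fit()`` runs the whole pipeline — permutation expansion, pairwise
concurrency, per-group entropy, per-cohort adherence and obligatory chains,
and the nonparametric cohort comparisons — and returns a
:class:`SwallowSequenceResults` carrying the tables with a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .concurrency import PAIR_NAMES, concurrency_table, summarize_concurrency
from .events import AnnotatedSwallow, Group
from .expansion import SequenceSet, expand_all
from .inference import GroupComparison, compare_groups, comparison_table
from .io import RejectedRow, parse_annotations
from .obligatory import AdherenceMatrix, ObligatoryChain, adherence_matrix, extract_obligatory_chains
from .variability import AggregationGroup, entropy_table, group_trials


class SwallowSequenceAnalysis:
    """Sequence analysis of a cohort-labelled swallow-trial dataset.

    Parameters
    ----------
    swallows
        Validated trials.
    matched_only
        Restrict entropy aggregation to the six bolus conditions shared by
        all cohorts (dry + 5 mL of IDDSI 0–4).
    entropy_base
        Logarithm base of the Shannon entropy (2 = bits, default).
    weighting
        ``"pooled"`` (each possible-sequence occurrence equally likely) or
        ``"per-trial"`` (each trial carries equal probability mass).
    adjust
        Dunn post hoc p-value adjustment: ``"holm"``, ``"bonferroni"``,
        ``"none"``.
    """

    def __init__(
        self,
        swallows: Sequence[AnnotatedSwallow],
        *,
        matched_only: bool = False,
        entropy_base: float = 2.0,
        weighting: Literal["pooled", "per-trial"] = "pooled",
        adjust: str = "holm",
    ):
        swallows = list(swallows)
        if not swallows:
            raise ValueError("analysis requires at least one valid swallow")
        self.swallows = swallows
        self.matched_only = matched_only
        self.entropy_base = entropy_base
        self.weighting = weighting
        self.adjust = adjust
        self.rejected: list[RejectedRow] = []

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **options) -> "SwallowSequenceAnalysis":
        swallows, rejected = parse_annotations(df)
        model = cls(swallows, **options)
        model.rejected = rejected
        return model

    @classmethod
    def from_csv(cls, path, **options) -> "SwallowSequenceAnalysis":
        return cls.from_dataframe(pd.read_csv(path), **options)

    def fit(self) -> "SwallowSequenceResults":
        concurrency = concurrency_table(self.swallows)
        concurrency_summary = summarize_concurrency(concurrency)

        groups = group_trials(self.swallows, matched_only=self.matched_only)
        entropies = entropy_table(groups, base=self.entropy_base, weighting=self.weighting)
        entropy_col = "entropy_bits" if self.entropy_base == 2.0 else "entropy"

        cohorts = sorted({sw.group for sw in self.swallows}, key=lambda g: g.value)
        pools: dict[str, SequenceSet] = {}
        adherence: dict[str, AdherenceMatrix] = {}
        chains: dict[str, list[ObligatoryChain]] = {}
        for cohort in cohorts:
            pool = expand_all(sw for sw in self.swallows if sw.group == cohort)
            pools[cohort.value] = pool
            matrix = adherence_matrix(pool)
            adherence[cohort.value] = matrix
            chains[cohort.value] = extract_obligatory_chains(
                matrix, nontrivial_only=True, longest_only=True
            )

        comparisons: list[GroupComparison] = []
        if len(cohorts) >= 2:
            for pair in PAIR_NAMES:
                samples = {
                    c.value: concurrency.loc[concurrency["group"] == c.value, pair]
                    .dropna()
                    .tolist()
                    for c in cohorts
                }
                if all(len(v) > 0 for v in samples.values()):
                    comparisons.append(compare_groups(pair, samples, adjust=self.adjust))
            ent_samples = {
                c.value: entropies.loc[entropies["group"] == c.value, entropy_col].tolist()
                for c in cohorts
            }
            if all(len(v) > 0 for v in ent_samples.values()):
                comparisons.append(
                    compare_groups(f"entropy ({'matched' if self.matched_only else 'all'} bolus)",
                                   ent_samples, adjust=self.adjust)
                )

        return SwallowSequenceResults(
            model=self,
            concurrency=concurrency,
            concurrency_summary=concurrency_summary,
            aggregation_groups=groups,
            entropies=entropies,
            pools=pools,
            adherence=adherence,
            obligatory_chains=chains,
            comparisons=comparisons,
        )


@dataclass
class SwallowSequenceResults:
    """Fitted pipeline outputs with reporting helpers."""

    model: SwallowSequenceAnalysis
    concurrency: pd.DataFrame
    concurrency_summary: pd.DataFrame
    aggregation_groups: list[AggregationGroup]
    entropies: pd.DataFrame
    pools: Mapping[str, SequenceSet]
    adherence: Mapping[str, AdherenceMatrix]
    obligatory_chains: Mapping[str, list[ObligatoryChain]]
    comparisons: list[GroupComparison]

    @property
    def comparison_table(self) -> pd.DataFrame:
        return comparison_table(self.comparisons)

    def summary(self) -> str:
        """Plain-text report: counts, SSC means, entropies, chains, tests."""
        model = self.model
        lines = ["Swallow sequence analysis", "=" * 25]
        lines.append(f"trials analysed: {len(model.swallows)}"
                     f" (rejected rows: {len(model.rejected)})")
        for cohort, pool in self.pools.items():
            lines.append(
                f"  {cohort}: {pool.n_trials} trials -> {pool.size} possible sequences"
                f" ({pool.n_unique} unique)"
            )

        lines.append("")
        lines.append("Mean overlap coefficients (defined values only)")
        pivot = self.concurrency_summary.pivot(index="pair", columns="group", values="mean")
        lines.append(pivot.round(3).to_string())

        lines.append("")
        label = "matched bolus conditions" if model.matched_only else "all bolus conditions"
        entropy_col = "entropy_bits" if model.entropy_base == 2.0 else "entropy"
        lines.append(f"Shannon entropy per participant-bolus group ({label})")
        ent = self.entropies.groupby("group")[entropy_col].agg(["count", "mean", "std"])
        lines.append(ent.round(3).to_string())

        lines.append("")
        lines.append("Maximal non-trivial obligatory chains per cohort")
        for cohort, chains in self.obligatory_chains.items():
            lines.append(f"  {cohort}:")
            if not chains:
                lines.append("    (none)")
            for c in chains:
                lines.append(f"    {c.symbols}: {c.human}")

        if self.comparisons:
            lines.append("")
            lines.append(f"Kruskal-Wallis / Dunn ({model.adjust}-adjusted) cohort comparisons")
            table = self.comparison_table.copy()
            num = table.select_dtypes("number").columns
            table[num] = table[num].round(3)
            lines.append(table.to_string(index=False))
        return "\n".join(lines)

    # -- optional plots ----------------------------------------------------
    def plot_concurrency(self, ax=None):
        """Bar plot of per-group mean overlap coefficients with 95% CI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        summary = self.concurrency_summary
        groups = sorted(summary["group"].unique())
        width = 0.8 / len(groups)
        for gi, group in enumerate(groups):
            sub = summary[summary["group"] == group].set_index("pair").loc[list(PAIR_NAMES)]
            x = [i + gi * width for i in range(len(PAIR_NAMES))]
            err = (sub["ci95_high"] - sub["mean"]).to_numpy()
            ax.bar(x, sub["mean"], width=width, yerr=err, label=group, capsize=2)
        ax.set_xticks([i + 0.4 - width / 2 for i in range(len(PAIR_NAMES))])
        ax.set_xticklabels(PAIR_NAMES, rotation=30, ha="right")
        ax.set_ylabel("mean overlap coefficient")
        ax.legend()
        return ax

    def plot_adherence(self, cohort: str, ax=None):
        """Heatmap of one cohort's event-order probability matrix."""
        import matplotlib.pyplot as plt
        import seaborn as sns

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        sns.heatmap(
            self.adherence[cohort].probabilities,
            vmin=0.0, vmax=1.0, annot=True, fmt=".2f", cmap="viridis", ax=ax,
        )
        ax.set_title(f"event order probability — {cohort}")
        return ax
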