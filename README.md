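# swallowseq

Sequence analyses of oropharyngeal swallowing temporality from annotated
event timestamps.

Swallowing is a tightly coordinated process: tongue base retraction (TB),
hyoid bone displacement (HB) and geniohyoid muscle contraction (GH) must
overlap in time to protect the airway and move the bolus. Instrumental
swallowing examinations (e.g. submental ultrasound at 15 Hz) yield, per
swallow trial, nine annotated video-frame indices — the onset, maximum and
offset of each structure's movement. `swallowseq` turns those nine integers
into quantitative temporal features for clinicians and deglutition
researchers comparing healthy young, healthy older and dysphagic cohorts:

- **Permutation expansion** — frames that tie at the acquisition frame rate
  do not determine a unique event order; every maximal block of k tied
  frames contributes all k! orderings, so a trial expands into Π(kᵢ!)
  equally likely *possible sequences*, encoded as 9-letter pseudo-DNA
  strings (`A`–`I` for TB_on … GH_off).
- **Concurrency** — the Szymkiewicz–Simpson overlap coefficient
  SSC(P, Q) = |P ∩ Q| / min(|P|, |Q|) over initiating (onset→maximum) and
  sustaining (maximum→offset) frame sets; SSC = 1 exactly when the shorter
  period nests inside the longer.
- **Variability** — the Shannon entropy H = −Σ p log₂ p of the distribution
  of possible sequences pooled per participant and bolus condition.
- **Obligatory sequences** — event chains every sequence adheres to, mined
  both as multiple longest common subsequences (a leveled-DAG enumeration
  of the complete MLCS set, with a brute-force oracle) and as maximal
  unanimous chains of a 9×9 event-order adherence matrix.
- **Group inference** — Kruskal–Wallis H with rank eta-squared
  η² = (H − k + 1)/(n − k) and Dunn's post hoc tests (Holm-adjusted by
  default).
- **Synthetic trials** — a seeded generator of cohort-graded annotation
  tables (nesting, jitter, tie frequency) so the whole pipeline is testable
  without clinical data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

The library is organised around a model/results pair:

```python
from swallowseq import SwallowSequenceAnalysis, three_cohort_dataset

swallows = three_cohort_dataset(seed=0)          # 1958 synthetic trials
results = SwallowSequenceAnalysis(swallows, matched_only=True).fit()
print(results.summary())
```

which prints (abridged):

```
Swallow sequence analysis
=========================
trials analysed: 1958 (rejected rows: 0)
  dysphagic: 198 trials -> 851 possible sequences (87 unique)
  healthy_older: 825 trials -> 4540 possible sequences (185 unique)
  healthy_young: 935 trials -> 5629 possible sequences (336 unique)

Mean overlap coefficients (defined values only)
group       dysphagic  healthy_older  healthy_young
HB-GH_init      0.009          0.199          0.960
HB-GH_sus       0.050          0.357          0.966
...

Shannon entropy per participant-bolus group (matched bolus conditions)
               count   mean    std
dysphagic         66  2.920  0.869
healthy_older     90  4.139  0.534
healthy_young    102  4.354  0.575
```

Reading the output: each trial's tied frames were expanded into possible
sequences (935 young trials yield 5,629 of them). The healthy young cohort
swallows with near-total HB–GH concurrency (mean SSC 0.96) that is
progressively lost with aging (0.20) and dysphagia (0.01) — the generator
builds in exactly this dissociation gradient — while sequence variability
(entropy per participant-bolus group, in bits) declines from young through
older to dysphagic. The fitted results also carry per-cohort adherence
matrices, the mined obligatory chains, and the Kruskal–Wallis/η²/Dunn
comparison table (`results.comparison_table`).

Single computations are available as plain functions, e.g. the
single-swallow extract annotated at HB 173/180/182 and GH 176/180/182:

```python
from swallowseq import overlap_coefficient, structure_periods
from swallowseq.events import Structure

hb_init, hb_sus = structure_periods(173, 180, 182, Structure.HB)
gh_init, gh_sus = structure_periods(176, 180, 182, Structure.GH)
overlap_coefficient(hb_init.frames, gh_init.frames)   # 1.0 — GH_init nests in HB_init
overlap_coefficient(hb_sus.frames, gh_sus.frames)     # 1.0 — identical frame sets
```

## Command line

Every stage is exposed as a subcommand over the standard annotation CSV
(`participant_id, group, bolus_volume_ml, consistency, trial_index,
frame_rate_hz, tb_on, … gh_off`):

```bash
swallowseq simulate --outdir out --seed 0        # synthetic annotation CSV
swallowseq validate --input out/annotations.csv  # row-level diagnostics
swallowseq concurrency --input out/annotations.csv --outdir out
swallowseq entropy --input out/annotations.csv --outdir out --matched-only
swallowseq adherence --input out/annotations.csv --outdir out
swallowseq stats --input out/annotations.csv --outdir out
swallowseq mlcs --input sequences.txt            # MLCS of plain-text strings
swallowseq demo --outdir out --seed 0            # full pipeline + report.txt
```

Each run echoes its configuration to a JSON file beside its outputs.

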