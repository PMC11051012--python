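# Methods

`swallowseq` quantifies the temporality of oropharyngeal swallowing from
annotated event timestamps. A swallow trial is described by nine video-frame
indices at a fixed frame rate (15 Hz by default): the onset, maximum and
offset of tongue base retraction (TB), hyoid bone displacement (HB) and
geniohyoid muscle contraction (GH). Everything downstream is derived from
those nine integers; no image processing is performed.

## Data model

Each (structure, state) combination is one *event state*, carrying a fixed
single-letter symbol so a totally ordered trial can be written as a 9-letter
pseudo-DNA string:

| TB_on | TB_max | TB_off | HB_on | HB_max | HB_off | GH_on | GH_max | GH_off |
|-------|--------|--------|-------|--------|--------|-------|--------|--------|
| A     | B      | C      | D     | E      | F      | G     | H      | I      |

For each structure the *initiating* period is the frame set
{on, …, max − 1} (empty when onset and maximum coincide) and the
*sustaining* period is {max, …, off}. The two partition {on..off}, and the
boundary convention — maximum excluded from init, included in sus — follows
the convention evident from the printed frame sets of the source protocol's
worked example. Frame indices are opaque non-negative integers: only order
and set membership matter, so no 0- or 1-based origin is assumed.

Validation enforces on ≤ max ≤ off per structure and the presence of all
nine timestamps; a record failing either is rejected with every violated
invariant listed (trials with missing structures are discarded, mirroring
clinical practice where out-of-view structures void a trial). Coincident
on = max or max = off frames are legal — at 15 Hz two states can genuinely
fall inside one 67 ms frame — and are only flagged, because an empty
initiating period makes the overlap coefficient undefined.

## Permutation expansion of tied timestamps

Sorting the nine frames ascending does not determine a unique event order
when frames tie. Every maximal block of k tied frames contributes all k!
orderings, so one trial expands into Π(kᵢ!) *possible sequences*, each
treated as equally likely. This generalizes uniformly to ties of any block
size ≥ 2 (a rule stated only for three-way ties would leave the frequent
two-way ties undefined). All k! orderings of a tied block are emitted, even
when a block spans one structure's own states (legal only when those frames
are equal, so the on ≤ max ≤ off relation still holds on the underlying
times); a helper reports whether a sequence also keeps the positional
on ≺ max ≺ off reading.

A guard caps expansion at 10,000 sequences per trial. The cap is reachable
in principle — a fully degenerate record with all nine frames equal would
expand to 9! = 362,880 — but such a record describes no observable swallow;
the guard raises a clear error rather than silently truncating.

Sequence multisets retain per-trial provenance and support a FASTA-like
export (one record per possible-sequence occurrence) for interoperability
with sequence tooling.

## Concurrency: overlap coefficient

For two periods with frame sets P and Q the Szymkiewicz–Simpson overlap
coefficient is

    SSC(P, Q) = |P ∩ Q| / min(|P|, |Q|),

which equals 1 exactly when the shorter period nests inside the longer —
the physiological reading of "fully concurrent". Six coefficients are
computed per swallow (three structure pairs × initiating/sustaining). An
empty operand makes the coefficient undefined; such pairs are flagged and
excluded from aggregation (with logged counts) rather than coerced to 0 or
1, either of which would bias group means. Group reporting uses mean ± SD
with a t-based 95% CI over defined values.

## Variability: Shannon entropy

Each participant's swallowing sequencing system, for one bolus volume and
consistency, is modelled as a probability distribution over event
sequences. All of a participant's trials with the same bolus condition are
pooled; with the default *pooled* weighting every possible-sequence
occurrence is equally likely, p(s) = multiplicity(s) / pooled size, and the
variability is the plug-in Shannon entropy H = −Σ p log₂ p in bits
(natural-log option available; the choice of base only rescales group
comparisons). A *per-trial* weighting is available in which each trial
carries total mass 1/n_trials split uniformly over its own permutations, so
tie-heavy trials do not dominate. The aggregation unit is per participant
per bolus condition; a *matched-only* switch restricts the analysis to the
six conditions shared by all cohorts (dry plus 5 mL of IDDSI levels 0–4)
so cohorts are compared on a common menu.

H is a plug-in estimate: it is biased low at small trial counts and no
entropy-rate or Markov structure is modelled.

## Obligatory sequences: MLCS and adherence

An obligatory sequence is an event chain that *every* possible sequence of
a pool adheres to — formally a (multiple) longest common subsequence
(MLCS). Two routes are implemented and cross-validated:

1. **Leveled DAG MLCS.** Level k of the DAG holds every length-k common
   subsequence, keyed by the end positions of its greedy leftmost embedding
   into each input string (per-string successor tables give O(1) symbol
   extension). The deepest non-empty level is the complete MLCS set,
   returned in lexicographic order. This enumeration is exhaustive by
   construction; classic dominant-point pruning was deliberately avoided
   because pruning a dominated point can drop distinct co-optimal strings
   that share its suffix but not its prefix. Inputs are deduplicated first
   (common subsequences are multiplicity-invariant). Worst-case node count
   grows with the number of distinct common subsequences, which is at most
   2⁹ for 9-symbol permutation pools and small for every intended use; no
   heuristic variant for very long strings is provided.
2. **Adherence matrices.** Entry (a, b) is the fraction of pooled
   sequences in which event a precedes event b; complements satisfy
   (a, b) + (b, a) = 1. Unanimity is decided by exact integer counting
   whenever counts are available — 1.0 means literally every sequence, with
   no floating-point tolerance. Chains of unanimously ordered events are
   enumerated as maximal cliques of the comparability graph (unanimous
   precedence is transitive on real pools, so cliques are totally ordered).

A *maximal* chain cannot be extended at either end or inside; a chain is
*trivial* when all its events belong to one structure (a structure's own
on → max → off order is obligatory by definition and uninformative).
Because obligatory sequences are defined through *longest* common
subsequences, the reporting mode used by the pipeline additionally keeps
only chains of the maximum length found (`longest_only`). The distinction
matters: a unanimous pair that extends into no longer chain is
extension-maximal yet is not an MLCS, and published adherence tables can
contain exactly such pairs. Both views are available.

## Group inference

Cohort effects on each sequence feature (six overlap coefficients, group
entropy) are tested with Kruskal–Wallis H on midranks with tie correction
(chi-square reference, k − 1 df; the all-values-identical degenerate case
returns H = 0, p = 1). The rank eta-squared effect size is

    η² = (H − k + 1) / (n − k),

adopted because it reproduces six of the printed effect sizes of the
reference analysis from their (H, k, n) triples to three decimals.
Pairwise contrasts use Dunn's z on pooled midranks with tie correction;
p-values are Holm-adjusted by default (Bonferroni and unadjusted
available — the reference analysis does not state its adjustment, and the
printed post hoc values cannot adjudicate it). Undefined coefficients are
excluded listwise per feature with their counts reported.

## Synthetic data generator

No raw annotations are publicly deposited, so the generator emulates the
annotation table: three cohorts (healthy young, healthy older, dysphagic),
a bolus menu of dry plus {5, 10} mL at IDDSI levels 0–4, and three to five
trials per condition. Each cohort profile blends two canonical timing
templates by a *nesting factor*: a fully nested template (onsets ascend
TB < HB < GH, maxima descend, offsets ascend, so all six overlap
coefficients are exactly 1 while all nine frames stay distinct) and a
dissociated template (hyoid period early, geniohyoid late). Gaussian jitter
(SD in frames) is added per event, frames are rounded to the 15 Hz grid,
each structure's triple is re-sorted to restore on ≤ max ≤ off, and a
tie-snap pass pulls an event already within one frame of its predecessor
onto the same frame with a configurable probability — ties arise only from
near-coincidence, as they would at 15 Hz, never from distant events
collapsing. Identical seeds give bit-identical datasets.

The demonstration dataset sizes the cohorts 17/15/11 with nesting, jitter
and tie rates all decreasing young → older → dysphagic (nesting 1.0/0.5/
0.35, jitter SD 1.1/0.8/0.5 frames, tie-snap 0.30/0.20/0.08), the dysphagic
cohort restricted to three trials of the six matched conditions. By
construction mean concurrency and mean entropy follow the young > older >
dysphagic ordering; the tests assert those orderings and chain recovery,
not specific means. The generator captures tie frequency, nesting structure
and cohort gradients, but not biomechanics, bolus-volume kinematics,
annotation error or inter-rater disagreement — passing tests therefore
certify the analysis machinery, not physiological claims about real
cohorts.

## Numerical choices and degenerate inputs

- Unanimity in adherence is integer-exact; matrices ingested from printed
  tables (floats) use a 1e−12 tolerance instead.
- Overlap coefficients with an empty operand are `None`, never 0/1.
- Entropy of a single unique sequence is exactly 0; probabilities are
  validated to sum to 1 within 1e−9.
- Permutation output order is deterministic (blocks in frame order, symbols
  lexicographic within a block); MLCS output is lexicographic.
- Report tables round to 3 decimals; stored CSVs keep full precision.
- All randomness flows through a single seeded NumPy generator.

## Problem sizes

The default test suite and the demonstration pipeline run ~2,000 synthetic
trials (≈ 5,600 possible sequences in the largest cohort), 500-instance
randomized MLCS cross-checks, and 10,000 null simulations for the
Kruskal–Wallis type-I-rate check; the full suite completes in well under a
minute on one CPU.

## Known limitations

- The plug-in entropy is not debiased; compare groups at similar trial
  counts.
- The uniform-permutation probability model treats every tied ordering as
  equally likely; no kinematic prior is applied.
- Chain extraction assumes the unanimity relation is transitively
  consistent, which holds for matrices computed from pools; hand-edited
  matrices violating it are dropped from the clique ordering with no
  repair attempted.
- The generator's cohort differences are stylized gradients, not fitted to
  any clinical dataset.
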