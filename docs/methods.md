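# Methods

## Model and procedure

`hopperpath` implements a rule-based, pathway-level reading of a
two-genotype × two-timepoint insect-infestation transcriptome
experiment.  There is no statistical model fitted at the pathway level:
the pipeline is a deterministic composition of a gene-level significance
filter, a set-valued mapping of genes onto pathways, a three-state
aggregation rule, a Venn partition and a class ruleset.  Its value is
reproducibility and testability of what is otherwise a manual
viewer-and-spreadsheet workflow.

**Gene-level filter.**  A record (gene, ratio, q) is differentially
expressed iff ratio ≥ t or ratio ≤ 1/t, with q < q_max.  Defaults
t = 2.0 (inclusive on both bounds) and q_max = 0.05 (strict).  Ratios
are always positive, oriented first-named-condition over second; signed
log2 input is canonicalized as ratio = 2^x.  The q-values are produced
upstream (SAM-style FDR in the original workflow) and are consumed,
never computed, here.

**Pathway calls.**  A pathway is called in a contrast iff at least one
DE gene maps to it — there is no minimum-gene rule, mirroring how
pathway-painting viewers highlight any pathway containing a gene above
threshold.  The direction is UP if all DE member genes are up, DOWN if
all are down, MIXED otherwise.  A locus observed through multiple probes
with conflicting directions contributes both directions (forcing MIXED):
evidence is preserved rather than averaged.  For genotype contrasts the
same states render as higher/lower/higher-lower with the resistant line
in the numerator.

**Shared/unique tallies.**  The up-regulated and down-regulated pathway
sets of the two temporal contrasts are intersected and differenced.
MIXED calls are excluded from these pure-direction tallies (they belong
to neither "up" nor "down") but still count as differentially regulated
in the per-category tabulation.  This exclusion is a documented choice;
the source analysis does not state how it handled mixed calls there.

**Venn partition.**  Each called pathway belongs to exactly one of the
15 non-empty subsets of the four contrasts.  Disjointness and coverage
are asserted on every run, not only in tests.

**Classes.**  With presence meaning "any call, including MIXED":

* resistance I:  `R6_R0` ∧ ¬`S6_S0` ∧ `R6_S6` ∧ ¬`R0_S0`
* resistance II: `R6_R0` ∧ ¬`S6_S0` ∧ `R6_S6` ∧ `R0_S0`
* Class III:     `R6_R0` and `S6_S0` both pure and strictly opposing
  (UP vs DOWN) ∧ `R6_S6`; `R0_S0` unconstrained.

Susceptibility I/II swap `R6_R0` and `S6_S0`; Class III is identical on
both axes by construction.  Two readings were genuinely open and were
fixed as follows: (a) the Class III wording ties the genotype-difference
requirement to "after attack and/or not before attack", which is read as
`R6_S6` required, `R0_S0` optional — consistent with the curated grid,
where one Class III pathway has a before-attack call and the other does
not; (b) "opposing differential changes" requires pure UP vs pure DOWN;
a MIXED call never opposes anything, since treating it as opposing would
be unfalsifiable from the published calls.  MIXED does satisfy
presence/absence tests in Classes I/II, because up/down is explicitly a
regulation state.  Susceptibility Class I is implemented although the
curated grid has no member; the simulator can plant it.

## Packaged reference data

Two small TSVs ship with the package: the per-contrast direction grid of
the 25 classed pathways and the free-amino-acid concentration table
(means ± SE, µg per g fresh weight, four conditions) from the
rice–SBPH study the pipeline models.  Both are inputs, not outputs: the
classifiers and the percent-change routine recompute everything from
them at run time.

**Percent change** is 100 × (after − before)/before, rounded to one
decimal half away from zero — the convention that reproduces the
published values (−46.97 → −47.0, 895.65 → 895.7).  Five analytes
(methionine, cystine, aspartic acid, cystathionine, serine) have
published change values that do not follow from their published
concentrations under any rounding; the table writer flags these rows
(|recomputed − printed| > 0.05, i.e. half of the last printed decimal)
instead of reconciling them.  The Total row is recomputed twice: from
the printed Total concentrations and from the column sums of the
analytes; the two disagree for the susceptible line (−47.0 vs −39.1),
which is a property of the source table, not of this code.

## Synthetic data

The generator emulates the statistical *shape* of the experiment — four
contrasts, ratio/q filtering, pathway membership — not microarray
physics.  Defaults: 30 pathways with gene counts drawn as
Poisson(mean 4, floor 1), 200 background genes outside any pathway, DE
effect sizes |log2 ratio| = max(1, N(1.5, 0.5)) so the filter (not the
generator) is the binding constraint, DE q ~ U(0, 0.0499), non-DE genes
get ratio 2^U(−0.9, 0.9) and q ~ U(0.05, 1) so both filter arms fail.
Planted patterns are realized exactly: every member gene of a planted
pathway is DE in the planted direction (MIXED alternates up/down across
members, and a planted MIXED pathway is grown to ≥ 2 genes), and member
genes of planted pathways are never DE in unplanted contrasts.  Pathway
gene sets are disjoint, which is what makes exact planting possible;
real pathway databases overlap, so false co-calls through shared loci
are not simulated.  Background genes become DE independently per
contrast with probability `background_de_prob` (default 0), producing
false pathway calls exactly the way the one-gene-calls-a-pathway rule
predicts.  Optional duplicate probes (with or without direction
conflicts) and unmapped probes exercise the translation and MIXED logic.
All randomness flows from one `numpy` `default_rng(seed)`; identical
configs give byte-identical files.

Passing recovery tests on these bundles shows the pipeline inverts its
own generative conventions perfectly in the noise-free case and degrades
only through background false calls; it does not validate normalization,
probe summarization or q-value estimation, which are upstream of this
package.

A separate truth-table implementation of the class rules inside the
simulator (not the classifier in `venn_classify`) labels each planted
pattern, so classifier/ground-truth agreement is a genuine two-route
check.

## Numerical and degenerate-input choices

* Fold-change bounds inclusive (2.0 and 0.5 both significant), q strict.
* Percent-change rounding via `decimal` with ROUND_HALF_UP (ties away
  from zero), avoiding binary-float round-half-even artifacts.
* Empty inputs: no records → no calls → empty partition; a pattern with
  zero calls is invalid by construction.
* Duplicate (pathway, gene) database rows deduplicate silently; a
  pathway id reappearing with a different name or hierarchy is an error
  (exit code 3).  Unknown loci map to no pathway; unmapped probes are
  dropped and counted, never fatal.
* Category tabulation clamps the requested hierarchy level to the
  deepest available, so one-level pathways group at their root.
* All outputs are sorted (pathway id, category order), so identical
  inputs give byte-identical outputs.

## Problem sizes

The test suite and acceptance script run on desk-scale instances chosen
as the package's own working sizes: the 25-pathway curated grid, toy
databases of ≤ 6 pathways, exhaustive enumeration of all 4^4 = 256
direction patterns, 100 × 10 random Venn instances, and noise-free
recovery bundles of 30 pathways across 5 seeds.  The original
experiment's gene-level counts (thousands of DE probes) are not
reproducible without the undeposited arrays and are treated as
descriptive context only.

## Known limitations

* Pathway membership via transport reactions, reaction-level resolution
  and compound modeling are out of scope; only pathway↔gene links exist.
* No graphical output (Venn rendering, pathway diagrams); every figure
  of the source workflow is reproduced as a table.
* The ranking of "strongest" responses among classed pathways has no
  stated metric in the source analysis and is not implemented.
* The simulator's disjoint pathway membership understates the
  correlation between pathway calls seen with real, overlapping
  databases.
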