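# Methods

## Model and procedure

`pepclust` clusters short peptides (typically 7–20 residues) by
progressive cluster growth. The working assumption is that a dataset
mixes (i) sequences carrying one of several short linear motifs —
a handful of constrained positions inside otherwise unconstrained
flanks — and (ii) noise: sequences with no motif, arising from
nonspecific binding or amplification bias. The goal is to recover one
cluster per motif, each with a multiple sequence alignment (MSA), and
to leave noise unassigned rather than force it into clusters.

### Greedy seeding

Unique sequences (duplicates collapsed, per-label copy counts kept) are
sorted — by total copy number descending by default, since high-copy
clones are the most reliable founders in display data — and swept once.
Each sequence is scored against all current representatives with a
deliberately restricted alignment: no inner gaps, only a relative shift
bounded by `max_shift` (default 1), overhangs scoring zero, scores from
a substitution matrix (BLOSUM62 default; any NCBI-format matrix file
can be substituted). The sequence joins the best representative if the
score reaches an absolute threshold, else founds a new cluster.
The default threshold is `round(2.0 × median length)` matrix units —
roughly "half of a typical self-score", demanding near-identity, which
is intentional: seeds should be tight, growth comes later.
Representatives never change, so the pass is single-pass deterministic;
score ties join the earliest-created cluster.

Only the largest clusters survive as cores (default: the top 2.5 % of
greedy clusters, at most 250, with at least 2 unique members); all
other sequences — including dissolved small clusters — form the
sequence pool. Core MSAs are built directly from the stored shift
alignments (members padded with edge gaps; no inner gaps can arise).

### Profile HMMs

Each cluster is summarized by a profile HMM over its **match columns**:
MSA columns with gap fraction strictly below 0.05 and information
content of at least 1.2 bits, where IC(c) = log₂20 − H(c) from the
non-gap residue frequencies, with no pseudocounts or small-sample
correction (the bound < 5 % gaps is strict and IC ≥ 1.2 inclusive,
read literally from the rule's wording). Match emissions are column
counts plus background-proportional pseudocounts (total weight 1.0 per
column); insert states emit the background; transitions are tallied
from each row's implied match/insert/delete path (rows are treated as
local fragments: leading/trailing deletions carry no information) with
a pseudocount of 1 per transition type.

Scoring is **local Viterbi log-odds** in bits against an i.i.d.
background null (BLOSUM62 marginal frequencies by default): uniform
entry over match states (probability 1/n_match), free exit from any
match state, unaligned flanks scoring zero. Viterbi rather than
Forward keeps scoring deterministic and yields an alignment path that
is reused verbatim to insert the sequence into the MSA. The
implementation is a vectorized DP over all pool sequences at once; it
is property-tested against an independent top-down enumeration of all
alignment paths.

Thresholds are expressed in **bits per match state** and multiplied by
the model's n_match, so one relaxation schedule works for models of any
size.

### Extension

Each pool sequence is assigned to the cluster giving its highest bit
score among those reaching `τ_ext × n_match` (ties: larger cluster,
then smaller id). Accepted sequences are inserted into the winner's
MSA in descending score order along their Viterbi paths: match-state
residues land in the existing match columns, each insert-state residue
opens a fresh column, deletions leave gaps, and flanking residues fill
existing edge columns before opening new ones. Each insertion is
individually vetoed by diversity control (below); vetoed sequences
remain pooled. HMMs are rebuilt once per modified cluster at the end
of the step (batch rebuild — insertion paths within one step all come
from the pre-step model, trading per-insertion exactness for
determinism and speed; a column map tracks the match columns as the
MSA widens mid-step).

### Merging

Cluster pairs are compared by a Smith–Waterman-style local alignment of
their match states under the co-emission log-sum-of-odds column score
`s(i,j) = log₂ Σ_r P_a,i(r) P_b,j(r) / bg(r)` with affine gap
penalties (open −3.0, extend −0.5 bits). No secondary-structure terms
are used — they are meaningless for short peptides. A pair qualifies
when its score reaches `τ_merge × min(n_match_a, n_match_b)`; the
`min()` normalizer keeps short local pairings from qualifying cheaply.

Qualifying pairs drive best-first agglomeration: a priority queue
ordered by score (ties: lexicographically smallest id pair), lazy
deletion of entries referencing merged-away clusters, rescoring of each
new cluster against all survivors. Merging maps the second cluster's
columns onto the first's through the aligned match-state pairs; between
anchors the columns are overlaid positionally (interior segments
left-aligned, flanks aligned toward the anchors) so only the excess
columns of the wider side become gap columns for the other side's rows.
A merge whose result fails diversity control is skipped and that pair
permanently discarded for the round. On termination every surviving
pair either scores below threshold or was constraint-rejected.

The **heuristic speedup** reuses extension-step information: each
cluster's *distant-hit set* (pool sequences reaching the lower
threshold `(τ_ext − 0.5) × n_match`). Clusters whose sets overlap are
directly similar; connected components of this relation (union–find)
partition the clusters into groups, and agglomeration runs within
groups only. This can only merge fewer pairs than the full routine, so
the final round always runs the complete agglomeration.

### Iteration and diversity control

Extension and merging alternate for `n_rounds = 3` rounds with
relaxing schedules, by default τ_ext = (2.0, 1.5, 1.0) and
τ_merge = (1.5, 1.0, 0.5) bits per match state. Early rounds admit
only near-certain members while profiles are small and noisy; later
rounds, with sharper profiles, admit the broader motif neighborhood.

Diversity control vetoes any insertion or merge whose resulting MSA
would have (i) fewer than `min_match_states = 4` match columns,
(ii) width above `max_positions` (default: longest input sequence + 4),
or (iii) more than `max_inner_gaps` inner gaps (gaps flanked by
residues within a row; default cap `round(0.2 × rows)`). All bounds
are inclusive at the limit. These caps are what keep distinct motifs
in distinct clusters: two profiles sharing only part of their anchors
can exceed a relaxed merge threshold, but their merged alignment washes
out the disagreeing columns and drops below 4 match states, so the
merge is rejected.

## Synthetic data: what it does and does not emulate

The generator plants motifs specified position-by-position (weighted
residue sets or background positions, e.g. `[RK]xxPxxP`) at a uniform
random offset inside background flanks; noise sequences are i.i.d.
background (BLOSUM62 marginals, matching the null model); copy numbers
follow a truncated discrete power law P(k) ∝ k^−α (α = 2.0, k ≤ 10⁴),
reproducing the few-popular-clones / long-tail structure of display
screens; occurrences can be spread over labels with fixed mixing
weights. Everything is seed-deterministic.

The bundled SH3-like fixture mimics the composition of a published
two-specificity screen: 2 457 unique 12-mers — 1 738 carrying
`[RK]xxPxxP`, 415 carrying `PxxPx[RK]`, 304 noise (~12 %).

Deliberate simplifications, and what they imply for test conclusions:

- **Background "x" positions.** Real motif-carrying ligands show
  residue preferences well beyond the canonical anchor positions; here
  non-anchor positions are pure background. The canonical SH3 patterns
  then carry exactly **3** informative positions each ([R/K], P, P —
  an `[RK]` position still yields IC 3.32), while diversity control
  requires ≥ 4 match states. A *complete* single-motif cluster is
  therefore structurally inadmissible under default diversity control:
  building the ideal ground-truth alignment of all 1 738 class-I
  fixture sequences yields exactly 3 columns passing the match rule.
  In practice the pipeline converges to several per-motif subclusters,
  each retaining a fourth, chance-conserved column, rather than one
  cluster per motif. Passing tests therefore demonstrate noise
  rejection, conservation and purity behavior — not one-cluster-per-
  motif convergence, which this generator cannot support for 3-anchor
  motifs.
- **Shared anchor geometry.** The two classes share the P..P spacing,
  so class-II sequences score against class-I profiles through the
  common anchors; some cross-contamination of clusters is inherent to
  the mixture, as it is in the real screens.
- **No amplification dynamics.** Labels carry static mixtures only; no
  per-round selection/amplification bias is simulated.
- **No sequencing errors**, so there are no mutational neighborhoods
  around high-copy clones; real data's near-duplicate structure makes
  greedy seeding easier than it is here.

## Numerical and design choices

- 0-based column indices, half-open intervals throughout.
- Shift-alignment ties prefer smaller |shift|, then the negative shift.
- Viterbi traceback ties resolve in a fixed option order; the exit cell
  tie-break prefers fewer consumed residues, then the earlier state.
- Extension insertion order: descending hit score, ties alphabetical.
- All reductions over clusters iterate in ascending id order, so thread
  count or set ordering can never change results.
- Degenerate inputs: a dataset with a single unique sequence yields no
  cores (minimum core size 2) and everything unassigned; a core whose
  MSA already fails diversity control is dissolved into the pool;
  all-gap columns are forbidden invariants, asserted in validation.
- KLD of a column set is Σ_cols Σ_r f(r) log₂(f(r)/bg(r)) with non-gap
  frequencies, no pseudocounts (0·log 0 = 0); the dataset-level value
  is the unique-sequence-count-weighted mean over clusters
  (configurable to unweighted).
- Purity of a cluster is the fraction of members whose true motif is
  the cluster majority; majority-noise clusters score 0 (noise is
  never a motif).

## Problem sizes in the test suite

Unit and property tests run on peptides of length 5–15, models of up to
6 match states (where DP results are checked against exhaustive path
enumeration), and agglomeration of up to 6 clusters (checked against a
naive rescan-and-merge-max oracle). End-to-end runs use planted-motif
datasets of 150–250 sequences across 20 seeds plus the 2 457-sequence
SH3-like fixture; a full fixture run takes ~15 s on one core.

## Known limitations

- Viterbi (max-path) scoring is less sensitive than Forward scoring
  with E-values; thresholds here are bit-score based and not
  numerically comparable to HMMER's.
- The greedy stage is O(sequences × representatives) with no k-mer
  prefilter; million-scale inputs would need one.
- Insertion paths within one extension step come from the pre-step
  model; a sequence inserted early in a step does not influence the
  paths of later insertions in that same step.
- The minimum of 4 match states makes motifs with fewer than 4
  informative positions unrecoverable as single clusters (see above);
  lowering `min_match_states` trades this against noise clusters
  surviving diversity control.
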