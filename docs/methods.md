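# Methods

This note documents the models implemented in `hotrecon`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make results
deterministic.

## Trees, supports, and bipartitions

All analyses operate on rooted trees whose leaves are strain
identifiers and whose internal non-root edges may carry bootstrap
supports as integer percents in [0, 100] (the RAxML convention of
supports as internal node labels).  Newick files whose numeric internal
labels all lie in [0, 1] are interpreted as fractions and rescaled by
100; this is logged.  A file containing the single internal label `1`
is therefore read as 100% under the automatic rule — pass
`support_scale="percent"` when such a file really encodes 1%.

Support semantics at thresholds are asymmetric by design and used
consistently everywhere:

* conflict detection requires support **strictly greater** than the
  threshold (default 70), matching the common ">70% BP" convention;
* edge collapsing during fixing removes edges with support **strictly
  less** than the threshold;
* a reference edge at **exactly** the threshold counts as weak for the
  "reference-uncertain" triage class;
* an edge with **no** support value is never collapsed (its topology is
  not negotiable without positive evidence of weakness) but counts as
  support 0 wherever a detection threshold is applied (it can never
  anchor a supported conflict).  Both directions are conservative.

A bipartition is the split of the taxon set induced by one edge; two
bipartitions on the same taxa are compatible iff at least one of the
four pairwise side-intersections is empty.  Trivial splits (singleton
side) are excluded from tree bipartition sets, and the two root-adjacent
edges of a rooted tree, which induce the same unrooted split, are
reported once.  Child order is never meaningful; all trees are
canonicalized (children sorted by smallest descendant leaf) so that
traversal order, tie-breaking, and serialization are deterministic.

## Undated DTL parsimony reconciliation

The reconciliation engine maps a rooted binary gene (or operon) tree
into a rooted binary species tree.  Each internal gene node is
explained as one of:

* **speciation** at a species node, its children continuing into the
  two descendant subtrees;
* **duplication** on a species edge, both children continuing in that
  subtree;
* **transfer**, one child continuing at the donor edge, the other
  entering any species edge *incomparable* with the donor (neither
  ancestral to the other) — the undated-model analogue of a
  contemporaneous recipient.

Losses are charged for every species edge a gene lineage enters without
leaving a sampled descendant, computed with the standard cheapest-entry
("in") recurrence; the transferred child lands directly on its
recipient edge, so no losses are charged at arrival (a deeper recipient
is simply a different recipient edge).  The gene root maps anywhere
free of charge.  Costs default to duplication 2, transfer 3, loss 1
(speciations free), the cost matrix commonly used with tree-fixing
tools; all three are configurable and only ratios matter.

Two deliberate modeling choices:

* **No global time consistency.**  Deciding whether a set of transfers
  admits a consistent dating is NP-hard; like standard parsimony
  implementations the DP does not enforce it.  A post-hoc heuristic
  (species-descent arcs plus donor→recipient arcs must form a DAG) is
  run on the reported scenario and exposed as
  `Reconciliation.time_consistent`.
* **Transfers are copy events.**  Replacement transfer is not a
  distinct event kind; when a recipient already carried the gene, the
  DP simply charges the loss of the original copy wherever that is
  optimal.  In practice each planted replacement transfer in the
  simulator is inferred as one transfer plus one loss at the
  recipient's original position.

### Co-optimal scenarios

Two scenarios are distinct iff they differ in the gene-node→species
mapping or in any event label.  The counting DP sums over co-optimal
alternatives and multiplies over independent children, giving the exact
count as an integer; enumeration backtracks over the same choices in a
fixed priority order, so its first scenario is the reported one and its
output length equals the count.  Tie-breaking prefers speciation over
duplication over transfer, mappings as shallow as possible, and
canonical species order otherwise.

The production DP runs on float64 vectors for speed, carrying scenario
counts as floats; float addition on integers is exact below 2⁵², and
the engine falls back to an exact big-integer path whenever any count
approaches that bound.  Cost comparisons use a relative tolerance of
1e-9, which is exact for integer-valued cost schemes.

Correctness is established against an independent brute-force oracle
(direct recursion over the model definition, enumerating children's
mapping targets explicitly) on hundreds of random instances with ≤ 7
leaves, including random cost schemes, for both the minimum cost and
the co-optimal count.

## Dollo loss counting

Under the vertical-inheritance null the operon originates once, at the
root, and can only be lost.  The minimal number of losses consistent
with a presence/absence pattern at the leaves is the number of maximal
all-absent clades; the reported loss edges are those clades' stems.
This equals the exhaustive minimum over all single-origin internal
state assignments (verified by enumeration on 10-leaf trees).

## Error-aware tree fixing

Per-site statistical tests used by alignment-aware tree-correction
tools need the original alignments, which tree files do not carry.
This package's fixing stage instead treats bootstrap support as the
statistical equivalence signal: edges of the associate tree supported
below a negotiability threshold (default 70, aligned with the conflict
threshold) are collapsed, and each resulting polytomy is re-resolved to
minimize the DTL cost against the reference.  Polytomies with ≤ 6
children are resolved exhaustively over all (2k−3)!! rooted resolutions
(945 at k = 6, the practical per-polytomy limit); larger ones by greedy
stepwise insertion in canonical order.  The original arrangement is
kept whenever it is at least as good as the best rearrangement, which
makes fixing monotone in cost (never worse), idempotent, and
conservative: bipartitions at or above the threshold always survive,
and the tree is never re-rooted.

## Conflict triage

A conflict is one supported associate-tree bipartition incompatible
with at least one reference bipartition — note the unit is the
bipartition, not the displaced taxon.  Triage follows the order fix →
reference-uncertainty → authentic: a conflict absent from the fixed
tree's supported-conflict set is *fixable*; one whose contradicted
reference edges are all weak (≤ threshold) is *reference-uncertain*;
the remainder are *authentic* single-gene HGT and their genes are
flagged for downstream exclusion.  Trees with unequal taxon sets are
pruned to the shared taxa first (logged); when edges merge during
pruning the surviving edge keeps the larger support, so pruning never
manufactures weakly supported structure.

## Marker selection and column filtering

A cluster gene qualifies as a marker iff it is (i) specific to the
cluster, (ii) universally present (not alternated with a replacement
gene in some strains — an explicit third criterion so that the one such
case is not conflated with cluster specificity), and (iii) at least 100
amino-acid positions long after column filtering, with the boundary
inclusive (exactly 100 qualifies).  The bundled 50-gene reference
annotation is transcribed at the level of criterion outcomes: published
sources record which side of the length cutoff each gene falls on, not
its exact post-filter length, so short rows are encoded just below the
cutoff and all others at it.  Selection yields 33 markers and 17
exclusions (8 not specific, 8 short, 1 not universal).

Column filtering removes alignment columns whose gap fraction is
strictly above 0.5 (a column at exactly half gaps is kept).  The
"highly variable positions" half of block-based filters is multi-rule
and parameter-rich; it is not emulated bit-exactly.  An optional,
clearly approximate conservation filter (drop columns whose modal
non-gap residue frequency falls below a configurable fraction) is
provided and off by default.  Kept column indices are reported 0-based
in original coordinates.

## Concerted-evolution test

If the operon's genes travel together, each gene's transfer count
relative to the operon tree should be lower than (1) its transfer count
relative to the organism tree and (2) the number of whole-operon
transfers.  Per-gene counts are obtained by fixing each gene tree
against the respective reference and reconciling against it, counting
transfers in the optimal scenario.  Both predictions use the one-sided
exact sign test (ties dropped); the binomial tail is exact, e.g.
p = 0.5ⁿ when all n differences are positive.  The underlying study
reports only "significantly lower" without naming the statistic, so the
sign test — assumption-free on the paired differences — is the
default, with Wilcoxon signed-rank available via `method="wilcoxon"`.
Prediction 2 treats the HOT count as a reference value in the same
paired design.  Five genes is the minimum for a p-value below
conventional thresholds; fewer raise an error.

## The simulator

The generator emulates the *structure* of the study design, not its
sequences:

* **Species tree**: Yule pure-birth, default 44 tips with birth rate
  1.0 per lineage per unit time; root splits at time 0; one extra
  exponential stretch after the n-th lineage so terminal branches have
  positive length; ultrametric by construction.
* **Operon history**: the operon starts at the root; on each carrier
  lineage losses arrive at rate λ_L and transfers at rate λ_T (per
  lineage per unit time); the transfer recipient is uniform among
  contemporaneous other lineages and has its operon replaced — one
  timed SPR on the operon genealogy.  Losses are terminal (regain only
  by transfer), matching the Dollo null.  All events are logged with
  times, donors, and recipients.
* **Gene trees**: each gene replays the operon history exactly and adds
  its own transfers at a per-gene rate among carrier lineages; a
  planting interface forces specific events for ground-truth tests.
* **Supports**: painted directly onto the true topologies (default 100
  on every internal edge, optional rounded-Gaussian noise), and random
  NNIs with a designated low support create "fixable" wrong edges.
  Sequence evolution, alignment error, and realistic bootstrap
  correlation structure are *not* simulated — so passing tests
  demonstrate correctness of the inference machinery on known-truth
  topologies, not robustness to phylogenetic estimation error in real
  data.

Default rates were calibrated once by Monte Carlo (300 replicates) to
the scale of the emulated study and then frozen: λ_T = 0.30 and
λ_L = 0.33 give on average ≈ 6.8 operon transfers and ≈ 7.5 losses per
44-tip tree with ≈ 43% of tips carrying the operon at the present (the
study system: 7 transfers, 8 losses, 42% photosynthetic strains); the
per-gene transfer rate 0.03 gives ≈ 0.8 transfer events per gene tree
(the study: ≈ 1 event per gene, 2.3% of gene copies affected).

For exact parameter-recovery experiments the planting helper draws k
transfers between terminal edges after the last speciation, with all 2k
tips having pairwise distinct parents: each event is then one
topology-changing SPR whose cheapest explanation is a single transfer,
independent of the others, so the inferred HOT count should equal k
exactly under noise-free supports.

Everything is deterministic under the seed: one `SeedSequence` is
spawned per component, and byte-identical outputs under identical
configurations are asserted in the test suite.

## Pipeline and problem sizes

`HotTransferModel.fit()` runs: gene-tree conflict triage against the
operon tree → operon-tree fixing against the carrier-pruned species
tree → DTL reconciliation (HOTs, losses, co-optimal count) → Dollo
null on the full species tree → concerted-evolution test.  The Dollo
count and the HOT + loss count are reported side by side as the two
competing explanations of the presence pattern.

The test suite and the acceptance script run at the study's own scale
(44 tips, 33 genes) or below; oracle cross-checks use ≤ 7-leaf
instances where exhaustive enumeration is exact, and Monte-Carlo
self-consistency checks use 300–1000 replicates on 12-tip trees.  A
44-tip reconciliation takes ~20 ms; the full 33-gene pipeline a few
seconds.

## Known limitations

* The undated transfer model can accept scenarios with no consistent
  dating (flagged, not forbidden), and parsimony undercounts transfers
  whose effects overlap — the planted-event tests therefore distinguish
  the non-interacting regime (exact recovery) from the general one
  (never overcounting).
* Scenario counting treats (mapping, event-label) identity as the
  equivalence; coarser notions (e.g. event-set identity) would give
  smaller counts.
* Fixing explores only the collapsed-edge neighborhood; a wrong but
  well-supported edge is deliberately out of reach.
* The sign test ignores difference magnitudes; use the Wilcoxon option
  when magnitudes are meaningful.
* Species trees must be binary; gene-tree polytomies must be resolved
  (by fixing) before reconciliation.
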