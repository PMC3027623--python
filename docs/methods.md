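# Methods

This note documents the models and conventions the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Character model and scoring

A matrix is a rectangular grid of state *sets*: observed singletons,
missing (`?`) and inapplicable (`-`) cells spanning the character's whole
alphabet, and polymorphic `(..)` / uncertain `{..}` multi-state cells.
Inapplicable is scored identically to missing — morphological matrices of
this school do not treat the gap as a fifth state — and the
polymorphic/uncertain distinction is recorded in the cell tag but both are
scored as free choice among the listed states, the standard Fitch
treatment. Character weights exist in the model but default to 1 (equal
weighting); the resampling machinery reuses them as integer multiplicities.

Unordered characters are scored with Hartigan's state-count generalisation
of Fitch, exact on arbitrary (multifurcating) trees; ordered characters
with Wagner costs |i − j| via a min-plus sweep over states. Both run in a
single postorder kernel, JIT-compiled with numba, operating on the tree
rooted at its lowest-numbered leaf (parsimony length is rooting-invariant;
tested). The test suite pins these scorers to brute-force enumeration over
all internal labelings on every tree shape up to 6 leaves.

Ensemble indices: CI = M/L and RI = (G − L)/(G − M), where M sums each
character's minimum conceivable steps (exact minimal hitting-set over state
sets for unordered; interval gap for ordered) and G sums star-tree maxima.
Whether such indices should include parsimony-uninformative characters is a
perennial ambiguity, so the report carries both variants; the headline
values include all active characters, matching the common software default.

## MPR machinery

Ancestral state sets, per-edge change bounds, synapomorphy diagnosis, and
branch collapsing all come from one vectorised Sankoff-style dynamic
program: a down pass (cost of the subtree below a node per state) and an up
pass (cost of the rest of the tree per state of the parent). A node's MPR
set is the states whose down+up total attains the optimum; an edge's
minimum/maximum change over all MPRs comes from the optimal
(parent-state, child-state) pairs. A change is *unambiguous* iff its edge
minimum is positive — i.e. every most-parsimonious reconstruction places a
change there.

**Rule-1 collapsing** contracts internal branches whose minimum optimised
length over MPRs is zero. Contraction is iterative (one branch at a time,
tables recomputed) because contracting one unsupported branch can make
another formerly-unsupported branch necessary; simultaneous contraction can
lengthen the tree, while the iterative rule provably preserves length
(asserted by tests on random inputs). Branches are examined in postorder,
which fixes the (rare) order-dependent ties deterministically.

## Heuristic search

The search protocol is the classic two-phase recipe: `n_replicates`
random-addition Wagner builds (each taxon inserted at a currently
cheapest edge, ties broken by the replicate's seeded stream), each followed
by TBR branch swapping. Swapping is steepest-descent with plateau
exploration: every tree in the buffer has its complete TBR neighbourhood
scored; equally optimal distinct topologies are enqueued up to
`hold_per_replicate` (10 by default), and the loop ends when every buffered
tree has been swapped without improvement. The final round pools the
replicate winners and swaps with an unbounded (or user-capped) buffer to
expand the full optimal set, which is then rule-1 collapsed and
deduplicated by canonical bipartition-set hash.

Neighbour evaluation scores *before* deduplicating: most neighbours are
worse, and their split sets (the expensive part) never need computing.
Scores come from full rescoring by the kernel — no incremental shortcut is
used, so scoring correctness is a single code path.

Per-replicate generators derive from one master seed via
`SeedSequence(seed, spawn_key=(replicate,))`: replicates are independent
and any run is reproducible from a single integer. Replicate hit counts
(how many replicates reached the final best length) are part of the result.

Constraints (groups required or forbidden to be monophyletic) filter both
Wagner insertions (applied to the group restricted to the taxa present so
far; forbid-mode only once all members are present, since subgroup
monophyly says nothing about the full group) and TBR acceptances. A group
is monophyletic iff some edge's bipartition isolates exactly that group —
no outgroup is needed for this unrooted definition.

On every matrix small enough to enumerate (≤ 8 taxa, 10 395 topologies)
the protocol with ≥ 5 replicates is required by the acceptance tests to
attain the enumerated optimum *and* the complete collapsed MPT set. Plateau
completeness on larger matrices depends on the optimal set being
TBR-connected from the replicate winners, which is not guaranteed in
general; MPT counts on real-size matrices are therefore soft.

## Consensus, rogues, support

Strict consensus intersects bipartition sets and rebuilds the tree from
the (automatically laminar) canonical masks; reduced strict consensus
prunes a taxon list first, and equals consensus∘prune exactly (tested).

Unstable-taxon identification is a greedy loop: prune the leaf whose
solitary removal most increases the consensus's resolved node count,
repeat while any removal helps (ties broken alphabetically, so the order is
deterministic). For each pruned taxon the distinct attachment positions
across the input trees are enumerated, and the cause is classified as
*missing_data* when per-character optimised lengths are identical across
its placements (compared on tree pairs that differ only in that taxon,
falling back to the characters the taxon is actually scored for), else
*character_conflict*. This is a self-contained stand-in for iterative
positional-congruence reduction, chosen for transparency; it is not a
re-implementation of any published code, and its cause classifier is a
heuristic when several rogues move simultaneously.

Bremer support defaults to the exact reverse-constraint method: for each
consensus clade, search for the best tree in which the clade is forbidden;
support is the extra length. A suboptimal sweep (one search retaining
trees within a slack) is available as a cheaper lower bound. On ≤ 7-taxon
fixtures the reverse-constraint values must equal full-enumeration values.

Resampling support: bootstrap redraws characters with replacement to the
original count; jackknife deletes each character independently with
probability 0.36 (the conventional removal probability; configurable).
Pseudoreplicates are searched at reduced effort (default 3 addition
replicates, hold 3) and the bipartitions of each pseudoreplicate's strict
consensus are tallied — so an under-resolved pseudoreplicate contributes to
no conflicting group. GC = own frequency − the most frequent incompatible
group's frequency; it is negative for groups beaten by a rival and equals
the absolute frequency when never contradicted.

## Templeton test

Per-character length differences between two topologies (computed by the
same scorer that measures tree length, so the differences sum exactly to
the length difference); zeros dropped; midranks for ties; T = min(R+, R−).
For N ≤ 25 the null is exact: doubling the midranks makes them integers
and the distribution of R+ under random signs is built by convolution
(tie-exact; verified against complete sign-assignment enumeration). Above
that, a normal approximation with tie correction (−Σ(t³−t)/48 in the
variance) and a 0.5 continuity correction, matching the generic
signed-rank routine to 10⁻⁹. Two-tailed p = min(1, 2·P(R+ ≤ T)); symmetric
in the two trees by construction. Both branches are selectable by flag
since published values may reflect either convention.

When many equally parsimonious trees exist, the reported comparison is
against the MPT with the fewest differing characters, with the p range
across MPTs alongside.

## Trait mapping

Discrete traits reuse the MPR machinery (the trait is one character);
changes on terminal branches are flagged autapomorphies, internal
unambiguous changes synapomorphies, everything else ambiguous.

Continuous traits use linear parsimony (Manhattan cost). Optima lie on
observed values, so the dynamic program runs on the breakpoint grid of
observed values and per-node *intervals* span every optimal assignment —
the natural way to present an ancestral "range". The grid claim and the
interval endpoints are pinned to a brute-force grid oracle on small trees.
Note the median-like behaviour: a single small-bodied terminal inside a
large-bodied clade reconstructs as an autapomorphic decrease; it does not
drag its stem interval down. Squared-change parsimony (each node the mean
of its neighbours, solved as a linear system) is available for comparison,
giving point estimates instead of intervals. A body-mass conversion of FML
is deliberately not applied by default — the pipeline reports the
measurement itself; any affine map on log values can be applied downstream.

## Synthetic data

Characters are simulated by placing a Poisson number of state changes on
uniformly chosen branches (unordered: jump to a uniformly chosen other
state; ordered: ±1 with reflection). This gives direct control of expected
homoplasy without branch lengths, which parsimony never consumes; ensemble
CI on the generating tree decreases monotonically in the change rate
(tested). Missing data are applied uniformly per cell, with optional
per-taxon "fragmentary" rates to create rogue-taxon behaviour;
polymorphism adds one neighbouring state to a cell.

The bundled study-shaped fixture is 50 taxa × 277 characters on a
pectinate backbone of twelve grades with small terminal clades: ~40%
missing cells overall, two rows at 85% missing, change rate 3 per
character (which lands ensemble CI near 0.5, the regime typical of
matrices this size), a sacral-configuration trait that gains a dorsosacral
and then a caudosacral toward the crown with one autapomorphic
S1+S2+CS deviation and one five-sacral crown taxon, and an FML trait
rising from ~2.5 to ~14 cm toward the crown with one 4 cm exception.
These values were fixed once, from the shape of real datasets of this
kind, before any test was run against them.

What passing on synthetic data does *not* show: real morphological
characters are correlated, missingness is structured by preservation, and
character conflict is not Poisson; recovery rates and support values here
are upper bounds on what equally sized real data would give.

## Problem sizes

The test suite and the acceptance script size their simulations to the
information each check needs, not more: oracle comparisons at ≤ 6–8
leaves where enumeration is exact; recovery at 8 taxa × 500 clean binary
characters; bootstrap at 200 pseudoreplicates; the full-protocol
demonstration scores and maps traits on the complete 50 × 277 fixture but
runs its search/consensus/hypothesis stages on a 25-taxon subsample, since
complete TBR neighbourhoods grow roughly cubically with taxon count. The
search itself has no size limit beyond patience.

## Known limitations

- No implied weighting, step matrices, or continuous matrix characters.
- No "new technology" searches (ratchet, drift, fusing); very large
  matrices will want them.
- MPT counts are sensitive to collapsing conventions (timing and rule);
  only the rule-1, collapse-after-search convention is implemented.
- The rogue-cause classifier is heuristic when several unstable taxa
  interact (see above).
- Exact Templeton p-values above N = 25 are not computed (the convolution
  would still be feasible but the normal branch is the convention there).
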