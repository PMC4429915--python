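# Methods

`seqhet` analyses **sequence heterochrony**: evolutionary change in the
*order* of developmental events between lineages, coded as ranked event
sequences.  This note describes the model, the search procedure, the
statistics, the numerical choices, and what the synthetic validation does
and does not show.

## Data model

A species' development is coded as a **ranked sequence**: each of a fixed
set of developmental events (the onset of an appendage bud, a ganglion
anlage, a muscle precursor group, ...) receives an ordinal rank — its
position in the series of operational stages (semaphoronts) at which it
first appears.  Events first seen in the same stage share a rank (a tie);
events never observed in a species carry an explicit ABSENT marker and take
part in no timing comparison.  Sequences are kept in *canonical dense* form
(ranks used are exactly `1..k`), which makes rank arithmetic comparable
between species whose stagings differ in resolution.

The built-in dataset covers 7 crustacean species × 33 events (6 epidermal
appendage-bud events, 1 segmentation event, 18 myogenic events, 7
neurogenic events, hatching), on the accepted phylogeny with the brine
shrimp *Artemia franciscana* as outgroup.  The outgroup row is entered
twice as two sister tips at the root (the analysis default): a nauplius
larva is ancestral for the wider clade, and the duplicated tip anchors the
root's reconstruction toward the outgroup condition instead of leaving the
root a free parameter.

## Edit cost (event-pair parsimony)

The unit of comparison between two sequences is the **event pair**: for
events *i*, *j* a sequence defines *i* before / simultaneous with / after
*j*, or leaves the pair undefined when either event is absent.  Between two
sequences the *changed pairs* are those defined in both and different.  The
edit cost is the **minimum number of moving events** that explains all
changed pairs.  Since every changed pair must contain at least one mover,
this is exactly a minimum vertex cover of the conflict graph whose edges
are the changed pairs.

The cover is computed **exactly** by branch and bound on bitmask-encoded
adjacency, per connected component: fold degree-1 vertices, branch on a
maximum-degree vertex (in the cover, or excluded with its whole
neighbourhood in), prune with a greedy maximal-matching lower bound.
Conflict graphs here never exceed 33 vertices, and pair encodings, costs
and conflict-pattern cover sizes are memoised, which is what makes the
millions of cost evaluations of the GA affordable.

Each mover is tagged with a direction from its *normalised* position
`(rank − 1)/(k − 1)` (0 when `k = 1`): **A**ccelerated when it sits earlier
in the descendant, **D**elayed when later, ambiguous when unchanged (a pure
tie join/split).  Normalisation makes sequences with different numbers of
rank levels comparable.  Presence/absence differences (evolutionary loss or
novelty) are reported separately from heterochrony: to the edit cost an
absence is missing data, not a timing statement.

## Ancestral-sequence search

The whole sequence is treated as one complex character.  An assignment of a
complete canonical sequence to every internal node is scored by the sum of
edit costs over all branches; tips contribute their observed sequences.
Ancestral candidates always contain every event present in at least one
tip: because absences only remove pairs, a search free to drop events would
trivially empty every ancestor at cost zero.

The search has three nested parts:

1. **Per-node GA.** With its neighbours fixed, a node's candidate sequence
   is optimised by selection over a population (default 200 per cycle, 100
   cycles) built by crossover (per-event uniform rank choice between two
   parents, re-canonicalised) and mutation (nudge one event by a half- or
   full level on a doubled rank scale — so a move can join an existing
   level or split out between two levels — or relocate it anywhere).  The
   node retains its best 100 candidates — *near*-optimal ones included, not
   only the co-optimal; this matters below.  A node's GA stops early after
   10 cycles without any change to the retained set.
2. **Sweeps.** Nodes are revisited in alternating post-/pre-order sweeps
   (at most 10), each visit moving the node to a locally optimal candidate;
   the best total cost never increases from sweep to sweep.
3. **Exact recombination.** Per-node descent alone stalls in local optima
   that require coordinated changes at several nodes.  Because the total
   cost decomposes over branches, the minimum-cost combination of the
   retained per-node candidates is found *exactly* by dynamic programming
   over the tree.  When recombination beats the sweep incumbent, the
   descent restarts from the recombined assignment.  On simulated data this
   loop reliably reaches (and sometimes beats) the cost of the generating
   history, where plain coordinate descent stayed 30–60% above it.

All equally most-parsimonious combinations are collected, up to a cap of
3,000 solutions.  When the optimal set is larger than the cap, solutions
are **sampled uniformly** from it (top-down through the DP's solution
counts) rather than truncated in enumeration order — order-based
truncation concentrated the entire pool on the lexicographically first
branch choices and visibly distorted the consensus supports.

A run is deterministic given its seed; the pipeline's independent runs use
seed, seed+1, seed+2.

## Consensus and support

For one solution and one branch, the implied heterochronies are the
(event, direction) pairs occurring in **more than half of all minimum move
sets** of that branch.  The vote fraction is computed exactly: the conflict
graph splits into connected components whose covers combine freely, so an
event's fraction over all minimum covers equals its fraction within its own
component's covers.  An event with an equally good alternative explanation
sits at exactly 50% and is (conservatively) excluded.

The **pseudoconsensus** of a run keeps, per branch, every heterochrony
present in more than 50% of that run's solutions, with the percentage as
support.  The **superconsensus** pools the raw solutions of all runs and
applies the same rule, so support remains interpretable as a fraction of
solutions.  Ancestral sequences are summarised per node by mean ranks over
solutions, re-ranked canonically; means are compared as exact fractions so
ties occur only at exact equality.  Mean-rank sequences can show small
positional differences that are not supported heterochronies; the records,
not the sequences, carry the support values.

## Heterochrony rates

The rate of an event is (number of supported changes across all branches) ×
(mean support of those changes, as a fraction); direction does not matter.
Aggregates: tissue rates are unweighted means over each tissue's events
(6 epidermal, 7 neural, 18 myogenic); the ectoderm rate is the unweighted
mean of the epidermis and neural tissue rates and the mesoderm rate equals
the muscle rate; the segment × tissue grid assigns each event's rate to its
segment(s) — a composite event (the joint antennal-bud event, the naupliar
ganglia) contributes its full rate to each of its segments, and where
several myogenic events share a segment their mean is used.  Four events
with no usable segment affiliation (segmentation offset, the stomodeal
muscle precursor, the nauplius eye anlage, hatching) are excluded from the
segment grid only; the first two and hatching are likewise outside every
tissue mean, while the nauplius eye counts as neural tissue.

## Synthetic data and what validation shows

The generator evolves a root sequence (default shape mirroring the real
data: 33 events, ~10 dense rank levels, frequent ties) down a rooted tree:
per branch, a Poisson number of relocations of uniformly chosen events to
uniformly chosen levels, plus optional inherited loss.  Every edit is
recorded, and replaying the log reproduces each node exactly.

Recovery is scored against the *detectable* planted shifts — those with
nonzero net normalised displacement over their branch; a shift cancelled
within a branch is unobservable in principle.  Validation uses a tree with
a trifurcating root, matching the root-identifiability situation of the
real analysis (which trifurcates the root via the duplicated outgroup): on
a bifurcating root, a shift on either root branch can be placed on the
other at equal cost, so its support splits at exactly 50% and majority-rule
consensus drops it — a property of rooted event-pair parsimony, not a
defect of the search.  Under these conditions (8 tips, 15 events, one
shift per branch, no loss, three runs) mean recall across seeds is ~0.85
with precision ~0.9.  The remaining misses are intrinsic: shifts whose
conflict graph is a single pair (vote tied at 50%), and planted histories
that parsimony legitimately re-explains with fewer moves.  What passing
does **not** show: robustness to correlated (module-wise) shifts, to
rate variation across branches, or to coding error in real data — the
generator models none of these.

## Problem sizes and profiles

The default GA settings (100 cycles, 200 per cycle, 100 retained, 3,000
solutions, three runs) are the analysis settings used for the built-in
dataset; one such run takes a few minutes on one core.  Tests and the
synthetic validation use a reduced profile (20 cycles, 50 per cycle, 20
retained, 200 solutions) that reaches the same optima on these instance
sizes at a fraction of the cost; the brute-force cover oracle and the
exhaustive tree search bound test instances to ≤ 12 events and ≤ 5 events /
4 internal nodes respectively.

## Known limitations

* The search is a heuristic; on the built-in dataset it consistently finds
  trees of length ~86–93, shorter than the 98–101 of the original
  genetic-algorithm analysis this re-implements, whose internals
  (population management, operators, node schedule) were never published.
  Shorter trees imply partly different supported heterochronies, so
  consensus-level statistics (per-event and tissue rates) should be
  compared with the original's only qualitatively.  The edit-cost function
  itself is exact and oracle-verified.
* Equal weights: all events and branches are weighted equally; no model of
  rate variation or event modularity.
* The NEXUS reader supports only the narrow dialect used here (symbols
  1–9, a, b, c; missing `z`; one rooted tree).
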