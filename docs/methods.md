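# Methods

## Scope and model

morphoclad analyses matrices of unordered discrete morphological characters
over small terminal-taxon sets (here: seven hominoid terminals; the exact
search accepts up to 16). All characters are treated as unordered and
equally weighted — the convention of the antecedent muscle-character
studies; no step matrices or ordering assumptions are supported. States are
small non-negative integers with 0 conventionally the ancestral condition
(CS0). A cell is a non-empty state set (singleton, or larger for
polymorphism), MISSING (`?`, no observation) or INAPPLICABLE (`-`, e.g. an
attachment detail of an absent muscle). MISSING and INAPPLICABLE both score
as full-domain wildcards — they can never force a step — and differ only in
reporting.

## Majority-rule coding

A taxon's state for a character is the state observed in ≥ 50% of counted
units. The default unit is the dissected specimen; side-based counting
(each observed body side = one unit) is available because published sample
tallies often count sides (123 ape specimens ≈ >200 sides for the palmaris
longus example). Under specimen counting a bilaterally asymmetric specimen
contributes weight 0.5 to each side's state; this weighting is this
package's declared convention — the source studies do not state one. The
boundary is inclusive: on a two-state character an exact 50:50 split codes
the conventional presence state (`presence_state`, default 1). Multistate
ties code as polymorphic state sets, which the parsimony machinery consumes
natively. Pooling own dissections with literature specimens is a keyed
union: identical duplicate specimen ids deduplicate, conflicting ones raise.

## Parsimony scoring

Tree length per character is computed by the unit-cost small-phylogeny
dynamic programme (Sankoff with uniform substitution cost): for each node
and state, the minimum subtree cost is `Σ_children min(c_child, min(c_child)
+ 1)`. On binary trees this equals Fitch set-counting; on polytomies it
remains exact (the Fitch set heuristic does not), which is why it is the
single scoring path. Search-time scoring vectorizes the same recursion over
all characters at once (a characters × states cost array per node, padded
with a large finite sentinel for narrower state domains).

Per-character bounds: the minimum `m_i` is (size of a minimum hitting set
of the scorable tip state sets) − 1, equal to (distinct observed states)
− 1 whenever no tip is polymorphic — the hitting-set refinement keeps
`m_i ≤ s_i` when a polymorphic tip mentions a state no tree need express.
The maximum `g_i` is the star-tree score, n_scorable − (best single-state
coverage), with polymorphic tips counting toward their most favourable
state. Ensemble indices: CI = Σm/Σs, RI = (Σg−Σs)/(Σg−Σm).
Parsimony-uninformative characters (g = m) are included in CI by default
(the PAUP convention) and excluded from the RI sums, where they would
contribute 0/0; both toggles are explicit because published CI/RI values do
not always state their convention. Percentages are rounded half away from
zero; full precision is retained alongside. A zero-length matrix has an
undefined CI, reported as 100 with a flag.

## Tree search

The unrooted search space is represented rooted, with the outgroup as the
first child of the root (the standard bijection between unrooted n-taxon
and rooted (n−1)-taxon topologies). Branch-and-bound proceeds by stepwise
addition in matrix order, pruning any partial tree strictly longer than the
incumbent optimum — valid because parsimony length is monotone under taxon
addition — and collecting every topology attaining the final minimum. The
edge above the outgroup is excluded from the insertion set (it is the same
unrooted edge as the root's other branch), so each unrooted topology is
generated exactly once. An exhaustive-enumeration search over all
(2n−5)!! unrooted topologies is kept in the library as the oracle
counterpart and is what the pruned search is tested against. No
rearrangement heuristics (NNI/SPR/TBR) exist; beyond 16 taxa the search
refuses rather than silently degrading.

## Ancestral reconstructions and change mapping

For one character, every most-parsimonious assignment of states to nodes is
enumerated by backtracking over the DP: root states attaining the minimum,
then per child the states t minimizing `cost_child(t) + [t ≠ parent]`.
Terminals are fixed to one element of their state set per reconstruction,
so wildcard tips multiply the MPR set (a guard raises beyond 100,000 MPRs).
Each reconstruction's change list is exactly the edges whose endpoints
differ; its size always equals the character's minimum length.

A change is *unambiguous* iff the identical (branch, from, to) transition
occurs in every MPR. Direction is classified against the root state of the
reconstruction under evaluation: a change is a reversion iff it returns to
that ancestral state from a non-ancestral one, otherwise an acquisition.

ACCTRAN/DELTRAN are implemented as preorder filters *within* the enumerated
MPR set: at each branch DELTRAN keeps the candidates that inherit the
parent's state whenever any candidate does (delaying transformations toward
the tips), ACCTRAN keeps the candidates that change whenever any candidate
does (accelerating them toward the root); remaining ties break on the
sorted node-state vector. Filtering inside the MPR set guarantees the
selected reconstruction is optimal, works unchanged on polytomies, and on
the worked hominoid characters reproduces the classical conventions
(DELTRAN: independent terminal gains for the char-66 and char-112 patterns;
ACCTRAN: stem gain with later reversals). DELTRAN is the default reporting
policy because the published reassignment of chars 83/140 to the
*P. troglodytes* terminal branch is DELTRAN-placed; both policies and the
full MPR set remain available since the underlying argument runs over the
whole equal-parsimony set.

## Differences and rates

A pairwise difference between two taxa is a character whose coded state
sets are disjoint; overlapping polymorphism is not a consistent difference,
and MISSING/INAPPLICABLE cells never count. Filters restrict to major
(presence/absence) characters or body regions. Rates are plain quotients
n_changes / span_Ma; display follows the field's mixed precision (two
decimals below 1, one at or above: 0.28, 0.50, 3.5) while stored values
keep full precision, and every table row satisfies rate × span = count
exactly before rounding. Node-age calibration presets: the default
8 Ma chimpanzee-human / 2 Ma chimpanzee-bonobo scheme, and the alternative
7.5 / 3 Ma scheme of the earlier rate study; deeper nodes carry
conventional hominoid ages (gorilla 9, orangutan 16, hylobatid 20, outgroup
25 Ma) that do not enter the headline arithmetic. The published gorilla
terminal rate uses a 7.1 Ma genus-appearance span rather than a split age;
rate tables accept such terminal-age flags directly.

## Fixtures

The fixture matrix encodes every character state the published analysis
prints: the seven chimpanzee-bonobo differences (two major), the twelve
hindlimb chimpanzee-human differences (seven major), the thirteen major
HN-FL chimpanzee-human differences ("contrahentes to digits 4 and 5"
deliberately split into two characters so that count is met), and the
individually numbered worked-example characters 66, 83, 112, 118, 120, 131
and 140. States the printed lists do not mention default to the ancestral
state 0; the few deeper-taxon states the printed reconstructions *imply*
(Pongo and Gorilla derived for chars 120/131, Gorilla derived for chars
83/140) are set to the minimal pattern that makes the published placements
unambiguous on the seven-terminal working topology, and each such choice is
recorded in the per-character provenance notes shipped beside the NEXUS
file. Fixture character ids 201+ are package-assigned (the source numbers
only the worked-example characters). The fixture matrix reproduces 15 of
the 16 printed HN-FL chimpanzee-human differences; the sixteenth minor
difference is not identified in the source text and is deliberately not
invented, so the 3.5/Ma headline rate is computed from the printed counts
(28 changes over 8 Ma), which the rates API takes as inputs.

## Synthetic data

The generator emulates hominoid-scale data sets: 10–20 terminals (default
12), ~166 mostly binary characters (default 90% binary, remainder
3-state), evolved on a known topology (random sequential attachment, or a
supplied Newick). The unit of simulation is the discrete change event, not
a per-site substitution process, because the analysis quantifies rates as
change events per Ma: each branch draws Poisson(rate) events per character
(default mean 0.05, per-branch overrides including exact zero for
stasis-regime branches), each event flips a binary state or moves a
multistate one uniformly, with an optional bias back toward state 0. The
true event log and the per-branch *net* changes are emitted alongside the
matrix; only net changes are observable to any inference, so recovery is
scored against them, exactly matched on (character, branch).

What the generator does not emulate: correlated characters, region- or
lineage-specific rate covariance (mosaicism is measured, not simulated),
missing data and polymorphism in the tips, and specimen-level noise below
the coded state. Passing recovery tests therefore show the inference chain
is correct under the stated generative model, not that real dissection data
meet that model.

Two intrinsic limits matter when reading recovery scores: a net change on
one of the two branches adjacent to the root cannot be polarized without
external information (the MPR set always admits the sister placement), and
events that cancel within a branch are invisible in principle. The
perfect-recovery assertions therefore use homoplasy-free realizations
without root-adjacent changes.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng(seed)`; a spec plus
seed fully determines generator output. Serialization is canonical
(children ordered by smallest descendant label), so equal topologies
serialize identically and reruns of the pipeline are byte-identical;
per-run manifests record config, package version and input checksums. The
problem sizes used by the shipped checks — 7-taxon fixtures, search
cross-checks at ≤7 taxa, and the topology-recovery experiment at 8 taxa ×
166 characters × 100 seeds with 0.03 expected changes per branch per
character — were chosen as the smallest sizes at which each property is
informative; the recovery experiment run at those conditions placed the
generating topology in the MPT set for 95 of 100 seeds, which is the
threshold the acceptance suite asserts.

## Known limitations

Exact search only (≤16 taxa); no support values, likelihood or Bayesian
estimation; no character weighting or ordering; NEXUS support covers
standard-category data with 0–9 symbols (no TNT/PHYLIP, continuous
characters or step matrices); per-character metadata rides in a private
NEXUS block that other programs will ignore silently; the full published
166-character supplementary matrix is not redistributed here, so the
whole-matrix score (L = 303, CI = 57, RI = 75, single MPT) is expressed as
a reporting contract that activates when such a matrix is supplied.
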