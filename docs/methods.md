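# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, and what the synthetic-data tests do and do
not demonstrate about real data.

## Character matrices

Cells are sets of single-character state symbols (`0`–`9`). Missing (`?`)
and inapplicable (`-`) cells are both scored as full ambiguity — the set of
every state the character shows — because parsimony offers no principled
way to distinguish them without extra assumptions. Polymorphic cells
(`{01}` / `[01]` on input) are carried as multi-state sets and resolved
optimally during scoring. Taxon labels are matched after trimming and
collapsing internal whitespace/underscores, so matrix, tree and range-table
spellings interoperate.

Parsers reduce each character's alphabet to the states actually observed
(the "normal form"); a written-then-reread matrix therefore equals the
normal form of the original. The round-trip property tests assert exactly
that contract.

## Parsimony scoring

Unordered characters use the Fitch downpass (Hartigan's generalisation at
polytomies, so strict-consensus trees can be scored exactly too). The one
ordered character in the pipeline — the stratigraphic character — is scored
by Sankoff dynamic programming with linear `|i − j|` costs. Per-character
bounds are `m = observed states − 1` (minimum) and
`g = scored taxa − count of the most frequent state` (maximum on any tree);
polymorphic cells are resolved greedily toward already-required states for
`m` and counted toward their most frequent member state for `g`.

Ensemble indices: `CI = ΣM/ΣS`, `RI = (ΣG − ΣS)/(ΣG − ΣM)`,
`RC = CI·RI`, `HI = 1 − CI`. Characters with `g = m` (parsimony-
uninformative) are always excluded from the RI sums, where they would be
0/0. Whether they enter the CI sums is a reporting convention: the default
(`include_uninformative=True`) matches the convention of mainstream
parsimony software; the informative-only variant is a flag, and every
statistics object records which convention produced it.

## Search

Exact search is branch-and-bound over stepwise tip addition (tree length
is monotone in taxon addition, so subtrees longer than the incumbent are
pruned); it is guarded at 12 taxa and returns *all* optimal topologies.
Heuristic search is random-addition-sequence starting trees followed by
first-improvement hill climbing under NNI, SPR or TBR (default TBR,
implemented as SPR with rerooting of the pruned subtree). The seed is a
mandatory part of the configuration and is echoed in the result; equal-
length optima are retained up to `max_trees`, deduplicated by unrooted
topology, and summarised by strict consensus. Sectorial searches,
ratchets, drifting and tree fusing used by some parsimony packages are
deliberately out of scope: on matrices of this size (tens of taxa),
repeated random addition plus TBR reliably reaches the same optimum and is
fully specifiable.

## ACCTRAN and synapomorphy ambiguity

ACCTRAN states are resolved by retaining the parental state wherever the
downpass set allows and otherwise taking the lexicographically smallest
admissible state (also at the root). This places changes as rootward as
the optimum permits and guarantees the recorded changes sum to the tree
length (property-tested). A change at a node is classified *unambiguous*
when **every** most-parsimonious reconstruction changes state on that
branch; this is decided exactly by comparing the constrained optimum
(parent state = child state on that branch) with the global optimum in a
two-pass DP, not by comparing two heuristic optimisations. Brute-force MPR
enumeration on small trees confirms the classification.

## Homoplasy screening

The source procedure — mapping candidate characters on published
topologies and judging their distributions by eye — is operationalised as
per-character CI on each reference tree, evaluated over the taxa the tree
shares with the matrix. A character failing `CI < threshold` (default 1.0)
on *any* reference tree is excluded (`rule="all"` requires failure on
every tree). Constant and unscorable characters are retained with a flag:
absence of evidence of homoplasy is not evidence of homoplasy.

## Stratigraphic congruence and dating

A node is stratigraphically consistent when its clade's oldest FAD is not
older than its sister clade's oldest FAD. Ties count as consistent —
stage-level age resolution makes strict inequality too brittle. The
denominator is the internal nodes excluding the root (n − 2 for n tips on
a binary rooted tree), matching the published "OTUs minus 2" convention;
the per-node verdict list is also reported so any other convention can be
recomputed from it. Taxa without ranges are pruned with a logged warning.
Minimum node ages are clade-oldest FADs; ghost lineage on a branch is the
parent's minimum age minus the child clade's FAD. These are *minimum*
dates by construction: with ranges sampled inside true lineage durations,
estimated ages can only underestimate true ages, a bias direction the
property tests assert.

## Stratocladistic ADR test

A candidate ancestor is removed as a terminal and re-enters as a degree-2
node spliced onto the descendant's stem, its observed states fixed there
(missing characters leave the node free). The resulting constrained length
minus the sister-group length is the hypothesis's debt. This placement
reproduces the classic "ancestorize the terminal with a zero-length
branch" manipulation: for the textbook case of an ancestor bearing one
autapomorphy it yields a debt of exactly one step (confirmed by exhaustive
constrained enumeration), whereas constraining the descendant's parent
after suppressing the old node would double-charge reversals.

The stratigraphic character maps each taxon's FAD to a geological-stage
bin (default: pre-Tortonian pooled, Tortonian, Messinian, Zanclean,
Piacenzian, Gelasian-and-younger — a reconstruction; override
`StratCharacterSpec` for other timescales) and is scored ordered with unit
cost per bin crossed, folded into total tree length with weight 1. A
consequence of the linear cost model worth knowing: when the candidate
ancestor is already the descendant's sister, per-character debt is
provably non-negative, so appending the stratigraphic character can
reduce the *relative* support for sisterhood only through ties, never by
making the ADR arrangement strictly shorter.

## Allometric body size

Unit conventions are fixed by the worked examples: Eq. 1 takes bizygomatic
width in mm and returns length in mm; Eq. 2 takes occipital breadth in mm
and returns mass in kg; Eq. 3 relates mass in kg to skeletal length in cm;
Eq. 4 relates supraoccipital to condylobasal length in mm. All logarithms
are base 10 — the only base that reproduces the printed ~13 m from a
1,660 mm bizygomatic width. Percentage "reductions" are multiplicative
(×0.63, ×0.53, ×0.60), and the Eq. 4 inverse is
`(sol + 62.803)/0.3937` (required by the printed 1,581.9 mm and the
4.74–6.37 m bracket). The consensus report spans all corrected length
estimates and carries the mass point reduced by the same fraction as the
Eq. 3 length. Estimates below the Eq. 4 intercept (supraoccipital
≤ 62.8 mm) are rejected as out of the regression's domain.

## Synthetic data: what it emulates, and what it does not

Trees are pure-birth with unit rate, rescaled to a 20 Myr root — the
timescale of the balaenoid record the pipeline targets. Characters evolve
under an equal-rates Mk model with changes Poisson in branch duration;
default rate 0.01 changes/character/Myr, chosen so the default 42-taxon
condition (~200 Myr of total branch length) carries about two changes per
character, the homoplasy level of a screened matrix with ensemble CI near
0.5. Homoplasy-free mode instead places exactly one change per character
on one uniformly chosen branch, guaranteeing per-character CI = 1 on the
true tree. Ranges sample the FAD uniformly inside each tip's true lineage
interval (LAD uniform below the FAD); measurement noise is multiplicative
lognormal, preserving positivity.

Two honest limitations. First, under Poisson placement short internal
branches often receive no change, so *exact* topology recovery by
parsimony is not guaranteed at moderate rates: measured exact recovery at
10–15 taxa and 80–100 characters was near zero, while mean split recovery
was ≈ 0.72; the tests therefore assert exact recovery only in
homoplasy-free mode and a split-recovery floor (≥ 0.55) at moderate rate.
Second, the generators draw characters independently — no correlated
change, no ascertainment toward variable characters — so passing tests
demonstrate algorithmic correctness under the stated models, not
robustness to the integration structure of real morphological data.

## Problem sizes in the shipped tests

Exhaustive-enumeration oracles run on ≤ 6-tip trees; exact-vs-heuristic
search comparisons on 8-taxon matrices; recovery studies on 10–15 taxa
with 60–100 characters and 12–25 replicates; range-sampling bias checks
over 100 replicates. These sizes make the whole suite run in well under a
minute while every claim remains the scaled form of the corresponding
full-size statement.
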