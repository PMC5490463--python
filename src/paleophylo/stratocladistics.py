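"""Stratocladistic test of ancestor-descendant relationship (ADR) hypotheses.

A fossil terminal is "ancestorized" by removing it from the tree and fixing
its observed character states as constraints at the internal node from
which its putative descendant springs; characters the candidate ancestor
was never scored for leave the node free. The parsimony length of that
constrained tree, minus the length of the conventional sister-group tree,
is the debt of the ancestor hypothesis: zero or negative debt means
ancestry is at least as parsimonious as sisterhood.

Stratigraphic evidence enters through one extra ordered character whose
states are geological time bins of each taxon's first appearance, scored
with linear |i - j| costs so each bin crossed costs one step. An old
ancestor below a young descendant then pays no stratigraphic penalty,
while a sister-group arrangement of taxa in different bins does.

The default bin edges are a reconstruction from named late Neogene stages
(no authoritative bin table accompanies the published character); override
them via StratCharacterSpec for other timescales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .matrix_io import CharacterDef, CharacterMatrix, PhyloTree, normalize_label
from .parsimony_core import constrained_length, fitch_score
from .stratigraphy import StratRangeTable

__all__ = [
    "StratCharacterSpec",
    "AdrHypothesis",
    "AdrScore",
    "AdrComparison",
    "BinningError",
    "HypothesisError",
    "default_stage_bins",
    "build_strat_character",
    "add_strat_character",
    "adr_score",
    "compare_adr",
]


class BinningError(ValueError):
    """A first-appearance age falls outside the bin coverage."""


class HypothesisError(ValueError):
    """Ill-formed ancestor-descendant hypothesis."""


@dataclass
class StratCharacterSpec:
    """Ordered time bins, old to young, as (name, older_edge, younger_edge).

    Bins must be contiguous and non-overlapping; state i is the index of the
    bin containing a taxon's FAD (older edge inclusive, younger exclusive,
    except the last bin which includes its younger edge).
    """

    bins: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("at least one bin required")
        for name, old, young in self.bins:
            if old <= young:
                raise ValueError(f"bin {name!r}: older edge must exceed younger")
        for (n1, _, y1), (n2, o2, _) in zip(self.bins, self.bins[1:]):
            if abs(y1 - o2) > 1e-9:
                raise ValueError(f"bins {n1!r} and {n2!r} not contiguous")
        if len(self.bins) > 10:
            raise ValueError("at most 10 bins (single-symbol states)")

    def bin_index(self, age_ma: float) -> int:
        for i, (name, old, young) in enumerate(self.bins):
            last = i == len(self.bins) - 1
            if (young < age_ma <= old) or (age_ma == old and i == 0) or (
                last and young - 1e-9 <= age_ma <= old
            ):
                return i
        raise BinningError(
            f"age {age_ma} Ma outside bin coverage "
            f"[{self.bins[-1][2]}, {self.bins[0][1]}]"
        )


def default_stage_bins() -> StratCharacterSpec:
    """Late Neogene stage bins extended through the Miocene so the whole
    balaenoid record (Burdigalian onward) maps to a state."""
    return StratCharacterSpec(
        bins=[
            ("pre-Tortonian", 23.03, 11.63),   # Aquitanian..Serravallian pooled
            ("Tortonian", 11.63, 7.246),
            ("Messinian", 7.246, 5.333),
            ("Zanclean", 5.333, 3.6),
            ("Piacenzian", 3.6, 2.588),
            ("Gelasian+", 2.588, 0.0),          # Pleistocene and younger pooled
        ]
    )


def build_strat_character(
    ranges: StratRangeTable,
    bins: StratCharacterSpec,
    taxa: Sequence[str],
) -> tuple[CharacterDef, list[frozenset[str]]]:
    """One ordered character column: state = FAD bin index per taxon.

    Taxa without a range get the full ambiguity set. The character uses
    linear ordered costs, so the parsimony cost between bins i and j is
    |i - j| (one step per bin boundary crossed).
    """
    alphabet = tuple(str(i) for i in range(len(bins.bins)))
    definition = CharacterDef(
        index=-1, state_alphabet=alphabet, ordered=True, label="stratigraphic"
    )
    column: list[frozenset[str]] = []
    for taxon in taxa:
        if taxon in ranges:
            column.append(frozenset([str(bins.bin_index(ranges.fad(taxon)))]))
        else:
            column.append(frozenset(alphabet))
    return definition, column


def add_strat_character(
    matrix: CharacterMatrix,
    ranges: StratRangeTable,
    bins: StratCharacterSpec | None = None,
) -> CharacterMatrix:
    """Return the matrix with the stratigraphic character appended."""
    bins = bins or default_stage_bins()
    definition, column = build_strat_character(ranges, bins, matrix.taxa)
    return matrix.with_character(definition, column)


# ---------------------------------------------------------------------------

@dataclass
class AdrHypothesis:
    """Ancestor tip placed at the node subtending the descendant tip/clade."""

    ancestor: str
    descendant: str | Sequence[str]

    def __post_init__(self) -> None:
        self.ancestor = normalize_label(self.ancestor)
        if isinstance(self.descendant, str):
            self.descendant_labels = [normalize_label(self.descendant)]
        else:
            self.descendant_labels = [normalize_label(d) for d in self.descendant]
        if self.ancestor in self.descendant_labels:
            raise HypothesisError("ancestor and descendant must differ")


@dataclass
class AdrScore:
    total_length: float
    morphology_length: float
    strat_length: float | None  # None when no stratigraphic character present
    constrained_node: int


def _strat_char_indices(matrix: CharacterMatrix) -> list[int]:
    return [i for i, c in enumerate(matrix.characters) if c.ordered]


def adr_score(
    tree: PhyloTree, matrix: CharacterMatrix, hypothesis: AdrHypothesis
) -> AdrScore:
    """Tree length under the ancestor hypothesis.

    The ancestor tip is pruned and re-enters as a zero-length degree-2 node
    on the branch subtending the descendant (tip or clade); its observed
    (non-missing) states are fixed there. Missing characters leave the node
    free, so an entirely unscored ancestor costs nothing beyond its own
    removal. When the ancestor was the descendant's sister this reproduces
    the classic "ancestorize the terminal" manipulation exactly.
    """
    if hypothesis.ancestor not in tree.leaf_labels:
        raise HypothesisError(f"ancestor {hypothesis.ancestor!r} not a tip")
    for d in hypothesis.descendant_labels:
        if d not in tree.leaf_labels:
            raise HypothesisError(f"descendant {d!r} not a tip")
    keep = [t for t in tree.leaf_labels if t != hypothesis.ancestor]
    pruned = tree.prune_to(keep)
    if len(hypothesis.descendant_labels) == 1:
        desc_node = pruned.find_leaf(hypothesis.descendant_labels[0])
    else:
        desc_node = pruned.mrca(hypothesis.descendant_labels)
    if desc_node.parent is None:
        raise HypothesisError(
            "descendant clade spans the whole pruned tree; no stem to occupy"
        )
    # splice the ancestorized node into the descendant's stem branch
    from .matrix_io import TreeNode as _TN

    anchor = _TN(max(n.id for n in pruned.preorder()) + 1)
    parent = desc_node.parent
    parent.children[parent.children.index(desc_node)] = anchor
    anchor.parent = parent
    anchor.children = [desc_node]
    desc_node.parent = anchor
    anc_row = matrix.taxon_index(hypothesis.ancestor)
    anc_cells = matrix.cells[anc_row]
    # constrain the anchor node character-by-character: a state symbol the
    # ancestor shows for one character must not constrain others
    total = morph = strat = 0.0
    strat_cols = set(_strat_char_indices(matrix))
    for ci in range(matrix.n_characters):
        cons = None if matrix.is_missing(anc_row, ci) else {
            anchor.id: anc_cells[ci]
        }
        one = matrix.subset_characters([ci]).subset_taxa(pruned.leaf_labels)
        ln, _ = constrained_length(pruned, one, cons)
        total += ln
        if ci in strat_cols:
            strat += ln
        else:
            morph += ln
    return AdrScore(
        total_length=total,
        morphology_length=morph,
        strat_length=strat if strat_cols else None,
        constrained_node=anchor.id,
    )


@dataclass
class AdrComparison:
    sister_morphology: float
    sister_total: float
    adr_morphology: float
    adr_total: float
    morphology_debt: float
    total_debt: float
    verdict: str  # 'adr', 'sister', or 'tie'


def compare_adr(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    hypothesis: AdrHypothesis,
    ranges: StratRangeTable | None = None,
    bins: StratCharacterSpec | None = None,
    alternative_topology: PhyloTree | None = None,
) -> AdrComparison:
    """Debt of the ancestor hypothesis with and without stratigraphic data.

    The sister-group reference length is that of ``tree`` itself (or of a
    user-supplied ``alternative_topology``, the hand-swapped-branches mode).
    When ``ranges`` is given, the stratigraphic character is appended and
    both lengths are also compared with it included.
    """
    reference = alternative_topology or tree
    work = matrix
    if ranges is not None:
        work = add_strat_character(matrix, ranges, bins)
    strat_cols = set(_strat_char_indices(work))
    ref_steps = fitch_score(reference, work).per_character_steps
    sister_total = float(ref_steps.sum())
    sister_morph = float(
        sum(s for i, s in enumerate(ref_steps) if i not in strat_cols)
    )
    adr = adr_score(reference, work, hypothesis)
    morph_debt = adr.morphology_length - sister_morph
    total_debt = adr.total_length - sister_total
    if total_debt < 0:
        verdict = "adr"
    elif total_debt > 0:
        verdict = "sister"
    else:
        verdict = "tie"
    return AdrComparison(
        sister_morphology=sister_morph,
        sister_total=sister_total,
        adr_morphology=adr.morphology_length,
        adr_total=adr.total_length,
        morphology_debt=morph_debt,
        total_debt=total_debt,
        verdict=verdict,
    )
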