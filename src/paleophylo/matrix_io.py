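"""Core data types and I/O for discrete morphological matrices and trees.

Character matrices hold taxa x discrete unordered (or ordered) characters,
with polymorphic, missing ('?') and inapplicable ('-') cells. Missing and
inapplicable cells are both scored as full ambiguity: the cell carries every
state of the character's alphabet, which is the standard treatment when the
data themselves do not distinguish the two. Supported dialects are NEXUS
(DATA/CHARACTERS block, parsed through dendropy) and the TNT ``xread``
format. Trees are rooted, optionally dated (node ages in Ma, increasing
root-ward), and round-trip through Newick.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "CharacterDef",
    "CharacterMatrix",
    "TreeNode",
    "PhyloTree",
    "MatrixParseError",
    "MatrixDimensionError",
    "SymbolError",
    "TreeError",
    "read_matrix",
    "write_matrix",
    "read_tree",
    "write_tree",
    "normalize_label",
]


class MatrixParseError(ValueError):
    """Raised when a matrix block is syntactically malformed."""


class MatrixDimensionError(ValueError):
    """Raised when a row length disagrees with the declared dimensions."""


class SymbolError(ValueError):
    """Raised when a cell holds a symbol outside the declared alphabet."""


class TreeError(ValueError):
    """Raised for malformed or inconsistent trees."""


# state symbols recognised in matrix cells
STATE_SYMBOLS = "0123456789"


def normalize_label(label: str) -> str:
    """Canonicalise a taxon label: trim, collapse whitespace/underscores.

    Matrix rows, tree tips and range-table taxa are matched through this
    normal form so that ``Eubalaena glacialis`` and ``Eubalaena_glacialis``
    name the same OTU.
    """
    return re.sub(r"[\s_]+", "_", label.strip())


@dataclass
class CharacterDef:
    """Definition of one character column.

    ``state_alphabet`` is the ordered tuple of state symbols observed in the
    column (or declared for a constructed character). ``ordered`` marks
    linear (Wagner/Sankoff |i-j| cost) characters: everything read from a
    matrix file is unordered; only the appended stratigraphic character is
    ordered. ``weight`` defaults to 1 and must be non-negative.
    """

    index: int
    state_alphabet: tuple[str, ...]
    ordered: bool = False
    weight: float = 1.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("character weight must be non-negative")
        if len(set(self.state_alphabet)) != len(self.state_alphabet):
            raise ValueError("state alphabet contains duplicates")

    @property
    def full_ambiguity(self) -> frozenset[str]:
        return frozenset(self.state_alphabet)


class CharacterMatrix:
    """Taxa x characters matrix of discrete state sets.

    Each cell is a non-empty frozenset of state symbols: a singleton for an
    observed state, a larger set for polymorphism, and the character's full
    alphabet for missing/inapplicable data.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[CharacterDef],
        cells: Sequence[Sequence[Iterable[str]]],
    ) -> None:
        self.taxa: list[str] = [normalize_label(t) for t in taxa]
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if any(not t for t in self.taxa):
            raise ValueError("taxon labels must be non-empty")
        self.characters: list[CharacterDef] = list(characters)
        self.cells: list[list[frozenset[str]]] = []
        if len(cells) != len(self.taxa):
            raise MatrixDimensionError(
                f"{len(cells)} rows for {len(self.taxa)} taxa"
            )
        for ti, row in enumerate(cells):
            row = [frozenset(c) for c in row]
            if len(row) != len(self.characters):
                raise MatrixDimensionError(
                    f"taxon {self.taxa[ti]!r}: {len(row)} cells for "
                    f"{len(self.characters)} characters"
                )
            for ci, cell in enumerate(row):
                if not cell:
                    raise ValueError(
                        f"empty cell for taxon {self.taxa[ti]!r}, "
                        f"character {ci}"
                    )
                extra = cell - set(self.characters[ci].state_alphabet)
                if extra:
                    raise SymbolError(
                        f"taxon {self.taxa[ti]!r}, character {ci}: "
                        f"symbols {sorted(extra)} outside alphabet"
                    )
            self.cells.append(row)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(normalize_label(label))
        except ValueError:
            raise KeyError(f"taxon {label!r} not in matrix") from None

    def cell(self, taxon: str, char_index: int) -> frozenset[str]:
        return self.cells[self.taxon_index(taxon)][char_index]

    def is_missing(self, taxon_i: int, char_i: int) -> bool:
        """True when the cell is fully ambiguous (no information)."""
        return self.cells[taxon_i][char_i] == self.characters[char_i].full_ambiguity

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and [c.state_alphabet for c in self.characters]
            == [c.state_alphabet for c in other.characters]
            and [c.ordered for c in self.characters]
            == [c.ordered for c in other.characters]
            and self.cells == other.cells
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"

    # -- derived matrices --------------------------------------------------
    def normal_form(self) -> "CharacterMatrix":
        """Copy with each alphabet reduced to the states actually observed.

        This is the form the parsers produce: a written-then-reread matrix
        equals ``normal_form()`` of the original cell-for-cell. Cells that
        were fully ambiguous stay fully ambiguous under the new alphabet.
        """
        chars: list[CharacterDef] = []
        observed_sets: list[set[str]] = []
        for ci, c in enumerate(self.characters):
            if c.ordered:
                # reducing an ordered alphabet would change |i-j| costs
                observed_sets.append(set(c.state_alphabet))
                chars.append(CharacterDef(ci, c.state_alphabet, True, c.weight, c.label))
                continue
            observed: set[str] = set()
            for ti in range(self.n_taxa):
                if not self.is_missing(ti, ci):
                    observed |= self.cells[ti][ci]
            if not observed:
                observed = {"0"}
            observed_sets.append(observed)
            chars.append(
                CharacterDef(ci, tuple(sorted(observed)), c.ordered, c.weight, c.label)
            )
        cells = []
        for ti in range(self.n_taxa):
            row = []
            for ci in range(self.n_characters):
                if self.is_missing(ti, ci):
                    row.append(frozenset(observed_sets[ci]))
                else:
                    row.append(self.cells[ti][ci])
            cells.append(row)
        return CharacterMatrix(self.taxa, chars, cells)

    def subset_taxa(self, labels: Sequence[str]) -> "CharacterMatrix":
        labels = [normalize_label(l) for l in labels]
        idx = [self.taxon_index(l) for l in labels]
        return CharacterMatrix(
            labels, self.characters, [self.cells[i] for i in idx]
        )

    def subset_characters(self, char_indices: Sequence[int]) -> "CharacterMatrix":
        chars = []
        for new_i, ci in enumerate(char_indices):
            c = self.characters[ci]
            chars.append(
                CharacterDef(new_i, c.state_alphabet, c.ordered, c.weight, c.label)
            )
        cells = [[row[ci] for ci in char_indices] for row in self.cells]
        return CharacterMatrix(self.taxa, chars, cells)

    def with_character(
        self, definition: CharacterDef, column: Sequence[Iterable[str]]
    ) -> "CharacterMatrix":
        """Return a copy with one extra character column appended."""
        chars = self.characters + [
            CharacterDef(
                self.n_characters,
                definition.state_alphabet,
                definition.ordered,
                definition.weight,
                definition.label,
            )
        ]
        if len(column) != self.n_taxa:
            raise MatrixDimensionError("appended column length != taxon count")
        cells = [row + [frozenset(column[i])] for i, row in enumerate(self.cells)]
        return CharacterMatrix(self.taxa, chars, cells)


def _columns_to_matrix(
    taxa: list[str], raw_rows: list[list[frozenset[str] | None]]
) -> CharacterMatrix:
    """Build a CharacterMatrix from parsed rows where None marks missing.

    The per-column alphabet is the union of observed symbols; missing cells
    become that full set. Columns with no observed state fall back to a
    one-state alphabet ('0') so that cells stay non-empty; such columns are
    constant and parsimony-inert.
    """
    n_chars = len(raw_rows[0]) if raw_rows else 0
    chars: list[CharacterDef] = []
    for ci in range(n_chars):
        observed: set[str] = set()
        for row in raw_rows:
            if row[ci] is not None:
                observed |= row[ci]  # type: ignore[arg-type]
        alphabet = tuple(sorted(observed)) if observed else ("0",)
        chars.append(CharacterDef(ci, alphabet))
    cells: list[list[frozenset[str]]] = []
    for row in raw_rows:
        out_row = []
        for ci, cell in enumerate(row):
            out_row.append(
                frozenset(chars[ci].state_alphabet) if cell is None else cell
            )
        cells.append(out_row)
    return CharacterMatrix(taxa, chars, cells)


# ---------------------------------------------------------------------------
# matrix reading
# ---------------------------------------------------------------------------

_POLY_RE = re.compile(r"[\[{]([^\]}]*)[\]}]")


def _parse_state_string(seq: str, taxon: str, line_no: int) -> list[frozenset[str] | None]:
    """Parse one row of state symbols into cells (None = missing)."""
    cells: list[frozenset[str] | None] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch in "{[":
            m = _POLY_RE.match(seq, i)
            if not m:
                raise MatrixParseError(
                    f"line {line_no}: unterminated polymorphism in row "
                    f"for {taxon!r}"
                )
            states = frozenset(m.group(1).replace(" ", ""))
            bad = states - set(STATE_SYMBOLS)
            if bad or not states:
                raise SymbolError(
                    f"line {line_no}: bad polymorphic cell {m.group(0)!r} "
                    f"for taxon {taxon!r}"
                )
            cells.append(states)
            i = m.end()
        elif ch in "?-":
            cells.append(None)
            i += 1
        elif ch in STATE_SYMBOLS:
            cells.append(frozenset(ch))
            i += 1
        elif ch.isspace():
            i += 1
        else:
            raise SymbolError(
                f"line {line_no}: unknown symbol {ch!r} in row for {taxon!r}"
            )
    return cells


def _read_tnt(text: str) -> CharacterMatrix:
    """Parse a TNT ``xread`` block: ``xread ['comment'] nchar ntax rows... ;``"""
    # strip single-quoted comment after xread, if any
    m = re.search(r"xread\b", text, flags=re.IGNORECASE)
    if not m:
        raise MatrixParseError("no xread block found")
    body = text[m.end():]
    body = re.sub(r"'[^']*'", " ", body, count=1)
    end = body.find(";")
    if end == -1:
        raise MatrixParseError("xread block not terminated by ';'")
    body = body[:end]
    tokens = body.split()
    if len(tokens) < 2:
        raise MatrixParseError("xread block missing dimensions")
    try:
        n_chars, n_taxa = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise MatrixParseError(
            f"bad xread dimensions: {tokens[0]!r} {tokens[1]!r}"
        ) from None
    rest = tokens[2:]
    if len(rest) % 2 != 0:
        raise MatrixParseError("xread rows must alternate taxon and states")
    taxa: list[str] = []
    rows: list[list[frozenset[str] | None]] = []
    for k in range(0, len(rest), 2):
        taxon, seq = rest[k], rest[k + 1]
        cells = _parse_state_string(seq, taxon, line_no=0)
        if len(cells) != n_chars:
            raise MatrixDimensionError(
                f"taxon {taxon!r}: {len(cells)} cells, expected {n_chars}"
            )
        taxa.append(taxon)
        rows.append(cells)
    if len(taxa) != n_taxa:
        raise MatrixDimensionError(
            f"{len(taxa)} taxa parsed, header declares {n_taxa}"
        )
    return _columns_to_matrix(taxa, rows)


def _read_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS standard-character matrix via dendropy."""
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus"
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise MatrixParseError(f"NEXUS parse failure: {exc}") from exc
    taxa = [t.label for t in dmat.taxon_namespace]
    rows: list[list[frozenset[str] | None]] = []
    for t in dmat.taxon_namespace:
        seq = dmat[t]
        row: list[frozenset[str] | None] = []
        for state in seq:
            symbols = frozenset(
                s.symbol for s in state.fundamental_states if s.symbol != "-"
            )
            symbols = symbols & set(STATE_SYMBOLS)
            if not symbols or state.symbol in ("?", "-"):
                row.append(None)
            else:
                row.append(symbols)
        rows.append(row)
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise MatrixDimensionError("unequal row lengths in NEXUS matrix")
    return _columns_to_matrix(taxa, rows)


def read_matrix(source, dialect: str) -> CharacterMatrix:
    """Read a character matrix from a text stream or string.

    dialect: 'nexus' or 'tnt'.
    """
    text = source.read() if hasattr(source, "read") else str(source)
    if dialect == "tnt":
        return _read_tnt(text)
    if dialect == "nexus":
        return _read_nexus(text)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# matrix writing
# ---------------------------------------------------------------------------

def _cell_text(cell: frozenset[str], char: CharacterDef) -> str:
    if cell == char.full_ambiguity and len(cell) != 1:
        return "?"
    if len(cell) == 1:
        return next(iter(cell))
    return "{" + "".join(sorted(cell)) + "}"


def write_matrix(matrix: CharacterMatrix, dialect: str) -> str:
    """Serialise a matrix to NEXUS or TNT text. Round-trips cell-for-cell."""
    rows = []
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for ti, taxon in enumerate(matrix.taxa):
        seq = "".join(
            _cell_text(matrix.cells[ti][ci], matrix.characters[ci])
            for ci in range(matrix.n_characters)
        )
        rows.append((taxon, seq))
    if dialect == "tnt":
        lines = [f"xread {matrix.n_characters} {matrix.n_taxa}"]
        lines += [f"{t} {s}" for t, s in rows]
        lines.append(";")
        return "\n".join(lines) + "\n"
    if dialect == "nexus":
        symbols = sorted({s for c in matrix.characters for s in c.state_alphabet})
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="'
            + "".join(symbols)
            + '" MISSING=? GAP=-;',
            "    MATRIX",
        ]
        lines += [f"        {t:<{width}}{s}" for t, s in rows]
        lines += ["    ;", "END;"]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    id: int
    label: str | None = None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    age: float | None = None  # Ma, older = larger

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:
        return f"<TreeNode {self.id} {self.label or ''}>"


class PhyloTree:
    """Rooted phylogenetic tree with optional node ages (Ma).

    Ages, when present, must weakly increase toward the root (a child can
    never be older than its parent).
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_nested(cls, nested) -> "PhyloTree":
        """Build from nested tuples/lists of tip labels, e.g. ('A', ('B','C'))."""
        counter = [0]

        def build(obj) -> TreeNode:
            node = TreeNode(counter[0])
            counter[0] += 1
            if isinstance(obj, (tuple, list)):
                for child in obj:
                    c = build(child)
                    c.parent = node
                    node.children.append(c)
            else:
                node.label = normalize_label(str(obj))
            return node

        return cls(build(nested))

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if any(l is None or l == "" for l in labels):
            raise TreeError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node.age is not None and node.parent is not None:
                if node.parent.age is not None and node.age > node.parent.age + 1e-9:
                    raise TreeError(
                        f"node {node.id} age {node.age} exceeds parent age "
                        f"{node.parent.age}"
                    )
            if node.age is not None and node.age < 0:
                raise TreeError("node ages must be non-negative")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self, include_root: bool = True) -> list[TreeNode]:
        return [
            n
            for n in self.preorder()
            if not n.is_leaf and (include_root or n is not self.root)
        ]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def find_leaf(self, label: str) -> TreeNode:
        label = normalize_label(label)
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(f"tip {label!r} not in tree")

    def mrca(self, labels: Sequence[str]) -> TreeNode:
        want = {normalize_label(l) for l in labels}
        below: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node.id] = {node.label}  # type: ignore[arg-type]
            else:
                below[node.id] = set().union(*(below[c.id] for c in node.children))
        # postorder visits children first, so the first covering node is the MRCA
        for node in self.postorder():
            if want <= below[node.id]:
                return node
        raise KeyError(f"labels {sorted(want)} not all present in tree")

    def is_binary(self) -> bool:
        return all(
            len(n.children) in (0, 2) for n in self.preorder()
        )

    # -- structure edits ---------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode, parent: TreeNode | None) -> TreeNode:
            c = TreeNode(node.id, node.label, parent, [], node.age)
            c.children = [clone(ch, c) for ch in node.children]
            return c

        return PhyloTree(clone(self.root, None))

    def renumber(self) -> None:
        """Reassign node ids in preorder (stable identifiers after edits)."""
        for i, node in enumerate(self.preorder()):
            node.id = i

    def prune_to(self, labels: Sequence[str]) -> "PhyloTree":
        """Return a copy restricted to the given tips, suppressing unary nodes."""
        keep = {normalize_label(l) for l in labels}
        missing = keep - set(self.leaf_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")

        def rebuild(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                if node.label in keep:
                    return TreeNode(0, node.label, None, [], node.age)
                return None
            kids = [rebuild(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = TreeNode(0, None, None, [], node.age)
            for k in kids:
                k.parent = new
            new.children = kids
            return new

        root = rebuild(self.root)
        if root is None:
            raise TreeError("pruning removed every tip")
        tree = PhyloTree(root)
        tree.renumber()
        return tree

    def reroot_above(self, node_label_or_labels) -> "PhyloTree":
        """Reroot so the clade containing the given tip(s) is one child of the
        new root and everything else is the other (outgroup rooting)."""
        labels = (
            [node_label_or_labels]
            if isinstance(node_label_or_labels, str)
            else list(node_label_or_labels)
        )
        tree = self.copy()
        target = tree.mrca(labels)
        if target is tree.root:
            raise TreeError("cannot reroot above the root (outgroup spans tree)")
        # detach target, then invert the path from its old parent to the root
        old_parent = target.parent
        assert old_parent is not None
        old_parent.children.remove(target)
        # walk up inverting parent links
        path = []
        node = old_parent
        while node is not None:
            path.append(node)
            node = node.parent
        for i in range(len(path) - 1):
            child, parent = path[i], path[i + 1]
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
        # suppress unary nodes created along the inverted path
        def suppress(node: TreeNode) -> TreeNode:
            while len(node.children) == 1:
                only = node.children[0]
                only.parent = node.parent
                node = only
            node.children = [suppress(c) for c in node.children]
            for c in node.children:
                c.parent = node
            return node

        other = suppress(old_parent)
        new_root = TreeNode(0, None, None, [], None)
        target.parent = new_root
        other.parent = new_root
        new_root.children = [target, other]
        out = PhyloTree(new_root)
        out.renumber()
        return out

    # -- comparisons -------------------------------------------------------
    def clades(self) -> set[frozenset[str]]:
        """Rooted clades as tip-label sets (excluding trivial singletons/root)."""
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node.id] = frozenset([node.label])  # type: ignore[list-item]
            else:
                below[node.id] = frozenset().union(*(below[c.id] for c in node.children))
                if node is not self.root:
                    out.add(below[node.id])
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Unrooted splits: each internal edge as a pair of tip-label sets."""
        all_tips = frozenset(self.leaf_labels)
        out = set()
        for clade in self.clades():
            if 1 < len(clade) < len(all_tips) - 1:
                out.add(frozenset([clade, all_tips - clade]))
        return out

    def same_unrooted_topology(self, other: "PhyloTree") -> bool:
        return (
            frozenset(self.leaf_labels) == frozenset(other.leaf_labels)
            and self.bipartitions() == other.bipartitions()
        )

    def __repr__(self) -> str:
        return f"<PhyloTree {len(self.leaves())} tips>"


# ---------------------------------------------------------------------------
# Newick I/O (parsing through dendropy)
# ---------------------------------------------------------------------------

def read_tree(source) -> PhyloTree:
    """Parse a Newick tree into a rooted PhyloTree."""
    text = source.read() if hasattr(source, "read") else str(source)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"Newick parse failure: {exc}") from exc

    counter = [0]

    def convert(dnode) -> TreeNode:
        node = TreeNode(counter[0])
        counter[0] += 1
        if dnode.taxon is not None:
            node.label = normalize_label(dnode.taxon.label)
        elif dnode.is_leaf() and dnode.label:
            node.label = normalize_label(dnode.label)
        for dchild in dnode.child_nodes():
            c = convert(dchild)
            c.parent = node
            node.children.append(c)
        return node

    return PhyloTree(convert(dtree.seed_node))


def write_tree(tree: PhyloTree) -> str:
    """Serialise a PhyloTree to Newick (topology and tip labels only)."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label  # type: ignore[return-value]
        return "(" + ",".join(render(c) for c in node.children) + ")"

    return render(tree.root) + ";"
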