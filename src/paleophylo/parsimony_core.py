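"""Unordered (Fitch) parsimony: scoring, search, indices, ACCTRAN mapping.

Tree length is the minimum number of character-state changes a tree implies.
For unordered characters every change costs 1 and the minimum is found with
the Fitch/Hartigan downpass; the single ordered character this package ever
sees (the stratigraphic character) is scored by Sankoff dynamic programming
with linear |i-j| costs. Ensemble indices follow the standard definitions:

    CI = M / S      M = sum of per-character minimum steps
    RI = (G - S) / (G - M)     G = sum of per-character maximum steps
    RC = CI * RI,   HI = 1 - CI

where S is the realised tree length. Whether parsimony-uninformative
characters enter the CI sums is a reporting convention (TNT includes them);
both conventions are available and the one used is recorded in the output.

Search is exact branch-and-bound up to a 12-taxon guard, and heuristic
random-addition-sequence plus NNI/SPR/TBR hill-climbing beyond that.
ACCTRAN ancestral states place changes as close to the root as the optimum
allows; synapomorphies are classified unambiguous when the change on that
branch occurs in every most-parsimonious reconstruction (checked exactly by
a constrained DP, not by heuristic comparison).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrix_io import (
    CharacterMatrix,
    PhyloTree,
    TreeError,
    TreeNode,
    normalize_label,
)

__all__ = [
    "TreeStatistics",
    "SynapomorphyRecord",
    "ChangeRecord",
    "SearchConfig",
    "SearchResult",
    "TaxonMismatchError",
    "UndefinedStatisticsError",
    "NoSynapomorphyError",
    "fitch_score",
    "tree_statistics",
    "branch_and_bound",
    "heuristic_search",
    "acctran_optimize",
    "classify_synapomorphy",
    "synapomorphy_table",
    "constrained_length",
    "character_min_steps",
    "character_max_steps",
    "strict_consensus",
]

_INF = 10 ** 12

_node_ids = itertools.count(10 ** 6)  # unique ids for nodes created during search


def _fresh_node(label=None):
    return TreeNode(next(_node_ids), label)


class TaxonMismatchError(ValueError):
    """A tree tip has no row in the matrix."""


class UndefinedStatisticsError(ValueError):
    """Ensemble indices are undefined (e.g. zero tree length)."""


class NoSynapomorphyError(ValueError):
    """Classification requested at a node with no change for that character."""


# ---------------------------------------------------------------------------
# encoding and elementary step bounds
# ---------------------------------------------------------------------------

def _check_tips(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    missing = set(tree.leaf_labels) - set(matrix.taxa)
    if missing:
        raise TaxonMismatchError(f"tree tips absent from matrix: {sorted(missing)}")


def _matrix_masks(matrix: CharacterMatrix, cols: tuple[int, ...]):
    """Per-taxon bitmask rows for the given columns, cached on the matrix."""
    cache = getattr(matrix, "_mask_cache", None)
    if cache is None:
        cache = {}
        matrix._mask_cache = cache  # type: ignore[attr-defined]
    if cols not in cache:
        sym_pos = [
            {s: b for b, s in enumerate(matrix.characters[ci].state_alphabet)}
            for ci in cols
        ]
        rows = {}
        for ti, taxon in enumerate(matrix.taxa):
            m = np.zeros(len(cols), dtype=np.int64)
            for j, ci in enumerate(cols):
                bits = 0
                for s in matrix.cells[ti][ci]:
                    bits |= 1 << sym_pos[j][s]
                m[j] = bits
            rows[taxon] = m
        cache[cols] = rows
    return cache[cols]


def _leaf_masks(tree: PhyloTree, matrix: CharacterMatrix, cols: Sequence[int]):
    """Bitmask per (tip, column); bit b set when alphabet state b is allowed."""
    rows = _matrix_masks(matrix, tuple(cols))
    return {leaf.id: rows[leaf.label] for leaf in tree.leaves()}


def _hartigan_steps(tree: PhyloTree, leaf_masks, n_cols: int):
    """Downpass step counts (exact for any vertex degree) and state sets."""
    down: dict[int, np.ndarray] = {}
    steps = np.zeros(n_cols, dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            down[node.id] = leaf_masks[node.id]
            continue
        kids = [down[c.id] for c in node.children]
        if len(kids) == 2:  # plain Fitch
            a, b = kids
            inter = a & b
            steps += inter == 0
            down[node.id] = np.where(inter != 0, inter, a | b)
        else:
            counts = np.zeros((64, n_cols), dtype=np.int64)
            for k in kids:
                for b in range(int(k.max()).bit_length()):
                    counts[b] += (k >> b) & 1
            kmax = counts.max(axis=0)
            steps += len(kids) - kmax
            mask = np.zeros(n_cols, dtype=np.int64)
            for b in range(counts.shape[0]):
                mask |= ((counts[b] == kmax).astype(np.int64)) << b
            down[node.id] = mask
    return steps, down


def character_min_steps(matrix: CharacterMatrix, char_index: int,
                        taxa: Iterable[str] | None = None) -> int:
    """Minimum conceivable steps for a character: observed states minus one.

    Only taxa with data (not fully ambiguous) are counted. Polymorphic cells
    are resolved greedily toward states already required, so they never
    inflate the bound.
    """
    rows = range(matrix.n_taxa) if taxa is None else [
        matrix.taxon_index(t) for t in taxa
    ]
    singles: set[str] = set()
    polys: list[frozenset[str]] = []
    for ti in rows:
        if matrix.is_missing(ti, char_index):
            continue
        cell = matrix.cells[ti][char_index]
        if len(cell) == 1:
            singles |= cell
        else:
            polys.append(cell)
    uncovered = [p for p in polys if not (p & singles)]
    while uncovered:
        # greedy: add the state resolving the most still-uncovered cells
        candidates: dict[str, int] = {}
        for p in uncovered:
            for s in p:
                candidates[s] = candidates.get(s, 0) + 1
        best = max(sorted(candidates), key=lambda s: candidates[s])
        singles.add(best)
        uncovered = [p for p in uncovered if best not in p]
    return max(len(singles) - 1, 0)


def character_max_steps(matrix: CharacterMatrix, char_index: int,
                        taxa: Iterable[str] | None = None) -> int:
    """Maximum steps on any tree (star-tree bound for unordered characters):
    scored taxa minus the count of the most frequent state."""
    rows = range(matrix.n_taxa) if taxa is None else [
        matrix.taxon_index(t) for t in taxa
    ]
    cells = [
        matrix.cells[ti][char_index]
        for ti in rows
        if not matrix.is_missing(ti, char_index)
    ]
    if not cells:
        return 0
    best = 0
    for s in matrix.characters[char_index].state_alphabet:
        best = max(best, sum(1 for c in cells if s in c))
    return len(cells) - best


# ---------------------------------------------------------------------------
# Sankoff DP (ordered characters, constrained scoring, MPR interrogation)
# ---------------------------------------------------------------------------

def _cost_matrix(char) -> np.ndarray:
    k = len(char.state_alphabet)
    idx = np.arange(k)
    if char.ordered:
        return np.abs(idx[:, None] - idx[None, :]).astype(float)
    return (idx[:, None] != idx[None, :]).astype(float)


def _sankoff_down(tree: PhyloTree, matrix: CharacterMatrix, char_index: int,
                  constraints: dict[int, frozenset[str]] | None = None):
    """Per-node minimal-cost vectors over states, rootward pass.

    Returns (down, contrib, cost) where contrib[child_id][s] is the child's
    term inside its parent's vector given parent state s.
    """
    char = matrix.characters[char_index]
    k = len(char.state_alphabet)
    pos = {s: i for i, s in enumerate(char.state_alphabet)}
    cost = _cost_matrix(char)
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    down: dict[int, np.ndarray] = {}
    contrib: dict[int, np.ndarray] = {}

    def constraint_vec(node: TreeNode) -> np.ndarray | None:
        if constraints and node.id in constraints:
            allowed = constraints[node.id]
            v = np.full(k, float(_INF))
            for s in allowed:
                v[pos[s]] = 0.0
            return v
        return None

    for node in tree.postorder():
        if node.is_leaf:
            cell = matrix.cells[taxon_row[node.label]][char_index]
            v = np.full(k, float(_INF))
            for s in cell:
                v[pos[s]] = 0.0
        else:
            v = np.zeros(k)
            for c in node.children:
                ct = (cost + down[c.id][None, :]).min(axis=1)
                contrib[c.id] = ct
                v = v + ct
        cv = constraint_vec(node)
        if cv is not None:
            v = v + cv
        down[node.id] = v
    return down, contrib, cost


def _sankoff_tables(tree: PhyloTree, matrix: CharacterMatrix, char_index: int,
                    constraints: dict[int, frozenset[str]] | None = None):
    """Down, up-edge tables and global minimum for one character."""
    down, contrib, cost = _sankoff_down(tree, matrix, char_index, constraints)
    min_len = float(down[tree.root.id].min())
    # up_edge[c][s]: cost of everything outside subtree(c), parent in state s
    up_edge: dict[int, np.ndarray] = {}
    up: dict[int, np.ndarray] = {tree.root.id: np.zeros(len(down[tree.root.id]))}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        for c in node.children:
            ue = up[node.id] + (down[node.id] - contrib[c.id])
            up_edge[c.id] = ue
            up[c.id] = (ue[:, None] + cost).min(axis=0)
    return down, up_edge, cost, min_len


def constrained_length(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    constraints: dict[int, frozenset[str]] | None = None,
) -> tuple[float, np.ndarray]:
    """Tree length with optional per-node state constraints.

    ``constraints`` maps node ids to the set of state symbols the node may
    take for every character in which those symbols exist; characters where
    a constrained symbol set has no overlap with the character's alphabet
    leave the node free (used for ancestor hypotheses with missing data).
    Returns (total length, per-character lengths).
    """
    _check_tips(tree, matrix)
    per_char = np.zeros(matrix.n_characters)
    for ci in range(matrix.n_characters):
        cons_ci = None
        if constraints:
            cons_ci = {}
            for node_id, symbols in constraints.items():
                allowed = frozenset(symbols) & set(
                    matrix.characters[ci].state_alphabet
                )
                if allowed:
                    cons_ci[node_id] = allowed
        down, _, _ = _sankoff_down(tree, matrix, ci, cons_ci or None)
        per_char[ci] = down[tree.root.id].min() * matrix.characters[ci].weight
    return float(per_char.sum()), per_char


# ---------------------------------------------------------------------------
# scoring and ensemble statistics
# ---------------------------------------------------------------------------

@dataclass
class TreeStatistics:
    """Tree length, per-character steps and ensemble fit indices."""

    length: float
    per_character_steps: np.ndarray
    ci: float | None = None
    ri: float | None = None
    rc: float | None = None
    hi: float | None = None
    includes_uninformative: bool = True

    def __post_init__(self) -> None:
        if self.ci is not None:
            assert 0 < self.ci <= 1 + 1e-12
            self.hi = 1.0 - self.ci
            if self.ri is not None:
                self.rc = self.ci * self.ri


def fitch_score(tree: PhyloTree, matrix: CharacterMatrix) -> TreeStatistics:
    """Minimum steps per character and total tree length.

    Unordered characters are scored by the Fitch/Hartigan downpass; ordered
    characters by linear-cost DP. Taxa fully missing for a character never
    add steps.
    """
    _check_tips(tree, matrix)
    work_tree = tree  # matrix may cover more taxa than the tree; only tips matter
    cols_u = [i for i, c in enumerate(matrix.characters) if not c.ordered]
    cols_o = [i for i, c in enumerate(matrix.characters) if c.ordered]
    per = np.zeros(matrix.n_characters)
    if cols_u:
        masks = _leaf_masks(work_tree, matrix, cols_u)
        steps, _ = _hartigan_steps(work_tree, masks, len(cols_u))
        for j, ci in enumerate(cols_u):
            per[ci] = steps[j]
    for ci in cols_o:
        down, _, _ = _sankoff_down(work_tree, matrix, ci)
        per[ci] = down[work_tree.root.id].min()
    weights = np.array([c.weight for c in matrix.characters])
    return TreeStatistics(length=float((per * weights).sum()),
                          per_character_steps=per)


def tree_statistics(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    include_uninformative: bool = True,
) -> TreeStatistics:
    """Ensemble CI, RI, RC and HI of a matrix on a tree.

    ``include_uninformative`` keeps constant/autapomorphic characters in the
    CI sums (the TNT reporting convention); set False to restrict all sums
    to parsimony-informative characters. Characters whose maximum equals
    their minimum conceivable steps are always excluded from the RI sums,
    where they would be 0/0.
    """
    base = fitch_score(tree, matrix)
    tips = tree.leaf_labels
    n = matrix.n_characters
    m = np.array([character_min_steps(matrix, i, tips) for i in range(n)], float)
    g = np.array([character_max_steps(matrix, i, tips) for i in range(n)], float)
    s = base.per_character_steps.astype(float)
    informative = g > m
    keep_ci = np.ones(n, bool) if include_uninformative else informative
    S, M = s[keep_ci].sum(), m[keep_ci].sum()
    if S <= 0:
        raise UndefinedStatisticsError(
            "tree length is zero; ensemble indices undefined"
        )
    ci = M / S
    G_, S_, M_ = g[informative].sum(), s[informative].sum(), m[informative].sum()
    ri = (G_ - S_) / (G_ - M_) if G_ > M_ else None
    stats = TreeStatistics(
        length=base.length,
        per_character_steps=base.per_character_steps,
        ci=ci,
        ri=ri,
        includes_uninformative=include_uninformative,
    )
    return stats


# ---------------------------------------------------------------------------
# tree manipulation primitives for search
# ---------------------------------------------------------------------------

def _attachment_points(tree: PhyloTree) -> list[TreeNode]:
    """Every node defines the edge above it; the root defines a new-root edge."""
    return list(tree.preorder())


def _insert_leaf_above(tree: PhyloTree, node: TreeNode, leaf: TreeNode) -> None:
    new = _fresh_node()
    parent = node.parent
    new.children = [node, leaf]
    node.parent = new
    leaf.parent = new
    if parent is None:
        tree.root = new
    else:
        parent.children[parent.children.index(node)] = new
        new.parent = parent


def _detach_leaf(tree: PhyloTree, leaf: TreeNode) -> None:
    parent = leaf.parent
    assert parent is not None
    parent.children.remove(leaf)
    leaf.parent = None
    _suppress_unary(tree, parent)


def _detach_subtree(tree: PhyloTree, node: TreeNode) -> None:
    parent = node.parent
    assert parent is not None
    parent.children.remove(node)
    node.parent = None
    _suppress_unary(tree, parent)


def _suppress_unary(tree: PhyloTree, node: TreeNode) -> None:
    if len(node.children) != 1:
        return
    only = node.children[0]
    gp = node.parent
    only.parent = gp
    if gp is None:
        tree.root = only
    else:
        gp.children[gp.children.index(node)] = only
    node.children = []
    node.parent = None


def _reroot_standalone(node: TreeNode, new_top: TreeNode) -> TreeNode:
    """Reroot a detached subtree so the edge above ``new_top`` holds the root."""
    if new_top is node:
        return node
    parent = new_top.parent
    assert parent is not None
    parent.children.remove(new_top)
    path = []
    walk: TreeNode | None = parent
    while walk is not None:
        path.append(walk)
        walk = walk.parent
    for i in range(len(path) - 1):
        child, par = path[i], path[i + 1]
        par.children.remove(child)
        child.children.append(par)
        par.parent = child
    # suppress any unary nodes introduced along the inverted path
    def fix(n: TreeNode) -> TreeNode:
        while len(n.children) == 1:
            n = n.children[0]
        n.children = [fix(c) for c in n.children]
        for c in n.children:
            c.parent = n
        return n

    other = fix(parent)
    root = _fresh_node()
    new_top.parent = root
    other.parent = root
    root.children = [new_top, other]
    return root


def _canonical(tree: PhyloTree) -> PhyloTree:
    t = tree.copy()
    t.renumber()
    return t


def _tree_key(tree: PhyloTree) -> frozenset:
    return frozenset(tree.bipartitions()) | frozenset(
        [frozenset(tree.leaf_labels)]
    )


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

def branch_and_bound(
    matrix: CharacterMatrix, max_taxa: int = 12
) -> tuple[list[PhyloTree], float]:
    """All minimum-length trees by exhaustive stepwise enumeration with a
    monotone length bound. Deterministic; guarded at ``max_taxa`` tips."""
    taxa = list(matrix.taxa)
    if len(taxa) > max_taxa:
        raise ValueError(
            f"{len(taxa)} taxa exceeds the exact-search guard of {max_taxa}; "
            "use heuristic_search"
        )
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(taxa) <= 3:
        tree = PhyloTree.from_nested(tuple(taxa) if len(taxa) > 1 else taxa[0])
        tree.renumber()
        return [tree], fitch_score(tree, matrix).length

    def score(tree: PhyloTree) -> float:
        return fitch_score(tree, matrix).length

    # greedy incumbent for the bound
    greedy = _stepwise_addition(matrix, taxa, rng=None)
    best_len = score(greedy)
    best: dict[frozenset, PhyloTree] = {}

    base = PhyloTree.from_nested((taxa[0], (taxa[1], taxa[2])))
    base.renumber()

    def recurse(tree: PhyloTree, next_i: int) -> None:
        nonlocal best_len
        cur = score(tree)
        if cur > best_len:
            return
        if next_i == len(taxa):
            if cur < best_len:
                best_len = cur
                best.clear()
            best.setdefault(_tree_key(tree), _canonical(tree))
            return
        leaf_label = taxa[next_i]
        for node in list(tree.preorder()):
            leaf = _fresh_node(normalize_label(leaf_label))
            _insert_leaf_above(tree, node, leaf)
            recurse(tree, next_i + 1)
            _detach_leaf(tree, leaf)
        return

    recurse(base, 3)
    return list(best.values()), best_len


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    """Heuristic search settings; the seed is mandatory and echoed in results."""

    replicates: int = 100
    operator: str = "tbr"  # one of nni, spr, tbr
    seed: int = 1
    max_trees: int = 100

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.operator not in ("nni", "spr", "tbr"):
            raise ValueError(f"unknown operator {self.operator!r}")


@dataclass
class SearchResult:
    best_trees: list[PhyloTree]
    best_length: float
    statistics: list[TreeStatistics]
    strict_consensus: PhyloTree
    multiple_optima: bool
    config: SearchConfig


def _stepwise_addition(
    matrix: CharacterMatrix, order: Sequence[str], rng: np.random.Generator | None
) -> PhyloTree:
    order = list(order)
    tree = PhyloTree.from_nested((order[0], (order[1], order[2])))
    tree.renumber()
    for label in order[3:]:
        best_len = None
        best_nodes: list[TreeNode] = []
        for node in list(tree.preorder()):
            leaf = _fresh_node(normalize_label(label))
            _insert_leaf_above(tree, node, leaf)
            ln = fitch_score(tree, matrix).length
            _detach_leaf(tree, leaf)
            if best_len is None or ln < best_len:
                best_len, best_nodes = ln, [node]
            elif ln == best_len:
                best_nodes.append(node)
        pick = best_nodes[0] if rng is None else best_nodes[
            int(rng.integers(len(best_nodes)))
        ]
        _insert_leaf_above(tree, pick, _fresh_node(normalize_label(label)))
    tree.renumber()
    return tree


def _spr_neighbors(tree: PhyloTree, tbr: bool = False):
    """Yield neighbour trees under subtree pruning-regrafting (optionally with
    reconnection rerooting of the pruned part, i.e. TBR)."""
    nodes = [n for n in tree.preorder() if n.parent is not None]
    for i, _ in enumerate(nodes):
        work = _canonical(tree)
        work_nodes = [n for n in work.preorder() if n.parent is not None]
        sub = work_nodes[i]
        if len(work.leaves()) - sum(1 for _ in _iter_leaves(sub)) < 2:
            continue
        _detach_subtree(work, sub)
        sub_roots = [sub]
        if tbr and not sub.is_leaf:
            for j, _ in enumerate(list(_iter_nodes(sub))[1:]):
                sub_copy = _copy_standalone(sub)
                inner = list(_iter_nodes(sub_copy))[1:][j]
                sub_roots.append(_reroot_standalone(sub_copy, inner))
        for sr in sub_roots:
            for target in list(work.preorder()):
                candidate = _canonical(work)
                t_nodes = list(candidate.preorder())
                target_c = t_nodes[list(work.preorder()).index(target)]
                _insert_leaf_above(candidate, target_c, _copy_standalone(sr))
                candidate.renumber()
                yield candidate


def _iter_nodes(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def _iter_leaves(node: TreeNode):
    return (n for n in _iter_nodes(node) if n.is_leaf)


def _copy_standalone(node: TreeNode) -> TreeNode:
    c = TreeNode(node.id, node.label, None, [], node.age)
    c.children = [_copy_standalone(ch) for ch in node.children]
    for ch in c.children:
        ch.parent = c
    return c


def _nni_neighbors(tree: PhyloTree):
    """Nearest-neighbour interchanges around every internal edge."""
    for node in list(tree.preorder()):
        if node.is_leaf or node.parent is None:
            continue
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        for sib in siblings:
            for child in node.children:
                work = _canonical(tree)
                nodes = list(tree.preorder())
                wnodes = list(work.preorder())
                w_node = wnodes[nodes.index(node)]
                w_sib = wnodes[nodes.index(sib)]
                w_child = wnodes[nodes.index(child)]
                w_parent = w_node.parent
                w_parent.children[w_parent.children.index(w_sib)] = w_child
                w_node.children[w_node.children.index(w_child)] = w_sib
                w_child.parent, w_sib.parent = w_parent, w_node
                work.renumber()
                yield work


def _hill_climb(
    tree: PhyloTree, matrix: CharacterMatrix, operator: str
) -> tuple[PhyloTree, float]:
    current = _canonical(tree)
    cur_len = fitch_score(current, matrix).length
    improved = True
    while improved:
        improved = False
        if operator == "nni":
            neighbors = _nni_neighbors(current)
        else:
            neighbors = _spr_neighbors(current, tbr=(operator == "tbr"))
        for cand in neighbors:
            ln = fitch_score(cand, matrix).length
            if ln < cur_len:
                current, cur_len = cand, ln
                improved = True
                break
    return current, cur_len


def heuristic_search(
    matrix: CharacterMatrix, config: SearchConfig | None = None
) -> SearchResult:
    """Random-addition-sequence + rearrangement search for shortest trees.

    Reproducible for a given seed; all optima found are retained (up to
    ``max_trees``, deduplicated by unrooted topology) together with the
    strict consensus.
    """
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed)
    best_len: float | None = None
    best: dict[frozenset, PhyloTree] = {}
    for _ in range(config.replicates):
        order = [matrix.taxa[i] for i in rng.permutation(matrix.n_taxa)]
        tree = _stepwise_addition(matrix, order, rng)
        tree, ln = _hill_climb(tree, matrix, config.operator)
        if best_len is None or ln < best_len:
            best_len, best = ln, {_tree_key(tree): tree}
        elif ln == best_len and len(best) < config.max_trees:
            best.setdefault(_tree_key(tree), tree)
    trees = list(best.values())
    stats = [tree_statistics(t, matrix) for t in trees]
    consensus = strict_consensus(trees)
    return SearchResult(
        best_trees=trees,
        best_length=float(best_len),
        statistics=stats,
        strict_consensus=consensus,
        multiple_optima=len(trees) > 1,
        config=config,
    )


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Strict consensus of rooted trees over the same tips (shared clades)."""
    if not trees:
        raise ValueError("no trees")
    tips = frozenset(trees[0].leaf_labels)
    if any(frozenset(t.leaf_labels) != tips for t in trees):
        raise TreeError("consensus requires identical tip sets")
    common = set.intersection(*(set(t.clades()) for t in trees))
    common = {c for c in common if len(c) > 1}
    # nest clades: parent of each clade is the smallest strict superset
    ordered = sorted(common | {tips}, key=len, reverse=True)
    nodes: dict[frozenset[str], TreeNode] = {
        c: _fresh_node() for c in ordered
    }
    for c in ordered[1:]:
        parent = min(
            (p for p in ordered if len(p) > len(c) and c < p), key=len
        )
        nodes[c].parent = nodes[parent]
        nodes[parent].children.append(nodes[c])
    for tip in sorted(tips):
        hosts = [c for c in ordered if tip in c]
        host = min(hosts, key=len)
        leaf = _fresh_node(tip)
        leaf.parent = nodes[host]
        nodes[host].children.append(leaf)
    out = PhyloTree(nodes[tips])
    out.renumber()
    return out


# ---------------------------------------------------------------------------
# ACCTRAN optimisation and synapomorphy mapping
# ---------------------------------------------------------------------------

@dataclass
class ChangeRecord:
    """One state change on the branch above ``node`` (ACCTRAN placement)."""

    node_id: int
    char_index: int
    from_state: str
    to_state: str
    steps: float = 1.0


@dataclass
class SynapomorphyRecord:
    node_id: int
    char_index: int
    from_state: str
    to_state: str
    ambiguity: str = "unambiguous"  # or "ambiguous"


def acctran_optimize(
    tree: PhyloTree, matrix: CharacterMatrix
) -> tuple[dict[int, list[str]], list[ChangeRecord]]:
    """ACCTRAN ancestral states and the implied change list.

    States are resolved by retaining the parental state wherever the Fitch
    downpass set allows it and otherwise taking the lexicographically
    smallest admissible state (ties at the root likewise), which places
    changes as rootward as the optimum permits. The summed steps of the
    change list always equal the tree length.
    """
    if tree.root.children and not tree.is_binary():
        raise TreeError("ACCTRAN optimisation requires a binary tree")
    _check_tips(tree, matrix)
    states: dict[int, list[str]] = {n.id: [] for n in tree.preorder()}
    changes: list[ChangeRecord] = []
    for ci, char in enumerate(matrix.characters):
        if char.ordered:
            _acctran_ordered(tree, matrix, ci, states, changes)
            continue
        masks = _leaf_masks(tree, matrix, [ci])
        _, down = _hartigan_steps(tree, masks, 1)
        alphabet = char.state_alphabet

        def lowest(mask: int) -> int:
            return (mask & -mask).bit_length() - 1

        for node in tree.preorder():
            d = int(down[node.id][0])
            if node.parent is None:
                b = lowest(d)
            else:
                pb = alphabet.index(states[node.parent.id][ci])
                if d >> pb & 1:
                    b = pb
                else:
                    b = lowest(d)
                    changes.append(
                        ChangeRecord(node.id, ci, alphabet[pb], alphabet[b], 1.0)
                    )
            states[node.id].append(alphabet[b])
    return states, changes


def _acctran_ordered(tree, matrix, ci, states, changes) -> None:
    char = matrix.characters[ci]
    down, _, cost = _sankoff_down(tree, matrix, ci)
    for node in tree.preorder():
        v = down[node.id]
        if node.parent is None:
            b = int(np.argmin(v))
        else:
            pb = char.state_alphabet.index(states[node.parent.id][ci])
            totals = v + cost[pb]
            best = totals.min()
            if totals[pb] == best:
                b = pb
            else:
                b = int(np.argmin(totals))
                changes.append(
                    ChangeRecord(
                        node.id, ci, char.state_alphabet[pb],
                        char.state_alphabet[b], float(cost[pb, b]),
                    )
                )
        states[node.id].append(char.state_alphabet[b])


def classify_synapomorphy(
    node_id: int, char_index: int, tree: PhyloTree, matrix: CharacterMatrix,
    changes: list[ChangeRecord] | None = None,
) -> str:
    """'unambiguous' when the branch above ``node_id`` changes state in every
    most-parsimonious reconstruction of the character; 'ambiguous' otherwise."""
    node = next((n for n in tree.preorder() if n.id == node_id), None)
    if node is None or node.parent is None:
        raise NoSynapomorphyError(f"node {node_id} is missing or is the root")
    if changes is None:
        _, changes = acctran_optimize(tree, matrix)
    if not any(
        c.node_id == node_id and c.char_index == char_index for c in changes
    ):
        raise NoSynapomorphyError(
            f"no ACCTRAN change at node {node_id} for character {char_index}"
        )
    down, up_edge, cost, min_len = _sankoff_tables(tree, matrix, char_index)
    same = up_edge[node.id] + down[node.id]  # parent state == child state
    forced = float(same.min()) > min_len + 1e-9
    return "unambiguous" if forced else "ambiguous"


def synapomorphy_table(
    tree: PhyloTree, matrix: CharacterMatrix
) -> list[SynapomorphyRecord]:
    """ACCTRAN changes at internal nodes, classified by MPR ambiguity."""
    _, changes = acctran_optimize(tree, matrix)
    internal = {n.id for n in tree.internal_nodes()}
    out = []
    for ch in changes:
        if ch.node_id not in internal:
            continue
        amb = classify_synapomorphy(
            ch.node_id, ch.char_index, tree, matrix, changes
        )
        out.append(
            SynapomorphyRecord(
                ch.node_id, ch.char_index, ch.from_state, ch.to_state, amb
            )
        )
    return out
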