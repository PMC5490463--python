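"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's Fitch/Sankoff machinery:
parsimony lengths are recomputed by exhaustive enumeration over all
internal-node state assignments, so they stay valid however the library
implementation changes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from paleophylo.matrix_io import CharacterMatrix, PhyloTree


def brute_force_length(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    constraints: dict[int, frozenset[str]] | None = None,
) -> float:
    """Exhaustive-enumeration parsimony length (any cost model, tiny trees).

    Enumerates every assignment of states to internal nodes; leaf cells are
    resolved optimally per edge. Supports per-node state constraints and
    both unordered and linear ordered costs.
    """
    total = 0.0
    internals = tree.internal_nodes(include_root=True)
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    for ci, char in enumerate(matrix.characters):
        alpha = char.state_alphabet
        pos = {s: i for i, s in enumerate(alpha)}

        def cost(a: int, b: int) -> float:
            return abs(a - b) if char.ordered else float(a != b)

        best = None
        choices = []
        for node in internals:
            if constraints and node.id in constraints:
                allowed = [
                    pos[s] for s in constraints[node.id] if s in pos
                ] or list(range(len(alpha)))
            else:
                allowed = list(range(len(alpha)))
            choices.append(allowed)
        for assign in itertools.product(*choices):
            states = {n.id: a for n, a in zip(internals, assign)}
            length = 0.0
            for node in tree.preorder():
                if node.parent is None:
                    continue
                ps = states[node.parent.id]
                if node.is_leaf:
                    cell = matrix.cells[taxon_row[node.label]][ci]
                    length += min(cost(ps, pos[s]) for s in cell)
                else:
                    length += cost(ps, states[node.id])
            if best is None or length < best:
                best = length
        total += best * char.weight
    return total


def random_matrix(
    rng: np.random.Generator,
    taxa: list[str],
    n_chars: int,
    n_states: int = 2,
    missing_prob: float = 0.0,
) -> CharacterMatrix:
    """Uniform random matrix, optionally with missing cells."""
    from paleophylo.matrix_io import CharacterDef

    symbols = tuple(str(i) for i in range(n_states))
    chars = [CharacterDef(i, symbols) for i in range(n_chars)]
    cells = []
    for _ in taxa:
        row = []
        for _ in range(n_chars):
            if missing_prob and rng.random() < missing_prob:
                row.append(frozenset(symbols))
            else:
                row.append(frozenset([symbols[int(rng.integers(n_states))]]))
        cells.append(row)
    return CharacterMatrix(taxa, chars, cells)


def random_topology(rng: np.random.Generator, taxa: list[str]) -> PhyloTree:
    """Uniform-ish random rooted binary tree by sequential attachment."""
    from paleophylo.parsimony_core import _fresh_node, _insert_leaf_above

    tree = PhyloTree.from_nested((taxa[0], taxa[1]))
    tree.renumber()
    for label in taxa[2:]:
        nodes = list(tree.preorder())
        target = nodes[int(rng.integers(len(nodes)))]
        _insert_leaf_above(tree, target, _fresh_node(label))
    tree.renumber()
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
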