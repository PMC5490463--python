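"""Homoplasy screening of candidate characters against reference trees.

A character's fit to a tree is summarised by its per-character consistency
index, CI = m / s, where m is the minimum conceivable number of steps
(observed states minus one) and s the steps the tree actually requires.
CI = 1 means the character changes exactly as often as its states demand
(homology); CI < 1 means extra, convergent or reversed, changes (homoplasy).
Screening maps every candidate character onto one or more published
reference topologies and excludes those whose CI falls below a threshold on
any of them. Characters that cannot be scored on a tree (constant over the
shared taxa, or no shared data at all) are retained with a flag: absence of
evidence of homoplasy is not evidence of homoplasy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .matrix_io import CharacterMatrix, PhyloTree
from .parsimony_core import character_min_steps, fitch_score

__all__ = [
    "CharacterScreenReport",
    "CoverageError",
    "per_character_ci",
    "screen_characters",
]


class CoverageError(ValueError):
    """A reference tree shares no scoreable taxa with the matrix."""


@dataclass
class CharacterScreenReport:
    """Audit of a screening run: one row per (character, reference tree)."""

    table: pd.DataFrame  # columns: character, tree, steps, min_steps, ci, verdict
    retained: list[int]
    excluded: list[int]
    threshold: float


def per_character_ci(
    tree: PhyloTree, matrix: CharacterMatrix
) -> list[float | None]:
    """CI of every character on the tree; None for constant characters
    (0/0 is undefined and such characters carry no screening signal)."""
    steps = fitch_score(tree, matrix).per_character_steps
    out: list[float | None] = []
    for ci_idx in range(matrix.n_characters):
        m = character_min_steps(matrix, ci_idx, tree.leaf_labels)
        if m == 0:
            out.append(None)
        else:
            out.append(m / steps[ci_idx])
    return out


def screen_characters(
    matrix: CharacterMatrix,
    reference_trees: Sequence[PhyloTree],
    threshold: float = 1.0,
    rule: str = "any",
) -> tuple[CharacterScreenReport, CharacterMatrix]:
    """Exclude characters whose CI falls below ``threshold`` on reference trees.

    ``rule='any'`` (default) excludes on failure against any single tree;
    ``rule='all'`` requires failure on every tree. Each tree is evaluated on
    the taxa it shares with the matrix. Returns the audit report and the
    retained-character submatrix. Deterministic and order-independent in the
    reference-tree list.
    """
    if rule not in ("any", "all"):
        raise ValueError(f"unknown combination rule {rule!r}")
    rows = []
    fails: dict[int, int] = {i: 0 for i in range(matrix.n_characters)}
    scoreable: dict[int, int] = {i: 0 for i in range(matrix.n_characters)}
    for t_id, tree in enumerate(reference_trees):
        shared = sorted(set(tree.leaf_labels) & set(matrix.taxa))
        if not shared:
            raise CoverageError(
                f"reference tree {t_id} shares no taxa with the matrix"
            )
        sub_tree = tree.prune_to(shared)
        sub_matrix = matrix.subset_taxa(shared)
        cis = per_character_ci(sub_tree, sub_matrix)
        steps = fitch_score(sub_tree, sub_matrix).per_character_steps
        for char_i, ci_val in enumerate(cis):
            if ci_val is None:
                verdict = "unscorable"
            else:
                scoreable[char_i] += 1
                if ci_val < threshold:
                    fails[char_i] += 1
                    verdict = "fail"
                else:
                    verdict = "pass"
            rows.append(
                {
                    "character": char_i,
                    "tree": t_id,
                    "steps": float(steps[char_i]),
                    "min_steps": character_min_steps(
                        sub_matrix, char_i, sub_tree.leaf_labels
                    ),
                    "ci": ci_val,
                    "verdict": verdict,
                }
            )
    excluded = []
    for char_i in range(matrix.n_characters):
        if scoreable[char_i] == 0:
            continue  # retained with unscorable flag in the table
        if rule == "any" and fails[char_i] > 0:
            excluded.append(char_i)
        elif rule == "all" and fails[char_i] == scoreable[char_i] > 0:
            excluded.append(char_i)
    retained = [i for i in range(matrix.n_characters) if i not in excluded]
    report = CharacterScreenReport(
        table=pd.DataFrame(rows),
        retained=retained,
        excluded=excluded,
        threshold=threshold,
    )
    return report, matrix.subset_characters(retained)
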