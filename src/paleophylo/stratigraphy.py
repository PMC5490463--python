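"""Stratigraphic congruence (SCI), ghost lineages, minimum divergence dates.

Fossil taxa carry a first-appearance datum (FAD) and last-appearance datum
(LAD) in Ma. On a rooted tree, the stratigraphic consistency index of
Huelsenbeck compares every internal node's oldest descendant fossil with
that of its sister: the node is consistent when its clade's oldest record
is not older than the sister clade's. SCI = consistent / evaluated nodes,
where the evaluated set is the internal nodes excluding the root (n - 2
nodes for n tips on a binary rooted tree, matching the published
"OTUs minus 2" convention). Ties (equal FADs, common under stage-level age
resolution) count as consistent.

Minimum divergence dating takes each node's age as its clade's oldest FAD;
the ghost lineage on a branch is the parent's minimum age minus the child
clade's FAD — fossil-record gaps the topology forces us to infer.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

from .matrix_io import PhyloTree, TreeNode, normalize_label

__all__ = [
    "StratRangeTable",
    "SciResult",
    "NodeVerdict",
    "DivergenceEstimate",
    "UndatableNodeError",
    "read_ranges",
    "clade_fad",
    "sci",
    "min_divergence_dates",
]

logger = logging.getLogger(__name__)


class UndatableNodeError(ValueError):
    """No dated tip below a node that must be dated."""


class StratRangeTable:
    """Per-taxon stratigraphic ranges: FAD >= LAD >= 0, in Ma."""

    def __init__(self, ranges: dict[str, tuple[float, float]]) -> None:
        self._ranges: dict[str, tuple[float, float]] = {}
        for taxon, (fad, lad) in ranges.items():
            taxon = normalize_label(taxon)
            if taxon in self._ranges:
                raise ValueError(f"duplicate taxon {taxon!r}")
            if not (fad >= lad >= 0):
                raise ValueError(
                    f"taxon {taxon!r}: require FAD >= LAD >= 0, got "
                    f"({fad}, {lad})"
                )
            self._ranges[taxon] = (float(fad), float(lad))

    @property
    def taxa(self) -> list[str]:
        return list(self._ranges)

    def __contains__(self, taxon: str) -> bool:
        return normalize_label(taxon) in self._ranges

    def fad(self, taxon: str) -> float:
        return self._ranges[normalize_label(taxon)][0]

    def lad(self, taxon: str) -> float:
        return self._ranges[normalize_label(taxon)][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"taxon": t, "fad_ma": f, "lad_ma": l}
                for t, (f, l) in self._ranges.items()
            ]
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def read_ranges(source) -> StratRangeTable:
    """Read a tab-separated table with columns taxon, fad_ma, lad_ma."""
    if hasattr(source, "read"):
        df = pd.read_csv(source, sep="\t")
    else:
        df = pd.read_csv(io.StringIO(str(source)), sep="\t")
    required = {"taxon", "fad_ma", "lad_ma"}
    if not required <= set(df.columns):
        raise ValueError(f"range table needs columns {sorted(required)}")
    return StratRangeTable(
        {r.taxon: (r.fad_ma, r.lad_ma) for r in df.itertuples()}
    )


# ---------------------------------------------------------------------------

def _tips_below(tree: PhyloTree) -> dict[int, list[str]]:
    below: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node.id] = [node.label]  # type: ignore[list-item]
        else:
            below[node.id] = [t for c in node.children for t in below[c.id]]
    return below


def clade_fad(
    node: TreeNode, tree: PhyloTree, ranges: StratRangeTable
) -> float:
    """Oldest first appearance among the tips descending from ``node``."""
    tips = [n.label for n in _iter_leaves(node)]
    dated = [ranges.fad(t) for t in tips if t in ranges]
    if not dated:
        raise UndatableNodeError(
            f"no dated tip below node {node.id} (tips: {tips})"
        )
    return max(dated)


def _iter_leaves(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


@dataclass
class NodeVerdict:
    node_id: int
    clade_fad: float
    sister_fad: float
    consistent: bool


@dataclass
class SciResult:
    consistent_nodes: int
    evaluated_nodes: int
    value: float
    verdicts: list[NodeVerdict] = field(default_factory=list)


def _prune_undated(tree: PhyloTree, ranges: StratRangeTable) -> PhyloTree:
    dated = [t for t in tree.leaf_labels if t in ranges]
    undated = sorted(set(tree.leaf_labels) - set(dated))
    if undated:
        logger.warning("pruning %d undated taxa before SCI: %s",
                       len(undated), undated)
    if len(dated) < 3:
        raise UndatableNodeError("fewer than 3 dated tips; SCI undefined")
    return tree.prune_to(dated) if undated else tree


def sci(tree: PhyloTree, ranges: StratRangeTable) -> SciResult:
    """Stratigraphic consistency index of a rooted tree.

    A non-root internal node is consistent when its clade's oldest FAD is
    not older than its sister group's oldest FAD (ties consistent). The
    denominator is the number of non-root internal nodes, the published
    n - 2 convention for binary rooted trees of n tips.
    """
    tree = _prune_undated(tree, ranges)
    fads: dict[int, float] = {}
    below = _tips_below(tree)
    for node in tree.postorder():
        dated = [ranges.fad(t) for t in below[node.id] if t in ranges]
        fads[node.id] = max(dated)
    verdicts: list[NodeVerdict] = []
    for node in tree.internal_nodes(include_root=False):
        parent = node.parent
        sisters = [c for c in parent.children if c is not node]
        sister_fad = max(fads[s.id] for s in sisters)
        verdicts.append(
            NodeVerdict(
                node_id=node.id,
                clade_fad=fads[node.id],
                sister_fad=sister_fad,
                consistent=fads[node.id] <= sister_fad + 1e-12,
            )
        )
    consistent = sum(v.consistent for v in verdicts)
    evaluated = len(verdicts)
    if evaluated == 0:
        raise UndatableNodeError("no evaluable internal nodes")
    return SciResult(
        consistent_nodes=consistent,
        evaluated_nodes=evaluated,
        value=consistent / evaluated,
        verdicts=verdicts,
    )


@dataclass
class DivergenceEstimate:
    """Fossil-constrained minimum node ages and per-branch ghost lineages."""

    node_ages: dict[int, float]  # internal node id -> minimum age (Ma)
    ghost_durations: dict[int, float]  # child node id -> Myr of ghost lineage
    table: pd.DataFrame

    @property
    def total_ghost(self) -> float:
        return float(sum(self.ghost_durations.values()))


def min_divergence_dates(
    tree: PhyloTree, ranges: StratRangeTable
) -> DivergenceEstimate:
    """Date every internal node at its clade's oldest FAD.

    The ghost lineage on the branch to a child is the parent's minimum age
    minus the child clade's oldest FAD; it is zero for the child that
    carries the oldest record.
    """
    tree = _prune_undated(tree, ranges)
    below = _tips_below(tree)
    fads: dict[int, float] = {}
    for node in tree.postorder():
        fads[node.id] = max(ranges.fad(t) for t in below[node.id] if t in ranges)
    node_ages = {
        n.id: fads[n.id] for n in tree.internal_nodes(include_root=True)
    }
    ghosts: dict[int, float] = {}
    rows = []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        for child in node.children:
            ghosts[child.id] = node_ages[node.id] - fads[child.id]
        rows.append(
            {
                "node": node.id,
                "min_age_ma": node_ages[node.id],
                "tips": ",".join(sorted(below[node.id])),
            }
        )
    return DivergenceEstimate(
        node_ages=node_ages,
        ghost_durations=ghosts,
        table=pd.DataFrame(rows),
    )
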