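"""Levene-gated recursive hierarchical clustering of projection vectors.

The dendrogram is built once over all usable neurons with average-linkage
agglomeration on the pairwise arccosine distances.  Starting from the root,
each node's neuron set is tested against a fresh swap-randomization of its
own submatrix (all columns, that node's rows): if the experimental pairwise
distance variance is significantly larger (one-tailed Levene), the node's
top bipartition is accepted and both subtrees are tested in turn.  Each
failure point is independent of the others; terminal nodes become the
projection classes, labeled A, B, ... in dendrogram left-to-right order
with the class size appended (A38 = leftmost class, 38 neurons).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .distance_stats import (
    EXPERIMENTAL,
    RANDOMIZED,
    LeveneResult,
    levene_one_tailed,
    pairwise_distances,
)
from .projection_null import SwapConfig, swap_randomize_counts
from .reconstruction_io import ProjectionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SplitConfig:
    """Gate parameters: significance level, minimum testable subtree, null chain."""

    alpha: float = 0.05
    min_subtree: int = 3
    swap_cfg: SwapConfig = field(default_factory=SwapConfig)
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_subtree < 2:
            raise ValueError("min_subtree must be >= 2")
        if self.linkage != "average":
            raise ValueError("only average linkage is supported")


@dataclass
class NodeRecord:
    """Per-dendrogram-node test record."""

    node_id: int
    neuron_ids: list[str]
    test: LeveneResult | None  # None when the subtree was too small to test
    is_class: bool
    label: str | None = None


@dataclass
class ClassTree:
    """Dendrogram plus per-node Levene records and terminal class assignments."""

    neuron_ids: list[str]  # usable (nonzero) neurons, clustering order
    linkage_matrix: np.ndarray
    nodes: dict[int, NodeRecord]
    classes: dict[str, list[str]]  # label -> neuron ids, dendrogram order
    unassigned: list[str] = field(default_factory=list)  # zero-count neurons

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_sizes(self) -> list[int]:
        return [len(v) for v in self.classes.values()]

    def assignments(self) -> dict[str, str]:
        return {nid: label for label, nids in self.classes.items() for nid in nids}

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.neuron_ids[node.id]}:{length:g}"
            left = walk(node.get_left(), node.dist)
            right = walk(node.get_right(), node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def average_linkage_tree(distance_matrix: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA-style) agglomeration on a square distance matrix.

    Ties in merge height are broken deterministically (lowest candidate index
    first, as scipy's nearest-neighbor chain does).  Returns the scipy
    linkage matrix.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square distance matrix")
    if np.any(np.isnan(D)):
        raise ValueError("NaN distances")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    return hierarchy.linkage(squareform(D, checks=False), method="average")


def _pairwise_square(counts: np.ndarray) -> np.ndarray:
    rows = counts.astype(float)
    rows = rows / np.linalg.norm(rows, axis=1, keepdims=True)
    gram = np.clip(rows @ rows.T, -1.0, 1.0)
    D = np.degrees(np.arccos(gram))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def discover_classes(
    matrix: ProjectionMatrix, cfg: SplitConfig | None = None
) -> ClassTree:
    """Run the full recursive classification on a projection matrix.

    Zero-count neurons are set aside (their projection angle is undefined)
    and reported in ``ClassTree.unassigned``.  Every tested node draws a
    fresh, independently seeded randomization of its own submatrix so each
    test conditions on that subtree's marginals.
    """
    cfg = cfg or SplitConfig()
    usable = matrix.row_sums() > 0
    unassigned = [nid for nid, u in zip(matrix.neuron_ids, usable) if not u]
    if unassigned:
        logger.warning("zero-count neurons excluded from classification: %s", unassigned)
    ids = [nid for nid, u in zip(matrix.neuron_ids, usable) if u]
    counts = matrix.counts[usable]
    n = len(ids)
    if n < cfg.min_subtree:
        raise ValueError(f"need at least {cfg.min_subtree} usable neurons, got {n}")

    Z = average_linkage_tree(_pairwise_square(counts))
    root = hierarchy.to_tree(Z)

    seed = cfg.swap_cfg.seed
    seed_seq = (
        np.random.SeedSequence(seed) if not isinstance(seed, np.random.Generator) else None
    )

    nodes: dict[int, NodeRecord] = {}
    terminal_nodes: list[tuple[int, list[int]]] = []  # (node_id, leaf order ids)

    def node_rng():
        if seed_seq is not None:
            return np.random.default_rng(seed_seq.spawn(1)[0])
        return seed  # caller-provided Generator, consumed sequentially

    def visit(node) -> None:
        leaf_ids = node.pre_order(lambda leaf: leaf.id)
        neuron_ids = [ids[i] for i in leaf_ids]
        if node.is_leaf() or len(leaf_ids) < cfg.min_subtree:
            nodes[node.id] = NodeRecord(node.id, neuron_ids, test=None, is_class=True)
            terminal_nodes.append((node.id, leaf_ids))
            return
        sub = counts[leaf_ids]
        sub_cfg = SwapConfig(
            n_successful_swaps=cfg.swap_cfg.n_successful_swaps,
            seed=node_rng(),
            delta_rule=cfg.swap_cfg.delta_rule,
        )
        exp = pairwise_distances(sub, label=EXPERIMENTAL)
        rnd = pairwise_distances(swap_randomize_counts(sub, sub_cfg), label=RANDOMIZED)
        result = levene_one_tailed(exp, rnd, alpha=cfg.alpha)
        if result.decision == "split":
            nodes[node.id] = NodeRecord(node.id, neuron_ids, result, is_class=False)
            visit(node.get_left())
            visit(node.get_right())
        else:
            nodes[node.id] = NodeRecord(node.id, neuron_ids, result, is_class=True)
            terminal_nodes.append((node.id, leaf_ids))

    visit(root)

    # label classes left-to-right in dendrogram order
    leaf_order = root.pre_order(lambda leaf: leaf.id)
    position = {leaf: k for k, leaf in enumerate(leaf_order)}
    terminal_nodes.sort(key=lambda item: min(position[i] for i in item[1]))
    classes: dict[str, list[str]] = {}
    for letter, (node_id, leaf_ids) in zip(_letters(), terminal_nodes):
        ordered = sorted(leaf_ids, key=position.__getitem__)
        label = f"{letter}{len(ordered)}"
        nodes[node_id].label = label
        classes[label] = [ids[i] for i in ordered]

    return ClassTree(
        neuron_ids=ids,
        linkage_matrix=Z,
        nodes=nodes,
        classes=classes,
        unassigned=unassigned,
    )


def _letters():
    for c in string.ascii_uppercase:
        yield c
    for c1 in string.ascii_uppercase:
        for c2 in string.ascii_uppercase:
            yield c1 + c2
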