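"""Model/Results front end for projection classification.

``ProjectionClassModel`` wraps a projection count matrix the way a
statsmodels model wraps its design matrix; ``fit`` runs the Levene-gated
recursive clustering and returns a ``ClassificationResults`` carrying the
class assignments, the per-node variance tests and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .class_discovery import ClassTree, SplitConfig, discover_classes
from .distance_stats import pairwise_distances
from .projection_null import SwapConfig
from .reconstruction_io import ProjectionMatrix


class ProjectionClassModel:
    """Discover statistically distinct projection classes from axonal counts.

    Parameters
    ----------
    matrix
        Neurons x (parcel, hemisphere) axonal point counts.
    alpha
        Significance level of the one-tailed Levene split gate.
    min_subtree
        Smallest subtree that can still be variance-tested (smaller subtrees
        terminate as classes).
    n_swaps
        Successful swaps per randomization; default 20x nonzero cells.
    """

    def __init__(
        self,
        matrix: ProjectionMatrix,
        alpha: float = 0.05,
        min_subtree: int = 3,
        n_swaps: int | None = None,
    ):
        self.matrix = matrix
        self.alpha = alpha
        self.min_subtree = min_subtree
        self.n_swaps = n_swaps

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ProjectionClassModel":
        """Build from a neurons x columns count DataFrame (columns "parcel|hemi")."""
        return cls(ProjectionMatrix.from_frame(frame), **kwargs)

    def fit(self, seed: int | None = None) -> "ClassificationResults":
        cfg = SplitConfig(
            alpha=self.alpha,
            min_subtree=self.min_subtree,
            swap_cfg=SwapConfig(n_successful_swaps=self.n_swaps, seed=seed),
        )
        tree = discover_classes(self.matrix, cfg)
        return ClassificationResults(self, tree, seed)


@dataclass
class ClassificationResults:
    """Fitted classification: class tree, assignments and diagnostics."""

    model: ProjectionClassModel
    tree: ClassTree
    seed: int | None

    @property
    def n_classes(self) -> int:
        return self.tree.n_classes

    @property
    def class_sizes(self) -> list[int]:
        return self.tree.class_sizes

    @property
    def labels(self) -> pd.Series:
        """Class label per neuron id (zero-count neurons get NaN)."""
        mapping = self.tree.assignments()
        return pd.Series(
            [mapping.get(nid) for nid in self.model.matrix.neuron_ids],
            index=self.model.matrix.neuron_ids,
            name="class",
        )

    def class_profile(self, label: str) -> np.ndarray:
        """Summed axonal counts of a class across columns (its signature)."""
        idx = {nid: i for i, nid in enumerate(self.model.matrix.neuron_ids)}
        rows = [idx[nid] for nid in self.tree.classes[label]]
        return self.model.matrix.counts[rows].sum(axis=0)

    def signature_matrix(self) -> np.ndarray:
        """Columns-of-matrix x classes raw signature counts (NNLS input)."""
        return np.column_stack(
            [self.class_profile(label) for label in self.tree.classes]
        )

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node in self.tree.nodes.values():
            t = node.test
            rows.append(
                {
                    "node_id": node.node_id,
                    "n_neurons": len(node.neuron_ids),
                    "var_experimental": t.var_experimental if t else np.nan,
                    "var_randomized": t.var_randomized if t else np.nan,
                    "levene_F": t.statistic if t else np.nan,
                    "p_one_tailed": (
                        t.p_one_tailed if t and t.p_one_tailed is not None else np.nan
                    ),
                    "decision": t.decision if t else "too-small",
                    "class": node.label if node.is_class else None,
                }
            )
        return pd.DataFrame(rows).sort_values("n_neurons", ascending=False)

    def summary(self) -> str:
        m = self.model.matrix
        exp_var = pairwise_distances(m).variance
        lines = [
            "Projection class discovery (Levene-gated average-linkage clustering)",
            "=" * 70,
            f"Neurons: {len(m.neuron_ids)}  Columns: {len(m.columns)}  "
            f"alpha: {self.model.alpha}  seed: {self.seed}",
            f"Pairwise distance variance (experimental, all neurons): {exp_var:.1f} deg^2",
            f"Classes found: {self.n_classes}",
            "",
            f"{'class':<8}{'size':>6}   members (first 6)",
            "-" * 70,
        ]
        for label, nids in self.tree.classes.items():
            preview = ", ".join(nids[:6]) + (", ..." if len(nids) > 6 else "")
            lines.append(f"{label:<8}{len(nids):>6}   {preview}")
        if self.tree.unassigned:
            lines.append(f"unassigned (zero counts): {self.tree.unassigned}")
        lines += ["", "Split tests (largest subtrees first):", "-" * 70]
        table = self.node_table()
        for _, row in table.head(12).iterrows():
            p = row["p_one_tailed"]
            if row["decision"] == "too-small":
                p_str = "-"
            elif np.isnan(p):
                p_str = "N/A"
            else:
                p_str = f"{p:.3g}"
            lines.append(
                f"n={int(row['n_neurons']):>4}  var(exp)={row['var_experimental']:>8.1f}"
                f"  var(rnd)={row['var_randomized']:>8.1f}  p={p_str:<9}"
                f" -> {row['decision']}"
            )
        return "\n".join(lines)

    def to_newick(self) -> str:
        return self.tree.to_newick()
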