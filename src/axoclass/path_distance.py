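"""Along-tree path distances and divergence/convergence rank tests.

For every axonal point in a target region the path distance is the summed
3-D Euclidean gaps along the unique tree path from the soma to that point —
the cable an action potential must travel, never less than the straight-line
distance.  Divergence asks whether one class reaches its different targets
at different path distances; convergence asks whether different classes
reach a shared target at different distances.  Both are tested pairwise with
the two-sample Mann-Whitney rank test on pooled per-point distances and
corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reconstruction_io import AXON, NeuronReconstruction

logger = logging.getLogger(__name__)


def path_distances_to_points(neuron: NeuronReconstruction) -> dict[int, float]:
    """Path distance (µm) from the soma to every point, by tree traversal."""
    dist = {neuron.root_id: 0.0}
    stack = [neuron.root_id]
    while stack:
        pid = stack.pop()
        p_xyz = neuron.points[pid].xyz
        for child in neuron.children[pid]:
            gap = float(np.linalg.norm(neuron.points[child].xyz - p_xyz))
            dist[child] = dist[pid] + gap
            stack.append(child)
    return dist


def path_distances(
    neuron: NeuronReconstruction,
    targets: dict[str, list[str]] | None = None,
    class_label: str | None = None,
) -> pd.DataFrame:
    """One row per in-target axonal point with its soma-to-point path distance.

    *targets* maps a target-group name to the parcel labels it covers; when
    None, every annotated parcel is its own target group.
    """
    dist = path_distances_to_points(neuron)
    parcel_to_group: dict[str, str] | None = None
    if targets is not None:
        parcel_to_group = {
            parcel: group for group, parcels in targets.items() for parcel in parcels
        }
    rows = []
    for p in neuron.points.values():
        if p.structure != AXON or p.parcel is None:
            continue
        group = (
            parcel_to_group.get(p.parcel) if parcel_to_group is not None else p.parcel
        )
        if group is None:
            continue
        rows.append(
            {
                "neuron_id": neuron.neuron_id,
                "class": class_label,
                "target": group,
                "hemisphere": p.hemisphere,
                "point_id": p.point_id,
                "path_distance_um": dist[p.point_id],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "class",
            "target",
            "hemisphere",
            "point_id",
            "path_distance_um",
        ],
    )


def cohort_path_distances(
    neurons: list[NeuronReconstruction],
    labels: dict[str, str],
    targets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Concatenated path-distance table for a labeled cohort."""
    frames = [
        path_distances(n, targets, class_label=labels.get(n.neuron_id))
        for n in neurons
    ]
    return pd.concat(frames, ignore_index=True)


def per_neuron_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Median path distance per neuron per (target, hemisphere)."""
    return (
        table.groupby(["class", "target", "hemisphere", "neuron_id"], dropna=False)[
            "path_distance_um"
        ]
        .median()
        .reset_index()
    )


@dataclass
class PairTest:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    significant: bool = False


def _pairwise_rank_tests(
    samples: dict[str, np.ndarray], alpha: float, use_medians_of: pd.DataFrame | None
) -> list[PairTest]:
    names = [k for k, v in samples.items() if len(v) > 0]
    skipped = [k for k, v in samples.items() if len(v) == 0]
    if skipped:
        logger.info("groups with empty samples skipped: %s", skipped)
    tests: list[PairTest] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = samples[names[i]], samples[names[j]]
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            tests.append(
                PairTest(
                    group_a=names[i],
                    group_b=names[j],
                    n_a=len(a),
                    n_b=len(b),
                    median_a=float(np.median(a)),
                    median_b=float(np.median(b)),
                    statistic=float(stat),
                    p_raw=float(p),
                )
            )
    if tests:
        reject, adj, _, _ = multipletests(
            [t.p_raw for t in tests], alpha=alpha, method="fdr_bh"
        )
        for t, r, q in zip(tests, reject, adj):
            t.p_adjusted = float(q)
            t.significant = bool(r)
    return tests


def _tests_frame(tests: list[PairTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": t.group_a,
                "group_b": t.group_b,
                "n_a": t.n_a,
                "n_b": t.n_b,
                "median_a_um": t.median_a,
                "median_b_um": t.median_b,
                "U": t.statistic,
                "p_raw": t.p_raw,
                "p_fdr": t.p_adjusted,
                "significant": t.significant,
            }
            for t in tests
        ],
        columns=[
            "group_a",
            "group_b",
            "n_a",
            "n_b",
            "median_a_um",
            "median_b_um",
            "U",
            "p_raw",
            "p_fdr",
            "significant",
        ],
    )


def divergence_test(
    table: pd.DataFrame,
    class_label: str,
    targets: list[str] | None = None,
    hemisphere: str | None = None,
    alpha: float = 0.05,
    use_medians: bool = False,
) -> pd.DataFrame:
    """Compare one class's path distances across its targets, pairwise.

    Pooled per-point distances by default (legend-style n's); with
    *use_medians* each neuron contributes its per-target median instead.
    Ipsilateral and contralateral rows should be analyzed separately
    (pass *hemisphere*).  P-values are Benjamini-Hochberg adjusted across
    all pairs in this call.
    """
    rows = table[table["class"] == class_label]
    if hemisphere is not None:
        rows = rows[rows["hemisphere"] == hemisphere]
    if use_medians:
        rows = per_neuron_medians(rows)
    wanted = targets if targets is not None else sorted(rows["target"].unique())
    samples = {
        t: rows.loc[rows["target"] == t, "path_distance_um"].to_numpy() for t in wanted
    }
    return _tests_frame(_pairwise_rank_tests(samples, alpha, None))


def convergence_test(
    table: pd.DataFrame,
    target: str,
    hemisphere: str | None = None,
    alpha: float = 0.05,
    use_medians: bool = False,
) -> pd.DataFrame:
    """Compare path distances to one target across classes, pairwise."""
    rows = table[table["target"] == target]
    if hemisphere is not None:
        rows = rows[rows["hemisphere"] == hemisphere]
    if use_medians:
        rows = per_neuron_medians(rows)
    classes = sorted(c for c in rows["class"].dropna().unique())
    samples = {
        c: rows.loc[rows["class"] == c, "path_distance_um"].to_numpy() for c in classes
    }
    if len(classes) < 2:
        return _tests_frame([])
    return _tests_frame(_pairwise_rank_tests(samples, alpha, None))


def box_summary(values: np.ndarray) -> dict[str, float]:
    """Box-and-whisker summary: median, quartiles, whiskers at 1.5 IQR."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "n": int(values.size),
    }
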