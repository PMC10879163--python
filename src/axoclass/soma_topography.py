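"""Convex-hull topography of class soma positions.

Each class's somata occupy a region of the source structure summarized by
their 3-D convex hull after leave-one-out outlier pruning (a point whose
removal changes the hull volume by more than 1/n of the full volume is an
outlier).  Spatial segregation between classes is scored by the
overlap/union volume ratio of their hulls; layer distributions complement
the geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

logger = logging.getLogger(__name__)

MIN_HULL_POINTS = 4  # minimum for a 3-D convex hull


@dataclass
class HullConfig:
    """Outlier rule and Monte-Carlo fallback parameters."""

    mc_samples: int = 100_000
    seed: int | None = None
    volume_rtol: float = 1e-9


@dataclass
class HullSummary:
    """Pruned hull of one class's somata."""

    class_label: str
    kept_points: np.ndarray
    removed_points: np.ndarray
    volume: float
    reverted: bool = False  # pruning would have left <4 points


def _hull_volume(points: np.ndarray) -> float:
    if len(points) < MIN_HULL_POINTS:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def prune_hull_outliers(
    points: np.ndarray, class_label: str = "", cfg: HullConfig | None = None
) -> HullSummary:
    """Leave-one-out hull pruning with the 1/n volume rule.

    Every point is compared against the original hull over all n points: if
    dropping it changes the hull volume by more than 1/n of the original
    volume, it is an outlier.  All flagged points are removed in one pass
    (simultaneous flags, so the outcome does not depend on point order).  If
    that would leave fewer than four somata — the minimum for a 3-D hull —
    all points are kept instead.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    n = len(pts)
    if n < MIN_HULL_POINTS:
        raise ValueError("need at least 4 points for a convex hull")

    v_all = _hull_volume(pts)
    if v_all == 0.0:
        raise ValueError("zero-volume hull: points are degenerate (coplanar)")
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        v_without = _hull_volume(np.delete(pts, i, axis=0))
        if abs(v_without - v_all) > v_all / n:
            flags[i] = True

    survivors = pts[~flags]
    if flags.any() and len(survivors) < MIN_HULL_POINTS:
        logger.info(
            "class %s: pruning would leave %d < 4 somata; keeping all %d points",
            class_label,
            len(survivors),
            n,
        )
        return HullSummary(
            class_label=class_label,
            kept_points=pts,
            removed_points=np.empty((0, 3)),
            volume=v_all,
            reverted=True,
        )
    return HullSummary(
        class_label=class_label,
        kept_points=survivors,
        removed_points=pts[flags] if flags.any() else np.empty((0, 3)),
        volume=_hull_volume(survivors),
    )


def _halfspaces(points: np.ndarray) -> np.ndarray:
    return ConvexHull(points).equations  # rows: [normal, offset], Ax + b <= 0 inside


def _interior_point(halfspaces: np.ndarray) -> np.ndarray | None:
    """Chebyshev center of the halfspace intersection via LP; None if empty."""
    norm = np.linalg.norm(halfspaces[:, :-1], axis=1)
    c = np.zeros(4)
    c[-1] = -1.0
    A_ub = np.hstack([halfspaces[:, :-1], norm[:, None]])
    b_ub = -halfspaces[:, -1]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * 3 + [(0, None)])
    if not res.success or res.x[-1] <= 1e-12:
        return None
    return res.x[:-1]


@dataclass
class OverlapResult:
    ratio: float
    vol_a: float
    vol_b: float
    vol_intersection: float
    method: str  # "exact" | "monte-carlo" | "empty"
    mc_standard_error: float | None = None
    degenerate: bool = False


def hull_overlap(
    a: HullSummary | np.ndarray,
    b: HullSummary | np.ndarray,
    cfg: HullConfig | None = None,
) -> OverlapResult:
    """Overlap/union volume ratio of two convex hulls, in [0, 1].

    The intersection is itself a convex polytope: when an interior point
    exists it is computed exactly by halfspace intersection, and the union
    follows by inclusion-exclusion.  If the exact route fails numerically, a
    seeded Monte-Carlo estimate over the bounding box of both hulls is used
    and its standard error reported.  A pair with no interior overlap scores
    exactly 0 (the "could not be calculated" degenerate case is flagged).
    """
    cfg = cfg or HullConfig()
    pa = a.kept_points if isinstance(a, HullSummary) else np.asarray(a, dtype=float)
    pb = b.kept_points if isinstance(b, HullSummary) else np.asarray(b, dtype=float)
    va, vb = _hull_volume(pa), _hull_volume(pb)
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero-volume hull")

    hs = np.vstack([_halfspaces(pa), _halfspaces(pb)])
    interior = _interior_point(hs)
    if interior is None:
        return OverlapResult(0.0, va, vb, 0.0, method="empty", degenerate=True)
    try:
        inter = HalfspaceIntersection(hs, interior)
        vi = float(ConvexHull(inter.intersections).volume)
        union = va + vb - vi
        return OverlapResult(vi / union, va, vb, vi, method="exact")
    except (QhullError, ValueError):
        return _mc_overlap(pa, pb, va, vb, cfg)


def _mc_overlap(pa, pb, va, vb, cfg: HullConfig) -> OverlapResult:
    rng = np.random.default_rng(cfg.seed)
    lo = np.minimum(pa.min(axis=0), pb.min(axis=0))
    hi = np.maximum(pa.max(axis=0), pb.max(axis=0))
    box_vol = float(np.prod(hi - lo))
    samples = rng.uniform(lo, hi, size=(cfg.mc_samples, 3))

    def inside(points, hull_points):
        eq = _halfspaces(hull_points)
        return np.all(points @ eq[:, :-1].T + eq[:, -1] <= 1e-9, axis=1)

    in_a = inside(samples, pa)
    in_b = inside(samples, pb)
    p_int = float(np.mean(in_a & in_b))
    p_union = float(np.mean(in_a | in_b))
    vi = p_int * box_vol
    union = p_union * box_vol
    ratio = 0.0 if union == 0 else vi / union
    se = float(np.sqrt(p_int * (1 - p_int) / cfg.mc_samples)) * box_vol
    return OverlapResult(
        ratio, va, vb, vi, method="monte-carlo", mc_standard_error=se
    )


def overlap_matrix(
    hulls: list[HullSummary], cfg: HullConfig | None = None
) -> pd.DataFrame:
    """Pairwise overlap/union ratios between class hulls."""
    labels = [h.class_label for h in hulls]
    out = pd.DataFrame(np.eye(len(hulls)), index=labels, columns=labels)
    for i in range(len(hulls)):
        for j in range(i + 1, len(hulls)):
            r = hull_overlap(hulls[i], hulls[j], cfg).ratio
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def layer_distribution(somata: pd.DataFrame) -> pd.DataFrame:
    """Per-class soma counts and percentages by layer.

    *somata* needs columns ``class`` and ``layer``; rows with a missing layer
    label are flagged (logged) and excluded from the percentages.
    """
    for col in ("class", "layer"):
        if col not in somata.columns:
            raise ValueError(f"somata table missing column '{col}'")
    missing = somata["layer"].isna()
    if missing.any():
        logger.warning("%d somata with missing layer label excluded", missing.sum())
    labeled = somata[~missing]
    counts = labeled.groupby(["class", "layer"]).size().unstack(fill_value=0)
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    counts.columns = [f"n_{c}" for c in counts.columns]
    pct.columns = [f"pct_{c}" for c in pct.columns]
    return pd.concat([counts, pct], axis=1)
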