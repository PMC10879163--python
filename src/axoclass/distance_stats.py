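"""Arccosine projection distances and the one-tailed Levene gate.

Two neurons' projection vectors are compared by the angle between them:
0 deg means proportional targeting, 90 deg disjoint targets.  A set of
neurons is declared heterogeneous when the variance of its pairwise angle
distribution significantly exceeds that of the swap-randomized null, judged
by a one-tailed Levene test (ANOVA on absolute deviations from the group
means, significant only in the var(experimental) > var(randomized)
direction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reconstruction_io import ProjectionMatrix

logger = logging.getLogger(__name__)

EXPERIMENTAL = "experimental"
RANDOMIZED = "randomized"


@dataclass
class DistanceSample:
    """Pairwise arccosine distances (degrees) over one set of neurons."""

    values: np.ndarray
    n_items: int
    label: str = EXPERIMENTAL

    @property
    def variance(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass
class LeveneResult:
    """Outcome of the one-tailed variance gate.

    ``p_one_tailed`` is None ("not applicable") when the experimental
    variance does not exceed the randomized variance; ``decision`` is then
    always "stop".
    """

    statistic: float
    p_one_tailed: float | None
    p_two_tailed: float
    var_experimental: float
    var_randomized: float
    decision: str  # "split" | "stop"
    alpha: float = 0.05

    @property
    def applicable(self) -> bool:
        return self.p_one_tailed is not None


def arccos_distance(u, v) -> float:
    """Angle in degrees between two non-negative count vectors.

    Clamped against floating-point rounding; raises on zero vectors, for
    which the projection angle is undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("undefined projection angle: zero vector")
    # 2*atan2 form: numerically stable near 0 and 180 deg, unlike arccos of
    # the clipped cosine
    a, b = u / nu, v / nv
    angle = 2.0 * np.arctan2(np.linalg.norm(a - b), np.linalg.norm(a + b))
    return float(np.degrees(angle))


def pairwise_distances(
    matrix: ProjectionMatrix | np.ndarray, label: str = EXPERIMENTAL
) -> DistanceSample:
    """All unordered pairwise angles, row-major order, zero rows excluded."""
    counts = matrix.counts if isinstance(matrix, ProjectionMatrix) else np.asarray(matrix)
    counts = counts.astype(float)
    norms = np.linalg.norm(counts, axis=1)
    usable = norms > 0
    n_zero = int((~usable).sum())
    if n_zero:
        logger.info("excluding %d zero-count rows from distance computation", n_zero)
    rows = counts[usable] / norms[usable, None]
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 usable rows for pairwise distances")
    gram = np.clip(rows @ rows.T, -1.0, 1.0)
    iu = np.triu_indices(n, k=1)
    return DistanceSample(
        values=np.degrees(np.arccos(gram[iu])), n_items=n, label=label
    )


def levene_absolute_two_tailed(x, y) -> tuple[float, float]:
    """Standard Levene test (center = mean): one-way ANOVA of |x - mean|.

    Returns (F, p).  This is the classic equality-of-variances test; the
    directional one-tailed version used for split gating wraps it below.
    """
    stat, p = stats.levene(np.asarray(x), np.asarray(y), center="mean")
    return float(stat), float(p)


def levene_one_tailed(
    exp: DistanceSample, rnd: DistanceSample, alpha: float = 0.05
) -> LeveneResult:
    """One-tailed Levene gate: split only if var(exp) significantly > var(rnd).

    The two-tailed p comes from ANOVA on absolute deviations from each
    group's mean; it is halved when the variance ordering favors the
    alternative and reported not-applicable otherwise (matching the
    convention of reporting "p = N/A" when the experimental spread is not
    even nominally larger).
    """
    if len(exp.values) < 2 or len(rnd.values) < 2:
        raise ValueError("need at least 2 distances per sample for Levene's test")
    var_exp = exp.variance
    var_rnd = rnd.variance
    stat, p_two = levene_absolute_two_tailed(exp.values, rnd.values)
    if var_exp > var_rnd:
        p_one = p_two / 2.0
        decision = "split" if p_one < alpha else "stop"
    else:
        p_one = None
        decision = "stop"
    return LeveneResult(
        statistic=stat,
        p_one_tailed=p_one,
        p_two_tailed=p_two,
        var_experimental=var_exp,
        var_randomized=var_rnd,
        decision=decision,
        alpha=alpha,
    )
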