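"""Class population fractions by non-negative least squares deconvolution.

Single-neuron reconstructions give each class's axonal signature across the
target regions (matrix A, regions x classes); bulk anterograde tracing gives
the region-wise projection weight of the whole source population (vector b,
mean projection volume x mean density per region, normalized to sum 1).
Solving min ||Ax - b|| with x >= 0 yields the mixing fractions x: the share
of source-region neurons belonging to each class.  A is bi-normalized first
(rows to 1, grand total to k, then columns to 1) so that neither axonal
extent nor the number of invaded regions biases the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls


@dataclass
class ClassSignature:
    """Bi-normalized regions x classes signature matrix."""

    A: np.ndarray
    regions: list[str]
    class_labels: list[str]

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def k(self) -> int:
        return self.A.shape[1]


@dataclass
class PopulationEstimate:
    """NNLS solution: per-class fractions and residual."""

    x: np.ndarray
    class_labels: list[str]
    residual_sq: float
    b_norm_sq: float

    @property
    def fractions_pct(self) -> np.ndarray:
        total = self.x.sum()
        if total == 0:
            return np.zeros_like(self.x)
        return 100.0 * self.x / total

    @property
    def residual_pct_of_b(self) -> float:
        """Residual as a percentage of ||b||^2 (comparison convention)."""
        return 100.0 * self.residual_sq / self.b_norm_sq

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions_pct, index=self.class_labels, name="pct")


def build_b(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Regional weight vector from per-experiment tracing profiles.

    *profiles* has columns region, experiment, volume, density.  Each
    region's entry is mean(volume) x mean(density) over its experiments; the
    vector is then normalized to sum 1.  Returns (b, region order).
    """
    required = {"region", "volume", "density"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles missing columns: {sorted(missing)}")
    if (profiles["volume"] < 0).any() or (profiles["density"] < 0).any():
        raise ValueError("negative projection volume or density")
    means = profiles.groupby("region", sort=False)[["volume", "density"]].mean()
    raw = (means["volume"] * means["density"]).to_numpy(dtype=float)
    total = raw.sum()
    if total == 0:
        raise ValueError("all regional weights are zero")
    return raw / total, list(means.index)


def binormalize_A(
    raw: np.ndarray,
    regions: list[str] | None = None,
    class_labels: list[str] | None = None,
) -> ClassSignature:
    """Sequential bi-normalization of the raw signature counts.

    Step 1 divides each region row by its sum (removes per-region scale),
    step 2 rescales the grand total to k (classes) over m (regions), step 3
    divides each class column by its sum.  After the pipeline every column
    sums to 1 and the grand total equals k.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D regions x classes array")
    m, k = raw.shape
    regions = regions or [f"region{i}" for i in range(m)]
    class_labels = class_labels or [f"class{i}" for i in range(k)]
    if np.any(raw < 0):
        raise ValueError("negative signature counts")
    row_sums = raw.sum(axis=1)
    if np.any(row_sums == 0):
        bad = regions[int(np.argmin(row_sums))]
        raise ValueError(f"all-zero region row: {bad}")
    col_sums = raw.sum(axis=0)
    if np.any(col_sums == 0):
        bad = class_labels[int(np.argmin(col_sums))]
        raise ValueError(f"all-zero class column: {bad}")

    A = raw / row_sums[:, None]
    A = A * (k / m)
    A = A / A.sum(axis=0, keepdims=True)
    return ClassSignature(A=A, regions=list(regions), class_labels=list(class_labels))


def solve_population(
    signature: ClassSignature | np.ndarray,
    b: np.ndarray,
    class_labels: list[str] | None = None,
) -> PopulationEstimate:
    """Solve min ||Ax - b||, x >= 0 (active-set NNLS)."""
    if isinstance(signature, ClassSignature):
        A = signature.A
        class_labels = class_labels or signature.class_labels
    else:
        A = np.asarray(signature, dtype=float)
        class_labels = class_labels or [f"class{i}" for i in range(A.shape[1])]
    b = np.asarray(b, dtype=float)
    if A.shape[0] != b.shape[0]:
        raise ValueError("A and b dimensions disagree")
    x, rnorm = nnls(A, b)
    return PopulationEstimate(
        x=x,
        class_labels=list(class_labels),
        residual_sq=float(rnorm**2),
        b_norm_sq=float(np.dot(b, b)),
    )


def afferent_composition(
    estimate: PopulationEstimate,
    class_mean_counts: dict[str, float],
) -> pd.Series:
    """Per-class share of one target's afferents, in percent.

    ``class_mean_counts`` maps class label -> mean axonal counts per neuron
    of that class inside the target.  The contribution of class c is
    fraction_c x mean counts_c, normalized over classes to 100%; using the
    per-neuron mean (not the class sum) keeps class size from entering twice,
    since it is already in the fitted fraction.
    """
    fractions = dict(zip(estimate.class_labels, estimate.fractions_pct))
    weights = {
        label: fractions.get(label, 0.0) * mean_counts
        for label, mean_counts in class_mean_counts.items()
    }
    total = sum(weights.values())
    if total == 0:
        raise ValueError("target receives no axonal points from any class")
    return pd.Series(
        {label: 100.0 * w / total for label, w in weights.items()}, name="pct"
    )


def class_mean_counts_in_target(
    matrix, classes: dict[str, list[str]], target_columns: list[int]
) -> dict[str, float]:
    """Mean per-neuron axonal counts of each class inside a set of columns."""
    idx = {nid: i for i, nid in enumerate(matrix.neuron_ids)}
    out = {}
    for label, nids in classes.items():
        rows = [idx[n] for n in nids]
        out[label] = float(matrix.counts[np.ix_(rows, target_columns)].sum() / len(rows))
    return out
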