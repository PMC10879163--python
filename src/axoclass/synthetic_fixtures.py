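"""Seeded generators of synthetic inputs with the method's assumed structure.

Every generator is a pure function of (spec, seed), so each module of the
package can be exercised offline.  A cohort is drawn from a multinomial count
model: neuron i of class c draws a total axonal extent from a log-normal and
spreads it over the target columns with class c's region-probability profile
— the minimal model under which "axonal points per region" is the sufficient
description of a projection pattern.  Convenience specs emulate the two study
systems: a motor-cortex-like cohort of 21 + 31 neurons split between
cortical and thalamic targeting, and a presubiculum-like cohort of 93
neurons in five classes of sizes 38/27/3/19/6 with the hallmark target mixes
(e.g. the A-class placing ~82% of its extra-source extent in lateral
entorhinal cortex, the C-class projecting contralaterally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reconstruction_io import (
    AXON,
    CONTRA,
    IPSI,
    SOMA,
    NeuronReconstruction,
    ProjectionMatrix,
    TracingPoint,
)


@dataclass
class ClassSpec:
    """One planted class: size and region-probability profile over columns."""

    n_neurons: int
    profile: np.ndarray  # non-negative, sums to 1 over the cohort's columns
    label: str = ""


@dataclass
class CohortSpec:
    """Planted cohort: classes, columns, and the per-neuron total-points model."""

    classes: list[ClassSpec]
    columns: list[tuple[str, str]]
    log_total_mu: float = float(np.log(1500.0))
    log_total_sigma: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        for c in self.classes:
            c.profile = np.asarray(c.profile, dtype=float)
            if c.n_neurons < 1:
                raise ValueError("class size must be >= 1")
            if np.any(c.profile < 0) or not np.isclose(c.profile.sum(), 1.0):
                raise ValueError("profiles must be non-negative and sum to 1")
            if c.profile.shape != (len(self.columns),):
                raise ValueError("profile length must match column count")


def generate_cohort(spec: CohortSpec) -> tuple[ProjectionMatrix, list[str]]:
    """Draw a cohort matrix plus ground-truth class labels."""
    rng = np.random.default_rng(spec.seed)
    rows, labels, ids = [], [], []
    for ci, cls in enumerate(spec.classes):
        label = cls.label or f"class{ci}"
        for k in range(cls.n_neurons):
            total = int(
                np.round(rng.lognormal(spec.log_total_mu, spec.log_total_sigma))
            )
            total = max(total, 1)
            rows.append(rng.multinomial(total, cls.profile))
            labels.append(label)
            ids.append(f"{label}-{k:03d}")
    matrix = ProjectionMatrix(
        neuron_ids=ids,
        columns=list(spec.columns),
        counts=np.array(rows, dtype=np.int64),
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# Study-condition cohorts

#: Target column groups of the presubiculum-like cohort (ipsi unless noted).
PRESUB_COLUMNS: list[tuple[str, str]] = [
    ("DG", IPSI),
    ("CA", IPSI),
    ("Sub", IPSI),
    ("LEC", IPSI),
    ("dMEC", IPSI),
    ("ParaS", IPSI),
    ("Retrohipp", IPSI),
    ("RSPgran", IPSI),
    ("RSPagran", IPSI),
    ("MidB", IPSI),
    ("Hyp", IPSI),
    ("mATN+LGN", IPSI),
    ("dvATN+MGN", IPSI),
    ("TH-other", IPSI),
    ("Sub", CONTRA),
    ("LEC", CONTRA),
    ("dMEC", CONTRA),
    ("ParaS", CONTRA),
]

_PRESUB_PROFILES: dict[str, dict[tuple[str, str], float]] = {
    # hippocampal / LEC "what" pathway; ~82% of extent in LEC.  The DG weight
    # is set so that, combined with the planted population fractions, the
    # dentate gyrus draws ~21% of its afferents from this class and ~79%
    # from the D class (0.306*0.054 : 0.381*0.163).
    "A": {
        ("LEC", IPSI): 0.82,
        ("DG", IPSI): 0.054,
        ("CA", IPSI): 0.03,
        ("Sub", IPSI): 0.046,
        ("RSPgran", IPSI): 0.05,
    },
    # parasubiculum / dorsal MEC "where" pathway; ~92.5% in dMEC
    "B": {
        ("dMEC", IPSI): 0.925,
        ("ParaS", IPSI): 0.045,
        ("Retrohipp", IPSI): 0.03,
    },
    # sparse contralateral projectors through callosal/commissural fibers
    "C": {
        ("dMEC", CONTRA): 0.42,
        ("LEC", CONTRA): 0.40,
        ("Sub", CONTRA): 0.14,
        ("ParaS", CONTRA): 0.04,
    },
    # subiculum/DG plus the exclusive subcortical set (hypothalamus, midbrain)
    "D": {
        ("Sub", IPSI): 0.408,
        ("DG", IPSI): 0.163,
        ("RSPagran", IPSI): 0.09,
        ("MidB", IPSI): 0.10,
        ("Hyp", IPSI): 0.14,
        ("mATN+LGN", IPSI): 0.099,
    },
    # complementary thalamic nuclei
    "E": {
        ("dvATN+MGN", IPSI): 0.75,
        ("TH-other", IPSI): 0.25,
    },
}

#: Planted class sizes of the presubiculum-like cohort.
PRESUB_SIZES: dict[str, int] = {"A": 38, "B": 27, "C": 3, "D": 19, "E": 6}

#: Planted population fractions (%) used when emulating the deconvolution.
PRESUB_POPULATION_PCT: dict[str, float] = {
    "A": 30.6,
    "B": 16.3,
    "C": 1.3,
    "D": 38.1,
    "E": 13.7,
}


def presubiculum_like_spec(seed: int | None = None) -> CohortSpec:
    """Five-class cohort emulating the presubicular projection blueprint."""
    classes = []
    for label, size in PRESUB_SIZES.items():
        weights = _PRESUB_PROFILES[label]
        profile = np.array([weights.get(col, 0.0) for col in PRESUB_COLUMNS])
        classes.append(ClassSpec(n_neurons=size, profile=profile / profile.sum(), label=label))
    return CohortSpec(classes=classes, columns=list(PRESUB_COLUMNS), seed=seed)


MOTOR_COLUMNS: list[tuple[str, str]] = [
    ("MOs", IPSI),
    ("MOp-upper", IPSI),
    ("SSp", IPSI),
    ("MOp", CONTRA),
    ("VAL", IPSI),
    ("VM", IPSI),
    ("PO", IPSI),
    ("PF", IPSI),
]


def motor_l6_like_spec(seed: int | None = None) -> CohortSpec:
    """Two-class cohort emulating layer-6 motor cortex (21 IT + 31 CT).

    IT neurons target motor cortical areas; CT neurons target thalamic
    nuclei with roughly twice the axonal point counts.
    """
    it = np.array([0.45, 0.30, 0.15, 0.10, 0.0, 0.0, 0.0, 0.0])
    ct = np.array([0.05, 0.0, 0.0, 0.0, 0.35, 0.30, 0.20, 0.10])
    return CohortSpec(
        classes=[
            ClassSpec(n_neurons=21, profile=it, label="IT"),
            ClassSpec(n_neurons=31, profile=ct, label="CT"),
        ],
        columns=list(MOTOR_COLUMNS),
        seed=seed,
    )


def single_class_spec(
    n_neurons: int = 40, n_columns: int = 8, seed: int | None = None
) -> CohortSpec:
    """Homogeneous cohort (type-I error conditions): one broad profile."""
    profile = np.linspace(1.0, 2.0, n_columns)
    profile = profile / profile.sum()
    columns = [(f"P{j}", IPSI) for j in range(n_columns)]
    return CohortSpec(
        classes=[ClassSpec(n_neurons=n_neurons, profile=profile, label="single")],
        columns=columns,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic reconstructions


@dataclass
class TreeSpec:
    """Parameters of a synthetic axonal tree.

    The abstract branch topology has ``n_bifurcations`` binary branch points;
    branches at Strahler orders <= ``order_cut`` draw their length and
    tracing-point spacing from the "low" band, higher orders from the "high"
    band — emulating denser point placement in terminal, synapse-bearing
    arbors than along fibers of passage.
    """

    n_bifurcations: int = 10
    order_cut: int = 3
    length_low: float = 150.0  # µm, mean branch length, Strahler <= order_cut
    length_high: float = 950.0
    length_sd_low: float | None = None  # default 30% of the band mean
    length_sd_high: float | None = None
    spacing_low: float = 20.0  # µm between consecutive tracing points
    spacing_high: float = 40.0
    spacing_sd_low: float = 2.0
    spacing_sd_high: float = 4.0
    lognormal: bool = False  # draw lengths/spacings log-normally (heavy tails)
    parcel_pool: list[str] = field(default_factory=lambda: ["P0", "P1", "P2"])
    seed: int | None = None


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal draw parameterized by its arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_tree(spec: TreeSpec) -> NeuronReconstruction:
    """Generate a valid annotated reconstruction with controlled spacing bands."""
    rng = np.random.default_rng(spec.seed)

    # abstract branch topology: start with one branch, split leaves
    children: dict[int, list[int]] = {0: []}
    leaves = [0]
    for _ in range(spec.n_bifurcations):
        target = leaves.pop(int(rng.integers(len(leaves))))
        a, b = len(children), len(children) + 1
        children[target] = [a, b]
        children[a] = []
        children[b] = []
        leaves.extend([a, b])

    # Strahler order of each abstract branch (leaves inward)
    order: dict[int, int] = {}

    def strahler(bid: int) -> int:
        if bid in order:
            return order[bid]
        kids = children[bid]
        if not kids:
            order[bid] = 1
        else:
            ords = [strahler(k) for k in kids]
            top = max(ords)
            order[bid] = top + 1 if ords.count(top) >= 2 else top
        return order[bid]

    strahler(0)

    points: dict[int, TracingPoint] = {
        0: TracingPoint(point_id=0, xyz=np.zeros(3), parent_id=None, structure=SOMA)
    }
    next_id = [1]

    def grow(bid: int, anchor_id: int, direction: np.ndarray) -> None:
        low = order[bid] <= spec.order_cut
        mean_len = spec.length_low if low else spec.length_high
        sd_len = (
            (spec.length_sd_low if low else spec.length_sd_high)
            if (spec.length_sd_low if low else spec.length_sd_high) is not None
            else 0.3 * mean_len
        )
        mean_sp = spec.spacing_low if low else spec.spacing_high
        sd_sp = spec.spacing_sd_low if low else spec.spacing_sd_high
        if spec.lognormal:
            spacing = max(1.0, _lognormal(rng, mean_sp, sd_sp))
            length = max(spacing, _lognormal(rng, mean_len, sd_len))
        else:
            spacing = max(1.0, rng.normal(mean_sp, sd_sp))
            length = max(spacing, rng.normal(mean_len, sd_len))
        n_gaps = max(1, int(round(length / spacing)))
        parcel = str(spec.parcel_pool[int(rng.integers(len(spec.parcel_pool)))])
        parent = anchor_id
        pos = points[anchor_id].xyz.copy()
        for _ in range(n_gaps):
            step = direction + rng.normal(0.0, 0.15, size=3)
            step = step / np.linalg.norm(step)
            pos = pos + spacing * step
            pid = next_id[0]
            next_id[0] += 1
            points[pid] = TracingPoint(
                point_id=pid,
                xyz=pos.copy(),
                parent_id=parent,
                structure=AXON,
                parcel=parcel,
            )
            parent = pid
        for kid in children[bid]:
            d = direction + rng.normal(0.0, 0.6, size=3)
            grow(kid, parent, d / np.linalg.norm(d))

    first = rng.normal(size=3)
    grow(0, 0, first / np.linalg.norm(first))
    neuron = NeuronReconstruction(
        neuron_id=f"syn-{spec.seed}", points=points, root_id=0
    )
    neuron.validate()
    return neuron


def generate_soma_clusters(
    k: int,
    separation: float,
    spread: float,
    n_per_class: int,
    seed: int | None = None,
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """Gaussian soma blobs: one isotropic cluster per class along an axis."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci in range(k):
        center = np.array([ci * separation, 0.0, 0.0])
        xyz = rng.normal(center, spread, size=(n_per_class, 3))
        for i in range(n_per_class):
            rows.append(
                {
                    "neuron_id": f"c{ci}-{i:03d}",
                    "x": xyz[i, 0],
                    "y": xyz[i, 1],
                    "z": xyz[i, 2],
                    "class": f"class{ci}",
                    "layer": (
                        layers[int(rng.integers(len(layers)))] if layers else None
                    ),
                }
            )
    return pd.DataFrame(rows)
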