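"""Reading single-neuron reconstructions and tabulating axonal point counts.

Reconstructions arrive either as 7-column SWC text or as MouseLight-style
JSON with per-point brain-parcel annotation.  Each neuron is validated as a
single rooted tree (the soma is the root), and the cohort is condensed into
a neurons x (parcel, hemisphere) matrix of axonal point counts -- the
k-dimensional projection vectors that every downstream statistic consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AXON = "axon"
SOMA = "soma"
DENDRITE = "dendrite"
OTHER = "other"

# SWC type codes per the de-facto standard
_SWC_STRUCTURE = {0: OTHER, 1: SOMA, 2: AXON, 3: DENDRITE, 4: DENDRITE}
_STRUCTURE_SWC = {SOMA: 1, AXON: 2, DENDRITE: 3, OTHER: 0}

IPSI = "ipsi"
CONTRA = "contra"


class ReconstructionError(ValueError):
    """Structural problem in a reconstruction file (dangling parent, cycle, ...)."""


@dataclass
class TracingPoint:
    """One digitized tracing node of a reconstruction.

    Coordinates are micrometres in an arbitrary common frame; ``parcel`` is
    the atlas region the point falls in (may be ``None`` for unannotated
    points) and ``hemisphere`` is relative to the soma's side of the midline.
    """

    point_id: int
    xyz: np.ndarray
    radius: float | None = None
    parent_id: int | None = None
    structure: str = AXON
    parcel: str | None = None
    hemisphere: str = IPSI


@dataclass
class NeuronReconstruction:
    """A single neuron as a rooted tree of tracing points."""

    neuron_id: str
    points: dict[int, TracingPoint]
    root_id: int
    soma_parcel: str | None = None
    soma_layer: str | None = None
    children: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {pid: [] for pid in self.points}
            for p in self.points.values():
                if p.parent_id is not None:
                    self.children[p.parent_id].append(p.point_id)

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.points[self.root_id].xyz

    @property
    def n_points(self) -> int:
        return len(self.points)

    def axon_points(self) -> list[TracingPoint]:
        return [p for p in self.points.values() if p.structure == AXON]

    def leaves(self) -> list[int]:
        return [pid for pid, ch in self.children.items() if not ch]

    def validate(self) -> None:
        """Check the point set forms one acyclic tree rooted at the soma."""
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            pid = stack.pop()
            if pid in seen:
                raise ReconstructionError(
                    f"{self.neuron_id}: cycle detected at point {pid}"
                )
            seen.add(pid)
            stack.extend(self.children[pid])
        if seen != set(self.points):
            orphan = sorted(set(self.points) - seen)[0]
            raise ReconstructionError(
                f"{self.neuron_id}: point {orphan} not reachable from root "
                f"(multiple roots or broken parent chain)"
            )
        for p in self.points.values():
            if not np.all(np.isfinite(p.xyz)):
                raise ReconstructionError(
                    f"{self.neuron_id}: non-finite coordinates at point {p.point_id}"
                )


def parse_swc(stream: TextIO | str, neuron_id: str = "neuron") -> NeuronReconstruction:
    """Parse a 7-column SWC file into a validated reconstruction.

    Columns: id, type, x, y, z, radius, parent (-1 for the root).  Lines
    starting with ``#`` are comments.  Exactly one root is required and every
    parent id must refer to an existing point.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    points: dict[int, TracingPoint] = {}
    roots: list[int] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise ReconstructionError(
                f"line {lineno}: expected 7 columns, got {len(fields)}"
            )
        try:
            pid = int(fields[0])
            stype = int(fields[1])
            xyz = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
            radius = float(fields[5])
            parent = int(fields[6])
        except ValueError as exc:
            raise ReconstructionError(f"line {lineno}: malformed number: {exc}") from exc
        if pid in points:
            raise ReconstructionError(f"line {lineno}: duplicate point id {pid}")
        parent_id = None if parent == -1 else parent
        if parent_id is None:
            roots.append(pid)
        points[pid] = TracingPoint(
            point_id=pid,
            xyz=xyz,
            radius=radius,
            parent_id=parent_id,
            structure=_SWC_STRUCTURE.get(stype, OTHER),
        )

    if not points:
        raise ReconstructionError("empty SWC file")
    if len(roots) != 1:
        raise ReconstructionError(
            f"expected exactly one root, found {len(roots)}: {sorted(roots)}"
        )
    for p in points.values():
        if p.parent_id is not None and p.parent_id not in points:
            raise ReconstructionError(
                f"dangling parent: point {p.point_id} refers to missing "
                f"parent {p.parent_id}"
            )
    neuron = NeuronReconstruction(neuron_id=neuron_id, points=points, root_id=roots[0])
    neuron.validate()
    return neuron


def write_swc(neuron: NeuronReconstruction) -> str:
    """Serialize a reconstruction back to canonical SWC text.

    Round-trips ``parse_swc`` bit-exactly for coordinates (repr-precision
    floats) and topology.
    """
    out = ["# id type x y z radius parent"]
    for pid in sorted(neuron.points):
        p = neuron.points[pid]
        parent = -1 if p.parent_id is None else p.parent_id
        radius = 1.0 if p.radius is None else p.radius
        x, y, z = (float(v) for v in p.xyz)
        out.append(
            f"{p.point_id} {_STRUCTURE_SWC.get(p.structure, 0)} "
            f"{x!r} {y!r} {z!r} {float(radius)!r} {parent}"
        )
    return "\n".join(out) + "\n"


def parse_projection_json(
    stream: TextIO | str, parcel_names: Mapping[int, str] | None = None
) -> list[NeuronReconstruction]:
    """Parse MouseLight-style JSON into annotated reconstructions.

    Expected layout: a top-level ``neurons`` list; each neuron record has an
    ``idString``, a ``soma`` record with ``x``/``y``/``z`` (and optionally
    ``allenLabel``/``allenId``), and an ``axon`` list of sample records with
    ``sampleNumber``, ``x``, ``y``, ``z``, ``parentNumber`` (-1 for the
    point attached to the soma) and a parcel annotation (``allenLabel`` or
    numeric ``allenId`` resolved through *parcel_names*).
    """
    text = stream if isinstance(stream, str) else stream.read()
    doc = json.loads(text)
    if "neurons" not in doc:
        raise ReconstructionError("JSON lacks a 'neurons' list")

    neurons = []
    for rec in doc["neurons"]:
        nid = str(rec.get("idString") or rec.get("id") or f"neuron{len(neurons)}")
        if "soma" not in rec:
            raise ReconstructionError(f"{nid}: JSON neuron record lacks a soma")
        soma = rec["soma"]
        for key in ("x", "y", "z"):
            if key not in soma:
                raise ReconstructionError(f"{nid}: soma missing coordinate '{key}'")
        points: dict[int, TracingPoint] = {
            0: TracingPoint(
                point_id=0,
                xyz=np.array([float(soma["x"]), float(soma["y"]), float(soma["z"])]),
                parent_id=None,
                structure=SOMA,
                parcel=_json_parcel(soma, parcel_names, required=False),
            )
        }
        for sample in rec.get("axon", []):
            for key in ("sampleNumber", "x", "y", "z", "parentNumber"):
                if key not in sample:
                    raise ReconstructionError(
                        f"{nid}: axon sample missing field '{key}'"
                    )
            pid = int(sample["sampleNumber"])
            parent = int(sample["parentNumber"])
            points[pid] = TracingPoint(
                point_id=pid,
                xyz=np.array(
                    [float(sample["x"]), float(sample["y"]), float(sample["z"])]
                ),
                radius=float(sample["radius"]) if "radius" in sample else None,
                parent_id=0 if parent == -1 else parent,
                structure=AXON,
                parcel=_json_parcel(sample, parcel_names, required=True, nid=nid),
            )
        neuron = NeuronReconstruction(
            neuron_id=nid,
            points=points,
            root_id=0,
            soma_parcel=points[0].parcel,
            soma_layer=rec.get("somaLayer"),
        )
        neuron.validate()
        neurons.append(neuron)
    return neurons


def _json_parcel(record, parcel_names, required, nid="?"):
    if "allenLabel" in record:
        return str(record["allenLabel"])
    if "allenId" in record:
        aid = int(record["allenId"])
        if parcel_names and aid in parcel_names:
            return parcel_names[aid]
        return str(aid)
    if required:
        raise ReconstructionError(f"{nid}: axon sample missing parcel annotation")
    return None


def assign_hemispheres(
    neuron: NeuronReconstruction, midline: float, axis: int = 0
) -> None:
    """Label every point ipsi/contra from its side of the midline vs the soma.

    The mediolateral coordinate is ``xyz[axis]``; a point on the same side of
    ``midline`` as the soma is ipsilateral.  Points exactly on the midline are
    ipsilateral by convention.
    """
    soma_side = neuron.soma_xyz[axis] - midline
    sign = 1.0 if soma_side >= 0 else -1.0
    for p in neuron.points.values():
        p.hemisphere = IPSI if sign * (p.xyz[axis] - midline) >= 0 else CONTRA


@dataclass
class ProjectionMatrix:
    """Neurons x (parcel, hemisphere) axonal point counts.

    ``counts[i, j]`` is the number of axon-structure tracing points of neuron
    ``i`` inside column ``j``.  Row sums are the neurons' total in-scope
    axonal extent and column sums the regional totals; the swap-randomization
    null preserves both.
    """

    neuron_ids: list[str]
    columns: list[tuple[str, str]]  # (parcel, hemisphere); hemisphere "both" if unsplit
    counts: np.ndarray
    source_parcel: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.neuron_ids), len(self.columns)):
            raise ValueError("counts shape does not match ids/columns")
        if np.any(self.counts < 0):
            raise ValueError("negative axonal counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def zero_rows(self) -> list[str]:
        return [nid for nid, s in zip(self.neuron_ids, self.row_sums()) if s == 0]

    def subset(self, neuron_ids: Sequence[str]) -> "ProjectionMatrix":
        index = {nid: i for i, nid in enumerate(self.neuron_ids)}
        rows = [index[nid] for nid in neuron_ids]
        return ProjectionMatrix(
            neuron_ids=list(neuron_ids),
            columns=list(self.columns),
            counts=self.counts[rows].copy(),
            source_parcel=self.source_parcel,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{p}|{h}" for p, h in self.columns]
        return pd.DataFrame(self.counts, index=self.neuron_ids, columns=cols)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, source_parcel: str | None = None
    ) -> "ProjectionMatrix":
        columns = []
        for c in frame.columns:
            parcel, _, hemi = str(c).partition("|")
            columns.append((parcel, hemi or "both"))
        return cls(
            neuron_ids=[str(i) for i in frame.index],
            columns=columns,
            counts=frame.to_numpy(),
            source_parcel=source_parcel,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="neuron_id")

    @classmethod
    def from_csv(cls, path) -> "ProjectionMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


def build_projection_matrix(
    neurons: Iterable[NeuronReconstruction],
    parcel_set: Sequence[str],
    include_source: bool = False,
    hemisphere_split: bool = True,
    source_parcel: str | None = None,
) -> ProjectionMatrix:
    """Tabulate axonal points per neuron per (parcel, hemisphere) column.

    Points in parcels outside *parcel_set* are dropped (a summary of the
    dropped counts is logged).  Source-region collaterals are excluded unless
    *include_source*; neurons left with zero in-scope points are retained in
    the matrix but logged, since they cannot enter angular distance
    computations.
    """
    if not parcel_set:
        raise ValueError("parcel_set must be non-empty")
    parcels = [p for p in parcel_set if include_source or p != source_parcel]
    if hemisphere_split:
        columns = [(p, h) for p in parcels for h in (IPSI, CONTRA)]
    else:
        columns = [(p, "both") for p in parcels]
    col_index = {c: j for j, c in enumerate(columns)}

    neurons = list(neurons)
    counts = np.zeros((len(neurons), len(columns)), dtype=np.int64)
    dropped: dict[str, int] = {}
    for i, neuron in enumerate(neurons):
        for p in neuron.axon_points():
            if p.parcel is None:
                continue
            key = (p.parcel, p.hemisphere if hemisphere_split else "both")
            j = col_index.get(key)
            if j is None:
                dropped[p.parcel] = dropped.get(p.parcel, 0) + 1
                continue
            counts[i, j] += 1
    if dropped:
        logger.info(
            "dropped %d axonal points in out-of-scope parcels: %s",
            sum(dropped.values()),
            dict(sorted(dropped.items())),
        )
    matrix = ProjectionMatrix(
        neuron_ids=[n.neuron_id for n in neurons],
        columns=columns,
        counts=counts,
        source_parcel=source_parcel,
    )
    zero = matrix.zero_rows()
    if zero:
        logger.warning("neurons with zero in-scope axonal points: %s", zero)
    return matrix


def read_parcel_dictionary(path) -> pd.DataFrame:
    """Read a parcel dictionary CSV with columns parcel_id,name,group."""
    df = pd.read_csv(path, dtype=str)
    required = {"parcel_id", "name", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcel dictionary missing columns: {sorted(missing)}")
    return df


def aggregate_parcels(
    matrix: ProjectionMatrix, grouping: Mapping[str, str]
) -> ProjectionMatrix:
    """Merge parcel columns into coarser groups (e.g. "CA3+CA1", "TH+LGN").

    Hemisphere labels are preserved; parcels missing from *grouping* keep
    their own name as the group.
    """
    grouped: dict[tuple[str, str], list[int]] = {}
    for j, (parcel, hemi) in enumerate(matrix.columns):
        key = (grouping.get(parcel, parcel), hemi)
        grouped.setdefault(key, []).append(j)
    columns = list(grouped)
    counts = np.column_stack(
        [matrix.counts[:, cols].sum(axis=1) for cols in grouped.values()]
    )
    return ProjectionMatrix(
        neuron_ids=list(matrix.neuron_ids),
        columns=columns,
        counts=counts,
        source_parcel=matrix.source_parcel,
    )
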