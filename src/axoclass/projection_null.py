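"""Marginal-preserving randomization of the projection count matrix.

The single-class null hypothesis is that neurons differ only through random
variation within the constraints of regional connectivity: each neuron keeps
its total axonal extent (row sum) and each region keeps its total innervation
(column sum), but the per-neuron allocation across regions is scrambled.
Sampling from this null uses repeated pairwise swaps: pick two neurons and
two columns, move delta points from one diagonal of the 2x2 submatrix to the
other.  Every accepted swap conserves all marginals exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reconstruction_io import ProjectionMatrix

DEFAULT_SWAPS_PER_CELL = 20


@dataclass
class SwapConfig:
    """Parameters of the swap chain.

    ``n_successful_swaps`` defaults to 20x the number of nonzero cells;
    ``delta_rule`` picks the amount moved per swap: ``uniform`` draws delta
    uniformly from {1..min(M[i,a], M[j,b])} (faster mixing), ``max`` always
    moves the feasible maximum.
    """

    n_successful_swaps: int | None = None
    seed: int | np.random.Generator | None = None
    delta_rule: str = "uniform"
    check_convergence: bool = False

    def resolve_swaps(self, counts: np.ndarray) -> int:
        if self.n_successful_swaps is not None:
            if self.n_successful_swaps < 1:
                raise ValueError("n_successful_swaps must be >= 1")
            return self.n_successful_swaps
        return DEFAULT_SWAPS_PER_CELL * max(int(np.count_nonzero(counts)), 1)


def swap_randomize_counts(
    counts: np.ndarray, cfg: SwapConfig | None = None
) -> np.ndarray:
    """Return a marginal-preserving randomization of a count array.

    Proposals draw rows i != j and columns a != b uniformly; a proposal with
    min(M[i,a], M[j,b]) = 0 is rejected and does not count toward the swap
    budget.  The chain state is integer throughout.
    """
    cfg = cfg or SwapConfig()
    M = np.asarray(counts)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("null model undefined: need at least a 2x2 matrix")
    if np.any(M < 0) or not np.issubdtype(M.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")

    # a swap needs nonzero cells in two distinct rows AND two distinct columns;
    # otherwise the marginal-preserving fiber is the singleton {M}
    if (
        int(np.count_nonzero(M.sum(axis=1))) < 2
        or int(np.count_nonzero(M.sum(axis=0))) < 2
    ):
        return M.copy()

    rng = (
        cfg.seed
        if isinstance(cfg.seed, np.random.Generator)
        else np.random.default_rng(cfg.seed)
    )
    n_swaps = cfg.resolve_swaps(M)
    uniform_delta = cfg.delta_rule == "uniform"
    if not uniform_delta and cfg.delta_rule != "max":
        raise ValueError(f"unknown delta_rule: {cfg.delta_rule!r}")

    n_rows, n_cols = M.shape
    # plain python lists: ~5x faster than numpy scalar indexing in this loop
    work = [list(map(int, row)) for row in M]
    done = 0
    block = max(4 * n_swaps, 1024)
    randint = rng.integers
    while done < n_swaps:
        rows = randint(0, n_rows, size=2 * block)
        cols = randint(0, n_cols, size=2 * block)
        deltas = rng.random(size=block) if uniform_delta else None
        for t in range(block):
            i, j = int(rows[2 * t]), int(rows[2 * t + 1])
            a, b = int(cols[2 * t]), int(cols[2 * t + 1])
            if i == j or a == b:
                continue
            cap = min(work[i][a], work[j][b])
            if cap == 0:
                continue
            delta = int(deltas[t] * cap) + 1 if uniform_delta else cap
            work[i][a] -= delta
            work[i][b] += delta
            work[j][a] += delta
            work[j][b] -= delta
            done += 1
            if done == n_swaps:
                break
    out = np.array(work, dtype=M.dtype)
    if cfg.check_convergence:
        _warn_if_not_mixed(M, out)
    return out


def randomize_matrix(
    matrix: ProjectionMatrix, cfg: SwapConfig | None = None
) -> ProjectionMatrix:
    """Swap-randomize a :class:`ProjectionMatrix`, preserving all marginals."""
    return ProjectionMatrix(
        neuron_ids=list(matrix.neuron_ids),
        columns=list(matrix.columns),
        counts=swap_randomize_counts(matrix.counts, cfg),
        source_parcel=matrix.source_parcel,
    )


def _warn_if_not_mixed(original: np.ndarray, randomized: np.ndarray) -> None:
    """Crude mixing check: the randomized matrix should have decorrelated cells."""
    a = original.ravel().astype(float)
    b = randomized.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return
    r = float(np.corrcoef(a, b)[0, 1])
    if r > 0.9:
        warnings.warn(
            f"swap chain may not have mixed (cellwise correlation {r:.2f} with "
            "the original); consider more swaps",
            stacklevel=3,
        )


def enumerate_fiber(row_sums, col_sums):
    """Enumerate all non-negative integer matrices with the given marginals.

    Brute-force recursion over rows; only feasible for tiny instances (used
    to verify that the swap chain can reach the whole fiber).
    """
    row_sums = list(row_sums)
    col_sums = list(col_sums)
    if sum(row_sums) != sum(col_sums):
        raise ValueError("marginals inconsistent")

    def compositions(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in compositions(total - first, caps[1:]):
                yield (first,) + rest

    results = []

    def fill(row_idx, remaining_cols, acc):
        if row_idx == len(row_sums):
            if all(c == 0 for c in remaining_cols):
                results.append(tuple(acc))
            return
        for row in compositions(row_sums[row_idx], remaining_cols):
            fill(
                row_idx + 1,
                [c - x for c, x in zip(remaining_cols, row)],
                acc + [row],
            )

    fill(0, col_sums, [])
    return results
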