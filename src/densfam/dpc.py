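"""Density Peak Clustering over a precomputed distance matrix.

The same two-step engine drives both clustering stages of the pipeline:
per-item densities are counted within a cutoff radius, each item is linked
to its nearest denser neighbour, peaks of the (density, separation) diagram
become cluster centers, and the remaining items inherit labels down the
density ordering.

Determinism: density ties are broken by ascending item index, i.e. item j
counts as "denser" than item i iff ``rho[j] > rho[i]`` or
``rho[j] == rho[i] and j < i``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NOISE = -1


@dataclass(frozen=True)
class DistanceMatrix:
    """A validated symmetric distance matrix with entries in [0, 1]."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {d.shape}")
        if d.shape[0] == 0:
            raise ValueError("empty distance matrix")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if d.min() < 0 or d.max() > 1:
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class DPCParams:
    """Knobs for one clustering run.

    ``dc=None`` selects the cutoff automatically as the 2nd percentile of
    off-diagonal distances, clamped to [0.01, 0.5].
    """

    dc: float | None = None
    kernel: str = "cutoff"  # "cutoff" or "gaussian"
    rho_min: float = 0.0
    delta_min: float = 0.5
    mark_noise: bool = False


@dataclass
class DPCResult:
    rho: np.ndarray
    delta: np.ndarray
    nearest_higher: np.ndarray  # index of nearest denser item; -1 for the peak
    centers: list[int]
    assignment: np.ndarray  # per-item cluster label; NOISE possible
    dc: float = field(default=np.nan)

    def partition(self) -> list[list[int]]:
        """Item indices grouped by label, ordered by label."""
        out: dict[int, list[int]] = {}
        for i, lab in enumerate(self.assignment):
            out.setdefault(int(lab), []).append(i)
        return [out[k] for k in sorted(out)]


def default_dc(dm: DistanceMatrix) -> float:
    """Cutoff radius heuristic: 2nd percentile of off-diagonal distances.

    The percentile is nudged up by 5% (plus an epsilon) so that distances
    tied exactly at the percentile still count as neighbours under the
    strict ``d < dc`` cutoff kernel; discrete distance spectra otherwise
    yield all-zero densities.
    """
    n = dm.n
    if n < 2:
        return 0.5
    off = dm.d[~np.eye(n, dtype=bool)]
    dc = 1.05 * float(np.percentile(off, 2.0)) + 1e-9
    return float(np.clip(dc, 0.01, 0.5))


def compute_density(dm: DistanceMatrix, dc: float, kernel: str = "cutoff") -> np.ndarray:
    """Per-item density.

    Cutoff kernel (default): number of other items strictly within ``dc``.
    Gaussian kernel: ``sum_j exp(-(d_ij/dc)^2)`` over j != i.
    """
    if not (0 < dc <= 1):
        raise ValueError(f"dc must be in (0, 1], got {dc}")
    d = dm.d
    n = dm.n
    eye = np.eye(n, dtype=bool)
    if kernel == "cutoff":
        rho = ((d < dc) & ~eye).sum(axis=1).astype(float)
    elif kernel == "gaussian":
        w = np.exp(-((d / dc) ** 2))
        w[eye] = 0.0
        rho = w.sum(axis=1)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return rho


def _denser_order(rho: np.ndarray) -> np.ndarray:
    """Item indices sorted from densest to sparsest, ties by ascending index."""
    n = len(rho)
    return np.lexsort((np.arange(n), -rho))


def compute_delta(dm: DistanceMatrix, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each item to its nearest denser item.

    The globally densest item (unique under the tie rule) gets the maximum
    distance of its own row and ``nearest_higher = -1``.
    """
    d = dm.d
    n = dm.n
    delta = np.empty(n)
    nearest = np.full(n, -1, dtype=int)
    order = _denser_order(rho)
    peak = order[0]
    delta[peak] = d[peak].max() if n > 1 else 0.0
    for rank in range(1, n):
        i = order[rank]
        denser = order[:rank]
        j = denser[np.argmin(d[i, denser])]
        delta[i] = d[i, j]
        nearest[i] = j
    return delta, nearest


def select_centers(
    rho: np.ndarray,
    delta: np.ndarray,
    rho_min: float = 0.0,
    delta_min: float = 0.5,
) -> list[int]:
    """Items with both high density and high separation become centers.

    If the thresholds exclude everything, the global density peak is forced
    so the result is never empty.
    """
    centers = [
        int(i)
        for i in range(len(rho))
        if rho[i] >= rho_min and delta[i] >= delta_min
    ]
    if not centers:
        centers = [int(_denser_order(rho)[0])]
    return centers


def assign_clusters(
    dm: DistanceMatrix,
    rho: np.ndarray,
    nearest_higher: np.ndarray,
    centers: list[int],
) -> np.ndarray:
    """Propagate center labels down the density ordering.

    Each non-center inherits the label of its nearest denser neighbour;
    processing in decreasing-density order guarantees the neighbour is
    already labelled. Labels are the ranks of the sorted center indices.
    """
    if not centers:
        raise ValueError("no centers")
    n = dm.n
    assignment = np.full(n, -2, dtype=int)
    label_of = {c: lab for lab, c in enumerate(sorted(centers))}
    for i in _denser_order(rho):
        if i in label_of:
            assignment[i] = label_of[i]
        else:
            assignment[i] = assignment[nearest_higher[i]]
    return assignment


def run_dpc(dm: DistanceMatrix, params: DPCParams = DPCParams()) -> DPCResult:
    """Full density→separation→centers→assignment run."""
    dc = params.dc if params.dc is not None else default_dc(dm)
    rho = compute_density(dm, dc, kernel=params.kernel)
    delta, nearest = compute_delta(dm, rho)
    centers = select_centers(rho, delta, params.rho_min, params.delta_min)
    assignment = assign_clusters(dm, rho, nearest, centers)
    if params.mark_noise:
        assignment = assignment.copy()
        assignment[(rho == 0) & ~np.isin(np.arange(dm.n), centers)] = NOISE
    return DPCResult(rho, delta, nearest, centers, assignment, dc=dc)


def dump_decision_graph(result: DPCResult, path: str) -> None:
    """Write the (rho, delta) diagnostic table as TSV."""
    with open(path, "w") as fh:
        fh.write("item\trho\tdelta\tnearest_higher\tlabel\n")
        for i in range(len(result.rho)):
            fh.write(
                f"{i}\t{result.rho[i]:g}\t{result.delta[i]:g}\t"
                f"{result.nearest_higher[i]}\t{result.assignment[i]}\n"
            )
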