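"""Clustering of primary clusters across queries into metaclusters.

Two primary clusters are close when they share many subject regions: a
member of one matches a member of the other when both lie on the same
subject protein and their intervals agree with Jaccard overlap above a
threshold. The shared count, normalized by the smaller cluster, defines
the distance used for the second density-clustering stage.
"""
from __future__ import annotations

from collections import defaultdict
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .dpc import DistanceMatrix, DPCParams, run_dpc
from .model import Region, region_jaccard
from .primary import PrimaryCluster


@dataclass(frozen=True)
class Metacluster:
    """A set of primary clusters flattened into seed regions: a putative family."""

    id: str
    primary_members: tuple[PrimaryCluster, ...]
    seeds: tuple[Region, ...]

    def __post_init__(self) -> None:
        if not self.primary_members:
            raise ValueError("metacluster must contain at least one primary cluster")

    @property
    def seed_count(self) -> int:
        return len(self.seeds)


def flatten_seeds(primary_clusters: Sequence[PrimaryCluster]) -> tuple[Region, ...]:
    """Union of subject regions with exact duplicates removed, sorted."""
    return tuple(sorted({r for pc in primary_clusters for r in pc.subject_regions}))


def make_metacluster_id(ordinal: int, width: int = 6) -> str:
    return f"MC{ordinal:0{width}d}"


def shared_member_count(
    a: PrimaryCluster,
    b: PrimaryCluster,
    overlap_threshold: float = 0.8,
) -> int:
    """Number of members the clusters share, under one-to-one matching.

    A pair (r in a, s in b) is a candidate when both regions are on the same
    subject protein and their Jaccard overlap is strictly greater than the
    threshold. Candidates are matched greedily, best overlap first (ties go
    to longer region pairs), each member used at most once.
    """
    if not (0 < overlap_threshold <= 1):
        raise ValueError(f"overlap_threshold must be in (0, 1], got {overlap_threshold}")
    by_protein_b: dict[str, list[int]] = defaultdict(list)
    regions_b = b.subject_regions
    for j, s in enumerate(regions_b):
        by_protein_b[s.protein_id].append(j)

    candidates = []
    for i, r in enumerate(a.subject_regions):
        for j in by_protein_b.get(r.protein_id, ()):
            s = regions_b[j]
            jac = region_jaccard(r, s)
            if jac > overlap_threshold:
                candidates.append((-jac, -(r.length + s.length), i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    count = 0
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        count += 1
    return count


def primary_cluster_distance(
    a: PrimaryCluster,
    b: PrimaryCluster,
    overlap_threshold: float = 0.8,
) -> float:
    """``1 - shared / min(|a|, |b|)``; 0 for identical clusters, 1 for unrelated."""
    shared = shared_member_count(a, b, overlap_threshold)
    return 1.0 - shared / min(a.size, b.size)


def _pc_sort_key(pc: PrimaryCluster):
    return (pc.query_id, pc.footprint.start, pc.footprint.end, -pc.size)


def metacluster(
    primary_clusters: Sequence[PrimaryCluster],
    params: DPCParams = DPCParams(),
    overlap_threshold: float = 0.8,
) -> list[Metacluster]:
    """Density-cluster primary clusters and flatten each class into a metacluster.

    The distance matrix is filled only for pairs of primary clusters that
    share at least one subject protein; all other pairs sit at distance 1.
    Metacluster ids are assigned by decreasing seed count.
    """
    if not primary_clusters:
        raise ValueError("no primary clusters to metacluster")
    pcs = sorted(primary_clusters, key=_pc_sort_key)
    n = len(pcs)

    by_protein: dict[str, list[int]] = defaultdict(list)
    for i, pc in enumerate(pcs):
        for pid in {r.protein_id for r in pc.subject_regions}:
            by_protein[pid].append(i)
    pairs: set[tuple[int, int]] = set()
    for idxs in by_protein.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                pairs.add((idxs[ai], idxs[bi]))

    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    for i, j in pairs:
        dij = primary_cluster_distance(pcs[i], pcs[j], overlap_threshold)
        d[i, j] = d[j, i] = dij

    result = run_dpc(DistanceMatrix(d), params)
    groups: dict[int, list[PrimaryCluster]] = defaultdict(list)
    for idx, lab in enumerate(result.assignment):
        groups[int(lab)].append(pcs[idx])

    drafts = []
    for lab in sorted(groups):
        members = tuple(groups[lab])
        drafts.append((members, flatten_seeds(members)))
    drafts.sort(key=lambda t: (-len(t[1]), _pc_sort_key(t[0][0])))
    return [
        Metacluster(make_metacluster_id(k + 1), members, seeds)
        for k, (members, seeds) in enumerate(drafts)
    ]
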