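"""Merging of density-split metaclusters, seed de-duplication, size filtering.

Density clustering can split one family across two peaks separated by a
high-density saddle. Metaclusters whose average pairwise primary-cluster
distance falls below a threshold are therefore merged; merging is by
connected components so the result is order-invariant and idempotent.
"""
from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

from .meta import (
    Metacluster,
    flatten_seeds,
    make_metacluster_id,
    primary_cluster_distance,
)
from .model import Region, region_jaccard


@dataclass(frozen=True)
class MergeDecision:
    mc_a: str
    mc_b: str
    avg_distance: float
    merged: bool


def metacluster_distance(
    a: Metacluster,
    b: Metacluster,
    overlap_threshold: float = 0.8,
) -> float:
    """Mean primary-cluster distance over all cross pairs of members."""
    if not a.primary_members or not b.primary_members:
        raise ValueError("cannot measure distance to an empty metacluster")
    total = 0.0
    count = 0
    for pa in a.primary_members:
        for pb in b.primary_members:
            total += primary_cluster_distance(pa, pb, overlap_threshold)
            count += 1
    return total / count


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_metaclusters(
    metaclusters: Sequence[Metacluster],
    merge_threshold: float = 0.9,
    overlap_threshold: float = 0.8,
    keep_shared_only: bool = False,
) -> tuple[list[Metacluster], list[MergeDecision]]:
    """Join metaclusters whose average distance is below the threshold.

    An edge is drawn between every pair with ``metacluster_distance <
    merge_threshold``; connected components become the merged metaclusters,
    with primary members concatenated and seeds re-flattened. Ids are
    re-assigned by decreasing seed count.

    ``keep_shared_only`` additionally restricts each merged metacluster's
    seeds to those supported by at least two of its constituent
    metaclusters (no-op for components of size one). Default off.
    """
    if not (0 < merge_threshold <= 1):
        raise ValueError(f"merge_threshold must be in (0, 1], got {merge_threshold}")
    mcs = sorted(metaclusters, key=lambda m: m.id)
    n = len(mcs)
    uf = _UnionFind(n)
    decisions = []
    for i in range(n):
        for j in range(i + 1, n):
            dist = metacluster_distance(mcs[i], mcs[j], overlap_threshold)
            merged = dist < merge_threshold
            decisions.append(MergeDecision(mcs[i].id, mcs[j].id, dist, merged))
            if merged:
                uf.union(i, j)

    components: dict[int, list[Metacluster]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(mcs[i])

    drafts = []
    for root in sorted(components):
        group = components[root]
        members = tuple(pc for mc in group for pc in mc.primary_members)
        if keep_shared_only and len(group) > 1:
            support: dict[Region, int] = {}
            for mc in group:
                for seed in set(mc.seeds):
                    support[seed] = support.get(seed, 0) + 1
            seeds = tuple(sorted(s for s, c in support.items() if c >= 2))
            if not seeds:
                seeds = flatten_seeds(members)
        else:
            seeds = flatten_seeds(members)
        drafts.append((members, seeds))
    drafts.sort(key=lambda t: (-len(t[1]), t[0][0].query_id, t[0][0].footprint.start))
    merged_mcs = [
        Metacluster(make_metacluster_id(k + 1), members, seeds)
        for k, (members, seeds) in enumerate(drafts)
    ]
    return merged_mcs, decisions


def deduplicate_seeds(mc: Metacluster, overlap_threshold: float = 0.8) -> Metacluster:
    """Collapse near-duplicate seed regions on the same protein.

    Seeds are visited longest-first (ties: smaller start); a seed is kept
    only if no already-kept seed on the same protein overlaps it with
    Jaccard above the threshold.
    """
    ordered = sorted(mc.seeds, key=lambda r: (-r.length, r.start, r.protein_id, r.end))
    kept: list[Region] = []
    kept_by_protein: dict[str, list[Region]] = {}
    for seed in ordered:
        dup = any(
            region_jaccard(seed, other) > overlap_threshold
            for other in kept_by_protein.get(seed.protein_id, ())
        )
        if not dup:
            kept.append(seed)
            kept_by_protein.setdefault(seed.protein_id, []).append(seed)
    return Metacluster(mc.id, mc.primary_members, tuple(sorted(kept)))


def mc_statistics(mc: Metacluster) -> tuple[int, float, float]:
    """Seed count, mean seed length, and population standard deviation."""
    if not mc.seeds:
        raise ValueError(f"metacluster {mc.id} has no seeds")
    lengths = [s.length for s in mc.seeds]
    n = len(lengths)
    mean = sum(lengths) / n
    var = sum((x - mean) ** 2 for x in lengths) / n
    return n, mean, math.sqrt(var)


def filter_metaclusters(
    metaclusters: Sequence[Metacluster],
    min_seeds: int = 50,
    min_mean_length: float = 50.0,
) -> list[Metacluster]:
    """Keep metaclusters with strictly more seeds and mean seed length than the bounds."""
    if min_seeds <= 0 or min_mean_length <= 0:
        raise ValueError("filter thresholds must be positive")
    kept = []
    for mc in metaclusters:
        count, mean, _ = mc_statistics(mc)
        if count > min_seeds and mean > min_mean_length:
            kept.append(mc)
    return kept
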