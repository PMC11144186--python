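"""Per-query clustering of aligned subject regions by query-footprint overlap.

For one query protein, every alignment hit covers some footprint along the
query. Hits whose footprints overlap heavily are density-clustered together;
each resulting group is a domain-like segment of the query carrying the
subject regions that aligned there.
"""
from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .dpc import DistanceMatrix, DPCParams, run_dpc
from .model import AlignmentHit, Region, interval_intersection_union


@dataclass(frozen=True)
class PrimaryCluster:
    """A query-anchored group of subject regions sharing a query footprint.

    ``members`` pairs each subject region with the query footprint of the
    hit it came from; ``footprint`` is the coordinate-wise median interval.
    """

    query_id: str
    members: tuple[tuple[Region, Region], ...]  # (subject_region, query_footprint)
    footprint: Region

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("primary cluster must have at least one member")
        for _, qfp in self.members:
            if qfp.protein_id != self.query_id:
                raise ValueError("member footprint is not on the query protein")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def subject_regions(self) -> tuple[Region, ...]:
        return tuple(m[0] for m in self.members)


def query_overlap_distance(qi: Region, qj: Region) -> float:
    """``1 - |qi ∩ qj| / |qi ∪ qj|`` for two footprints on the same query.

    Zero iff the footprints are identical, one iff they are disjoint.
    """
    inter, union = interval_intersection_union(qi, qj)
    return 1.0 - inter / union


def _median_footprint(query_id: str, footprints: Sequence[Region]) -> Region:
    starts = np.array([f.start for f in footprints])
    ends = np.array([f.end for f in footprints])
    start = int(round(float(np.median(starts))))
    end = int(round(float(np.median(ends))))
    return Region(query_id, start, max(start, end))


def _hit_sort_key(h: AlignmentHit):
    return (
        h.query_region.start,
        h.query_region.end,
        h.subject_id,
        h.subject_region.start,
        h.subject_region.end,
        -h.bit_score,
    )


def cluster_query(
    hits: Sequence[AlignmentHit],
    params: DPCParams = DPCParams(),
    min_members: int = 2,
) -> list[PrimaryCluster]:
    """Partition one query's hits into primary clusters.

    Hits are sorted canonically first, so the result does not depend on
    input order. Clusters smaller than ``min_members`` are discarded.
    """
    if not hits:
        raise ValueError("no hits for query")
    query_id = hits[0].query_id
    if any(h.query_id != query_id for h in hits):
        raise ValueError("hits do not share a single query id")
    hits = sorted(hits, key=_hit_sort_key)

    n = len(hits)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = query_overlap_distance(
                hits[i].query_region, hits[j].query_region
            )
    result = run_dpc(DistanceMatrix(d), params)

    groups: dict[int, list[AlignmentHit]] = defaultdict(list)
    for idx, lab in enumerate(result.assignment):
        groups[int(lab)].append(hits[idx])

    clusters = []
    for lab in sorted(groups):
        group = groups[lab]
        if len(group) < min_members:
            continue
        members = tuple((h.subject_region, h.query_region) for h in group)
        footprint = _median_footprint(query_id, [h.query_region for h in group])
        clusters.append(PrimaryCluster(query_id, members, footprint))
    clusters.sort(key=lambda c: (c.footprint.start, c.footprint.end))
    return clusters


def cluster_all_queries(
    hits: Iterable[AlignmentHit],
    params: DPCParams = DPCParams(),
    min_members: int = 2,
) -> list[PrimaryCluster]:
    """Run ``cluster_query`` independently for every query, queries sorted by id."""
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    clusters: list[PrimaryCluster] = []
    for qid in sorted(by_query):
        clusters.extend(cluster_query(by_query[qid], params, min_members))
    return clusters
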