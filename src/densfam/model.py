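"""Core domain types and 1-based inclusive interval algebra.

All residue coordinates in this package are 1-based and inclusive, matching
the tabular output of common local-alignment tools. Conversions happen only
at file-format boundaries, never internally.
"""
from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True, order=True)
class Region:
    """A residue interval ``[start, end]`` (1-based, inclusive) on a protein."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region on {self.protein_id!r}: "
                f"need 1 <= start <= end, got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return (
            self.protein_id == other.protein_id
            and self.start <= other.end
            and other.start <= self.end
        )


def interval_intersection_union(a: Region, b: Region) -> tuple[int, int]:
    """Residue counts of ``a ∩ b`` and ``a ∪ b`` for regions on one protein.

    The union counts only residues covered by at least one interval; residues
    in a gap between disjoint intervals are not counted.
    """
    if a.protein_id != b.protein_id:
        raise ValueError(
            f"regions on different proteins: {a.protein_id!r} vs {b.protein_id!r}"
        )
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    inter = max(inter, 0)
    union = a.length + b.length - inter
    return inter, union


def region_jaccard(a: Region, b: Region) -> float:
    """Jaccard similarity of two same-protein intervals, in [0, 1]."""
    inter, union = interval_intersection_union(a, b)
    return inter / union


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment pairing a query region with a subject region."""

    query_id: str
    subject_id: str
    query_region: Region
    subject_region: Region
    percent_identity: float
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.query_region.protein_id != self.query_id:
            raise ValueError("query_region is not on the query protein")
        if self.subject_region.protein_id != self.subject_id:
            raise ValueError("subject_region is not on the subject protein")
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")

    @property
    def is_self_hit(self) -> bool:
        return (
            self.query_id == self.subject_id
            and self.query_region == self.subject_region
        )


class ProteinSet(Mapping[str, str]):
    """An ordered, immutable mapping ``protein_id -> amino-acid sequence``."""

    def __init__(self, sequences: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = sequences.items() if isinstance(sequences, Mapping) else sequences
        self._seqs: dict[str, str] = {}
        for pid, seq in items:
            if pid in self._seqs:
                raise ValueError(f"duplicate protein id: {pid!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"invalid residues {sorted(bad)} in protein {pid!r}"
                )
            self._seqs[pid] = seq

    def __getitem__(self, pid: str) -> str:
        return self._seqs[pid]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __repr__(self) -> str:
        return f"ProteinSet({len(self)} proteins)"

    def length_of(self, pid: str) -> int:
        return len(self._seqs[pid])

    def total_residues(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def subsequence(self, region: Region) -> str:
        """Extract the residues covered by ``region`` (1-based inclusive)."""
        seq = self._seqs[region.protein_id]
        if region.end > len(seq):
            raise ValueError(
                f"region {region} extends past protein of length {len(seq)}"
            )
        return seq[region.start - 1 : region.end]


@dataclass(frozen=True)
class DomainAnnotation:
    """A reference family annotation on a protein region."""

    protein_id: str
    family_id: str
    clan_id: str | None
    region: Region

    def __post_init__(self) -> None:
        if self.region.protein_id != self.protein_id:
            raise ValueError("annotation region is not on the annotated protein")


@dataclass
class ResidueTracks:
    """Per-residue boolean property masks and per-protein transmembrane counts.

    Masks are keyed by protein id; a protein absent from a mask dict is
    treated as all-False by consumers.
    """

    low_complexity: dict[str, np.ndarray] = field(default_factory=dict)
    coiled_coil: dict[str, np.ndarray] = field(default_factory=dict)
    disordered: dict[str, np.ndarray] = field(default_factory=dict)
    tm_count: dict[str, int] = field(default_factory=dict)

    def validate_against(self, proteins: ProteinSet) -> None:
        for name, masks in (
            ("low_complexity", self.low_complexity),
            ("coiled_coil", self.coiled_coil),
            ("disordered", self.disordered),
        ):
            for pid, mask in masks.items():
                if pid in proteins and len(mask) != proteins.length_of(pid):
                    raise ValueError(
                        f"{name} mask length {len(mask)} != protein "
                        f"{pid!r} length {proteins.length_of(pid)}"
                    )
        for pid, n in self.tm_count.items():
            if n < 0:
                raise ValueError(f"negative tm_count for {pid!r}")
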