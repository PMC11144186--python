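"""Validation analytics against reference domain annotations.

Covers: dominant-architecture comparison per metacluster (exact / clan-level
/ sub- / super-architecture match percentages, boundary-overlap fractions
and the four-way equivalent/reduced/extended/shifted label), composition
labels from per-residue property tracks, residue/sequence coverage, and the
heavy-tail fit of the family-size distribution.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .meta import Metacluster
from .model import DomainAnnotation, ProteinSet, Region, ResidueTracks

UNK = "UNK"

Architecture = tuple[str, ...]


@dataclass(frozen=True)
class ComparisonRecord:
    """Per-metacluster reference-comparison metadata (one XML/TSV row)."""

    mc_id: str
    DA: Architecture | str  # UNK when no seed is annotated
    DAC: Architecture | str
    Percent_DA: float
    Percent_DAC: float
    Percent_DACF: float
    Percent_DACFA: float
    Label: str  # equivalent | reduced | extended | shifted | UNK
    Fred: float
    Fext: float
    Pfam_sequences: int

    def __post_init__(self) -> None:
        for name in ("Percent_DA", "Percent_DAC", "Percent_DACF", "Percent_DACFA"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.Label != UNK and self.Percent_DA < 50:
            raise ValueError("overlap label requires a dominant architecture >= 50%")


@dataclass(frozen=True)
class PropertyLabels:
    """Composition labels derived from residue property tracks."""

    mc_id: str
    frac_low_complexity: float
    frac_coiled_coil: float
    frac_disordered: float
    mean_tm: float
    labels: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class TailFit:
    """Pareto-tail fit of a size distribution (CCDF exponent)."""

    exponent: float
    scale: float
    threshold: float
    stderr: float


def _index_annotations(
    annotations: Iterable[DomainAnnotation],
) -> dict[str, list[DomainAnnotation]]:
    by_protein: dict[str, list[DomainAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_protein[ann.protein_id].append(ann)
    for anns in by_protein.values():
        anns.sort(key=lambda a: (a.region.start, a.region.end, a.family_id))
    return by_protein


def build_clan_map(annotations: Iterable[DomainAnnotation]) -> dict[str, str]:
    """Family → clan mapping; families without a clan map to themselves."""
    clan_map: dict[str, str] = {}
    for ann in annotations:
        clan_map[ann.family_id] = ann.clan_id if ann.clan_id else ann.family_id
    return clan_map


def seed_architecture(
    seed: Region,
    annotations_by_protein: dict[str, list[DomainAnnotation]],
) -> Architecture | None:
    """Ordered family ids of annotations overlapping the seed by >= 1 residue."""
    overlapping = [
        a
        for a in annotations_by_protein.get(seed.protein_id, ())
        if a.region.overlaps(seed)
    ]
    if not overlapping:
        return None
    return tuple(a.family_id for a in overlapping)


def dominant_architecture(
    mc: Metacluster,
    annotations_by_protein: dict[str, list[DomainAnnotation]],
    level: str = "family",
    clan_map: dict[str, str] | None = None,
) -> tuple[Architecture | str, float]:
    """Modal architecture among annotated seeds; percent over *all* seeds.

    Returns ``(UNK, 0.0)`` when no seed is annotated. Ties are broken by the
    lexicographically smaller architecture tuple.
    """
    if not mc.seeds:
        raise ValueError(f"metacluster {mc.id} has no seeds")
    if level not in ("family", "clan"):
        raise ValueError(f"level must be 'family' or 'clan', got {level!r}")
    archs = []
    for seed in mc.seeds:
        arch = seed_architecture(seed, annotations_by_protein)
        if arch is None:
            continue
        if level == "clan":
            cm = clan_map or {}
            arch = tuple(cm.get(f, f) for f in arch)
        archs.append(arch)
    if not archs:
        return UNK, 0.0
    counts = Counter(archs)
    best = min(counts, key=lambda a: (-counts[a], a))
    return best, 100.0 * counts[best] / len(mc.seeds)


def _is_contiguous_subsequence(small: Architecture, big: Architecture) -> bool:
    if len(small) > len(big):
        return False
    if not small:
        return True
    k = len(small)
    return any(big[i : i + k] == small for i in range(len(big) - k + 1))


def percent_variants(
    mc: Metacluster,
    da: Architecture,
    annotations_by_protein: dict[str, list[DomainAnnotation]],
    clan_map: dict[str, str] | None = None,
) -> tuple[float, float, float, float]:
    """Match percentages against the dominant architecture, loosest last.

    - exact family-level match;
    - exact match at clan level;
    - clan-level match or a contiguous sub-architecture of it (seeds with no
      annotation count as the empty sub-architecture);
    - additionally allowing super-architectures.

    The four values are monotone non-decreasing.
    """
    if da == UNK:
        raise ValueError("dominant architecture is UNK")
    cm = clan_map or {}
    dac = tuple(cm.get(f, f) for f in da)
    n = len(mc.seeds)
    n_da = n_dac = n_dacf = n_dacfa = 0
    for seed in mc.seeds:
        arch = seed_architecture(seed, annotations_by_protein)
        arch_f = arch if arch is not None else ()
        arch_c = tuple(cm.get(f, f) for f in arch_f)
        if arch_f == da:
            n_da += 1
        if arch_c == dac:
            n_dac += 1
        if arch_c == dac or _is_contiguous_subsequence(arch_c, dac):
            n_dacf += 1
        if (
            arch_c == dac
            or _is_contiguous_subsequence(arch_c, dac)
            or _is_contiguous_subsequence(dac, arch_c)
        ):
            n_dacfa += 1
    return tuple(100.0 * k / n for k in (n_da, n_dac, n_dacf, n_dacfa))  # type: ignore[return-value]


def overlap_fractions(
    mc: Metacluster,
    da: Architecture,
    annotations_by_protein: dict[str, list[DomainAnnotation]],
) -> tuple[float, float]:
    """Mean uncovered fractions between matching seeds and their reference span.

    For every seed whose family architecture equals the dominant one, the
    reference span is the interval from the first to the last residue of the
    annotations composing the architecture on that protein. The first value
    is the fraction of the span the seed leaves uncovered; the second is the
    fraction of the seed lying outside the span. Both are averaged over all
    matching seeds.
    """
    if da == UNK:
        raise ValueError("dominant architecture is UNK")
    freds, fexts = [], []
    for seed in mc.seeds:
        anns = [
            a
            for a in annotations_by_protein.get(seed.protein_id, ())
            if a.region.overlaps(seed)
        ]
        if tuple(a.family_id for a in anns) != tuple(da):
            continue
        span = Region(
            seed.protein_id,
            min(a.region.start for a in anns),
            max(a.region.end for a in anns),
        )
        inter = max(0, min(span.end, seed.end) - max(span.start, seed.start) + 1)
        freds.append((span.length - inter) / span.length)
        fexts.append((seed.length - inter) / seed.length)
    if not freds:
        raise ValueError(f"no seed of {mc.id} matches the dominant architecture")
    return float(np.mean(freds)), float(np.mean(fexts))


def classify_overlap(fred: float, fext: float, threshold: float = 0.2) -> str:
    """Four-way overlap label from the two uncovered fractions.

    Both within the threshold (inclusive) → equivalent; both above →
    shifted; only the reference under-covered → reduced; only the cluster
    over-extending → extended.
    """
    if not (0 <= fred <= 1 and 0 <= fext <= 1):
        raise ValueError(f"fractions must lie in [0, 1], got ({fred}, {fext})")
    red = fred > threshold
    ext = fext > threshold
    if red and ext:
        return "shifted"
    if red:
        return "reduced"
    if ext:
        return "extended"
    return "equivalent"


def compare_metacluster(
    mc: Metacluster,
    annotations: Iterable[DomainAnnotation] | dict[str, list[DomainAnnotation]],
    clan_map: dict[str, str] | None = None,
    da_percent_min: float = 50.0,
) -> ComparisonRecord:
    """Full Table-style comparison record for one metacluster."""
    if isinstance(annotations, dict):
        by_protein = annotations
    else:
        annotations = list(annotations)
        by_protein = _index_annotations(annotations)
        if clan_map is None:
            clan_map = build_clan_map(annotations)
    cm = clan_map or {}

    da, pct = dominant_architecture(mc, by_protein, level="family")
    n_annotated = sum(
        1 for s in mc.seeds if seed_architecture(s, by_protein) is not None
    )
    if da == UNK:
        return ComparisonRecord(
            mc.id, UNK, UNK, 0.0, 0.0, 0.0, 0.0, UNK, 0.0, 0.0, n_annotated
        )
    p_da, p_dac, p_dacf, p_dacfa = percent_variants(mc, da, by_protein, cm)
    fred, fext = overlap_fractions(mc, da, by_protein)
    label = classify_overlap(fred, fext) if pct >= da_percent_min else UNK
    dac = tuple(cm.get(f, f) for f in da)
    return ComparisonRecord(
        mc.id, da, dac, p_da, p_dac, p_dacf, p_dacfa, label, fred, fext, n_annotated
    )


def composition_labels(
    mc: Metacluster,
    tracks: ResidueTracks,
    lc_threshold: float = 0.10,
    cc_threshold: float = 0.10,
    dis_threshold: float = 0.50,
    tm_threshold: float = 2.0,
) -> PropertyLabels:
    """Pooled property fractions over all seed residues, plus the labels.

    Low-complexity and coiled-coil labels require strictly more than their
    thresholds; disordered strictly more than its; the transmembrane label
    is inclusive at the mean-count threshold. Proteins missing from a track
    contribute all-False residues.
    """
    total = 0
    counts = {"lc": 0, "cc": 0, "dis": 0}
    tms = []
    for seed in mc.seeds:
        total += seed.length
        sl = slice(seed.start - 1, seed.end)
        for key, masks in (
            ("lc", tracks.low_complexity),
            ("cc", tracks.coiled_coil),
            ("dis", tracks.disordered),
        ):
            mask = masks.get(seed.protein_id)
            if mask is not None:
                counts[key] += int(np.count_nonzero(mask[sl]))
        tms.append(tracks.tm_count.get(seed.protein_id, 0))
    if total == 0:
        raise ValueError(f"metacluster {mc.id} has no seed residues")
    frac_lc = counts["lc"] / total
    frac_cc = counts["cc"] / total
    frac_dis = counts["dis"] / total
    mean_tm = float(np.mean(tms))
    labels = set()
    if frac_lc > lc_threshold:
        labels.add("LowComplexity")
    if frac_cc > cc_threshold:
        labels.add("CoiledCoil")
    if frac_dis > dis_threshold:
        labels.add("Disordered")
    if mean_tm >= tm_threshold:
        labels.add("Transmembrane")
    return PropertyLabels(mc.id, frac_lc, frac_cc, frac_dis, mean_tm, frozenset(labels))


def coverage_stats(
    members: Iterable[Region],
    proteins: ProteinSet,
) -> tuple[float, float]:
    """Fraction of residues and of sequences covered by the member regions.

    Overlapping regions count each residue once. Returns fractions in [0, 1].
    """
    by_protein: dict[str, list[Region]] = defaultdict(list)
    for r in members:
        if r.protein_id not in proteins:
            raise ValueError(f"member region on unknown protein {r.protein_id!r}")
        by_protein[r.protein_id].append(r)
    covered_residues = 0
    for pid, regions in by_protein.items():
        regions.sort(key=lambda r: (r.start, r.end))
        cur_start, cur_end = regions[0].start, regions[0].end
        for r in regions[1:]:
            if r.start <= cur_end + 1:
                cur_end = max(cur_end, r.end)
            else:
                covered_residues += cur_end - cur_start + 1
                cur_start, cur_end = r.start, r.end
        covered_residues += cur_end - cur_start + 1
    total_res = proteins.total_residues()
    residue_cov = covered_residues / total_res if total_res else 0.0
    sequence_cov = len(by_protein) / len(proteins) if len(proteins) else 0.0
    return residue_cov, sequence_cov


def size_ccdf(sizes: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical complementary CDF ``P(X >= x)`` at each distinct size."""
    xs = np.sort(np.asarray(sizes, dtype=float))
    n = len(xs)
    out = []
    for x in np.unique(xs):
        out.append((float(x), float(np.sum(xs >= x) / n)))
    return out


def fit_pareto_tail(
    sizes: Sequence[float],
    threshold: float | None = None,
    min_tail: int = 30,
) -> TailFit:
    """Maximum-likelihood power-law exponent of the size-distribution tail.

    Uses the Hill estimator on sizes at or above the threshold (default: the
    sample minimum): ``alpha = n / sum(log(x_i / threshold))`` with standard
    error ``alpha / sqrt(n)``. This is the CCDF exponent of the equivalent
    generalized-Pareto tail (shape ``xi = 1/alpha``).
    """
    xs = np.asarray(sizes, dtype=float)
    if threshold is None:
        threshold = float(xs.min())
    tail = xs[xs >= threshold]
    n = len(tail)
    if n < min_tail:
        raise ValueError(f"only {n} sizes at or above threshold {threshold}; need {min_tail}")
    log_sum = float(np.sum(np.log(tail / threshold)))
    if log_sum <= 0:
        raise ValueError("degenerate size distribution: no spread above the threshold")
    alpha = n / log_sum
    return TailFit(
        exponent=alpha,
        scale=float(threshold),
        threshold=float(threshold),
        stderr=alpha / math.sqrt(n),
    )


def size_ccdf_and_tail_fit(
    sizes: Sequence[float],
    threshold: float | None = None,
) -> tuple[list[tuple[float, float]], TailFit]:
    """Empirical CCDF plus the Pareto-tail fit of the same sizes."""
    return size_ccdf(sizes), fit_pareto_tail(sizes, threshold)


def index_annotations(
    annotations: Iterable[DomainAnnotation],
) -> dict[str, list[DomainAnnotation]]:
    """Public wrapper: group annotations by protein, sorted by start."""
    return _index_annotations(annotations)
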