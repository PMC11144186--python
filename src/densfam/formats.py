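"""Readers and writers for every external format the pipeline touches.

Plain-text formats only: FASTA, the 12-column tab-separated local-alignment
table, TSV domain annotations and residue tracks, TSV pipeline
intermediates, and the per-metacluster XML report.
"""
from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from collections import defaultdict
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .compare import UNK, Architecture, ComparisonRecord, PropertyLabels
from .meta import Metacluster
from .model import (
    AlignmentHit,
    DomainAnnotation,
    ProteinSet,
    Region,
    ResidueTracks,
)
from .primary import PrimaryCluster

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> ProteinSet:
    """Parse a FASTA file into a ProteinSet.

    The protein id is the header token before the first whitespace;
    sequences are uppercased. Duplicate ids and empty files are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            pid = header.split()[0] if header.split() else header
            if pid in seen:
                raise ValueError(f"duplicate protein id in {path}: {pid!r}")
            seen.add(pid)
            records.append((pid, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return ProteinSet(records)


def write_fasta(
    proteins: ProteinSet | Iterable[tuple[str, str]],
    path: str | Path,
    width: int = 60,
) -> None:
    items = proteins.items() if isinstance(proteins, ProteinSet) else proteins
    with open(path, "w") as fh:
        for pid, seq in items:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_seed_fasta(
    mc: Metacluster, proteins: ProteinSet, path: str | Path
) -> None:
    """Seed subsequences with ``proteinid/start-end`` headers."""
    write_fasta(
        ((f"{s.protein_id}/{s.start}-{s.end}", proteins.subsequence(s)) for s in mc.seeds),
        path,
    )


# ------------------------------------------------------------- alignment table

_N_ALN_COLS = 12


def read_alignment_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tab-separated local-alignment table.

    Columns: query id, subject id, % identity, alignment length, mismatches,
    gap opens, q.start, q.end, s.start, s.end, E-value, bit score.
    Full self-hits (query == subject with identical regions) are excluded.
    """
    hits: list[AlignmentHit] = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _N_ALN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_N_ALN_COLS} columns, got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if qs > qe:
                raise ValueError(
                    f"{path}:{lineno}: q.start {qs} > q.end {qe} (forward-only)"
                )
            if ss > se:
                raise ValueError(
                    f"{path}:{lineno}: s.start {ss} > s.end {se} (forward-only)"
                )
            hit = AlignmentHit(
                qid, sid, Region(qid, qs, qe), Region(sid, ss, se), pident, evalue, bits
            )
            if hit.is_self_hit:
                n_self += 1
                continue
            hits.append(hit)
    if n_self:
        log.info("excluded %d self-hit(s) from %s", n_self, path)
    return hits


def write_alignment_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (mismatch/gap columns set to 0/0
    when unknown)."""
    with open(path, "w") as fh:
        for h in hits:
            aln_len = max(h.query_region.length, h.subject_region.length)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        aln_len,
                        0,
                        0,
                        h.query_region.start,
                        h.query_region.end,
                        h.subject_region.start,
                        h.subject_region.end,
                        f"{h.evalue:.2e}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


# ----------------------------------------------------------------- annotations

def read_annotations(path: str | Path) -> list[DomainAnnotation]:
    """TSV columns: protein_id, family_id, clan_id ('-' or empty = none), start, end."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            pid, fam, clan, start, end = fields
            clan_id = None if clan in ("", "-", "NONE") else clan
            out.append(
                DomainAnnotation(pid, fam, clan_id, Region(pid, int(start), int(end)))
            )
    return out


def write_annotations(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily_id\tclan_id\tstart\tend\n")
        for a in annotations:
            clan = a.clan_id if a.clan_id else "-"
            fh.write(f"{a.protein_id}\t{a.family_id}\t{clan}\t{a.region.start}\t{a.region.end}\n")


# ---------------------------------------------------------------- residue tracks

def _mask_to_str(mask: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in mask)


def read_tracks(path: str | Path) -> ResidueTracks:
    """TSV columns: protein_id, low_complexity, coiled_coil, disordered
    (masks as 0/1 strings), tm_count."""
    tracks = ResidueTracks()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            pid, lc, cc, dis, tm = fields
            lengths = {len(lc), len(cc), len(dis)}
            if len(lengths) != 1:
                raise ValueError(f"{path}:{lineno}: mask lengths differ for {pid!r}")
            tracks.low_complexity[pid] = np.frombuffer(lc.encode(), dtype="S1") == b"1"
            tracks.coiled_coil[pid] = np.frombuffer(cc.encode(), dtype="S1") == b"1"
            tracks.disordered[pid] = np.frombuffer(dis.encode(), dtype="S1") == b"1"
            tracks.tm_count[pid] = int(tm)
    return tracks


def write_tracks(tracks: ResidueTracks, path: str | Path) -> None:
    pids = sorted(
        set(tracks.low_complexity)
        | set(tracks.coiled_coil)
        | set(tracks.disordered)
        | set(tracks.tm_count)
    )
    with open(path, "w") as fh:
        fh.write("protein_id\tlow_complexity\tcoiled_coil\tdisordered\ttm_count\n")
        for pid in pids:
            lc = tracks.low_complexity.get(pid)
            length = len(lc) if lc is not None else 0
            for masks in (tracks.coiled_coil, tracks.disordered):
                m = masks.get(pid)
                if m is not None:
                    length = max(length, len(m))
            zeros = np.zeros(length, dtype=bool)
            fh.write(
                "\t".join(
                    (
                        pid,
                        _mask_to_str(tracks.low_complexity.get(pid, zeros)),
                        _mask_to_str(tracks.coiled_coil.get(pid, zeros)),
                        _mask_to_str(tracks.disordered.get(pid, zeros)),
                        str(tracks.tm_count.get(pid, 0)),
                    )
                )
                + "\n"
            )


# ------------------------------------------------------- pipeline intermediates

def write_primary_clusters(
    clusters: Sequence[PrimaryCluster], path: str | Path, header_comment: str = ""
) -> None:
    """One row per member: query, cluster index within query, footprint,
    subject region and the member's own query footprint."""
    index_within: dict[str, int] = defaultdict(int)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "query_id\tcluster_index\tfootprint_start\tfootprint_end\t"
            "subject_id\tsubject_start\tsubject_end\tqfp_start\tqfp_end\n"
        )
        for pc in clusters:
            idx = index_within[pc.query_id]
            index_within[pc.query_id] += 1
            for subj, qfp in sorted(pc.members):
                fh.write(
                    f"{pc.query_id}\t{idx}\t{pc.footprint.start}\t{pc.footprint.end}\t"
                    f"{subj.protein_id}\t{subj.start}\t{subj.end}\t{qfp.start}\t{qfp.end}\n"
                )


def read_primary_clusters(path: str | Path) -> list[PrimaryCluster]:
    rows: dict[tuple[str, int], dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id\t"):
                continue
            (qid, idx, fs, fe, sid, ss, se, qs, qe) = line.split("\t")
            key = (qid, int(idx))
            entry = rows.setdefault(
                key, {"footprint": Region(qid, int(fs), int(fe)), "members": []}
            )
            entry["members"].append(
                (Region(sid, int(ss), int(se)), Region(qid, int(qs), int(qe)))
            )
    return [
        PrimaryCluster(qid, tuple(entry["members"]), entry["footprint"])
        for (qid, _), entry in sorted(rows.items())
    ]


def write_metacluster_membership(
    metaclusters: Sequence[Metacluster], path: str | Path, header_comment: str = ""
) -> None:
    """Seed table: one row per seed region, keyed by metacluster id."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("mc_id\tprotein_id\tstart\tend\n")
        for mc in metaclusters:
            for s in mc.seeds:
                fh.write(f"{mc.id}\t{s.protein_id}\t{s.start}\t{s.end}\n")


# ------------------------------------------------------------------------- XML

_COMPARISON_FIELDS = (
    "DA",
    "DAC",
    "Percent_DA",
    "Percent_DAC",
    "Percent_DACF",
    "Percent_DACFA",
    "Label",
    "Fred",
    "Fext",
    "Pfam_sequences",
)


def _arch_to_str(arch: Architecture | str) -> str:
    if isinstance(arch, str):
        return arch
    return " ".join(arch)


def _str_to_arch(s: str) -> Architecture | str:
    if s == UNK:
        return UNK
    return tuple(s.split())


def write_metacluster_xml(
    metaclusters: Sequence[Metacluster],
    comparisons: dict[str, ComparisonRecord],
    property_labels: dict[str, PropertyLabels],
    path: str | Path,
    seed_stats: dict[str, tuple[int, float, float]] | None = None,
    config_hash: str = "",
) -> None:
    """Write the per-metacluster XML report.

    Comparison fields are emitted with their canonical names; a metacluster
    missing from ``comparisons`` gets an all-UNK record, mirroring the
    convention that an absent dominant architecture is reported as UNK.
    """
    from .mergefilter import mc_statistics

    root = ET.Element("metaclusters", count=str(len(metaclusters)))
    if config_hash:
        root.set("config_hash", config_hash)
    for mc in metaclusters:
        el = ET.SubElement(root, "metacluster", id=mc.id)
        if seed_stats and mc.id in seed_stats:
            n, mean, sd = seed_stats[mc.id]
        else:
            n, mean, sd = mc_statistics(mc)
        seeds_el = ET.SubElement(
            el,
            "seeds",
            count=str(n),
            mean_length=repr(mean),
            sd_length=repr(sd),
        )
        for s in mc.seeds:
            ET.SubElement(
                seeds_el,
                "seed",
                protein=s.protein_id,
                start=str(s.start),
                end=str(s.end),
            )
        props = property_labels.get(mc.id)
        props_el = ET.SubElement(el, "properties")
        if props is not None:
            ET.SubElement(props_el, "low_complexity_fraction").text = repr(
                props.frac_low_complexity
            )
            ET.SubElement(props_el, "coiled_coil_fraction").text = repr(
                props.frac_coiled_coil
            )
            ET.SubElement(props_el, "disordered_fraction").text = repr(
                props.frac_disordered
            )
            ET.SubElement(props_el, "mean_transmembrane").text = repr(props.mean_tm)
            ET.SubElement(props_el, "labels").text = ",".join(sorted(props.labels))
        comp = comparisons.get(mc.id)
        comp_el = ET.SubElement(el, "comparison")
        if comp is None:
            comp = ComparisonRecord(mc.id, UNK, UNK, 0.0, 0.0, 0.0, 0.0, UNK, 0.0, 0.0, 0)
        values = {
            "DA": _arch_to_str(comp.DA),
            "DAC": _arch_to_str(comp.DAC),
            "Percent_DA": repr(comp.Percent_DA),
            "Percent_DAC": repr(comp.Percent_DAC),
            "Percent_DACF": repr(comp.Percent_DACF),
            "Percent_DACFA": repr(comp.Percent_DACFA),
            "Label": comp.Label,
            "Fred": repr(comp.Fred),
            "Fext": repr(comp.Fext),
            "Pfam_sequences": str(comp.Pfam_sequences),
        }
        for name in _COMPARISON_FIELDS:
            ET.SubElement(comp_el, name).text = values[name]
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_metacluster_xml(
    path: str | Path,
) -> tuple[
    list[Metacluster],
    dict[str, ComparisonRecord],
    dict[str, PropertyLabels],
    dict[str, tuple[int, float, float]],
]:
    """Parse the XML report back into in-memory records.

    Metaclusters round-trip with their seed regions only (primary-cluster
    provenance is not serialized in the XML); ``primary_members`` is left
    as a single placeholder cluster spanning the first seed.
    """
    from .primary import PrimaryCluster as PC

    tree = ET.parse(path)
    root = tree.getroot()
    mcs: list[Metacluster] = []
    comparisons: dict[str, ComparisonRecord] = {}
    props: dict[str, PropertyLabels] = {}
    stats: dict[str, tuple[int, float, float]] = {}
    for el in root.findall("metacluster"):
        mc_id = el.get("id")
        seeds_el = el.find("seeds")
        seeds = tuple(
            Region(s.get("protein"), int(s.get("start")), int(s.get("end")))
            for s in seeds_el.findall("seed")
        )
        stats[mc_id] = (
            int(seeds_el.get("count")),
            float(seeds_el.get("mean_length")),
            float(seeds_el.get("sd_length")),
        )
        placeholder = PC(
            seeds[0].protein_id, ((seeds[0], seeds[0]),), seeds[0]
        ) if seeds else None
        mcs.append(Metacluster(mc_id, (placeholder,), seeds))
        comp_el = el.find("comparison")
        comparisons[mc_id] = ComparisonRecord(
            mc_id,
            _str_to_arch(comp_el.findtext("DA")),
            _str_to_arch(comp_el.findtext("DAC")),
            float(comp_el.findtext("Percent_DA")),
            float(comp_el.findtext("Percent_DAC")),
            float(comp_el.findtext("Percent_DACF")),
            float(comp_el.findtext("Percent_DACFA")),
            comp_el.findtext("Label"),
            float(comp_el.findtext("Fred")),
            float(comp_el.findtext("Fext")),
            int(comp_el.findtext("Pfam_sequences")),
        )
        props_el = el.find("properties")
        if props_el is not None and props_el.findtext("low_complexity_fraction") is not None:
            labels_text = props_el.findtext("labels") or ""
            props[mc_id] = PropertyLabels(
                mc_id,
                float(props_el.findtext("low_complexity_fraction")),
                float(props_el.findtext("coiled_coil_fraction")),
                float(props_el.findtext("disordered_fraction")),
                float(props_el.findtext("mean_transmembrane")),
                frozenset(x for x in labels_text.split(",") if x),
            )
    return mcs, comparisons, props, stats
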