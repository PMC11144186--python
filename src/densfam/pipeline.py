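"""End-to-end stage orchestration over serialized TSV intermediates.

Each stage is a plain function reading and writing inspectable text files,
so the single-shot runner and the per-stage CLI subcommands share one code
path and produce identical outputs.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

from . import formats
from .align import all_vs_all, blosum62_scoring
from .compare import (
    build_clan_map,
    compare_metacluster,
    composition_labels,
    coverage_stats,
    fit_pareto_tail,
    index_annotations,
    size_ccdf,
)
from .config import PipelineConfig
from .dpc import DPCParams
from .mergefilter import (
    deduplicate_seeds,
    filter_metaclusters,
    mc_statistics,
    merge_metaclusters,
)
from .meta import metacluster as run_metaclustering
from .model import ProteinSet
from .primary import cluster_all_queries
from .profiles import NullBackend, build_family_artifacts, greedy_identity_prune

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def dpc_params(config: PipelineConfig) -> DPCParams:
    return DPCParams(
        dc=None if config.dc <= 0 else config.dc,
        kernel=config.kernel,
        rho_min=config.rho_min,
        delta_min=config.delta_min,
    )


def run_in_memory(hits, config: PipelineConfig):
    """Clustering stages without file I/O; returns per-stage results.

    Output keys: ``primary`` (primary clusters), ``metaclusters`` (raw),
    ``merged`` (post-merge, seed-deduplicated), ``filtered`` (post size
    filter), ``decisions`` (merge log).
    """
    params = dpc_params(config)
    primary = cluster_all_queries(hits, params, config.min_members)
    if not primary:
        return {"primary": [], "metaclusters": [], "merged": [], "filtered": [], "decisions": []}
    mcs = run_metaclustering(primary, params, config.member_overlap)
    merged, decisions = merge_metaclusters(
        mcs, config.merge_threshold, config.member_overlap, config.keep_shared_only
    )
    merged = [deduplicate_seeds(mc, config.seed_dedup_overlap) for mc in merged]
    filtered = filter_metaclusters(merged, config.min_seeds, config.min_mean_length)
    return {
        "primary": primary,
        "metaclusters": mcs,
        "merged": merged,
        "filtered": filtered,
        "decisions": decisions,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write all artifacts into ``outdir``.

    Any stage failure writes a FAILED marker naming the stage and re-raises;
    partial outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.write(outdir / "config.txt")
    log_lines: list[str] = [f"config_hash={chash}"]
    stage = "setup"
    try:
        stage = "input"
        if not config.fasta:
            raise ValueError("config.fasta is required")
        proteins = formats.read_fasta(config.fasta)
        log_lines.append(f"proteins={len(proteins)}")

        stage = "align"
        if config.alignments:
            if not Path(config.alignments).exists():
                raise FileNotFoundError(f"alignment table not found: {config.alignments}")
            hits = formats.read_alignment_table(config.alignments)
        else:
            hits = all_vs_all(
                proteins,
                blosum62_scoring(),
                score_min=config.score_min,
                max_hsps=config.max_hsps,
            )
            formats.write_alignment_table(hits, outdir / "alignments.tsv")
        log_lines.append(f"hits={len(hits)}")

        stage = "primary"
        params = dpc_params(config)
        primary = cluster_all_queries(hits, params, config.min_members)
        formats.write_primary_clusters(
            primary, outdir / "primary_clusters.tsv", f"config_hash={chash}"
        )
        log_lines.append(f"primary_clusters={len(primary)}")
        if not primary:
            raise ValueError("no primary clusters survived; nothing to metacluster")

        stage = "metacluster"
        mcs = run_metaclustering(primary, params, config.member_overlap)
        formats.write_metacluster_membership(
            mcs, outdir / "metaclusters_raw.tsv", f"config_hash={chash}"
        )
        log_lines.append(f"metaclusters_raw={len(mcs)}")

        stage = "merge"
        merged, decisions = merge_metaclusters(
            mcs, config.merge_threshold, config.member_overlap, config.keep_shared_only
        )
        merged = [deduplicate_seeds(mc, config.seed_dedup_overlap) for mc in merged]
        with open(outdir / "merge_log.tsv", "w") as fh:
            fh.write(f"# config_hash={chash}\nmc_a\tmc_b\tavg_distance\tmerged\n")
            for d in decisions:
                fh.write(f"{d.mc_a}\t{d.mc_b}\t{d.avg_distance:.6f}\t{int(d.merged)}\n")
        formats.write_metacluster_membership(
            merged, outdir / "metaclusters_merged.tsv", f"config_hash={chash}"
        )
        log_lines.append(f"metaclusters_merged={len(merged)}")

        stage = "filter"
        filtered = filter_metaclusters(merged, config.min_seeds, config.min_mean_length)
        formats.write_metacluster_membership(
            filtered, outdir / "metaclusters_filtered.tsv", f"config_hash={chash}"
        )
        log_lines.append(f"metaclusters_filtered={len(filtered)}")
        # Reporting set: the filtered list when non-empty, otherwise the
        # merged list (small synthetic runs rarely clear publication-scale
        # size filters).
        report = filtered if filtered else merged
        log_lines.append(f"reporting_set={'filtered' if filtered else 'merged'}")

        stage = "seeds"
        seeds_dir = outdir / "seeds"
        seeds_dir.mkdir(exist_ok=True)
        for mc in report:
            formats.write_seed_fasta(mc, proteins, seeds_dir / f"{mc.id}.fasta")

        stage = "prune"
        pruned_dir = outdir / "pruned_seeds"
        pruned_dir.mkdir(exist_ok=True)
        backend = NullBackend()
        for mc in report:
            seqs = {
                f"{s.protein_id}/{s.start}-{s.end}": proteins.subsequence(s)
                for s in mc.seeds
            }
            pruned = greedy_identity_prune(seqs, config.prune_identity, mc.id)
            formats.write_fasta(
                ((name, seqs[name]) for name in pruned.representatives),
                pruned_dir / f"{mc.id}.fasta",
            )
            build_family_artifacts(
                pruned,
                seqs,
                backend,
                pruned_dir / f"{mc.id}.msa.fasta",
                pruned_dir / f"{mc.id}.hmm",
            )

        stage = "compare"
        comparisons = {}
        if config.annotations:
            if not Path(config.annotations).exists():
                raise FileNotFoundError(f"annotation file not found: {config.annotations}")
            annotations = formats.read_annotations(config.annotations)
            by_protein = index_annotations(annotations)
            clan_map = build_clan_map(annotations)
            for mc in report:
                comparisons[mc.id] = compare_metacluster(mc, by_protein, clan_map)
            write_comparison_tsv(comparisons, report, outdir / "comparison.tsv", chash)

        stage = "label"
        props = {}
        if config.tracks:
            if not Path(config.tracks).exists():
                raise FileNotFoundError(f"tracks file not found: {config.tracks}")
            tracks = formats.read_tracks(config.tracks)
            for mc in report:
                props[mc.id] = composition_labels(mc, tracks)
            write_properties_tsv(props, report, outdir / "properties.tsv", chash)

        stage = "coverage"
        members = [s for mc in report for s in mc.seeds]
        res_cov, seq_cov = coverage_stats(members, proteins)
        log_lines.append(f"residue_coverage={res_cov:.4f}")
        log_lines.append(f"sequence_coverage={seq_cov:.4f}")

        stage = "xml"
        stats = {mc.id: mc_statistics(mc) for mc in report}
        formats.write_metacluster_xml(
            report, comparisons, props, outdir / "metaclusters.xml", stats, chash
        )

        stage = "tailfit"
        sizes = [mc.seed_count for mc in report]
        try:
            fit = fit_pareto_tail(sizes)
            ccdf = size_ccdf(sizes)
            with open(outdir / "size_ccdf.tsv", "w") as fh:
                fh.write(f"# config_hash={chash}\n")
                fh.write(
                    f"# pareto_exponent={fit.exponent:.4f} stderr={fit.stderr:.4f} "
                    f"threshold={fit.threshold:g}\n"
                )
                fh.write("size\tccdf\n")
                for x, p in ccdf:
                    fh.write(f"{x:g}\t{p:.6g}\n")
            log_lines.append(f"pareto_exponent={fit.exponent:.4f}")
        except ValueError as exc:
            log_lines.append(f"tail_fit=skipped ({exc})")

        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        return outdir
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + f"\nFAILED at stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc


def write_comparison_tsv(comparisons, metaclusters, path, chash: str = "") -> None:
    with open(path, "w") as fh:
        if chash:
            fh.write(f"# config_hash={chash}\n")
        fh.write(
            "mc_id\tDA\tDAC\tPercent_DA\tPercent_DAC\tPercent_DACF\tPercent_DACFA\t"
            "Label\tFred\tFext\tPfam_sequences\n"
        )
        for mc in metaclusters:
            c = comparisons[mc.id]
            da = c.DA if isinstance(c.DA, str) else " ".join(c.DA)
            dac = c.DAC if isinstance(c.DAC, str) else " ".join(c.DAC)
            fh.write(
                f"{c.mc_id}\t{da}\t{dac}\t{c.Percent_DA:.2f}\t{c.Percent_DAC:.2f}\t"
                f"{c.Percent_DACF:.2f}\t{c.Percent_DACFA:.2f}\t{c.Label}\t"
                f"{c.Fred:.4f}\t{c.Fext:.4f}\t{c.Pfam_sequences}\n"
            )


def write_properties_tsv(props, metaclusters, path, chash: str = "") -> None:
    with open(path, "w") as fh:
        if chash:
            fh.write(f"# config_hash={chash}\n")
        fh.write(
            "mc_id\tfrac_low_complexity\tfrac_coiled_coil\tfrac_disordered\t"
            "mean_tm\tlabels\n"
        )
        for mc in metaclusters:
            p = props[mc.id]
            fh.write(
                f"{p.mc_id}\t{p.frac_low_complexity:.4f}\t{p.frac_coiled_coil:.4f}\t"
                f"{p.frac_disordered:.4f}\t{p.mean_tm:.4f}\t{','.join(sorted(p.labels))}\n"
            )
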