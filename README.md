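# densfam

Unsupervised protein-family discovery by two-stage density-peak clustering
of locally aligned regions, plus the validation analytics to characterize
the resulting families against reference domain annotations.

The pipeline consumes an all-versus-all local-alignment table (12-column
tab-separated, `blastp -outfmt 6` dialect) over a set of protein sequences
and proceeds in stages:

1. **Primary clustering** — for each query protein, alignment hits are
   grouped by the overlap of their footprints along the query
   (`1 − |∩|/|∪|` interval distance), yielding domain-like segments.
2. **Metaclustering** — primary clusters from different queries are
   clustered by how many subject regions they share (members matched
   one-to-one at Jaccard overlap > 0.8, normalized by the smaller cluster).
3. **Merging and filtering** — metaclusters at average pairwise distance
   < 0.9 are merged (connected components), near-duplicate seeds are
   collapsed, and only metaclusters with > 50 seeds and mean seed length
   > 50 residues pass the final filter.
4. **Post-processing** — greedy identity pruning of seeds at 60%,
   plus pluggable wrappers for external MSA/profile-HMM tools (a null
   backend keeps everything runnable with zero external installs).

Validation analytics include dominant-architecture comparison against
reference annotations (exact / clan-level / sub- / super-architecture match
percentages, boundary-overlap fractions and the four-way
equivalent/reduced/extended/shifted label), composition labels from
low-complexity / coiled-coil / disorder / transmembrane tracks, residue and
sequence coverage, and a generalized-Pareto tail fit of the family-size
distribution.

A synthetic-proteome generator with planted domain families and a built-in
Smith–Waterman aligner (numba-accelerated, affine gaps, multiple HSPs per
pair via iterated masking) makes the whole pipeline runnable and testable
offline.

## Command line

One executable, one subcommand per stage plus an end-to-end runner:

```sh
# generate a synthetic fixture set with planted families
densfam synth --families 5 --proteins 50 --seed 1 --out fixtures/

# one-shot pipeline (computes alignments with the built-in aligner)
densfam run --fasta fixtures/proteins.fasta \
            --annotations fixtures/annotations.tsv \
            --tracks fixtures/tracks.tsv \
            --out results/

# or stage by stage over inspectable TSV intermediates
densfam align --fasta fixtures/proteins.fasta --out aln.tsv
densfam primary --alignments aln.tsv --out pc.tsv
densfam metacluster --primary pc.tsv --out mc.tsv
densfam merge --primary pc.tsv --metaclusters mc.tsv --out merged.tsv
densfam filter --primary pc.tsv --metaclusters merged.tsv --out kept.tsv
densfam prune --fasta fixtures/proteins.fasta --primary pc.tsv \
              --metaclusters kept.tsv --out pruned/
densfam compare --annotations fixtures/annotations.tsv --primary pc.tsv \
                --metaclusters kept.tsv --out comparison.tsv
densfam label --tracks fixtures/tracks.tsv --primary pc.tsv \
              --metaclusters kept.tsv --out properties.tsv
densfam tailfit --metaclusters merged.tsv --out ccdf.tsv
```

The run directory contains the per-stage TSVs, per-metacluster seed and
pruned-seed FASTA files, the comparison/property tables, a consolidated
XML report, the size-distribution CCDF with its tail fit, and a run log;
every output names the configuration hash that produced it. Configuration
is a flat `key=value` file (`--config`) mirroring `PipelineConfig`; all
method constants (overlap 0.8, merge threshold 0.9, size/length filters,
prune identity 0.60, E-value thresholds 0.03/0.01) are defaults there.

Exit codes: `0` success, `2` input error, `3` stage failure.

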