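"""Seed pruning and pluggable hand-off to external MSA / profile-HMM tools.

Pruning re-implements greedy incremental identity clustering at desk scale:
sequences are visited longest-first and join the first representative they
match at or above the identity threshold, where identity is the best
ungapped sliding-window match count divided by the shorter length.

External aligners and profile searches are wrapped behind a backend
interface with a null implementation, so the package builds and tests with
no external installs; real backends shell out to tools found on PATH.
"""
from __future__ import annotations

import shutil
import subprocess
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from .model import Region


@dataclass(frozen=True)
class PrunedSeedSet:
    mc_id: str
    representatives: tuple[str, ...]  # seed names, subset of the input keys
    identity_threshold: float


def pairwise_identity(a: str, b: str) -> float:
    """Best ungapped sliding-offset match count over the shorter length."""
    if not a or not b:
        return 0.0
    if len(a) < len(b):
        a, b = b, a
    best = 0
    la, lb = len(a), len(b)
    for offset in range(-lb + 1, la):
        matches = 0
        start = max(0, -offset)
        stop = min(lb, la - offset)
        for i in range(start, stop):
            if b[i] == a[i + offset]:
                matches += 1
        if matches > best:
            best = matches
    return best / lb


def greedy_identity_prune(
    seed_sequences: Mapping[str, str],
    threshold: float = 0.60,
    mc_id: str = "",
) -> PrunedSeedSet:
    """Longest-first greedy clustering; cluster representatives are returned."""
    if not seed_sequences:
        raise ValueError("no seed sequences to prune")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(seed_sequences, key=lambda k: (-len(seed_sequences[k]), k))
    reps: list[str] = []
    for name in ordered:
        seq = seed_sequences[name]
        if not any(pairwise_identity(seq, seed_sequences[r]) >= threshold for r in reps):
            reps.append(name)
    return PrunedSeedSet(mc_id, tuple(reps), threshold)


# -------------------------------------------------------------------- backends

class BackendError(RuntimeError):
    """Raised when an external tool fails or is unavailable."""


class NullBackend:
    """Format-testing stand-in: pads sequences instead of aligning them.

    The emitted MSA is NOT a real alignment and the profile file is a
    placeholder; both are flagged in their first line.
    """

    name = "null"

    def build_msa(self, sequences: Mapping[str, str], out_path: str | Path) -> None:
        if not sequences:
            raise ValueError("no sequences to align")
        width = max(len(s) for s in sequences.values())
        with open(out_path, "w") as fh:
            fh.write("; null backend: padded stack, not a real alignment\n")
            for name, seq in sequences.items():
                fh.write(f">{name}\n{seq.ljust(width, '-')}\n")

    def build_hmm(self, msa_path: str | Path, out_path: str | Path) -> None:
        with open(out_path, "w") as fh:
            fh.write("# null backend placeholder: not a real profile\n")
            fh.write(f"# source msa: {msa_path}\n")


@dataclass
class ExternalBackend:
    """Shells out to an MSA tool and hmmbuild found on PATH."""

    msa_cmd: Sequence[str] = ("mafft", "--auto", "{in}")
    msa_to_stdout: bool = True
    hmmbuild_cmd: Sequence[str] = ("hmmbuild", "{out}", "{in}")
    name: str = field(default="external")

    def _run(self, argv: list[str], stdout_path: str | Path | None) -> None:
        if shutil.which(argv[0]) is None:
            raise BackendError(f"backend unavailable: {argv[0]!r} not on PATH")
        try:
            if stdout_path is not None:
                with open(stdout_path, "w") as out:
                    subprocess.run(
                        argv, stdout=out, stderr=subprocess.PIPE, check=True, text=True
                    )
            else:
                subprocess.run(argv, capture_output=True, check=True, text=True)
        except subprocess.CalledProcessError as exc:
            raise BackendError(
                f"{argv[0]} failed with exit code {exc.returncode}: {exc.stderr}"
            ) from exc

    def build_msa(self, sequences: Mapping[str, str], out_path: str | Path) -> None:
        if not sequences:
            raise ValueError("no sequences to align")
        out_path = Path(out_path)
        tmp_in = out_path.with_suffix(".in.fasta")
        with open(tmp_in, "w") as fh:
            for name, seq in sequences.items():
                fh.write(f">{name}\n{seq}\n")
        argv = [a.replace("{in}", str(tmp_in)).replace("{out}", str(out_path)) for a in self.msa_cmd]
        self._run(argv, out_path if self.msa_to_stdout else None)
        tmp_in.unlink(missing_ok=True)

    def build_hmm(self, msa_path: str | Path, out_path: str | Path) -> None:
        argv = [
            a.replace("{in}", str(msa_path)).replace("{out}", str(out_path))
            for a in self.hmmbuild_cmd
        ]
        self._run(argv, None)


def build_family_artifacts(
    pruned: PrunedSeedSet,
    sequences: Mapping[str, str],
    backend,
    msa_path: str | Path,
    hmm_path: str | Path,
) -> tuple[Path, Path]:
    """Produce the MSA and profile files for one pruned seed set."""
    if not pruned.representatives:
        raise ValueError("empty pruned seed set")
    rep_seqs = {name: sequences[name] for name in pruned.representatives}
    backend.build_msa(rep_seqs, msa_path)
    backend.build_hmm(msa_path, hmm_path)
    return Path(msa_path), Path(hmm_path)


# ------------------------------------------------------------ profile search

def parse_domain_table(path: str | Path) -> list[dict]:
    """Parse a profile-search per-domain table (``--domtblout`` dialect).

    Returns one dict per row with target/query names, full-sequence E-value,
    per-domain independent E-value and the target-coordinate alignment span.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 22 whitespace-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                rows.append(
                    {
                        "target": fields[0],
                        "query": fields[3],
                        "full_evalue": float(fields[6]),
                        "domain_evalue": float(fields[12]),
                        "ali_from": int(fields[17]),
                        "ali_to": int(fields[18]),
                    }
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return rows


def filter_domain_hits(
    rows: Sequence[dict],
    domain_evalue: float = 0.03,
    protein_evalue: float = 0.01,
) -> list[tuple[str, Region, float]]:
    """Retain hits passing both E-value thresholds; return member regions."""
    out = []
    for row in rows:
        if row["domain_evalue"] <= domain_evalue and row["full_evalue"] <= protein_evalue:
            out.append(
                (
                    row["target"],
                    Region(row["target"], row["ali_from"], row["ali_to"]),
                    row["domain_evalue"],
                )
            )
    return out


def hmmsearch_handoff(
    hmm_path: str | Path,
    fasta_path: str | Path,
    domain_evalue: float = 0.03,
    protein_evalue: float = 0.01,
    hmmsearch_cmd: Sequence[str] = ("hmmsearch",),
) -> list[tuple[str, Region, float]]:
    """Run an external profile search and return thresholded member regions.

    Raises BackendError when the tool is missing; callers treat this as
    "no membership extension" and continue.
    """
    exe = hmmsearch_cmd[0]
    if shutil.which(exe) is None:
        raise BackendError(f"backend unavailable: {exe!r} not on PATH")
    hmm_path = Path(hmm_path)
    domtbl = hmm_path.with_suffix(".domtbl")
    argv = [*hmmsearch_cmd, "--domtblout", str(domtbl), str(hmm_path), str(fasta_path)]
    try:
        subprocess.run(argv, capture_output=True, check=True, text=True)
    except subprocess.CalledProcessError as exc:
        raise BackendError(
            f"{exe} failed with exit code {exc.returncode}: {exc.stderr}"
        ) from exc
    return filter_domain_hits(parse_domain_table(domtbl), domain_evalue, protein_evalue)
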