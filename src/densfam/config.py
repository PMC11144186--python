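"""Pipeline configuration: one flat record of every threshold and path.

Defaults match the published constants of the method (member overlap 0.8,
merge threshold 0.9, strict >50-seed / >50-residue filters, 60% pruning
identity, domain/protein E-values 0.03/0.01). Density-clustering knobs have
no published values and are explicit, documented defaults.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    # input paths (empty string = not provided)
    fasta: str = ""
    alignments: str = ""
    annotations: str = ""
    tracks: str = ""

    # density clustering (both stages); dc <= 0 means automatic percentile rule
    dc: float = -1.0
    kernel: str = "cutoff"
    rho_min: float = 0.0
    delta_min: float = 0.5

    # primary clustering
    min_members: int = 2

    # metaclustering / merging
    member_overlap: float = 0.8
    merge_threshold: float = 0.9
    keep_shared_only: bool = False
    seed_dedup_overlap: float = 0.8

    # filtering
    min_seeds: int = 50
    min_mean_length: float = 50.0

    # built-in aligner
    score_min: float = 60.0
    max_hsps: int = 5

    # post-processing
    prune_identity: float = 0.60
    domain_evalue: float = 0.03
    protein_evalue: float = 0.01

    rng_seed: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = ";".join(f"{k}={v}" for k, v in sorted(self.to_dict().items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# config_hash={self.config_hash()}\n")
            for k, v in sorted(self.to_dict().items()):
                fh.write(f"{k}={v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key=value`` file; unknown keys are an error."""
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes", "on")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)
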