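from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from densfam.meta import Metacluster
from densfam.model import Region
from densfam.primary import PrimaryCluster


def make_pc(query_id: str, footprint: tuple[int, int], subjects) -> PrimaryCluster:
    """Primary cluster from (protein_id, start, end) subject triples."""
    fp = Region(query_id, *footprint)
    members = tuple((Region(pid, s, e), fp) for pid, s, e in subjects)
    return PrimaryCluster(query_id, members, fp)


def make_mc(mc_id: str, *pcs: PrimaryCluster) -> Metacluster:
    seeds = tuple(sorted({r for pc in pcs for r in pc.subject_regions}))
    return Metacluster(mc_id, tuple(pcs), seeds)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_synthetic():
    """3 planted families, 30 single-domain proteins, full alignment table."""
    from densfam.align import all_vs_all, blosum62_scoring
    from densfam.synth import generate_proteome, single_domain_design

    design = single_domain_design(n_families=3, n_proteins=30, rng_seed=1)
    proteins, truth, annotations, tracks = generate_proteome(design)
    hits = all_vs_all(proteins, blosum62_scoring(), score_min=60.0, max_hsps=5)
    return {
        "design": design,
        "proteins": proteins,
        "truth": truth,
        "annotations": annotations,
        "tracks": tracks,
        "hits": hits,
    }
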