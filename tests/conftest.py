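from __future__ import annotations

import random

import pytest

from capsid.aln_io import AlignmentRecord
from capsid.pipeline import run_world
from capsid.synth import SimConfig, make_world
from capsid.taxonomy import TaxonomyTree, TaxonNode


def build_tree(nodes: dict[int, tuple[int, str]]) -> TaxonomyTree:
    """In-memory taxonomy from {taxid: (parent, rank)}."""
    root = next(t for t, (p, _) in nodes.items() if p == t)
    return TaxonomyTree(
        nodes={t: TaxonNode(t, p, rank) for t, (p, rank) in nodes.items()},
        root=root,
    )


@pytest.fixture(scope="session")
def mini_tree() -> TaxonomyTree:
    """root → {Bacteria → host sp., Viruses → family → 2 genera → 4 species}."""
    return build_tree(
        {
            1: (1, "no rank"),
            2: (1, "superkingdom"),
            2001: (2, "species"),
            10239: (1, "superkingdom"),
            11000: (10239, "family"),
            12001: (11000, "genus"),
            12002: (11000, "genus"),
            13001: (12001, "species"),
            13002: (12001, "species"),
            13003: (12002, "species"),
            13004: (12002, "species"),
            14001: (13001, "no rank"),  # strain below species
        }
    )


def make_record(
    taxid: int,
    q_start: int,
    q_end: int,
    bits: float,
    kind: str = "nt",
    query_id: str = "c1",
    subject_id: str | None = None,
) -> AlignmentRecord:
    return AlignmentRecord(
        query_id=query_id,
        subject_id=subject_id or f"e{taxid}",
        subject_taxid=taxid,
        kind=kind,
        q_start=q_start,
        q_end=q_end,
        s_start=1,
        s_end=q_end - q_start + 1,
        identity=0.9,
        bits=bits,
    )


def random_instance(rng: random.Random, max_taxa=5, max_records=20, max_len=50):
    """One random small scoring instance for oracle-equivalence checks."""
    length = rng.randint(5, max_len)
    taxa = rng.sample(range(100, 200), rng.randint(1, max_taxa))
    records = []
    for i in range(rng.randint(1, max_records)):
        q_start = rng.randint(1, length)
        q_end = rng.randint(q_start, length)
        records.append(
            make_record(
                taxid=rng.choice(taxa),
                q_start=q_start,
                q_end=q_end,
                bits=round(rng.uniform(1.0, 2.0 * (q_end - q_start + 1)), 3),
                kind=rng.choice(["nt", "aa"]),
                subject_id=f"e{i}",
            )
        )
    return records, length


@pytest.fixture(scope="session")
def study_world():
    """The standard synthetic study conditions (4 viruses, 5–15% divergence,
    20× coverage, 1% error, 30% host background)."""
    return make_world(SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_result(study_world):
    """One full pipeline run on the standard world, shared across tests."""
    return run_world(study_world)
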