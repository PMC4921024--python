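"""Shared fixtures: small hand-built datasets and random-instance builders."""

from __future__ import annotations

import numpy as np
import pytest

from domfuse import CDDRecord, DomainHit, GeneRecord, SimConfig, Thresholds, generate


def make_hit(
    gene_id="g1",
    cdd_id="cddA",
    gene_start=1,
    gene_end=100,
    cdd_start=1,
    cdd_end=100,
    e_value=1e-20,
    pct_identity=80.0,
) -> DomainHit:
    return DomainHit(gene_id, cdd_id, gene_start, gene_end, cdd_start, cdd_end, e_value, pct_identity)


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture
def toy_dataset():
    """Five genes yielding workflow stage counts 3 / 2 / 1.

    g_fusion passes every stage; g_repeat carries the same full-gene
    domain twice (disjoint) and dies at the set-distinctness criterion;
    g_naive carries two disjoint sub-domain alignments whose models are
    never full-gene and stops at the naive stage; g_single/g_single2 are
    the standalone genes that make cddA/cddB full-gene.
    """
    genes = {
        # fusion: two full-gene domains, standalone partners elsewhere
        "g_fusion": GeneRecord("g_fusion", "genomeA", 700, ["role_A", "role_B"]),
        "g_repeat": GeneRecord("g_repeat", "genomeA", 700, ["role_C"]),
        "g_single": GeneRecord("g_single", "genomeB", 210, ["role_A"]),
        "g_single2": GeneRecord("g_single2", "genomeB", 310, ["role_B"]),
        "g_naive": GeneRecord("g_naive", "genomeB", 500, ["role_D"]),
    }
    cdds = {
        "cddA": CDDRecord("cddA", 200),
        "cddB": CDDRecord("cddB", 300),
        "cddSub1": CDDRecord("cddSub1", 500),
        "cddSub2": CDDRecord("cddSub2", 500),
    }
    hits = [
        # fusion gene: cddA at 10-190 (181 aa), cddB at 350-650 (301 aa)
        make_hit("g_fusion", "cddA", 10, 190, 1, 190),
        make_hit("g_fusion", "cddB", 350, 650, 1, 295),
        # standalone genes making cddA/cddB full-gene
        make_hit("g_single", "cddA", 5, 200, 1, 196),
        make_hit("g_single2", "cddB", 5, 300, 1, 296),
        # repeated-domain gene: the same full-gene model twice, disjoint
        make_hit("g_repeat", "cddA", 10, 190, 1, 181),
        make_hit("g_repeat", "cddA", 350, 530, 1, 181),
        # naive-only gene: two disjoint sub-domain hits, models never full-gene
        make_hit("g_naive", "cddSub1", 10, 150, 50, 190),
        make_hit("g_naive", "cddSub2", 250, 400, 100, 250),
    ]
    return genes, cdds, hits


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic study cohort (2 x 500 genes, 10% fusions, seed 42)."""
    return generate(SimConfig())


@pytest.fixture(scope="session")
def clean_cohort():
    """Same cohort with every decoy class and coverage noise switched off."""
    cfg = SimConfig(
        fraction_multifunctional_single_domain=0.0,
        fraction_subdomain_decoys=0.0,
        fraction_promiscuous=0.0,
        coverage_noise_max=1e-9,
    )
    return generate(cfg)


def random_hits_for_gene(rng: np.random.Generator, gene_id: str, gene_len: int, cdd_pool: dict[str, CDDRecord], n: int):
    """Random, possibly overlapping hits with random model coverage."""
    hits = []
    cdd_ids = sorted(cdd_pool)
    for _ in range(n):
        cdd_id = cdd_ids[int(rng.integers(0, len(cdd_ids)))]
        ml = cdd_pool[cdd_id].model_length
        span = int(rng.integers(30, min(ml, gene_len) + 1))
        gs = int(rng.integers(1, gene_len - span + 2))
        cs = int(rng.integers(1, ml - span + 2))
        hits.append(
            DomainHit(
                gene_id,
                cdd_id,
                gs,
                gs + span - 1,
                cs,
                cs + span - 1,
                float(10.0 ** -rng.uniform(3, 40)),
                float(rng.uniform(20, 99)),
            )
        )
    return hits
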