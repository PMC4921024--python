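"""Full-gene marking, set consolidation and co-occurrence accounting,
each checked against an independent brute-force oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from domfuse import (
    CDDRecord,
    GeneRecord,
    Thresholds,
    build_cdd_sets,
    build_cooccurrence_index,
    mark_full_gene_cdds,
)
from domfuse.atlas import footprint_similarity

from conftest import make_hit, random_hits_for_gene


def _random_instance(seed, n_genes=20, n_cdds=12, hits_per_gene=(1, 6)):
    rng = np.random.default_rng(seed)
    genes = {
        f"g{i}": GeneRecord(f"g{i}", f"G{i % 3}", int(rng.integers(200, 1200)))
        for i in range(n_genes)
    }
    cdds = {f"c{i:02d}": CDDRecord(f"c{i:02d}", int(rng.integers(80, 500))) for i in range(n_cdds)}
    hits = []
    for gid, gene in genes.items():
        n = int(rng.integers(*hits_per_gene))
        hits.extend(random_hits_for_gene(rng, gid, gene.length, cdds, n))
    return genes, cdds, hits


# ---------------------------------------------------------------------------
# full-gene marking

def test_full_gene_bidirectional_example():
    """A hit covering 100/100 of the model and 100/105 of the gene is
    bidirectionally >90% and makes the model full-gene."""
    genes = {"g1": GeneRecord("g1", "G1", 105)}
    cdds = {"cddA": CDDRecord("cddA", 100)}
    hits = [make_hit("g1", "cddA", 1, 100, 1, 100)]
    mark_full_gene_cdds(hits, genes, cdds)
    assert cdds["cddA"].is_full_gene is True


def test_full_gene_empty_input():
    cdds = {"cddA": CDDRecord("cddA", 100)}
    mark_full_gene_cdds([], {}, cdds)
    assert cdds["cddA"].is_full_gene is False


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_full_gene_matches_bruteforce(seed):
    genes, cdds, hits = _random_instance(seed, n_genes=40, hits_per_gene=(1, 8))
    t = Thresholds()
    mark_full_gene_cdds(hits, genes, cdds, t)
    for cid, rec in cdds.items():
        expected = any(
            h.cdd_id == cid
            and h.model_span / rec.model_length > t.full_gene_coverage
            and h.aln_length / genes[h.gene_id].length > t.full_gene_coverage
            for h in hits
        )
        assert rec.is_full_gene == expected, cid


def test_full_gene_monotone_in_coverage():
    """Lowering the coverage cut never unsets a flag."""
    import copy

    genes, cdds, hits = _random_instance(3, n_genes=40, hits_per_gene=(1, 8))
    strict = {c.cdd_id: c.is_full_gene for c in
              mark_full_gene_cdds(hits, genes, copy.deepcopy(cdds), Thresholds(full_gene_coverage=0.9)).values()}
    loose = {c.cdd_id: c.is_full_gene for c in
             mark_full_gene_cdds(hits, genes, copy.deepcopy(cdds), Thresholds(full_gene_coverage=0.6)).values()}
    for cid, flag in strict.items():
        assert not flag or loose[cid]


# ---------------------------------------------------------------------------
# set consolidation

def test_identical_footprints_form_one_set():
    cdds = {"a": CDDRecord("a", 200), "b": CDDRecord("b", 200)}
    hits = []
    for i in range(5):
        for cid in ("a", "b"):
            hits.append(make_hit(f"g{i}", cid, 10, 190, 1, 181))
    sets = build_cdd_sets(hits, cdds)
    assert len(sets) == 1
    assert sets[0].members == frozenset({"a", "b"})


def test_unrelated_cdds_are_singletons():
    cdds = {c: CDDRecord(c, 100) for c in ("a", "b", "c")}
    hits = [make_hit(f"g_{c}", c, 1, 90, 1, 90) for c in cdds]
    sets = build_cdd_sets(hits, cdds)
    assert len(sets) == 3
    assert all(len(s.members) == 1 for s in sets)


def _bruteforce_components(hits, cdds, similarity_min=0.5, jaccard_min=0.8):
    """All-pairs similarity + transitive closure, straight from the definition."""
    by_cdd = {}
    for h in hits:
        by_cdd.setdefault(h.cdd_id, {}).setdefault(h.gene_id, []).append(h)
    parent = {c: c for c in cdds}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(sorted(cdds), 2):
        sim = footprint_similarity(by_cdd.get(a, {}), by_cdd.get(b, {}), jaccard_min)
        if sim >= similarity_min:
            parent[find(a)] = find(b)
    comps = {}
    for c in cdds:
        comps.setdefault(find(c), set()).add(c)
    return {frozenset(v) for v in comps.values()}


@pytest.mark.parametrize("seed", [10, 11])
def test_sets_match_bruteforce_single_linkage(seed):
    rng = np.random.default_rng(seed)
    cdds = {f"c{i:02d}": CDDRecord(f"c{i:02d}", 200) for i in range(50)}
    # hits engineered so some models share footprints on the same genes
    hits = []
    for g in range(30):
        gid = f"g{g}"
        n = int(rng.integers(1, 4))
        for _ in range(n):
            base = int(rng.integers(1, 400))
            span = int(rng.integers(100, 200))
            # a small cluster of models sharing (roughly) this footprint
            for cid in rng.choice(sorted(cdds), size=int(rng.integers(1, 4)), replace=False):
                jitter = int(rng.integers(-10, 11))
                gs = max(1, base + jitter)
                hits.append(make_hit(gid, str(cid), gs, gs + span - 1, 1, span))
    got = {s.members for s in build_cdd_sets(hits, cdds)}
    expected = _bruteforce_components(hits, cdds)
    assert got == expected


def test_sets_partition_catalogue():
    """Every model lands in exactly one set; mean size x count = catalogue size."""
    genes, cdds, hits = _random_instance(4, n_genes=30, n_cdds=15)
    sets = build_cdd_sets(hits, cdds)
    seen = [m for s in sets for m in s.members]
    assert sorted(seen) == sorted(cdds)
    mean_size = sum(len(s.members) for s in sets) / len(sets)
    assert mean_size * len(sets) == pytest.approx(len(cdds))


# ---------------------------------------------------------------------------
# co-occurrence

def test_lone_cdd_has_zero_cooccurrence():
    cdds = {"a": CDDRecord("a", 100)}
    hits = [make_hit(f"g{i}", "a", 1, 90, 1, 90) for i in range(5)]
    sets = build_cdd_sets(hits, cdds)
    idx = build_cooccurrence_index(hits, sets)
    assert idx.cooccurring("a") == 0


def test_cooccurring_pair_counts_each_other():
    cdds = {"a": CDDRecord("a", 100), "b": CDDRecord("b", 100)}
    hits = [make_hit("g1", "a", 1, 90, 1, 90), make_hit("g1", "b", 200, 290, 1, 90)]
    sets = build_cdd_sets(hits, cdds)
    idx = build_cooccurrence_index(hits, sets)
    assert idx.cooccurring("a") >= 1
    assert idx.cooccurring("b") >= 1
    assert idx.matches("a", "b") == idx.matches("b", "a")  # symmetric


@pytest.mark.parametrize("seed", [20, 21])
def test_cooccurrence_matches_bruteforce(seed):
    genes, cdds, hits = _random_instance(seed, n_genes=20, n_cdds=10, hits_per_gene=(1, 6))
    sets = build_cdd_sets(hits, cdds)
    idx = build_cooccurrence_index(hits, sets)
    set_of = {m: s.set_id for s in sets for m in s.members}
    by_gene = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    for cid in cdds:
        foreign = set()
        for gid, ghits in by_gene.items():
            if any(h.cdd_id == cid for h in ghits):
                foreign |= {set_of[h.cdd_id] for h in ghits}
        foreign.discard(set_of[cid])
        assert idx.cooccurring(cid) == len(foreign), cid
    # pair matches: distinct genes where the two models align to
    # essentially the same region (>= 50% of the shorter alignment)
    for a, b in itertools.combinations(sorted(cdds), 2):
        expected = 0
        for gid, ghits in by_gene.items():
            found = any(
                ha.overlap(hb) >= 0.5 * min(ha.aln_length, hb.aln_length)
                for ha in ghits
                if ha.cdd_id == a
                for hb in ghits
                if hb.cdd_id == b
            )
            expected += int(found)
        assert idx.matches(a, b) == expected, (a, b)
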