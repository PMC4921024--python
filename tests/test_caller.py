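"""The detection algorithm: interval selection, the eight criteria and the
Rosetta-stone check, verified against exhaustive/brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from domfuse import (
    CDDRecord,
    GeneRecord,
    Thresholds,
    apply_criteria,
    build_cdd_sets,
    build_cooccurrence_index,
    call_fusions,
    mark_full_gene_cdds,
    naive_multidomain,
    rosetta_stone_check,
    select_partition,
    stage_summary,
)
from domfuse.caller import FusionCandidate, Stage

from conftest import make_hit


# ---------------------------------------------------------------------------
# naive multi-domain stage

def test_naive_disjoint_hits(thresholds):
    gene = GeneRecord("g1", "G1", 700)
    hits = [make_hit("g1", "a", 10, 190), make_hit("g1", "b", 350, 650, 1, 100)]
    assert naive_multidomain(gene, hits, thresholds)


def test_naive_single_or_overlapping_hits(thresholds):
    gene = GeneRecord("g1", "G1", 700)
    assert not naive_multidomain(gene, [make_hit("g1", "a", 10, 190)], thresholds)
    overlapping = [make_hit("g1", "a", 10, 190), make_hit("g1", "b", 150, 400, 1, 251)]
    assert not naive_multidomain(gene, overlapping, thresholds)


@pytest.mark.parametrize("seed", range(5))
def test_naive_matches_bruteforce_pairs(seed, thresholds):
    rng = np.random.default_rng(seed)
    gene = GeneRecord("g1", "G1", 500)
    hits = []
    for _ in range(12):
        span = int(rng.integers(20, 250))
        gs = int(rng.integers(1, 500 - span + 1))
        hits.append(make_hit("g1", "a", gs, gs + span - 1, 1, span, float(10 ** -rng.uniform(3, 20))))
    kept = [h for h in hits if h.e_value < thresholds.e_value_max]
    expected = any(
        a.overlap(b) == 0 for a, b in itertools.combinations(kept, 2)
    )
    assert naive_multidomain(gene, hits, thresholds) == expected


# ---------------------------------------------------------------------------
# partition selection

@pytest.fixture
def full_gene_pair():
    cdds = {
        "cddA": CDDRecord("cddA", 200, is_full_gene=True),
        "cddB": CDDRecord("cddB", 300, is_full_gene=True),
    }
    return cdds


def test_select_partition_two_domains(full_gene_pair, thresholds):
    gene = GeneRecord("g1", "G1", 700)
    hits = [
        make_hit("g1", "cddA", 10, 190, 1, 190),
        make_hit("g1", "cddB", 350, 650, 1, 295),
    ]
    cand = select_partition(gene, hits, full_gene_pair, thresholds)
    assert cand is not None
    assert cand.cdd_ids == ("cddA", "cddB")
    assert cand.gaps == ((191, 349),)


def test_select_partition_model_coverage_floor(full_gene_pair, thresholds):
    """A hit covering only 47% of its model is not selectable."""
    gene = GeneRecord("g1", "G1", 700)
    hits = [
        make_hit("g1", "cddA", 10, 190, 1, 190),
        make_hit("g1", "cddB", 350, 489, 1, 140),  # 140/300 < 0.5
    ]
    assert select_partition(gene, hits, full_gene_pair, thresholds) is None


def _oracle_best_subset(eligible, tol=0):
    """Exhaustive search over all subsets with the same preference order:
    max cardinality, then max summed alignment length, then lexicographic
    cdd_id sequence, then start coordinates."""
    n = len(eligible)
    bad = [0] * n
    for i, j in itertools.combinations(range(n), 2):
        a, b = eligible[i], eligible[j]
        lo, hi = (a, b) if a.gene_start <= b.gene_start else (b, a)
        if hi.gene_start <= lo.gene_end - tol:
            bad[i] |= 1 << j
            bad[j] |= 1 << i
    best = None
    best_key = None
    for mask in range(1, 1 << n):
        ok = True
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if bad[i] & mask:
                ok = False
                break
            m &= m - 1
        if not ok:
            continue
        chosen = sorted(
            (eligible[i] for i in range(n) if mask >> i & 1),
            key=lambda h: h.gene_start,
        )
        key = (
            -len(chosen),
            -sum(h.aln_length for h in chosen),
            tuple(h.cdd_id for h in chosen),
            tuple(h.gene_start for h in chosen),
        )
        if best_key is None or key < best_key:
            best_key = key
            best = chosen
    return best if best and len(best) >= 2 else None


@pytest.mark.parametrize("seed", range(8))
def test_select_partition_equals_exhaustive_search(seed, thresholds):
    rng = np.random.default_rng(seed)
    cdds = {f"c{i}": CDDRecord(f"c{i}", 100, is_full_gene=bool(rng.random() < 0.8)) for i in range(6)}
    gene = GeneRecord("g1", "G1", 600)
    hits = []
    for _ in range(int(rng.integers(2, 16))):
        cid = f"c{int(rng.integers(0, 6))}"
        span = int(rng.integers(50, 101))  # >= 50% of the 100-residue models
        gs = int(rng.integers(1, 600 - span + 1))
        hits.append(make_hit("g1", cid, gs, gs + span - 1, 1, span))
    got = select_partition(gene, hits, cdds, thresholds)
    eligible = [
        h
        for h in hits
        if cdds[h.cdd_id].is_full_gene
        and h.model_span / 100 >= thresholds.domain_coverage_min
    ]
    expected = _oracle_best_subset(eligible)
    if expected is None:
        assert got is None
    else:
        assert got is not None
        assert got.selected == tuple(expected)


# ---------------------------------------------------------------------------
# the eight criteria

def _toy_context(toy_dataset):
    genes, cdds, hits = toy_dataset
    t = Thresholds()
    mark_full_gene_cdds(hits, genes, cdds, t)
    sets = build_cdd_sets(hits, cdds)
    idx = build_cooccurrence_index(hits, sets)
    return genes, cdds, hits, sets, idx, t


def test_criteria_worked_example(toy_dataset):
    """700aa gene with domains at 10-190 and 350-650: length, combined
    coverage (482/700) and gap position (midpoint 270) all pass."""
    genes, cdds, hits, sets, idx, t = _toy_context(toy_dataset)
    gene = genes["g_fusion"]
    ghits = [h for h in hits if h.gene_id == "g_fusion"]
    cand = select_partition(gene, ghits, cdds, t)
    res = apply_criteria(cand, gene, ghits, idx, sets, t)
    assert res.passed[1] and res.values[1] == 700
    assert res.values[2] == pytest.approx(482 / 700)
    assert res.passed[2]
    assert res.values[4] == pytest.approx(270.0)
    assert res.passed[4]  # 270 >= 60 and >= 70 from both termini
    assert res.verdict


def test_criterion1_length_boundary(toy_dataset):
    """'Must exceed 600' means a 600-residue gene fails."""
    genes, cdds, hits, sets, idx, t = _toy_context(toy_dataset)
    gene = GeneRecord("g_edge", "G1", 600)
    cand = FusionCandidate.from_hits(
        "g_edge",
        [make_hit("g_edge", "cddA", 10, 190, 1, 190), make_hit("g_edge", "cddB", 300, 590, 1, 291)],
    )
    res = apply_criteria(cand, gene, list(cand.selected), idx, sets, t)
    assert not res.passed[1]


def test_criterion5_same_set_fails(toy_dataset):
    """Two selected domains from one consolidated set are not a fusion."""
    genes, cdds, hits, sets, idx, t = _toy_context(toy_dataset)
    gene = genes["g_repeat"]
    ghits = [h for h in hits if h.gene_id == "g_repeat"]
    cand = select_partition(gene, ghits, cdds, t)
    res = apply_criteria(cand, gene, ghits, idx, sets, t)
    assert res.values[5] == 1
    assert not res.passed[5]
    assert not res.verdict


def test_criterion6_gap_crossing(toy_dataset):
    """Hits spanning the inter-domain gap count against the candidate."""
    genes, cdds, hits, sets, idx, t = _toy_context(toy_dataset)
    gene = genes["g_fusion"]
    ghits = [h for h in hits if h.gene_id == "g_fusion"]
    cand = select_partition(gene, ghits, cdds, t)
    crossing = [make_hit("g_fusion", "cddSub1", 100, 400, 1, 301)] * 3
    res = apply_criteria(cand, gene, ghits + crossing, idx, sets, t)
    assert res.values[6] == pytest.approx(3 / 5)
    assert not res.passed[6]


# ---------------------------------------------------------------------------
# the full workflow

def test_call_fusions_toy_stages(toy_dataset):
    genes, cdds, hits = toy_dataset
    calls = call_fusions(genes, hits, cdds)
    stages = {c.gene_id: c.stage for c in calls}
    assert stages == {
        "g_fusion": Stage.final_fusion,
        "g_repeat": Stage.full_gene_candidate,
        "g_naive": Stage.naive_multidomain,
    }
    summary = stage_summary(calls)
    totals = {k: sum(row[k] for row in summary.values()) for k in summary["genomeA"]}
    assert totals == {"naive_multidomain": 3, "full_gene_candidate": 2, "final_fusion": 1}


def test_call_fusions_deterministic(toy_dataset, tmp_path):
    from domfuse import io as dio

    genes, cdds, hits = toy_dataset
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    dio.write_fusion_calls(call_fusions(genes, hits, cdds), p1)
    dio.write_fusion_calls(call_fusions(genes, hits, cdds), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_stage_counts_non_increasing(default_cohort):
    res = default_cohort
    calls = call_fusions(res.gene_index, res.hits, res.cdds)
    summary = stage_summary(calls)
    for row in summary.values():
        assert row["naive_multidomain"] >= row["full_gene_candidate"] >= row["final_fusion"]
    # every final fusion is also a naive multi-domain gene by construction
    assert all(c.candidate is not None for c in calls if c.is_final)


def test_tightening_thresholds_never_increases_final_count(toy_dataset):
    genes, cdds, hits = toy_dataset
    base = sum(c.is_final for c in call_fusions(genes, hits, cdds))
    tightened = [
        {"min_protein_length": 800},
        {"combined_coverage_min": 0.9},
        {"min_alignment_length": 400},
    ]
    for kw in tightened:
        import copy

        n = sum(c.is_final for c in call_fusions(genes, copy.deepcopy(hits), copy.deepcopy(cdds), Thresholds(**kw)))
        assert n <= base


# ---------------------------------------------------------------------------
# Rosetta-stone check

def _rosetta_fixture():
    cdds = {
        "cddA": CDDRecord("cddA", 200, is_full_gene=True),
        "cddB": CDDRecord("cddB", 300, is_full_gene=True),
    }
    fusion_hits = [
        make_hit("g_fus", "cddA", 10, 190, 1, 190, 1e-30, 60.0),
        make_hit("g_fus", "cddB", 350, 650, 1, 295, 1e-30, 70.0),
    ]
    cand = FusionCandidate.from_hits("g_fus", fusion_hits)
    solo = make_hit("g_solo", "cddA", 5, 200, 1, 196, 1e-40, 65.0)
    return cdds, cand, fusion_hits, solo


def test_rosetta_true_when_solo_partner_exists():
    cdds, cand, fusion_hits, solo = _rosetta_fixture()
    result = rosetta_stone_check(cand, fusion_hits + [solo], cdds)
    assert result["cddA"] is True
    assert result["cddB"] is False  # never aligns alone anywhere


def test_rosetta_not_evaluable_without_identity():
    cdds, cand, fusion_hits, solo = _rosetta_fixture()
    no_ident = [
        make_hit("g_fus", "cddA", 10, 190, 1, 190, 1e-30, None),
        make_hit("g_fus", "cddB", 350, 650, 1, 295, 1e-30, 70.0),
    ]
    cand2 = FusionCandidate.from_hits("g_fus", no_ident)
    result = rosetta_stone_check(cand2, no_ident + [solo], cdds)
    assert result["cddA"] is None
    assert result["cddB"] is False


@pytest.mark.parametrize("seed", [30, 31])
def test_rosetta_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    cdds = {f"c{i}": CDDRecord(f"c{i}", 100, is_full_gene=True) for i in range(5)}
    hits = []
    for g in range(25):
        gid = f"g{g}"
        for cid in rng.choice(sorted(cdds), size=int(rng.integers(1, 3)), replace=False):
            span = int(rng.integers(80, 101))
            gs = int(rng.integers(1, 500))
            hits.append(
                make_hit(gid, str(cid), gs, gs + span - 1, 1, span, 1e-30, float(rng.uniform(30, 90)))
            )
    fusion_hits = [
        make_hit("g_fus", "c0", 10, 109, 1, 100, 1e-30, 60.0),
        make_hit("g_fus", "c1", 200, 299, 1, 100, 1e-30, 40.0),
    ]
    cand = FusionCandidate.from_hits("g_fus", fusion_hits)
    allh = hits + fusion_hits
    result = rosetta_stone_check(cand, allh, cdds)
    for h in fusion_hits:
        cdds_of = {}
        for x in allh:
            cdds_of.setdefault(x.gene_id, set()).add(x.cdd_id)
        solo = any(
            g != "g_fus" and members == {h.cdd_id} for g, members in cdds_of.items()
        )
        expected = (
            h.model_span / 100 >= 0.90 and h.pct_identity > 50.0 and solo
        )
        assert result[h.cdd_id] == expected
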