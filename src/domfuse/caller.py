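"""The fusion-detection algorithm.

A gene is called a fusion in three stages:

1. *naive multi-domain* — the gene has at least two pairwise
   non-overlapping domain alignments (necessary but far from sufficient);
2. *full-gene candidate* — a maximum-cardinality set of pairwise
   non-overlapping alignments to full-gene domain models, each covering at
   least half of its model, contains >= 2 alignments;
3. *final fusion* — the candidate passes the eight-criteria filter
   (length, combined coverage, alignment length, fusion-point position,
   set distinctness, gap crossing, promiscuity, pair matches).

The Rosetta-stone check is a separate validation: each selected domain
should also occur as the *only* domain of some other gene, with a
full-length, >50%-identity alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .atlas import CDDSet, CooccurrenceIndex, build_cooccurrence_index, build_cdd_sets, mark_full_gene_cdds
from .types import CDDRecord, ConfigError, DomainHit, GeneRecord, Thresholds

__all__ = [
    "Stage",
    "FusionCandidate",
    "CriteriaResult",
    "FusionCall",
    "naive_multidomain",
    "select_partition",
    "apply_criteria",
    "call_fusions",
    "rosetta_stone_check",
    "stage_summary",
]


class Stage(str, Enum):
    """How far a gene progressed through the workflow (monotone)."""

    naive_multidomain = "naive_multidomain"
    full_gene_candidate = "full_gene_candidate"
    final_fusion = "final_fusion"


_STAGE_ORDER = {
    Stage.naive_multidomain: 0,
    Stage.full_gene_candidate: 1,
    Stage.final_fusion: 2,
}


@dataclass(frozen=True)
class FusionCandidate:
    """A gene plus its selected non-overlapping full-gene-domain alignments.

    ``selected`` is ordered N->C by gene_start; consecutive alignments are
    pairwise non-overlapping.  ``gaps`` holds the residue intervals between
    consecutive selected alignments; a gap may be empty (start > end) when
    the alignments abut.
    """

    gene_id: str
    selected: tuple[DomainHit, ...]
    gaps: tuple[tuple[int, int], ...]

    @property
    def cdd_ids(self) -> tuple[str, ...]:
        return tuple(h.cdd_id for h in self.selected)

    @staticmethod
    def from_hits(gene_id: str, hits: list[DomainHit]) -> "FusionCandidate":
        sel = tuple(sorted(hits, key=lambda h: (h.gene_start, h.gene_end, h.cdd_id)))
        gaps = tuple(
            (sel[i].gene_end + 1, sel[i + 1].gene_start - 1) for i in range(len(sel) - 1)
        )
        return FusionCandidate(gene_id=gene_id, selected=sel, gaps=gaps)


@dataclass(frozen=True)
class CriteriaResult:
    """Measured values and pass/fail of the eight filter criteria.

    Keys are criterion numbers 1..8; ``values[i]`` is the measured
    quantity (length, fraction, count, ...) and ``passed[i]`` the flag.
    The ``verdict`` is a pure function of the eight flags and the policy.
    """

    values: dict[int, float]
    passed: dict[int, bool]
    verdict: bool

    @staticmethod
    def from_flags(values: dict[int, float], passed: dict[int, bool], t: Thresholds) -> "CriteriaResult":
        n_pass = sum(bool(v) for v in passed.values())
        if t.criteria_policy == "all":
            verdict = n_pass == len(passed)
        else:
            verdict = n_pass >= t.criteria_k
        return CriteriaResult(values=values, passed=passed, verdict=verdict)


@dataclass(frozen=True)
class FusionCall:
    """Per-gene outcome of the workflow."""

    gene_id: str
    genome_id: str
    stage: Stage
    candidate: FusionCandidate | None = None
    criteria: CriteriaResult | None = None

    @property
    def is_final(self) -> bool:
        return self.stage is Stage.final_fusion


def _compatible(a: DomainHit, b: DomainHit, tolerance: int) -> bool:
    """True if two alignments count as non-overlapping (shared residues <= tolerance)."""
    return a.overlap(b) <= tolerance


def naive_multidomain(gene: GeneRecord, hits: list[DomainHit], t: Thresholds) -> bool:
    """True iff the gene carries >= 2 pairwise non-overlapping hits (any model)."""
    kept = [h for h in hits if h.e_value < t.e_value_max]
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if _compatible(kept[i], kept[j], t.overlap_tolerance):
                return True
    return False


def _better(a: tuple, b: tuple) -> tuple:
    """Pick the preferred of two solutions.

    A solution is (count, total_aln_len, hits_tuple).  Preference: larger
    count, then larger summed alignment length, then lexicographically
    smaller cdd_id sequence, then smaller start-coordinate sequence
    (full determinism).
    """
    if a[0] != b[0]:
        return a if a[0] > b[0] else b
    if a[1] != b[1]:
        return a if a[1] > b[1] else b
    a_ids = tuple(h.cdd_id for h in a[2])
    b_ids = tuple(h.cdd_id for h in b[2])
    if a_ids != b_ids:
        return a if a_ids < b_ids else b
    a_starts = tuple(h.gene_start for h in a[2])
    b_starts = tuple(h.gene_start for h in b[2])
    return a if a_starts <= b_starts else b


def select_partition(
    gene: GeneRecord,
    hits: list[DomainHit],
    cdds: dict[str, CDDRecord],
    t: Thresholds,
) -> FusionCandidate | None:
    """Maximum-cardinality non-overlapping selection of full-gene-domain hits.

    Eligible hits pass the E-value cut, belong to a full-gene model and
    cover at least ``domain_coverage_min`` of that model.  Among
    maximum-cardinality pairwise non-overlapping subsets, ties are broken
    by larger summed alignment length, then lexicographic cdd_id order.
    Returns ``None`` when fewer than two alignments can be selected.
    """
    eligible = [
        h
        for h in hits
        if h.e_value < t.e_value_max
        and h.cdd_id in cdds
        and cdds[h.cdd_id].is_full_gene
        and h.model_coverage(cdds[h.cdd_id].model_length) >= t.domain_coverage_min
    ]
    if len(eligible) < 2:
        return None
    eligible.sort(key=lambda h: (h.gene_start, h.gene_end, h.cdd_id, h.cdd_start))
    n = len(eligible)
    tol = t.overlap_tolerance

    # exact DP over the start-sorted suffix: best(i) = better(skip i, take i)
    empty = (0, 0, ())
    best: list[tuple] = [empty] * (n + 1)
    for i in range(n - 1, -1, -1):
        h = eligible[i]
        # consecutive selected alignments may share at most `tol` residues:
        # next.gene_start must exceed h.gene_end - tol.  Starts are sorted,
        # so the compatible hits form a suffix and best[j] is reusable.
        j = i + 1
        while j < n and eligible[j].gene_start <= h.gene_end - tol:
            j += 1
        take_tail = best[j]
        take = (take_tail[0] + 1, take_tail[1] + h.aln_length, (h,) + take_tail[2])
        best[i] = _better(best[i + 1], take)
    count, _total, chosen = best[0]
    if count < 2:
        return None
    return FusionCandidate.from_hits(gene.gene_id, list(chosen))


def apply_criteria(
    candidate: FusionCandidate,
    gene: GeneRecord,
    all_hits: list[DomainHit],
    index: CooccurrenceIndex,
    sets: list[CDDSet],
    t: Thresholds,
) -> CriteriaResult:
    """Evaluate the eight filter criteria on a candidate.

    1. protein length > ``min_protein_length``;
    2. combined selected-alignment residues >= ``combined_coverage_min``
       of the gene length;
    3. every selected alignment >= ``min_alignment_length`` residues;
    4. every gap midpoint >= ``min_gap_distance_residues`` AND
       >= ``min_gap_distance_fraction`` of gene length from both termini;
    5. selected domains span >= 2 distinct consolidated domain sets;
    6. fraction of the gene's hits crossing any gap < ``gap_crossing_fraction_max``;
    7. each selected domain co-occurs with < ``max_cooccurring_sets`` sets;
    8. each selected domain pair has < ``max_pair_matches`` matches.
    """
    if index is None:
        raise ConfigError("apply_criteria requires a co-occurrence index")
    L = gene.length
    sel = candidate.selected

    values: dict[int, float] = {}
    passed: dict[int, bool] = {}

    values[1] = float(L)
    passed[1] = L > t.min_protein_length

    combined = sum(h.aln_length for h in sel)
    values[2] = combined / L
    passed[2] = values[2] >= t.combined_coverage_min

    values[3] = float(min(h.aln_length for h in sel))
    passed[3] = values[3] >= t.min_alignment_length

    # minimum distance of any gap midpoint from either terminus
    min_dist = float("inf")
    for i in range(len(sel) - 1):
        mid = (sel[i].gene_end + sel[i + 1].gene_start) / 2.0
        min_dist = min(min_dist, mid, L - mid)
    values[4] = min_dist
    passed[4] = (
        min_dist >= t.min_gap_distance_residues
        and min_dist >= t.min_gap_distance_fraction * L
    )

    distinct_sets = {index.set_of.get(c, c) for c in candidate.cdd_ids}
    values[5] = float(len(distinct_sets))
    passed[5] = len(distinct_sets) >= 2

    n_hits = len(all_hits)
    n_crossing = 0
    for h in all_hits:
        for i in range(len(sel) - 1):
            if h.gene_start <= sel[i].gene_end and h.gene_end >= sel[i + 1].gene_start:
                n_crossing += 1
                break
    values[6] = n_crossing / n_hits if n_hits else 0.0
    passed[6] = values[6] < t.gap_crossing_fraction_max

    values[7] = float(max(index.cooccurring(c) for c in candidate.cdd_ids))
    passed[7] = values[7] < t.max_cooccurring_sets

    pair_max = 0
    ids = candidate.cdd_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair_max = max(pair_max, index.matches(ids[i], ids[j]))
    values[8] = float(pair_max)
    passed[8] = pair_max < t.max_pair_matches

    return CriteriaResult.from_flags(values, passed, t)


def call_fusions(
    genes: dict[str, GeneRecord],
    hits: list[DomainHit],
    cdds: dict[str, CDDRecord],
    t: Thresholds | None = None,
    sets: list[CDDSet] | None = None,
    index: CooccurrenceIndex | None = None,
) -> list[FusionCall]:
    """Run the full workflow over a dataset; one call per naive-stage gene.

    Builds the domain atlas (full-gene flags, consolidated sets,
    co-occurrence index) from the E-value-filtered hits unless supplied.
    Output is sorted by gene_id and deterministic for fixed input.
    """
    t = t or Thresholds()
    kept = [h for h in hits if h.e_value < t.e_value_max and h.gene_id in genes]
    mark_full_gene_cdds(kept, genes, cdds, t)
    if sets is None:
        sets = build_cdd_sets(kept, cdds, t.set_similarity_min, t.set_interval_jaccard_min)
    if index is None:
        index = build_cooccurrence_index(kept, sets)

    by_gene: dict[str, list[DomainHit]] = {}
    for h in kept:
        by_gene.setdefault(h.gene_id, []).append(h)

    calls: list[FusionCall] = []
    for gene_id in sorted(by_gene):
        gene = genes[gene_id]
        gh = by_gene[gene_id]
        if not naive_multidomain(gene, gh, t):
            continue
        candidate = select_partition(gene, gh, cdds, t)
        if candidate is None:
            calls.append(FusionCall(gene_id, gene.genome_id, Stage.naive_multidomain))
            continue
        criteria = apply_criteria(candidate, gene, gh, index, sets, t)
        stage = Stage.final_fusion if criteria.verdict else Stage.full_gene_candidate
        calls.append(FusionCall(gene_id, gene.genome_id, stage, candidate, criteria))
    return calls


def rosetta_stone_check(
    candidate: FusionCandidate,
    hits: list[DomainHit],
    cdds: dict[str, CDDRecord],
    t: Thresholds | None = None,
) -> dict[str, bool | None]:
    """Rosetta-stone validation of each selected domain.

    For each selected domain: (i) its alignment covers the full model
    (>= ``full_gene_coverage``); (ii) percent identity > 50; (iii) some
    *other* gene exists on which this domain aligns as that gene's only
    domain.  Returns ``None`` for a domain whose hit lacks percent
    identity (not evaluable), never ``False`` for that reason.
    """
    t = t or Thresholds()
    kept = [h for h in hits if h.e_value < t.e_value_max]
    genes_of_cdd: dict[str, set[str]] = {}
    cdds_of_gene: dict[str, set[str]] = {}
    for h in kept:
        genes_of_cdd.setdefault(h.cdd_id, set()).add(h.gene_id)
        cdds_of_gene.setdefault(h.gene_id, set()).add(h.cdd_id)

    out: dict[str, bool | None] = {}
    for h in candidate.selected:
        if h.pct_identity is None:
            out[h.cdd_id] = None
            continue
        full = h.model_coverage(cdds[h.cdd_id].model_length) >= t.full_gene_coverage
        ident = h.pct_identity > 50.0
        solo = any(
            g != candidate.gene_id and cdds_of_gene[g] == {h.cdd_id}
            for g in genes_of_cdd.get(h.cdd_id, ())
        )
        out[h.cdd_id] = full and ident and solo
    return out


def stage_summary(calls: list[FusionCall]) -> dict[str, dict[str, int]]:
    """Per-genome counts of genes reaching each workflow stage.

    Counts are cumulative downward: every candidate is also a naive
    multi-domain gene, every final fusion also a candidate.
    """
    out: dict[str, dict[str, int]] = {}
    for c in calls:
        row = out.setdefault(
            c.genome_id, {"naive_multidomain": 0, "full_gene_candidate": 0, "final_fusion": 0}
        )
        rank = _STAGE_ORDER[c.stage]
        row["naive_multidomain"] += 1
        if rank >= 1:
            row["full_gene_candidate"] += 1
        if rank >= 2:
            row["final_fusion"] += 1
    return out
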