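"""Database-wide domain bookkeeping.

Three pieces of global context feed the per-gene filter criteria:

* **full-gene flags** — a domain model is "full-gene" once some gene in
  the database shows a single alignment covering more than 90% (by
  default) of *both* the model and the gene; only such models can anchor
  a fusion call, which removes sub-domain-only models wholesale;
* **consolidated domain sets** — models with near-identical alignment
  footprints across many genes are merged (single linkage) into sets and
  treated as one unit when counting distinctness and co-occurrence;
* **co-occurrence index** — per model, how many foreign sets it shares a
  gene with (the promiscuity measure), and per model pair, on how many
  genes the two models align to essentially the same region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .types import CDDRecord, DomainHit, GeneRecord, Thresholds

__all__ = [
    "CDDSet",
    "CooccurrenceIndex",
    "mark_full_gene_cdds",
    "build_cdd_sets",
    "build_cooccurrence_index",
]


@dataclass(frozen=True)
class CDDSet:
    """A group of domain models with interchangeable alignment footprints."""

    set_id: str
    members: frozenset[str]


@dataclass
class CooccurrenceIndex:
    """Promiscuity statistics over consolidated domain sets.

    ``cooccurring_sets[c]`` counts the distinct sets, other than the one
    containing ``c``, with a member hit on at least one gene that ``c``
    also hits.  ``pair_matches[(a, b)]`` (keys sorted) counts the distinct
    genes on which ``a`` and ``b`` both align with mutual gene-interval
    overlap of at least half the shorter alignment — i.e. genes where the
    two models look like the *same* domain rather than fused partners.
    """

    set_of: dict[str, str] = field(default_factory=dict)
    cooccurring_sets: dict[str, int] = field(default_factory=dict)
    pair_matches: dict[tuple[str, str], int] = field(default_factory=dict)

    def cooccurring(self, cdd_id: str) -> int:
        return self.cooccurring_sets.get(cdd_id, 0)

    def matches(self, a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        return self.pair_matches.get(key, 0)


def mark_full_gene_cdds(
    hits: list[DomainHit],
    genes: dict[str, GeneRecord],
    cdds: dict[str, CDDRecord],
    t: Thresholds | None = None,
) -> dict[str, CDDRecord]:
    """Set ``is_full_gene`` on every model in the catalogue.

    A model is full-gene iff some single hit covers strictly more than
    ``t.full_gene_coverage`` of both the model length and the gene length
    (a bidirectional >90% alignment by default).  Hits are expected to be
    pre-filtered to the E-value cut.  Mutates and returns ``cdds``.
    """
    t = t or Thresholds()
    for rec in cdds.values():
        rec.is_full_gene = False
    for h in hits:
        gene = genes.get(h.gene_id)
        rec = cdds.get(h.cdd_id)
        if gene is None or rec is None or rec.is_full_gene:
            continue
        if (
            h.model_coverage(rec.model_length) > t.full_gene_coverage
            and h.gene_coverage(gene.length) > t.full_gene_coverage
        ):
            rec.is_full_gene = True
    return cdds


def _interval_jaccard(a: DomainHit, b: DomainHit) -> float:
    inter = a.overlap(b)
    union = a.aln_length + b.aln_length - inter
    return inter / union if union else 0.0


def footprint_similarity(
    a_hits: dict[str, list[DomainHit]],
    b_hits: dict[str, list[DomainHit]],
    jaccard_min: float,
) -> float:
    """Fraction of jointly-relevant genes where two models align alike.

    Similarity of models *a*, *b* = |genes where some a-hit and some b-hit
    have gene-interval Jaccard >= ``jaccard_min``| / |genes hit by a or b|.
    """
    all_genes = set(a_hits) | set(b_hits)
    if not all_genes:
        return 0.0
    n_similar = 0
    for g in set(a_hits) & set(b_hits):
        if any(
            _interval_jaccard(ha, hb) >= jaccard_min
            for ha in a_hits[g]
            for hb in b_hits[g]
        ):
            n_similar += 1
    return n_similar / len(all_genes)


def build_cdd_sets(
    hits: list[DomainHit],
    cdds: dict[str, CDDRecord],
    similarity_min: float = 0.5,
    interval_jaccard_min: float = 0.8,
) -> list[CDDSet]:
    """Partition the model catalogue into consolidated sets.

    Two models are linked when their footprint similarity (see
    :func:`footprint_similarity`) reaches ``similarity_min``; sets are the
    single-linkage connected components.  Models without hits form
    singleton sets.  The result covers every model exactly once.
    """
    by_cdd: dict[str, dict[str, list[DomainHit]]] = {}
    by_gene: dict[str, set[str]] = {}
    for h in hits:
        if h.cdd_id not in cdds:
            continue
        by_cdd.setdefault(h.cdd_id, {}).setdefault(h.gene_id, []).append(h)
        by_gene.setdefault(h.gene_id, set()).add(h.cdd_id)

    g = nx.Graph()
    g.add_nodes_from(cdds)
    # only pairs sharing at least one gene can be similar
    candidate_pairs: set[tuple[str, str]] = set()
    for members in by_gene.values():
        ordered = sorted(members)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                candidate_pairs.add((ordered[i], ordered[j]))
    for a, b in sorted(candidate_pairs):
        sim = footprint_similarity(by_cdd[a], by_cdd[b], interval_jaccard_min)
        if sim >= similarity_min:
            g.add_edge(a, b)

    sets = []
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    for k, comp in enumerate(components, start=1):
        sets.append(CDDSet(set_id=f"set_{k:05d}", members=frozenset(comp)))
    return sets


def build_cooccurrence_index(hits: list[DomainHit], sets: list[CDDSet]) -> CooccurrenceIndex:
    """Count per-model co-occurring foreign sets and per-pair footprint matches."""
    set_of: dict[str, str] = {}
    for s in sets:
        for m in s.members:
            set_of[m] = s.set_id

    genes_of_cdd: dict[str, set[str]] = {}
    hits_by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        genes_of_cdd.setdefault(h.cdd_id, set()).add(h.gene_id)
        hits_by_gene.setdefault(h.gene_id, []).append(h)

    sets_of_gene: dict[str, set[str]] = {
        g: {set_of[h.cdd_id] for h in ghits if h.cdd_id in set_of}
        for g, ghits in hits_by_gene.items()
    }

    cooccurring: dict[str, int] = {}
    for cdd_id, gene_ids in genes_of_cdd.items():
        own = set_of.get(cdd_id)
        foreign: set[str] = set()
        for g in gene_ids:
            foreign |= sets_of_gene[g]
        foreign.discard(own)
        cooccurring[cdd_id] = len(foreign)

    pair_genes: dict[tuple[str, str], set[str]] = {}
    for g, ghits in hits_by_gene.items():
        seen: set[tuple[str, str]] = set()
        for i in range(len(ghits)):
            for j in range(i + 1, len(ghits)):
                a, b = ghits[i], ghits[j]
                if a.cdd_id == b.cdd_id:
                    continue
                shorter = min(a.aln_length, b.aln_length)
                if a.overlap(b) >= 0.5 * shorter:
                    key = (a.cdd_id, b.cdd_id) if a.cdd_id <= b.cdd_id else (b.cdd_id, a.cdd_id)
                    seen.add(key)
        for key in seen:
            pair_genes.setdefault(key, set()).add(g)

    pair_matches = {k: len(v) for k, v in pair_genes.items()}
    return CooccurrenceIndex(set_of=set_of, cooccurring_sets=cooccurring, pair_matches=pair_matches)
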