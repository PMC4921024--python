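"""Metabolic interpretation of fusion calls.

Two fused roles are *adjacent in metabolism* when some product of a
reaction catalyzed by one is a substrate of a reaction catalyzed by the
other; such fusions frequently bracket unstable or toxic intermediates.
The variety/frequency accounting summarizes, for a pathway role of
interest, how many distinct binary fusion architectures it enters and
what fraction of its gene copies across a genome cohort are fused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .caller import FusionCall
from .types import FormatError, GeneRecord

log = logging.getLogger(__name__)

__all__ = [
    "ReactionMap",
    "AdjacentFusion",
    "VarietyResult",
    "adjacent_reaction_fusions",
    "fusion_variety",
    "fusion_frequency",
    "read_reaction_map",
]

PARTNER_CATEGORIES = ("same-pathway", "other-metabolism", "unknown")


@dataclass
class ReactionMap:
    """Role -> reactions, and reaction -> substrate/product metabolite sets."""

    role_reactions: dict[str, set[str]] = field(default_factory=dict)
    substrates: dict[str, set[str]] = field(default_factory=dict)
    products: dict[str, set[str]] = field(default_factory=dict)

    def metabolites(self, role: str, side: str, reversible: bool = False) -> set[str]:
        """Union of substrate or product metabolites over a role's reactions."""
        table = self.substrates if side == "substrate" else self.products
        other = self.products if side == "substrate" else self.substrates
        out: set[str] = set()
        for rxn in self.role_reactions.get(role, ()):
            out |= table.get(rxn, set())
            if reversible:
                out |= other.get(rxn, set())
        return out


@dataclass(frozen=True)
class AdjacentFusion:
    """A fused role pair whose reactions share a metabolite.

    ``shared`` holds the metabolites that are products of ``role_from``
    and substrates of ``role_to`` (direction recorded; always non-empty).
    """

    gene_id: str
    role_from: str
    role_to: str
    shared: frozenset[str]


def read_reaction_map(role_reactions_path: str | Path, reactions_path: str | Path) -> ReactionMap:
    """Read a reaction map from two TSVs.

    ``role_reactions``: columns role, reactions (semicolon-separated ids).
    ``reactions``: columns reaction_id, substrates, products
    (semicolon-separated metabolite ids).
    """
    rmap = ReactionMap()
    rr = pd.read_csv(role_reactions_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("role", "reactions"):
        if col not in rr.columns:
            raise FormatError(f"{role_reactions_path}: missing column {col!r}")
    for _, row in rr.iterrows():
        rmap.role_reactions.setdefault(row["role"], set()).update(
            x for x in row["reactions"].split(";") if x
        )
    rx = pd.read_csv(reactions_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("reaction_id", "substrates", "products"):
        if col not in rx.columns:
            raise FormatError(f"{reactions_path}: missing column {col!r}")
    for _, row in rx.iterrows():
        rmap.substrates[row["reaction_id"]] = {x for x in row["substrates"].split(";") if x}
        rmap.products[row["reaction_id"]] = {x for x in row["products"].split(";") if x}
    return rmap


def adjacent_reaction_fusions(
    calls: list[FusionCall],
    genes: dict[str, GeneRecord],
    rmap: ReactionMap,
    reversible: bool = False,
) -> tuple[list[AdjacentFusion], int]:
    """Find fused role pairs catalyzing adjacent reactions.

    For every final fusion carrying >= 2 roles, emits each ordered role
    pair (A, B) where a product of A's reactions is a substrate of B's,
    with the shared metabolites.  ``reversible`` treats every reaction as
    bidirectional (union of both orientations).  Roles absent from the
    map are skipped; returns (fusions, n_skipped_roles).
    """
    out: list[AdjacentFusion] = []
    skipped: set[str] = set()
    for c in calls:
        if not c.is_final:
            continue
        gene = genes.get(c.gene_id)
        if gene is None or len(gene.roles) < 2:
            continue
        roles = []
        for r in gene.roles:
            if r in rmap.role_reactions:
                roles.append(r)
            else:
                skipped.add(r)
        for i in range(len(roles)):
            for j in range(len(roles)):
                if i == j:
                    continue
                a, b = roles[i], roles[j]
                shared = rmap.metabolites(a, "product", reversible) & rmap.metabolites(
                    b, "substrate", reversible
                )
                if shared:
                    out.append(
                        AdjacentFusion(
                            gene_id=c.gene_id, role_from=a, role_to=b, shared=frozenset(shared)
                        )
                    )
    if skipped:
        log.warning("adjacent_reaction_fusions: %d role(s) absent from reaction map", len(skipped))
    return out, len(skipped)


@dataclass(frozen=True)
class VarietyResult:
    """Distinct binary fusion architectures of a role, by partner category."""

    total: int
    by_category: dict[str, int]


def fusion_variety(
    role: str,
    calls: list[FusionCall],
    genes: dict[str, GeneRecord],
    partner_categories: dict[str, str] | None = None,
) -> VarietyResult:
    """Count the distinct (role, partner) architectures the role enters.

    Each distinct unordered pairing of the role with a partner role is one
    architecture, counted once no matter how many genes realize it.
    Partners are split across categories (same-pathway / other-metabolism
    / unknown); uncategorized partners fall in "unknown".
    """
    partner_categories = partner_categories or {}
    partners: set[str] = set()
    for c in calls:
        if not c.is_final:
            continue
        gene = genes.get(c.gene_id)
        if gene is None or role not in gene.roles:
            continue
        partners.update(r for r in gene.roles if r != role)
    by_cat = {cat: 0 for cat in PARTNER_CATEGORIES}
    for p in partners:
        by_cat[partner_categories.get(p, "unknown")] += 1
    return VarietyResult(total=len(partners), by_category=by_cat)


def fusion_frequency(
    role: str,
    calls: list[FusionCall],
    genes: dict[str, GeneRecord],
    genome_subset: set[str] | None = None,
) -> float | None:
    """Fraction of the role's gene copies that are fused, over a cohort.

    Numerator: gene copies annotated with the role, inside the genome
    subset, that appear in final fusion calls.  Denominator: all copies of
    the role in the subset (each copy counts once).  Returns ``None`` when
    the role is absent from the subset (rather than 0%).
    """
    final = {c.gene_id for c in calls if c.is_final}
    n_total = 0
    n_fused = 0
    for g in genes.values():
        if genome_subset is not None and g.genome_id not in genome_subset:
            continue
        if role in g.roles:
            n_total += 1
            if g.gene_id in final:
                n_fused += 1
    if n_total == 0:
        return None
    return n_fused / n_total
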