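"""Scoring predicted fusions against curated training sets.

The curated truth distinguishes *confirmed* fusions, *uncertain* genes
(excluded from scoring entirely — neither credited nor penalized) and
*rejected* genes (curated non-fusions).  The false-negative rate is the
fraction of confirmed fusions the caller misses; the false-positive rate
reported here is (predictions - captured)/predictions within the scored
scope, emitted alongside the raw counts so alternative denominators can
be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .caller import FusionCall
from .types import GeneRecord, TrainingEntry, TrainingStatus

__all__ = ["ConfusionSummary", "evaluate", "source_overlap", "category_distribution", "percent"]


def percent(fraction: float) -> int:
    """Present a fraction as a whole-number percentage, rounding half up."""
    return int(Decimal(fraction * 100).quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Capture/miss accounting of a call set against a curated truth set."""

    n_truth: int
    n_captured: int
    n_predicted: int
    per_source: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def capture_fraction(self) -> float:
        return self.n_captured / self.n_truth

    @property
    def fn_rate(self) -> float:
        return 1.0 - self.capture_fraction

    @property
    def fp_rate(self) -> float:
        return (self.n_predicted - self.n_captured) / self.n_predicted if self.n_predicted else float("nan")


def evaluate(
    calls: list[FusionCall],
    truth: list[TrainingEntry],
    genes: dict[str, GeneRecord] | None = None,
    genomes: set[str] | None = None,
) -> ConfusionSummary:
    """Score final fusion calls against a curated training set.

    ``genomes`` optionally restricts scoring to a genome subset (requires
    ``genes`` to resolve the genome of truth entries).  Uncertain entries
    are excluded from numerator and denominator; predictions on uncertain
    genes are likewise excluded from the prediction count.
    """
    if genes is not None:
        missing = sorted({e.gene_id for e in truth} - set(genes))
        if missing:
            raise ValueError(f"truth gene(s) absent from gene table: {missing}")

    def in_scope(gene_id: str, genome_id: str | None = None) -> bool:
        if genomes is None:
            return True
        if genome_id is None:
            if genes is None:
                raise ValueError("genome scoping requires the gene table")
            genome_id = genes[gene_id].genome_id
        return genome_id in genomes

    confirmed = {
        e.gene_id for e in truth if e.status is TrainingStatus.confirmed_fusion and in_scope(e.gene_id)
    }
    uncertain = {e.gene_id for e in truth if e.status is TrainingStatus.uncertain}
    if not confirmed:
        raise ValueError("empty confirmed truth set: rates are undefined")

    predicted = {
        c.gene_id
        for c in calls
        if c.is_final and c.gene_id not in uncertain and in_scope(c.gene_id, c.genome_id)
    }
    captured = confirmed & predicted

    per_source: dict[str, tuple[int, int]] = {}
    for e in truth:
        if e.status is not TrainingStatus.confirmed_fusion or e.gene_id not in confirmed:
            continue
        for src in e.sources:
            n_t, n_c = per_source.get(src, (0, 0))
            per_source[src] = (n_t + 1, n_c + (1 if e.gene_id in predicted else 0))

    return ConfusionSummary(
        n_truth=len(confirmed),
        n_captured=len(captured),
        n_predicted=len(predicted),
        per_source=per_source,
    )


def source_overlap(truth: list[TrainingEntry]) -> dict:
    """Per-source totals, exclusive counts and pairwise intersections."""
    totals: dict[str, int] = {}
    exclusive: dict[str, int] = {}
    pairwise: dict[tuple[str, str], int] = {}
    for e in truth:
        srcs = sorted(e.sources)
        for s in srcs:
            totals[s] = totals.get(s, 0) + 1
        if len(srcs) == 1:
            exclusive[srcs[0]] = exclusive.get(srcs[0], 0) + 1
        for i in range(len(srcs)):
            for j in range(i + 1, len(srcs)):
                key = (srcs[i], srcs[j])
                pairwise[key] = pairwise.get(key, 0) + 1
    for s in totals:
        exclusive.setdefault(s, 0)
    return {"total": totals, "exclusive": exclusive, "pairwise": pairwise}


def category_distribution(
    truth: list[TrainingEntry],
    categories: dict[str, str],
) -> dict[str, tuple[int, int]]:
    """Count confirmed fusions per functional category.

    Returns {category: (count, percentage)} over the confirmed set, with
    percentages rounded half-up to integers.  Every confirmed gene must be
    categorized.
    """
    confirmed = [e.gene_id for e in truth if e.status is TrainingStatus.confirmed_fusion]
    missing = sorted(g for g in confirmed if g not in categories)
    if missing:
        raise ValueError(f"uncategorized gene(s): {missing}")
    counts: dict[str, int] = {}
    for g in confirmed:
        counts[categories[g]] = counts.get(categories[g], 0) + 1
    total = len(confirmed)
    return {cat: (n, percent(n / total)) for cat, n in sorted(counts.items())}
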