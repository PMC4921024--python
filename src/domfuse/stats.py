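"""Cohort-level fusion-frequency statistics.

For every functional role (and, at coarser granularity, every subsystem)
the cohort yields a fused-gene proportion.  A role is *frequently fused*
when its proportion exceeds the cohort mean by more than ``z_min``
standard deviations — equivalently, exceeds the implied threshold
``mu + z_min * sigma`` — and a one-sided exact binomial test of its fused
count against the cohort mean is significant.  With a cohort mean of 0.11
and SD of 0.25 the implied threshold is 0.61.

Roles are counted per gene-role pair: a bifunctional gene contributes to
each of its roles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binomtest

from .caller import FusionCall
from .types import GeneRecord

__all__ = [
    "RoleStats",
    "CohortFlagging",
    "ProportionalityResult",
    "compute_role_stats",
    "compute_subsystem_stats",
    "filter_roles",
    "implied_threshold",
    "frequently_fused",
    "subsystem_stats",
    "genome_proportionality",
    "GENERIC_DESCRIPTORS",
]

#: Generic annotation words that disqualify a role from cohort statistics.
GENERIC_DESCRIPTORS = ("predicted", "hypothetical", "putative", "possible", "probable")

_GENERIC_RE = re.compile(
    r"\b(" + "|".join(GENERIC_DESCRIPTORS) + r")\b", flags=re.IGNORECASE
)


@dataclass(frozen=True)
class RoleStats:
    """Fusion statistics for one functional role (or subsystem)."""

    role: str
    n_genes: int
    n_genomes: int
    n_fused: int
    z: float | None = None
    p: float | None = None
    frequently_fused: bool | None = None

    @property
    def proportion(self) -> float:
        return self.n_fused / self.n_genes


@dataclass(frozen=True)
class CohortFlagging:
    """Outcome of the frequently-fused test over a role cohort."""

    roles: tuple[RoleStats, ...]
    mean: float
    sd: float
    implied_threshold: float

    @property
    def flagged(self) -> tuple[RoleStats, ...]:
        return tuple(r for r in self.roles if r.frequently_fused)


@dataclass(frozen=True)
class ProportionalityResult:
    """Cohort-wide fused fraction and through-origin regression slope."""

    fraction: float
    slope: float


def _stats_by_attr(
    genes: dict[str, GeneRecord],
    fused_ids: set[str],
    attr: str,
) -> list[RoleStats]:
    n_genes: dict[str, int] = {}
    n_fused: dict[str, int] = {}
    genomes: dict[str, set[str]] = {}
    for g in genes.values():
        for label in getattr(g, attr):
            n_genes[label] = n_genes.get(label, 0) + 1
            genomes.setdefault(label, set()).add(g.genome_id)
            if g.gene_id in fused_ids:
                n_fused[label] = n_fused.get(label, 0) + 1
    return [
        RoleStats(
            role=label,
            n_genes=n_genes[label],
            n_genomes=len(genomes[label]),
            n_fused=n_fused.get(label, 0),
        )
        for label in sorted(n_genes)
    ]


def _final_ids(calls: list[FusionCall]) -> set[str]:
    return {c.gene_id for c in calls if c.is_final}


def compute_role_stats(genes: dict[str, GeneRecord], calls: list[FusionCall]) -> list[RoleStats]:
    """Per-role gene counts, genome spread and fused-gene counts."""
    return _stats_by_attr(genes, _final_ids(calls), "roles")


def compute_subsystem_stats(genes: dict[str, GeneRecord], calls: list[FusionCall]) -> list[RoleStats]:
    """Per-subsystem gene counts and fused-gene counts (empty subsystems never appear)."""
    return _stats_by_attr(genes, _final_ids(calls), "subsystems")


def filter_roles(roles: list[RoleStats], min_genomes: int = 10) -> list[RoleStats]:
    """Keep roles propagated to >= ``min_genomes`` genomes whose names lack
    generic descriptors (predicted/hypothetical/putative/possible/probable,
    case-insensitive whole-word match)."""
    return [
        r
        for r in roles
        if r.n_genomes >= min_genomes and not _GENERIC_RE.search(r.role)
    ]


def implied_threshold(mean: float, sd: float, z_min: float = 2.0) -> float:
    """Proportion above which a role exceeds the mean by > z_min SDs."""
    return mean + z_min * sd


def frequently_fused(
    roles: list[RoleStats],
    z_min: float = 2.0,
    p_max: float = 0.05,
) -> CohortFlagging:
    """Flag roles whose fused proportion is a significant excess.

    The cohort mean mu and SD sigma are computed over the supplied roles'
    proportions.  A role is flagged when its proportion strictly exceeds
    ``mu + z_min * sigma`` AND a one-sided exact binomial test of
    (n_fused of n_genes) against mu gives p < ``p_max``.  The threshold
    form keeps the test well defined on a degenerate cohort (sigma = 0):
    no role can then exceed the mean, so nothing is flagged.
    """
    if not roles:
        raise ValueError("empty role cohort")
    props = np.array([r.proportion for r in roles], dtype=float)
    mean = float(props.mean())
    sd = float(props.std(ddof=1)) if len(roles) > 1 else 0.0
    threshold = implied_threshold(mean, sd, z_min)
    p_ref = min(max(mean, 0.0), 1.0)

    out = []
    for r in roles:
        z = (r.proportion - mean) / sd if sd > 0 else float("nan")
        if r.proportion > threshold:
            p = binomtest(r.n_fused, r.n_genes, p_ref, alternative="greater").pvalue
            flag = p < p_max
        else:
            p = None
            flag = False
        out.append(replace(r, z=z, p=p, frequently_fused=flag))
    return CohortFlagging(roles=tuple(out), mean=mean, sd=sd, implied_threshold=threshold)


def subsystem_stats(
    genes: dict[str, GeneRecord],
    calls: list[FusionCall],
    z_min: float = 2.0,
    p_max: float = 0.05,
) -> CohortFlagging:
    """The same excess test applied at subsystem granularity."""
    rows = compute_subsystem_stats(genes, calls)
    return frequently_fused(rows, z_min=z_min, p_max=p_max)


def genome_proportionality(counts: dict[str, tuple[int, int]]) -> ProportionalityResult:
    """Fusion counts versus genome size.

    ``counts`` maps genome_id -> (n_genes, n_fused).  Returns the pooled
    fused fraction (total fused / total genes) and the least-squares
    through-origin slope of fused-vs-genes across genomes
    (sum(x*y)/sum(x^2)).  Requires >= 2 genomes.
    """
    if len(counts) < 2:
        raise ValueError("genome proportionality requires >= 2 genomes")
    x = np.array([v[0] for v in counts.values()], dtype=float)
    y = np.array([v[1] for v in counts.values()], dtype=float)
    fraction = float(y.sum() / x.sum())
    slope = float((x * y).sum() / (x * x).sum())
    return ProportionalityResult(fraction=fraction, slope=slope)
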