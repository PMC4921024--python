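"""Core domain types shared by the whole fusion-detection pipeline.

Conventions
-----------
All residue coordinates are 1-based and inclusive (BLAST tabular
convention); an alignment spanning positions ``start..end`` therefore has
length ``end - start + 1``.  Multi-valued annotation cells (functional
roles, subsystems, training-set sources) are semicolon-separated on disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected format."""


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration keys/values."""


@dataclass
class GeneRecord:
    """A protein-coding gene: identity, genome, length and annotation.

    ``length`` is the protein length in amino-acid residues.  ``roles`` is
    the list of functional roles annotated on the gene (a bifunctional
    fusion carries one role per fused activity); ``subsystems`` lists the
    pathway/complex subsystems the gene belongs to (possibly empty).
    """

    gene_id: str
    genome_id: str
    length: int
    roles: list[str] = field(default_factory=list)
    subsystems: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FormatError(
                f"gene {self.gene_id!r}: length must be >= 1, got {self.length}"
            )
        if self.roles is None or self.subsystems is None:
            raise FormatError(f"gene {self.gene_id!r}: roles/subsystems may not be null")


@dataclass
class CDDRecord:
    """A conserved-domain model with its length and full-gene status.

    ``is_full_gene`` is computed by the atlas stage: True once some gene in
    the database shows a bidirectional alignment covering more than the
    configured fraction (default 90%) of both the model and the gene —
    i.e. the domain represents an entire standalone gene somewhere.
    Initially ``None`` (unset).
    """

    cdd_id: str
    model_length: int
    description: str = ""
    is_full_gene: bool | None = None

    def __post_init__(self) -> None:
        if self.model_length < 1:
            raise FormatError(
                f"CDD {self.cdd_id!r}: model_length must be >= 1, got {self.model_length}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One alignment of one domain model to one gene.

    Coordinates on both the gene and the domain model are 1-based
    inclusive.  ``pct_identity`` is optional (absent in some scan outputs).
    """

    gene_id: str
    cdd_id: str
    gene_start: int
    gene_end: int
    cdd_start: int
    cdd_end: int
    e_value: float
    pct_identity: float | None = None

    def __post_init__(self) -> None:
        if self.gene_start < 1 or self.cdd_start < 1:
            raise FormatError(f"hit {self.gene_id}/{self.cdd_id}: coordinates must be >= 1")
        if self.gene_end < self.gene_start or self.cdd_end < self.cdd_start:
            raise FormatError(f"hit {self.gene_id}/{self.cdd_id}: end precedes start")
        if self.e_value < 0:
            raise FormatError(f"hit {self.gene_id}/{self.cdd_id}: negative E-value")

    @property
    def aln_length(self) -> int:
        """Alignment length on the gene, in residues."""
        return self.gene_end - self.gene_start + 1

    @property
    def model_span(self) -> int:
        """Alignment length on the domain model, in residues."""
        return self.cdd_end - self.cdd_start + 1

    def model_coverage(self, model_length: int) -> float:
        return self.model_span / model_length

    def gene_coverage(self, gene_length: int) -> float:
        return self.aln_length / gene_length

    def overlap(self, other: "DomainHit") -> int:
        """Number of gene residues shared with ``other`` (0 if disjoint)."""
        return max(
            0,
            min(self.gene_end, other.gene_end)
            - max(self.gene_start, other.gene_start)
            + 1,
        )


class TrainingStatus(str, Enum):
    confirmed_fusion = "confirmed_fusion"
    uncertain = "uncertain"
    rejected = "rejected"


#: Curation sources recognised in training tables.
TRAINING_SOURCES = ("Enright", "Serres", "IMG", "SEED", "Bvitamin")


@dataclass(frozen=True)
class TrainingEntry:
    """One curated training-set gene: its status and curation source(s)."""

    gene_id: str
    status: TrainingStatus
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.sources) - set(TRAINING_SOURCES)
        if bad:
            raise FormatError(
                f"training entry {self.gene_id!r}: unknown source(s) {sorted(bad)}"
            )


@dataclass
class Thresholds:
    """All numeric knobs of the detection pipeline.

    Defaults are the published operating point of the eight-criteria
    filter: hits below E-value 1e-5, full-gene domains at >90%
    bidirectional coverage, selected alignments covering >=50% of their
    model, protein length >600 aa, combined domain coverage >=40% of the
    gene, alignments >=50 aa, fusion points >=60 aa and >=10% of length
    from either terminus, <1500 co-occurring domain sets, <1000 pair
    matches, and fewer than half of all hits crossing a gap.
    """

    e_value_max: float = 1e-5
    full_gene_coverage: float = 0.90
    domain_coverage_min: float = 0.50
    min_protein_length: int = 600
    combined_coverage_min: float = 0.40
    min_alignment_length: int = 50
    min_gap_distance_residues: int = 60
    min_gap_distance_fraction: float = 0.10
    max_cooccurring_sets: int = 1500
    max_pair_matches: int = 1000
    gap_crossing_fraction_max: float = 0.5
    criteria_policy: str = "all"  # "all" or "at_least_k"
    criteria_k: int = 8
    # residues two selected alignments may share and still count as
    # non-overlapping (0 = strictly disjoint)
    overlap_tolerance: int = 0
    # CDD-set consolidation: fraction of jointly-hit genes required to link
    # two models, and the per-gene interval Jaccard calling their
    # footprints "the same alignment"
    set_similarity_min: float = 0.5
    set_interval_jaccard_min: float = 0.8

    _FRACTIONS = (
        "full_gene_coverage",
        "domain_coverage_min",
        "combined_coverage_min",
        "min_gap_distance_fraction",
        "gap_crossing_fraction_max",
        "set_similarity_min",
        "set_interval_jaccard_min",
    )
    _COUNTS = (
        "min_protein_length",
        "min_alignment_length",
        "min_gap_distance_residues",
        "max_cooccurring_sets",
        "max_pair_matches",
        "criteria_k",
        "overlap_tolerance",
    )

    def __post_init__(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        for name in self._COUNTS:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.e_value_max < 0:
            raise ConfigError("e_value_max must be >= 0")
        if self.criteria_policy not in ("all", "at_least_k"):
            raise ConfigError(
                f"criteria_policy must be 'all' or 'at_least_k', got {self.criteria_policy!r}"
            )

    def replace(self, **kwargs) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))
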