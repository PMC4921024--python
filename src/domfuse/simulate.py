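"""Synthetic fixture generator with planted ground truth.

The generator emulates the false-positive taxonomy observed in curated
fusion datasets so that every workflow stage can be exercised without
any database access:

* ``true_fusion`` — two disjoint, nearly full-model alignments from
  distinct non-promiscuous domains, with gap geometry satisfying the
  default filter criteria; both domains also occur as standalone
  single-domain genes (the Rosetta-stone configuration);
* ``single_domain`` — one domain covering essentially the whole gene
  (these genes are what makes domains "full-gene");
* ``multifunctional_single_domain`` — one full-gene domain but two
  annotated functional roles: an annotation-level false fusion;
* ``subdomain_decoy`` — two disjoint alignments from models that only
  ever align as small sub-domains and never reach bidirectional
  full-gene coverage anywhere; these inflate the naive multi-domain
  count but are removed wholesale by the full-gene-domain filter;
* ``promiscuous_multidomain`` — short modular proteins reusing a small
  pool of promiscuous modules across many partners (two-component /
  ABC-transporter style); realistic module sizes keep these genes at or
  under 600 aa, the regime the protein-length criterion targets.

Class labels are assigned by exact stratification (rounded fractions,
labels shuffled by the seeded generator) so planted counts sit at their
expectation and the final-stage count is invariant to decoy-fraction
changes.  All sampling is drawn from a single seeded generator in a fixed
order; identical configuration implies byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .caller import FusionCall
from .types import CDDRecord, ConfigError, DomainHit, GeneRecord

__all__ = ["SimConfig", "SimResult", "RecoveryResult", "generate", "score_recovery", "PLANTED_CLASSES"]

PLANTED_CLASSES = (
    "true_fusion",
    "single_domain",
    "multifunctional_single_domain",
    "subdomain_decoy",
    "promiscuous_multidomain",
)

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults: two genomes of 500 genes, 10% planted fusions and 10% of
    each decoy class.  Domain lengths are uniform within bounds; flank
    lengths (the residues outside aligned domains) are log-normal;
    alignment ends are trimmed by up to ``coverage_noise_max`` of the
    model length to mimic ragged scan alignments.
    """

    n_genomes: int = 2
    genes_per_genome: int = 500
    fraction_true_fusions: float = 0.10
    fraction_multifunctional_single_domain: float = 0.10
    fraction_subdomain_decoys: float = 0.10
    fraction_promiscuous: float = 0.10
    n_core_domains: int = 80
    n_promiscuous_domains: int = 6
    n_subdomain_cdds: int = 12
    domain_length_range: tuple[int, int] = (280, 400)
    promiscuous_domain_length_range: tuple[int, int] = (130, 240)
    subdomain_model_length_range: tuple[int, int] = (450, 650)
    gene_flank_lognorm: tuple[float, float] = (2.0, 0.6)
    coverage_noise_max: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_true_fusions,
            self.fraction_multifunctional_single_domain,
            self.fraction_subdomain_decoys,
            self.fraction_promiscuous,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise ConfigError("planted-class fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ConfigError("planted-class fractions must sum to <= 1")
        for name in ("n_genomes", "genes_per_genome", "n_core_domains",
                     "n_promiscuous_domains", "n_subdomain_cdds"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def role_of(cdd_id: str) -> str:
    """Canonical functional-role string for a synthetic domain."""
    return f"role_{cdd_id}"


@dataclass
class SimResult:
    """One generated cohort: tables plus the planted truth."""

    config: SimConfig
    genes: list[GeneRecord]
    cdds: dict[str, CDDRecord]
    hits: list[DomainHit]
    truth: dict[str, str]
    n_resampled: int = 0

    @property
    def gene_index(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}

    def write(self, outdir: str | Path, fasta: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_gene_table(self.genes, outdir / "genes.tsv")
        dio.write_cdd_table(self.cdds, outdir / "cdds.tsv")
        dio.write_domain_hits(self.hits, outdir / "hits.tsv")
        pd.DataFrame(
            {"gene_id": list(self.truth), "planted_class": list(self.truth.values())}
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if fasta:
            self.write_fasta(outdir / "proteins.fasta")

    def write_fasta(self, path: str | Path) -> None:
        """Dummy protein sequences (no homology content) for tools that
        expect sequence input."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        rng = np.random.default_rng(self.config.seed + 1)
        records = []
        for g in self.genes:
            seq = rng.choice(_AA, size=g.length).tobytes().decode()
            records.append(SeqRecord(Seq(seq), id=g.gene_id, description=g.genome_id))
        seqio_write(records, str(path), "fasta")


def _flank(rng: np.random.Generator, cfg: SimConfig, cap: int) -> int:
    mu, sigma = cfg.gene_flank_lognorm
    return min(int(rng.lognormal(mu, sigma)), cap)


def _trims(rng: np.random.Generator, cfg: SimConfig, model_length: int) -> tuple[int, int]:
    max_trim = int(cfg.coverage_noise_max * model_length)
    return int(rng.integers(0, max_trim + 1)), int(rng.integers(0, max_trim + 1))


def _hit(rng, gene_id, cdd_id, offset, model_length, ts, te) -> DomainHit:
    """An alignment of the whole model (minus end trims) placed at offset."""
    return DomainHit(
        gene_id=gene_id,
        cdd_id=cdd_id,
        gene_start=offset + 1 + ts,
        gene_end=offset + model_length - te,
        cdd_start=1 + ts,
        cdd_end=model_length - te,
        e_value=float(10.0 ** -rng.uniform(20, 80)),
        pct_identity=float(rng.uniform(55, 95)),
    )


def generate(cfg: SimConfig | None = None) -> SimResult:
    """Generate one cohort with planted ground truth (deterministic per seed)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_genomes * cfg.genes_per_genome

    # --- domain catalogue (fixed draw order) -------------------------------
    cdds: dict[str, CDDRecord] = {}
    core_ids, prom_ids, sub_ids = [], [], []
    lo, hi = cfg.domain_length_range
    for i in range(cfg.n_core_domains):
        cid = f"D{i + 1:04d}"
        core_ids.append(cid)
        cdds[cid] = CDDRecord(cid, int(rng.integers(lo, hi + 1)), f"core domain {cid}")
    lo, hi = cfg.promiscuous_domain_length_range
    for i in range(cfg.n_promiscuous_domains):
        cid = f"P{i + 1:03d}"
        prom_ids.append(cid)
        cdds[cid] = CDDRecord(cid, int(rng.integers(lo, hi + 1)), f"promiscuous module {cid}")
    lo, hi = cfg.subdomain_model_length_range
    for i in range(cfg.n_subdomain_cdds):
        cid = f"S{i + 1:03d}"
        sub_ids.append(cid)
        cdds[cid] = CDDRecord(cid, int(rng.integers(lo, hi + 1)), f"sub-domain model {cid}")

    # subsystem labels over core domains (blocks of 8)
    subsystem_of = {cid: f"subsystem_{i // 8 + 1:02d}" for i, cid in enumerate(core_ids)}

    # --- stratified class assignment ---------------------------------------
    n_fus = round(cfg.fraction_true_fusions * n_total)
    n_multi = round(cfg.fraction_multifunctional_single_domain * n_total)
    n_sub = round(cfg.fraction_subdomain_decoys * n_total)
    n_prom = round(cfg.fraction_promiscuous * n_total)
    n_single = n_total - n_fus - n_multi - n_sub - n_prom
    if n_single < 0:
        raise ConfigError("planted-class fractions leave no room for single-domain genes")
    labels = np.array(
        ["true_fusion"] * n_fus
        + ["multifunctional_single_domain"] * n_multi
        + ["subdomain_decoy"] * n_sub
        + ["promiscuous_multidomain"] * n_prom
        + ["single_domain"] * n_single
    )
    rng.shuffle(labels)

    # pre-assign standalone domains to single-domain genes: a couple of
    # core domains first (fusions need >= 2 full-gene cores to draw from),
    # then one standalone per promiscuous module (each needs a standalone
    # gene to become full-gene), then the remaining cores cyclically
    single_positions = [i for i in range(n_total) if labels[i] == "single_domain"]
    standalone_domain: dict[int, str] = {}
    standalone_cores: list[str] = []
    n_reserved = min(2, len(core_ids)) if n_fus > 0 else 0
    for k, pos in enumerate(single_positions):
        if n_reserved <= k < n_reserved + len(prom_ids):
            standalone_domain[pos] = prom_ids[k - n_reserved]
        else:
            j = k if k < n_reserved else k - n_reserved - len(prom_ids)
            cid = core_ids[j % len(core_ids)]
            standalone_domain[pos] = cid
            if cid not in standalone_cores:
                standalone_cores.append(cid)
    if n_fus > 0 and len(standalone_cores) < 2:
        raise ConfigError("too few single-domain genes to anchor full-gene domains for fusions")

    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    truth: dict[str, str] = {}
    n_resampled = 0

    for i in range(n_total):
        genome = f"genome_{i // cfg.genes_per_genome + 1:03d}"
        gene_id = f"g{i + 1:06d}"
        cls = str(labels[i])
        roles: list[str] = []
        subsystems: list[str] = []

        if cls in ("single_domain", "multifunctional_single_domain"):
            if cls == "single_domain":
                cid = standalone_domain[i]
            else:
                cid = core_ids[int(rng.integers(0, len(core_ids)))]
            ml = cdds[cid].model_length
            fcap = max(1, int(0.025 * ml))
            f_n = _flank(rng, cfg, fcap)
            f_c = _flank(rng, cfg, fcap)
            ts, te = _trims(rng, cfg, ml)
            length = f_n + ml + f_c
            hits.append(_hit(rng, gene_id, cid, f_n, ml, ts, te))
            roles = [role_of(cid)]
            if cls == "multifunctional_single_domain":
                roles.append(role_of(cid) + "_secondary")
            if cid in subsystem_of:
                subsystems = [subsystem_of[cid]]

        elif cls == "true_fusion":
            while True:
                pick = rng.choice(len(standalone_cores), size=2, replace=False)
                d1, d2 = standalone_cores[int(pick[0])], standalone_cores[int(pick[1])]
                l1, l2 = cdds[d1].model_length, cdds[d2].model_length
                gap = int(rng.integers(60, 121))
                f_n = _flank(rng, cfg, 15)
                f_c = _flank(rng, cfg, 15)
                length = f_n + l1 + gap + l2 + f_c
                if length > 600:
                    break
                n_resampled += 1  # geometry too short for the length criterion
            t1s, t1e = _trims(rng, cfg, l1)
            t2s, t2e = _trims(rng, cfg, l2)
            hits.append(_hit(rng, gene_id, d1, f_n, l1, t1s, t1e))
            hits.append(_hit(rng, gene_id, d2, f_n + l1 + gap, l2, t2s, t2e))
            roles = [role_of(d1), role_of(d2)]
            subsystems = sorted({subsystem_of[d1], subsystem_of[d2]})

        elif cls == "subdomain_decoy":
            pick = rng.choice(len(sub_ids), size=2, replace=False)
            s1, s2 = sub_ids[int(pick[0])], sub_ids[int(pick[1])]
            a1 = int(rng.integers(80, 161))
            a2 = int(rng.integers(80, 161))
            f_n = int(rng.integers(20, 61))
            gap = int(rng.integers(40, 91))
            f_c = int(rng.integers(20, 61))
            length = f_n + a1 + gap + a2 + f_c
            cs1 = int(rng.integers(1, cdds[s1].model_length - a1 + 2))
            cs2 = int(rng.integers(1, cdds[s2].model_length - a2 + 2))
            hits.append(
                DomainHit(gene_id, s1, f_n + 1, f_n + a1, cs1, cs1 + a1 - 1,
                          float(10.0 ** -rng.uniform(6, 20)), float(rng.uniform(25, 45)))
            )
            hits.append(
                DomainHit(gene_id, s2, f_n + a1 + gap + 1, f_n + a1 + gap + a2,
                          cs2, cs2 + a2 - 1,
                          float(10.0 ** -rng.uniform(6, 20)), float(rng.uniform(25, 45)))
            )
            roles = [f"uncharacterized protein {gene_id}"]

        elif cls == "promiscuous_multidomain":
            pick = rng.choice(len(prom_ids), size=2, replace=False)
            p1, p2 = prom_ids[int(pick[0])], prom_ids[int(pick[1])]
            l1, l2 = cdds[p1].model_length, cdds[p2].model_length
            gap = int(rng.integers(20, 61))
            f_n = _flank(rng, cfg, 10)
            f_c = _flank(rng, cfg, 10)
            length = f_n + l1 + gap + l2 + f_c
            t1s, t1e = _trims(rng, cfg, l1)
            t2s, t2e = _trims(rng, cfg, l2)
            hits.append(_hit(rng, gene_id, p1, f_n, l1, t1s, t1e))
            hits.append(_hit(rng, gene_id, p2, f_n + l1 + gap, l2, t2s, t2e))
            roles = [role_of(p1), role_of(p2)]

        else:  # pragma: no cover
            raise AssertionError(cls)

        genes.append(GeneRecord(gene_id, genome, length, roles, subsystems))
        truth[gene_id] = cls

    return SimResult(config=cfg, genes=genes, cdds=cdds, hits=hits, truth=truth,
                     n_resampled=n_resampled)


@dataclass(frozen=True)
class RecoveryResult:
    """Precision/recall of a call set against the planted truth."""

    recall: float
    precision: float
    n_planted: int
    n_final: int
    called_by_class: dict[str, int]


def score_recovery(calls: list[FusionCall], truth: dict[str, str]) -> RecoveryResult:
    """Confusion accounting of final calls versus planted classes.

    ``recall`` = called planted fusions / planted fusions; ``precision`` =
    called planted fusions / all final calls.  Either is NaN when its
    denominator is zero (e.g. a caller that flags nothing has undefined
    precision, not zero).
    """
    final = {c.gene_id for c in calls if c.is_final}
    planted = {g for g, cls in truth.items() if cls == "true_fusion"}
    called_true = len(final & planted)
    by_class: dict[str, int] = {cls: 0 for cls in PLANTED_CLASSES}
    for g in final:
        if g in truth:
            by_class[truth[g]] += 1
    recall = called_true / len(planted) if planted else float("nan")
    precision = called_true / len(final) if final else float("nan")
    return RecoveryResult(
        recall=recall,
        precision=precision,
        n_planted=len(planted),
        n_final=len(final),
        called_by_class=by_class,
    )


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a flat YAML mapping; unknown keys are errors."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    unknown = sorted(set(data) - set(SimConfig.field_names()))
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {unknown}")
    for key in ("domain_length_range", "promiscuous_domain_length_range",
                "subdomain_model_length_range", "gene_flank_lognorm"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimConfig(**data)
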