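"""Readers and writers for every on-disk format the pipeline touches.

All tables are header-carrying TSV; column order is free (headers are
mapped by name).  Multi-valued cells use semicolon separators with no
quoting dialect.  Every reader/writer pair is a lossless round trip for
valid data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .caller import CriteriaResult, FusionCall, FusionCandidate, Stage
from .types import (
    CDDRecord,
    ConfigError,
    DomainHit,
    FormatError,
    GeneRecord,
    Thresholds,
    TrainingEntry,
    TrainingStatus,
)

log = logging.getLogger(__name__)

_GENE_COLUMNS = ("gene_id", "genome_id", "length", "roles")
_HIT_COLUMNS = ("gene_id", "cdd_id", "gene_start", "gene_end", "cdd_start", "cdd_end", "e_value")
_CDD_COLUMNS = ("cdd_id", "model_length")


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _split_multi(cell: str) -> list[str]:
    return [part for part in cell.split(";") if part] if cell else []


def _int_cell(row, col, path) -> int:
    raw = row[col]
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: non-integer {col} value {raw!r}") from None


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene/genome annotation table; duplicate gene_id is rejected."""
    df = _read_tsv(path, _GENE_COLUMNS)
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicated gene_id {dup.iloc[0]!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            GeneRecord(
                gene_id=row["gene_id"],
                genome_id=row["genome_id"],
                length=_int_cell(row, "length", path),
                roles=_split_multi(row["roles"]),
                subsystems=_split_multi(row["subsystems"]) if "subsystems" in df.columns else [],
            )
        )
    return out


def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "genome_id": [g.genome_id for g in genes],
            "length": [g.length for g in genes],
            "roles": [";".join(g.roles) for g in genes],
            "subsystems": [";".join(g.subsystems) for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cdd_table(path: str | Path) -> dict[str, CDDRecord]:
    """Read a domain-model catalogue keyed by cdd_id."""
    df = _read_tsv(path, _CDD_COLUMNS)
    out: dict[str, CDDRecord] = {}
    for _, row in df.iterrows():
        cdd_id = row["cdd_id"]
        if cdd_id in out:
            raise FormatError(f"{path}: duplicated cdd_id {cdd_id!r}")
        out[cdd_id] = CDDRecord(
            cdd_id=cdd_id,
            model_length=_int_cell(row, "model_length", path),
            description=row["description"] if "description" in df.columns else "",
        )
    return out


def write_cdd_table(cdds: dict[str, CDDRecord], path: str | Path) -> None:
    recs = sorted(cdds.values(), key=lambda r: r.cdd_id)
    df = pd.DataFrame(
        {
            "cdd_id": [r.cdd_id for r in recs],
            "model_length": [r.model_length for r in recs],
            "description": [r.description for r in recs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_domain_hits(
    path: str | Path,
    genes: dict[str, GeneRecord],
    cdds: dict[str, CDDRecord],
) -> tuple[list[DomainHit], int]:
    """Read a BLAST-tabular-style domain-hit table.

    Hits violating coordinate invariants against the gene/model lengths,
    or referring to unknown genes or models, are dropped with a logged
    count (large scan outputs contain edge artifacts); negative or
    non-numeric coordinates are a format error.  Returns (hits, n_dropped).
    """
    df = _read_tsv(path, _HIT_COLUMNS)
    hits: list[DomainHit] = []
    dropped = 0
    has_ident = "pct_identity" in df.columns
    for _, row in df.iterrows():
        gs = _int_cell(row, "gene_start", path)
        ge = _int_cell(row, "gene_end", path)
        cs = _int_cell(row, "cdd_start", path)
        ce = _int_cell(row, "cdd_end", path)
        if min(gs, ge, cs, ce) < 0:
            raise FormatError(f"{path}: negative coordinate on gene {row['gene_id']!r}")
        try:
            e_value = float(row["e_value"])
        except ValueError:
            raise FormatError(f"{path}: non-numeric e_value {row['e_value']!r}") from None
        ident = None
        if has_ident and row["pct_identity"] != "":
            ident = float(row["pct_identity"])
        gene = genes.get(row["gene_id"])
        model = cdds.get(row["cdd_id"])
        if (
            gene is None
            or model is None
            or gs < 1
            or cs < 1
            or ge < gs
            or ce < cs
            or ge > gene.length
            or ce > model.model_length
            or e_value < 0
        ):
            dropped += 1
            continue
        hits.append(
            DomainHit(
                gene_id=row["gene_id"],
                cdd_id=row["cdd_id"],
                gene_start=gs,
                gene_end=ge,
                cdd_start=cs,
                cdd_end=ce,
                e_value=e_value,
                pct_identity=ident,
            )
        )
    if dropped:
        log.warning("%s: dropped %d hit(s) violating invariants", path, dropped)
    return hits, dropped


def write_domain_hits(hits: list[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hits],
            "cdd_id": [h.cdd_id for h in hits],
            "gene_start": [h.gene_start for h in hits],
            "gene_end": [h.gene_end for h in hits],
            "cdd_start": [h.cdd_start for h in hits],
            "cdd_end": [h.cdd_end for h in hits],
            "e_value": [repr(h.e_value) for h in hits],
            "pct_identity": ["" if h.pct_identity is None else repr(h.pct_identity) for h in hits],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_training_table(path: str | Path) -> list[TrainingEntry]:
    """Read a curated training-set table (gene_id, status, sources)."""
    df = _read_tsv(path, ("gene_id", "status"))
    out = []
    for _, row in df.iterrows():
        try:
            status = TrainingStatus(row["status"])
        except ValueError:
            raise FormatError(f"{path}: unknown status {row['status']!r}") from None
        sources = frozenset(_split_multi(row["sources"])) if "sources" in df.columns else frozenset()
        out.append(TrainingEntry(gene_id=row["gene_id"], status=status, sources=sources))
    return out


def write_training_table(entries: list[TrainingEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in entries],
            "status": [e.status.value for e in entries],
            "sources": [";".join(sorted(e.sources)) for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fusion-call table

def _encode_hit(h: DomainHit) -> str:
    ident = "" if h.pct_identity is None else repr(h.pct_identity)
    return ":".join(
        [h.cdd_id, str(h.gene_start), str(h.gene_end), str(h.cdd_start), str(h.cdd_end), repr(h.e_value), ident]
    )


def _decode_hit(gene_id: str, token: str) -> DomainHit:
    cdd_id, gs, ge, cs, ce, ev, ident = token.split(":")
    return DomainHit(
        gene_id=gene_id,
        cdd_id=cdd_id,
        gene_start=int(gs),
        gene_end=int(ge),
        cdd_start=int(cs),
        cdd_end=int(ce),
        e_value=float(ev),
        pct_identity=float(ident) if ident else None,
    )


def write_fusion_calls(calls: list[FusionCall], path: str | Path) -> None:
    """Write the per-gene call table; read-back reproduces the calls.

    One row per call: gene, genome, selected cdd_ids in N->C order, the
    encoded selected alignments, per-criterion measured value and
    pass/fail, stage reached and final verdict.
    """
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "gene_id": c.gene_id,
            "genome_id": c.genome_id,
            "stage": c.stage.value,
            "cdd_ids": ",".join(c.candidate.cdd_ids) if c.candidate else "",
            "segments": ";".join(_encode_hit(h) for h in c.candidate.selected) if c.candidate else "",
            "verdict": "" if c.criteria is None else str(c.criteria.verdict),
        }
        for k in range(1, 9):
            row[f"c{k}_value"] = "" if c.criteria is None else repr(c.criteria.values[k])
            row[f"c{k}_pass"] = "" if c.criteria is None else str(c.criteria.passed[k])
        rows.append(row)
    cols = ["gene_id", "genome_id", "stage", "cdd_ids", "segments", "verdict"]
    cols += [f"c{k}_{w}" for k in range(1, 9) for w in ("value", "pass")]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_fusion_calls(path: str | Path) -> list[FusionCall]:
    df = _read_tsv(path, ("gene_id", "genome_id", "stage"))
    calls = []
    for _, row in df.iterrows():
        candidate = None
        if row.get("segments", ""):
            hits = [_decode_hit(row["gene_id"], tok) for tok in row["segments"].split(";")]
            candidate = FusionCandidate.from_hits(row["gene_id"], hits)
        criteria = None
        if row.get("verdict", "") != "":
            values = {k: float(row[f"c{k}_value"]) for k in range(1, 9)}
            passed = {k: row[f"c{k}_pass"] == "True" for k in range(1, 9)}
            criteria = CriteriaResult(values=values, passed=passed, verdict=row["verdict"] == "True")
        calls.append(
            FusionCall(
                gene_id=row["gene_id"],
                genome_id=row["genome_id"],
                stage=Stage(row["stage"]),
                candidate=candidate,
                criteria=criteria,
            )
        )
    return calls


def write_stage_summary(summary: dict[str, dict[str, int]], path: str | Path) -> None:
    """Per-genome workflow-stage counts as TSV."""
    rows = [
        {
            "genome_id": genome,
            "naive_multidomain": counts["naive_multidomain"],
            "full_gene_candidate": counts["full_gene_candidate"],
            "final_fusion": counts["final_fusion"],
        }
        for genome, counts in sorted(summary.items())
    ]
    pd.DataFrame(
        rows, columns=["genome_id", "naive_multidomain", "full_gene_candidate", "final_fusion"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# atlas dumps (optional outputs mirroring the call tables)

def write_cdd_sets(sets, index, path: str | Path) -> None:
    """Dump consolidated domain sets with per-model co-occurrence counts."""
    rows = []
    for s in sorted(sets, key=lambda s: s.set_id):
        for m in sorted(s.members):
            rows.append(
                {"set_id": s.set_id, "cdd_id": m, "cooccurring_sets": index.cooccurring(m)}
            )
    pd.DataFrame(rows, columns=["set_id", "cdd_id", "cooccurring_sets"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id (generator output only)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# configuration

def load_thresholds(path: str | Path) -> Thresholds:
    """Load a flat key/value config mapping 1:1 onto threshold fields.

    Unknown keys are an error, protecting against silent typos in
    threshold names.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    known = set(Thresholds.field_names())
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {unknown}")
    return Thresholds(**data)


def write_thresholds(t: Thresholds, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(t.to_dict(), fh, sort_keys=True)
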