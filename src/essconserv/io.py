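"""Readers and writers for the tabular and sequence formats the pipeline touches.

Sequences travel as FASTA; annotations (essentiality labels, COG letters,
homolog-presence counts) and all results travel as tab-separated tables
with a header row. Homology hits use the 12-column BLAST tabular dialect
(outfmt 6), 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from Bio import SeqIO

from .codons import GeneticCode, InternalStopError, translate_cds

logger = logging.getLogger(__name__)

ESSENTIAL_LABELS = {"E": True, "NE": False}


@dataclass
class GeneRecord:
    """One annotated protein-coding gene."""

    gene_id: str
    organism_id: str
    cds: str
    protein: str
    essential: bool
    cog_letters: frozenset = frozenset()


@dataclass
class OrganismDataset:
    """All labelled genes of one organism plus homolog-presence evidence.

    ``homolog_counts`` maps gene_id to the number of *other* organisms in
    which a homologous protein was found — the evidence behind persistent-
    nonessential calls. Genes absent from the table count 0.
    """

    organism_id: str
    genes: Dict[str, GeneRecord]
    homolog_counts: Dict[str, int] = field(default_factory=dict)

    def homolog_count(self, gene_id: str) -> int:
        return self.homolog_counts.get(gene_id, 0)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column BLAST tabular (outfmt 6) file."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping.

    Ids are the first whitespace-delimited token of each header; duplicate
    ids and empty files are errors.
    """
    records: Dict[str, str] = {}
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _read_tsv_rows(path) -> Iterable[List[str]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_annotations(
    organism_id: str,
    cds_by_id: Mapping[str, str],
    ess_path,
    cog_path=None,
    homolog_path=None,
    code: GeneticCode | int = 11,
) -> OrganismDataset:
    """Assemble an :class:`OrganismDataset` from sequences plus annotation tables.

    Only genes with an essentiality label enter the dataset. Genes missing
    from the COG table get an empty letter set (the study design must
    tolerate whole organisms without COG annotation); genes missing from
    the homolog table count 0. Genes whose CDS contains an internal stop
    are rejected with a logged warning, mirroring how annotation artefacts
    are dropped rather than propagated into site counts.
    """
    if isinstance(code, int):
        code = GeneticCode.from_table_id(code)

    labels: Dict[str, bool] = {}
    for lineno, fields in _read_tsv_rows(ess_path):
        if fields[0] == "gene_id":
            continue
        gene_id, token = fields[0], fields[1]
        if gene_id not in cds_by_id:
            raise ValueError(
                f"{ess_path}:{lineno}: essentiality label for unknown gene {gene_id!r}"
            )
        if token not in ESSENTIAL_LABELS:
            raise ValueError(
                f"{ess_path}:{lineno}: unknown essentiality label {token!r} "
                f"(expected one of {sorted(ESSENTIAL_LABELS)})"
            )
        labels[gene_id] = ESSENTIAL_LABELS[token]

    cogs: Dict[str, frozenset] = {}
    if cog_path is not None:
        for lineno, fields in _read_tsv_rows(cog_path):
            if fields[0] == "gene_id":
                continue
            letters = fields[1].strip() if len(fields) > 1 else ""
            cogs[fields[0]] = frozenset(letters)

    homolog_counts: Dict[str, int] = {}
    if homolog_path is not None:
        for lineno, fields in _read_tsv_rows(homolog_path):
            if fields[0] == "gene_id":
                continue
            n = int(fields[1])
            if n < 0:
                raise ValueError(f"{homolog_path}:{lineno}: negative homolog count")
            homolog_counts[fields[0]] = n

    genes: Dict[str, GeneRecord] = {}
    for gene_id, essential in labels.items():
        cds = cds_by_id[gene_id]
        try:
            protein = translate_cds(cds, code)
        except InternalStopError as exc:
            logger.warning(
                "organism %s: rejecting gene %s (%s)", organism_id, gene_id, exc
            )
            continue
        genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            organism_id=organism_id,
            cds=cds.upper(),
            protein=protein,
            essential=essential,
            cog_letters=cogs.get(gene_id, frozenset()),
        )
    homolog_counts = {g: n for g, n in homolog_counts.items() if g in genes}
    return OrganismDataset(
        organism_id=organism_id, genes=genes, homolog_counts=homolog_counts
    )


_HIT_FIELDS = (
    ("query_id", str),
    ("subject_id", str),
    ("percent_identity", float),
    ("alignment_length", int),
    ("mismatches", int),
    ("gap_opens", int),
    ("query_start", int),
    ("query_end", int),
    ("subject_start", int),
    ("subject_end", int),
    ("evalue", float),
    ("bit_score", float),
)


def read_hit_table(path) -> List[HitRecord]:
    """Parse a 12-column BLAST tabular file; '#' comment lines are skipped."""
    hits: List[HitRecord] = []
    for lineno, fields in _read_tsv_rows(path):
        if len(fields) != 12:
            raise ValueError(
                f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        kwargs = {}
        for (name, cast), value in zip(_HIT_FIELDS, fields):
            try:
                kwargs[name] = cast(value)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad value {value!r} for column {name}"
                ) from exc
        hits.append(HitRecord(**kwargs))
    return hits


def write_hit_table(hits: Sequence[HitRecord], path) -> None:
    with open(path, "w") as out:
        for h in hits:
            out.write(
                "\t".join(
                    _format_cell(getattr(h, name)) for name, _ in _HIT_FIELDS
                )
                + "\n"
            )


def read_kaks_table(path) -> Dict[str, "KaKsResult"]:
    """Read a per-pair Ka/Ks results TSV back into KaKsResult objects,
    keyed by query gene id ("NA" cells become None / invalid flags)."""
    from .ng86 import KaKsResult

    def _opt(v):
        return None if v == "NA" else float(v)

    results: Dict[str, KaKsResult] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ka = _opt(f[col["Ka"]])
            ks = _opt(f[col["Ks"]])
            results[f[col["query"]]] = KaKsResult(
                S=float(f[col["S"]]),
                N=float(f[col["N"]]),
                Sd=float(f[col["Sd"]]),
                Nd=float(f[col["Nd"]]),
                pS=_opt(f[col["pS"]]),
                pN=_opt(f[col["pN"]]),
                Ka=ka,
                Ks=ks,
                ratio=_opt(f[col["KaKs"]]),
                valid_ka=ka is not None,
                valid_ks=ks is not None,
                zero_variation=f[col["zero_variation"]] == "True",
                n_codons=int(f[col["n_codons"]]) if "n_codons" in col else 0,
            )
    return results


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_table(
    records: Sequence[Mapping], path, columns: Sequence[str]
) -> None:
    """Write row mappings as a header-bearing TSV.

    Floats are rendered to 6 significant digits; None/NaN become "NA".
    Every record must supply every column.
    """
    with open(path, "w") as out:
        out.write("\t".join(columns) + "\n")
        for i, rec in enumerate(records):
            missing = [c for c in columns if c not in rec]
            if missing:
                raise ValueError(f"record {i} missing columns {missing}")
            out.write("\t".join(_format_cell(rec[c]) for c in columns) + "\n")
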