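"""Readers and writers for the flat-file formats the pipeline consumes.

3'UTRs travel as FASTA (record id up to the first whitespace is the gene
id); mature miRNAs as 2-column tab-separated text (name, RNA sequence) with
``#`` comments; precomputed conserved-site universes as TargetScan-style
tab-separated predicted-target files.  All output tables are tab-separated
with one header line and ``.`` for missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seeds import MatureMirna
from .sites import UtrRecord
from .universe import SeedUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "read_utr_fasta",
    "write_utr_fasta",
    "read_mirna_table",
    "write_mirna_table",
    "read_targetscan",
    "write_tsv",
]

#: TargetScan seed-match labels accepted (case-insensitive) and their
#: canonical spelling.
_TARGETSCAN_SITE_TYPES = {"8mer": "8mer", "7mer-m8": "7mer-m8", "7mer-1a": "7mer-1A"}


def read_utr_fasta(path) -> List[UtrRecord]:
    """Read 3'UTRs from FASTA; the id up to the first whitespace is the gene id."""
    records = [
        UtrRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in {path}")
        seen.add(rec.gene_id)
    return records


def write_utr_fasta(utrs: Sequence[UtrRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(u.sequence), id=u.gene_id, description="") for u in utrs),
        str(path),
        "fasta",
    )


def read_mirna_table(path) -> List[MatureMirna]:
    """Read (name, mature RNA sequence) rows from tab-separated text."""
    mirnas: List[MatureMirna] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        mirnas.append(MatureMirna(parts[0].strip(), parts[1].strip()))
    return mirnas


def write_mirna_table(mirnas: Sequence[MatureMirna], path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tsequence\n")
        for m in mirnas:
            fh.write(f"{m.name}\t{m.sequence}\n")


def read_targetscan(
    path,
    species_id: str = "10090",
    background_genes: Optional[Iterable[str]] = None,
) -> SeedUniverse:
    """Build a seed-site universe from a TargetScan-style flat file.

    The file is tab-separated with a header; columns are interpreted
    positionally as (miR family, gene id, gene symbol, species id, UTR start,
    UTR end, seed match type, ...).  Rows are filtered to ``species_id`` and
    to the accepted seed-match labels.  ``background_genes`` extends the
    universe with interrogated genes that carry no predicted site.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 7:
        raise ValueError(
            f"{path}: expected >= 7 tab-separated columns, found {table.shape[1]}"
        )
    family_col, gene_col = table.columns[0], table.columns[1]
    species_col, type_col = table.columns[3], table.columns[6]
    rows = table[table[species_col].astype(str) == str(species_id)]
    site_type = rows[type_col].astype(str).str.lower()
    rows = rows[site_type.isin(_TARGETSCAN_SITE_TYPES)]
    logger.info(
        "TargetScan file %s: kept %d/%d rows for species %s",
        path, len(rows), len(table), species_id,
    )
    incidence: Dict[str, Dict[str, int]] = {}
    for family, gene in zip(rows[family_col], rows[gene_col]):
        per_gene = incidence.setdefault(str(family), {})
        per_gene[str(gene)] = per_gene.get(str(gene), 0) + 1
    genes = list(dict.fromkeys(str(g) for g in rows[gene_col]))
    if background_genes is not None:
        for gene in background_genes:
            if gene not in set(genes):
                genes.append(gene)
    total = sum(c for pg in incidence.values() for c in pg.values())
    return SeedUniverse(
        genes=genes,
        families=sorted(incidence),
        incidence=incidence,
        n_sites_total=total,
    )


def write_tsv(frame: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a report table: tab-separated, one header line, '.' for missing."""
    frame.to_csv(path, sep="\t", index=False, na_rep=".", float_format=float_format)
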