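"""Readers and writers for every external format the pipeline touches.

Formats: 7-column gene table TSV, plain FASTA, 14-column extended BLAST
tabular ("std qlen slen"), phenotype CSV and Newick. All downstream modules
operate on in-memory domain types only.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence, Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .types import DEFAULT_MOBILE_KEYWORDS, GeneRecord, PhenotypeTable, SimilarityHit

PathLike = Union[str, Path]

GENE_TABLE_COLUMNS = [
    "genome_id",
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "annotation",
]

#: Column order of the extended BLAST tabular dialect: the standard 12 columns
#: plus query and subject sequence lengths, which the >=50%-of-either-protein
#: coverage rule requires.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(
    path: PathLike,
    mobile_keywords: Sequence[str] = DEFAULT_MOBILE_KEYWORDS,
) -> list[GeneRecord]:
    """Read a 7-column gene table TSV into validated, sorted GeneRecords.

    Records are sorted by (genome_id, contig_id, start); ``is_mobile`` is set
    from a case-insensitive substring match of the annotation against
    ``mobile_keywords``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene table is missing column(s) {', '.join(missing)}")
    records: list[GeneRecord] = []
    seen: set[str] = set()
    low_keywords = [k.lower() for k in mobile_keywords]
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer coordinate on line {i}") from exc
        if end < start:
            raise ValidationError(f"{path}: end < start on line {i} (gene {row.gene_id})")
        if row.gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene_id {row.gene_id!r} on line {i}")
        seen.add(row.gene_id)
        ann_low = row.annotation.lower()
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                contig_id=row.contig_id,
                start=start,
                end=end,
                strand=row.strand,
                annotation=row.annotation,
                is_mobile=any(k in ann_low for k in low_keywords),
            )
        )
    records.sort(key=lambda r: (r.genome_id, r.contig_id, r.start))
    return records


def write_gene_table(records: Iterable[GeneRecord], path: PathLike) -> None:
    rows = [
        (r.genome_id, r.gene_id, r.contig_id, r.start, r.end, r.strand, r.annotation)
        for r in records
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[GeneRecord], path: PathLike) -> None:
    """Write nucleotide sequences (gene_id as record id); skips records without one."""
    seqs = [
        SeqRecord(Seq(r.nt_seq), id=r.gene_id, description="")
        for r in records
        if r.nt_seq is not None
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into a {sequence_id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def attach_sequences(records: Sequence[GeneRecord], seqs: dict[str, str]) -> list[GeneRecord]:
    """Return copies of ``records`` with nt_seq/aa_len filled from ``seqs``."""
    out = []
    for r in records:
        seq = seqs.get(r.gene_id)
        if seq is None:
            out.append(r)
        else:
            out.append(dataclasses.replace(r, nt_seq=seq, aa_len=len(seq) // 3))
    return out


# ---------------------------------------------------------------------------
# similarity hits
# ---------------------------------------------------------------------------

def read_hits(path: PathLike) -> list[SimilarityHit]:
    """Read 14-column extended BLAST tabular hits; self-hits are dropped."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 14:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} columns, expected 14 "
                    "(standard 12-column tabular plus qlen, slen)"
                )
            if fields[0] == fields[1]:  # self-hit
                continue
            try:
                hits.append(
                    SimilarityHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        e_value=float(fields[10]),
                        q_len=int(fields[12]),
                        s_len=int(fields[13]),
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}: non-numeric field on line {lineno}") from exc
    return hits


def write_hits(hits: Iterable[SimilarityHit], path: PathLike) -> None:
    """Write hits as 14-column tabular rows.

    Fields not carried by SimilarityHit (mismatch, gapopen, coordinates,
    bitscore) are reconstructed deterministically from the carried ones.
    """
    with open(path, "w") as fh:
        for h in hits:
            mismatch = round(h.aln_length * (1.0 - h.pct_identity / 100.0))
            bitscore = round(2.0 * h.aln_length)
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.6g}",
                        str(h.aln_length),
                        str(mismatch),
                        "0",
                        "1",
                        str(h.aln_length),
                        "1",
                        str(h.aln_length),
                        f"{h.e_value:.6g}",
                        str(bitscore),
                        str(h.q_len),
                        str(h.s_len),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: PathLike) -> PhenotypeTable:
    """Read a strain x carbohydrate OD CSV (first column 'strain')."""
    df = pd.read_csv(path)
    if df.columns[0] != "strain":
        raise FormatError(f"{path}: first column must be 'strain', got {df.columns[0]!r}")
    df = df.set_index("strain")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric OD value") from exc
    if df.isna().values.any():
        raise ValidationError(f"{path}: missing OD value")
    return PhenotypeTable(od=df)


def write_phenotypes(pheno: PhenotypeTable, path: PathLike) -> None:
    pheno.od.to_csv(path, index_label="strain", float_format="%.6g")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: PathLike) -> list[dendropy.Tree]:
    """Read one or more Newick trees (shared taxon namespace).

    Trees are interpreted as unrooted for consensus purposes; branch lengths
    are preserved but unused downstream.
    """
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error classes
        raise FormatError(f"{path}: Newick parse error: {exc}") from exc
    for idx, t in enumerate(trees):
        labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError(f"{path}: duplicate leaf label in tree {idx + 1}")
    return list(trees)


def write_newick(trees: Iterable[dendropy.Tree], path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(
                t.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
            )
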