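"""Core in-memory domain types.

Coordinates are 1-based and fully inclusive (GenBank convention), so a gene's
length is ``end - start + 1``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import ValidationError

#: Annotation substrings (matched case-insensitively) that mark a gene as part
#: of the mobilome (IS elements, transposases, phage genes, ...).
DEFAULT_MOBILE_KEYWORDS: tuple[str, ...] = (
    "transposase",
    "is element",
    "insertion sequence",
    "integrase",
    "phage",
    "mobile element",
)

VALID_STRANDS = frozenset({"+", "-"})


def is_mobile_annotation(
    annotation: str, keywords: Sequence[str] = DEFAULT_MOBILE_KEYWORDS
) -> bool:
    """Return True when the annotation matches any mobilome keyword."""
    low = annotation.lower()
    return any(k.lower() in low for k in keywords)


@dataclass(frozen=True)
class GeneRecord:
    """One ORF: identity, location, strand, annotation and optional sequence."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    annotation: str = ""
    is_mobile: bool = False
    nt_seq: Optional[str] = None
    aa_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SimilarityHit:
    """One directed pairwise alignment row (a BLAST-style hit)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    e_value: float
    q_len: int
    s_len: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: identity {self.pct_identity} not in [0, 100]"
            )
        if self.aln_length < 1:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: alignment length must be >= 1"
            )
        if self.q_len < 1 or self.s_len < 1:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: q_len and s_len must be >= 1"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: E-value must be >= 0"
            )


@dataclass
class PhenotypeTable:
    """Strains x carbohydrates OD600 endpoint readings (24 h)."""

    od: pd.DataFrame  # index = strains, columns = carbohydrates

    def __post_init__(self) -> None:
        if self.od.index.duplicated().any():
            dup = self.od.index[self.od.index.duplicated()][0]
            raise ValidationError(f"duplicate strain {dup!r} in phenotype table")
        if self.od.columns.duplicated().any():
            dup = self.od.columns[self.od.columns.duplicated()][0]
            raise ValidationError(f"duplicate carbohydrate {dup!r} in phenotype table")
        if (self.od.values < 0).any():
            raise ValidationError("phenotype table contains negative OD values")

    @property
    def strains(self) -> list[str]:
        return list(self.od.index)

    @property
    def carbohydrates(self) -> list[str]:
        return list(self.od.columns)
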