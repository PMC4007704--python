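"""Per-genome and panel-level descriptive statistics.

Covers gene counts and lengths, hypothetical-annotation fractions, start-codon
usage, tRNA/IS-element tallies from annotation text, round-half-up panel
averages, and coordinate-interval arithmetic for reported inversions.

Two coordinate conventions coexist deliberately: gene lengths use the
inclusive convention (end - start + 1), while inversion spans reported from a
printed coordinate pair use end - start with Kb truncated (floor), matching
how such spans are conventionally printed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .errors import ConfigError, ValidationError
from .types import GeneRecord

START_CODONS = ("ATG", "GTG", "TTG", "CTG")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Arithmetic rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if ndigits == 0 else v


@dataclass
class GenomeSummary:
    genome_id: str
    genome_length_bp: int
    n_genes: int
    n_trna: int
    n_is_elements: int
    pct_hypothetical: float
    pct_assigned: float
    start_codon_freqs: dict = field(default_factory=dict)


@dataclass
class PanelAverages:
    mean_genome_length_bp: int
    mean_n_genes: int
    mean_n_trna: int
    mean_n_is: int
    mean_pct_hypothetical: int
    mean_pct_assigned: int


def summarize_genome(
    genes: Sequence[GeneRecord], genome_length: Optional[int] = None
) -> GenomeSummary:
    """Descriptive statistics for one genome's gene set.

    Start codons are taken from the first 3 nt of each stored sequence
    (sequences are coding-strand oriented); genes without a sequence are
    excluded from the codon tally.
    """
    if not genes:
        raise ConfigError("cannot summarize an empty gene list")
    genomes = {g.genome_id for g in genes}
    if len(genomes) != 1:
        raise ValidationError(f"genes from multiple genomes: {sorted(genomes)}")
    max_end = max(g.end for g in genes)
    if genome_length is None:
        genome_length = max_end
    elif genome_length < max_end:
        raise ValidationError(
            f"genome_length {genome_length} < furthest gene end {max_end}"
        )
    n = len(genes)
    n_hypo = sum("hypothetical" in g.annotation.lower() for g in genes)
    pct_hypo = 100.0 * n_hypo / n
    codon_counts = {c: 0 for c in START_CODONS}
    codon_counts["other"] = 0
    n_with_seq = 0
    for g in genes:
        if g.nt_seq is None:
            continue
        n_with_seq += 1
        codon = g.nt_seq[:3].upper()
        codon_counts[codon if codon in codon_counts else "other"] += 1
    freqs = (
        {c: 100.0 * v / n_with_seq for c, v in codon_counts.items()} if n_with_seq else {}
    )
    return GenomeSummary(
        genome_id=genes[0].genome_id,
        genome_length_bp=genome_length,
        n_genes=n,
        n_trna=sum("trna" in g.annotation.lower() for g in genes),
        n_is_elements=sum(g.is_mobile for g in genes),
        pct_hypothetical=pct_hypo,
        pct_assigned=100.0 - pct_hypo,
        start_codon_freqs=freqs,
    )


def panel_averages(summaries: Sequence[GenomeSummary]) -> PanelAverages:
    """Arithmetic means across genomes, rounded half-up to integer precision."""
    if not summaries:
        raise ConfigError("panel_averages requires at least one genome summary")
    n = len(summaries)

    def mean_of(attr: str) -> float:
        return sum(getattr(s, attr) for s in summaries) / n

    return PanelAverages(
        mean_genome_length_bp=round_half_up(mean_of("genome_length_bp")),
        mean_n_genes=round_half_up(mean_of("n_genes")),
        mean_n_trna=round_half_up(mean_of("n_trna")),
        mean_n_is=round_half_up(mean_of("n_is_elements")),
        mean_pct_hypothetical=round_half_up(mean_of("pct_hypothetical")),
        mean_pct_assigned=round_half_up(mean_of("pct_assigned")),
    )


def interval_length(start: int, end: int) -> tuple[int, int]:
    """Span of a printed coordinate pair: (end - start) bp and floor Kb."""
    if end < start:
        raise ValidationError(f"interval end {end} < start {start}")
    bp = end - start
    return bp, bp // 1000


def panel_start_codon_freqs(genes: Sequence[GeneRecord]) -> dict[str, float]:
    """Start-codon usage (percent) over all genes carrying a sequence."""
    counts = {c: 0 for c in START_CODONS}
    counts["other"] = 0
    total = 0
    for g in genes:
        if g.nt_seq is None:
            continue
        total += 1
        codon = g.nt_seq[:3].upper()
        counts[codon if codon in counts else "other"] += 1
    if total == 0:
        raise ConfigError("no sequences available for start-codon statistics")
    return {c: 100.0 * v / total for c, v in counts.items()}
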