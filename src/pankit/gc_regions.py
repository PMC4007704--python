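"""Per-ORF G+C content, deviant-gene flagging and variable-region aggregation.

Genes whose G+C percentage deviates strongly from the genomic background
(above 68% or below 49% for a ~58% G+C genome) are putative horizontal gene
transfer (HGT) candidates; runs of flagged genes along a contig are merged
into variable genomic regions.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import IntegrityError, ValidationError
from .families import GeneFamily
from .types import GeneRecord

HIGH_GC_THRESHOLD = 68.0
LOW_GC_THRESHOLD = 49.0


@dataclass(frozen=True)
class GCProfile:
    gene_id: str
    gc_percent: float
    flag: str = "none"  # none | high | low


@dataclass
class VariableRegion:
    """A contiguous run of deviant-G+C genes on one contig (1-based, inclusive
    span from the first to the last flagged member)."""

    region_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    member_genes: list[str]
    flagged_genes: list[str]

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_genes)


def gc_percent(seq: str) -> float:
    """G+C percentage of a nucleotide sequence over {A,C,G,T,N}.

    N bases are excluded from both numerator and denominator; a sequence with
    no counted bases is an error.
    """
    if not seq:
        raise ValidationError("empty sequence")
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    n = up.count("N")
    if gc + at + n != len(up):
        bad = sorted(set(up) - set("ACGTN"))
        raise ValidationError(f"sequence contains non-ACGTN characters: {bad}")
    if gc + at == 0:
        raise ValidationError("G+C content undefined: sequence is all N")
    return 100.0 * gc / (gc + at)


def profiles_from_records(records: Iterable[GeneRecord]) -> list[GCProfile]:
    """Compute (unflagged) G+C profiles for records carrying a sequence."""
    return [
        GCProfile(gene_id=r.gene_id, gc_percent=gc_percent(r.nt_seq))
        for r in records
        if r.nt_seq is not None
    ]


def flag_deviant(
    profiles: Iterable[GCProfile],
    high_threshold: float = HIGH_GC_THRESHOLD,
    low_threshold: float = LOW_GC_THRESHOLD,
) -> list[GCProfile]:
    """Flag genes with G+C strictly above ``high_threshold`` or strictly below
    ``low_threshold``; boundary values are unflagged."""
    if not low_threshold < high_threshold:
        raise ValidationError("low_threshold must be < high_threshold")
    out = []
    for p in profiles:
        if p.gc_percent > high_threshold:
            flag = "high"
        elif p.gc_percent < low_threshold:
            flag = "low"
        else:
            flag = "none"
        out.append(GCProfile(p.gene_id, p.gc_percent, flag))
    return out


def aggregate_regions(
    genes: Sequence[GeneRecord],
    profiles: Iterable[GCProfile],
    max_gap_genes: int = 5,
    min_genes: int = 5,
) -> list[VariableRegion]:
    """Merge flagged genes into variable regions, per contig.

    Flagged genes separated by at most ``max_gap_genes`` unflagged genes join
    one region; regions with fewer than ``min_genes`` flagged members are
    discarded. Unflagged genes inside a region's span are listed as members
    but not counted as flagged.
    """
    flag_of = {p.gene_id: p.flag for p in profiles}
    by_contig: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_contig[(g.genome_id, g.contig_id)].append(g)

    regions: list[VariableRegion] = []
    counter = 0
    for (genome_id, contig_id) in sorted(by_contig):
        contig_genes = by_contig[(genome_id, contig_id)]
        starts = [g.start for g in contig_genes]
        if starts != sorted(starts):
            raise IntegrityError(
                f"genes on {genome_id}/{contig_id} are not sorted by start position"
            )
        flagged_idx = [
            i for i, g in enumerate(contig_genes) if flag_of.get(g.gene_id, "none") != "none"
        ]
        if not flagged_idx:
            continue
        # group flagged indices with gaps of at most max_gap_genes unflagged genes
        groups: list[list[int]] = [[flagged_idx[0]]]
        for idx in flagged_idx[1:]:
            if idx - groups[-1][-1] - 1 <= max_gap_genes:
                groups[-1].append(idx)
            else:
                groups.append([idx])
        for grp in groups:
            if len(grp) < min_genes:
                continue
            counter += 1
            lo, hi = grp[0], grp[-1]
            span = contig_genes[lo : hi + 1]
            regions.append(
                VariableRegion(
                    region_id=f"REG{counter}",
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=span[0].start,
                    end=span[-1].end,
                    member_genes=[g.gene_id for g in span],
                    flagged_genes=[contig_genes[i].gene_id for i in grp],
                )
            )
    return regions


def deviation_summary(
    families: Sequence[GeneFamily],
    profiles: Iterable[GCProfile],
    regions: Sequence[VariableRegion],
) -> dict:
    """Panel-level fractions: families with a deviant member, flagged genes
    inside regions, and a per-genome region table."""
    profiles = list(profiles)
    flagged = {p.gene_id for p in profiles if p.flag != "none"}
    n_dev_families = sum(
        any(gid in flagged for gid, _ in f.members) for f in families
    )
    in_region = set()
    for reg in regions:
        in_region.update(g for g in reg.flagged_genes)
    per_genome: dict[str, dict] = {}
    for reg in regions:
        entry = per_genome.setdefault(reg.genome_id, {"n_regions": 0, "n_flagged_in_regions": 0})
        entry["n_regions"] += 1
        entry["n_flagged_in_regions"] += reg.n_flagged
    return {
        "n_families": len(families),
        "n_families_deviant": n_dev_families,
        "family_deviation_fraction": (n_dev_families / len(families)) if families else 0.0,
        "n_flagged_genes": len(flagged),
        "n_flagged_in_regions": len(in_region & flagged),
        "flagged_in_region_fraction": (len(in_region & flagged) / len(flagged)) if flagged else 0.0,
        "n_regions": len(regions),
        "per_genome": per_genome,
    }
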