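"""Gene-trait matching: OD binarization, presence/absence pattern clusters,
and Hamming matching distances between clusters and growth phenotypes.

A strain either grows on a carbohydrate (24-h endpoint OD600 >= 0.3) or it
does not; gene families restricted to the assayed strains are grouped by
their binary presence pattern, and each pattern is compared against each
sugar's growth column. A matching distance of 0 means the pattern explains
the phenotype perfectly across strains.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigError, IntegrityError
from .pangenome import PresenceMatrix
from .types import PhenotypeTable

OD_CUTOFF = 0.3


@dataclass
class GrowthMatrix:
    strains: list[str]
    carbohydrates: list[str]
    growth: np.ndarray  # (n_strains, n_carbs) of 0/1
    cutoff: float

    def column(self, carbohydrate: str) -> np.ndarray:
        return self.growth[:, self.carbohydrates.index(carbohydrate)]


@dataclass
class TraitCluster:
    cluster_id: str
    member_families: list[str]
    pattern: np.ndarray  # 0/1 presence over the assayed strains


@dataclass
class MatchResult:
    cluster_id: str
    carbohydrate: str
    distance: int
    rank: int
    anti_distance: int  # n_strains - distance; surfaced but never ranked


def binarize_growth(pheno: PhenotypeTable, cutoff: float = OD_CUTOFF) -> GrowthMatrix:
    """Binarize OD readings; an OD exactly at the cutoff counts as growth."""
    growth = (pheno.od.values >= cutoff).astype(int)
    return GrowthMatrix(
        strains=pheno.strains,
        carbohydrates=pheno.carbohydrates,
        growth=growth,
        cutoff=cutoff,
    )


def _majority_pattern(patterns: np.ndarray) -> np.ndarray:
    """Majority-vote consensus of 0/1 row patterns; ties resolve to 1."""
    return (patterns.mean(axis=0) >= 0.5).astype(int)


def cluster_patterns(
    m: PresenceMatrix,
    strains: Optional[Sequence[str]] = None,
    mode: str = "exact",
    linkage_method: str = "average",
    cut_height: float = 0.0,
) -> tuple[list[TraitCluster], list[str]]:
    """Group gene families by their binary presence pattern over the assayed
    strains.

    Returns (clusters, constant_family_ids). Families whose pattern is
    constant across the assayed strains (the core and the all-absent) are set
    aside and reported separately, since they carry no discriminating signal.
    ``mode='exact'`` groups identical patterns; ``mode='hcl'`` further merges
    patterns by agglomerative clustering on Hamming distance cut at
    ``cut_height`` (in strain units; 0 reproduces the exact grouping), each
    merged cluster represented by its majority pattern (ties -> 1).
    """
    strains = list(strains) if strains is not None else list(m.genomes)
    if len(strains) < 2:
        raise ConfigError("pattern clustering requires at least 2 assayed strains")
    try:
        cols = [m.genomes.index(s) for s in strains]
    except ValueError as exc:
        raise IntegrityError(f"assayed strain not in presence matrix: {exc}") from exc
    pres = (m.counts[:, cols] >= 1).astype(int)

    constant: list[str] = []
    variable_rows: list[int] = []
    for i, fam in enumerate(m.families):
        s = int(pres[i].sum())
        if s == 0 or s == len(strains):
            constant.append(fam)
        else:
            variable_rows.append(i)

    # exact grouping: one cluster per distinct pattern, in order of first appearance
    pattern_order: list[tuple] = []
    groups: dict[tuple, list[str]] = {}
    for i in variable_rows:
        key = tuple(pres[i])
        if key not in groups:
            groups[key] = []
            pattern_order.append(key)
        groups[key].append(m.families[i])

    if mode == "exact" or cut_height <= 0 or len(pattern_order) < 2:
        merged = [(np.array(key), groups[key]) for key in pattern_order]
    elif mode == "hcl":
        pat = np.array(pattern_order)
        # cityblock on 0/1 vectors = integer Hamming distance in strain units
        z = linkage(pdist(pat, metric="cityblock"), method=linkage_method)
        labels = fcluster(z, t=cut_height, criterion="distance")
        merged = []
        seen: dict[int, int] = {}
        for j, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(merged)
                merged.append((None, []))
            idx = seen[lab]
            merged[idx][1].extend(groups[pattern_order[j]])
        out = []
        for lab, idx in seen.items():
            rows = pat[labels == lab]
            out.append((_majority_pattern(rows), merged[idx][1]))
        merged = out
    else:
        raise ConfigError(f"unknown clustering mode {mode!r}")

    clusters = [
        TraitCluster(cluster_id=f"Cluster{k}", member_families=fams, pattern=np.asarray(pattern))
        for k, (pattern, fams) in enumerate(merged, start=1)
    ]
    return clusters, constant


def constant_traits(g: GrowthMatrix) -> list[str]:
    """Carbohydrates with the same growth call in every strain (unmatchable)."""
    out = []
    for j, carb in enumerate(g.carbohydrates):
        col = g.growth[:, j]
        if col.min() == col.max():
            out.append(carb)
    return out


def match_traits(clusters: Sequence[TraitCluster], g: GrowthMatrix) -> list[MatchResult]:
    """Hamming matching distance of every cluster pattern against every
    differential sugar, with per-sugar ascending ranks (ties share the lower
    rank; deterministic ordering by cluster_id)."""
    n = len(g.strains)
    for c in clusters:
        if len(c.pattern) != n:
            raise IntegrityError(
                f"{c.cluster_id}: pattern over {len(c.pattern)} strains, growth over {n}"
            )
    skip = set(constant_traits(g))
    results: list[MatchResult] = []
    for j, carb in enumerate(g.carbohydrates):
        if carb in skip:
            continue
        col = g.growth[:, j]
        dists = [(int(np.sum(c.pattern != col)), c.cluster_id) for c in clusters]
        for c, (d, _) in zip(clusters, dists):
            rank = 1 + sum(1 for d2, _ in dists if d2 < d)
            results.append(
                MatchResult(
                    cluster_id=c.cluster_id,
                    carbohydrate=carb,
                    distance=d,
                    rank=rank,
                    anti_distance=n - d,
                )
            )
    return results


def distance_matrix(results: Sequence[MatchResult]) -> "np.ndarray":
    """Clusters x sugars distance matrix as a pandas DataFrame (heatmap source)."""
    import pandas as pd

    carbs = sorted({r.carbohydrate for r in results})
    clusters = sorted({r.cluster_id for r in results}, key=lambda c: int(c.removeprefix("Cluster")))
    df = pd.DataFrame(index=clusters, columns=carbs, dtype=float)
    for r in results:
        df.loc[r.cluster_id, r.carbohydrate] = r.distance
    return df


def candidate_report(
    results: Sequence[MatchResult],
    clusters: Sequence[TraitCluster],
    annotations: Optional[Mapping[str, Sequence[str]]] = None,
    g: Optional[GrowthMatrix] = None,
    k: int = 3,
) -> dict:
    """Per-sugar top-k candidate clusters with member-family annotations."""
    by_cluster = {c.cluster_id: c for c in clusters}
    per_sugar: dict[str, list[MatchResult]] = {}
    for r in results:
        per_sugar.setdefault(r.carbohydrate, []).append(r)
    report: dict = {"sugars": {}, "unmatchable_sugars": constant_traits(g) if g else []}
    for carb in sorted(per_sugar):
        ranked = sorted(
            per_sugar[carb], key=lambda r: (r.distance, int(r.cluster_id.removeprefix("Cluster")))
        )
        entries = []
        for r in ranked[:k]:
            cl = by_cluster[r.cluster_id]
            fam_ann = {}
            for fam in cl.member_families:
                if annotations and fam in annotations:
                    fam_ann[fam] = list(annotations[fam])
            entries.append(
                {
                    "cluster_id": r.cluster_id,
                    "distance": r.distance,
                    "rank": r.rank,
                    "member_families": cl.member_families,
                    "annotations": fam_ann,
                }
            )
        report["sugars"][carb] = entries
    return report
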