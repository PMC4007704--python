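"""Gene-family construction from all-vs-all protein similarity hits.

The pipeline is: filter hits (E-value, identity, coverage of either protein),
build a bidirectional similarity graph, cluster it with the Markov Cluster
Algorithm (MCL), and classify the resulting families as core (present in all
genomes), dispensable (in a proper subset of >= 2 genomes) or unique (one
genome). Core families with exactly one member per genome and no mobilome
annotation form the single-copy orthologue pool.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IntegrityError
from .types import GeneRecord, SimilarityHit

logger = logging.getLogger(__name__)

#: -log10(E) is capped here; an E-value of exactly 0 maps to the cap.
MAX_EDGE_WEIGHT = 200.0


@dataclass
class GeneFamily:
    """A cluster of genes across genomes, with class and copy-number profile."""

    family_id: str
    members: list[tuple[str, str]]  # (gene_id, genome_id)
    copy_profile: dict[str, int]
    family_class: str  # core | dispensable | unique
    is_single_copy_orthologue: bool
    contains_mobile: bool

    @property
    def n_genomes(self) -> int:
        return len(self.copy_profile)

    @property
    def size(self) -> int:
        return len(self.members)


def filter_hits(
    hits: Iterable[SimilarityHit],
    max_evalue: float = 1e-4,
    min_identity: float = 50.0,
    min_cov_frac: float = 0.5,
) -> list[SimilarityHit]:
    """Keep hits with E <= max_evalue, identity >= min_identity and alignment
    covering at least ``min_cov_frac`` of *either* protein (i.e. of the shorter
    of the two)."""
    return [
        h
        for h in hits
        if h.e_value <= max_evalue
        and h.pct_identity >= min_identity
        and h.aln_length >= min_cov_frac * min(h.q_len, h.s_len)
    ]


def build_graph(filtered: Iterable[SimilarityHit]) -> nx.Graph:
    """Build the undirected similarity graph from filtered hits.

    An edge (a, b) exists only when passing hits exist in both directions;
    its weight is min(200, -log10(best E-value)) with E = 0 mapping to 200.
    """
    directions: dict[tuple[str, str], set[str]] = {}
    best_e: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for h in filtered:
        nodes.add(h.query_id)
        nodes.add(h.subject_id)
        key = (h.query_id, h.subject_id) if h.query_id < h.subject_id else (h.subject_id, h.query_id)
        directions.setdefault(key, set()).add(h.query_id)
        if key not in best_e or h.e_value < best_e[key]:
            best_e[key] = h.e_value
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for key, dirs in directions.items():
        if len(dirs) < 2:  # not bidirectional
            continue
        e = best_e[key]
        weight = MAX_EDGE_WEIGHT if e == 0.0 else min(MAX_EDGE_WEIGHT, -math.log10(e))
        g.add_edge(key[0], key[1], weight=weight)
    return g


def _mcl_component(a: np.ndarray, inflation: float, max_iter: int, tol: float, prune: float) -> np.ndarray:
    """Run MCL on one dense weighted adjacency matrix; return the limit matrix."""
    n = a.shape[0]
    m = a.copy().astype(float)
    # self-loops: node's maximum incident edge weight (1 for isolated nodes)
    loops = m.max(axis=0)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(m, loops)
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        m2 = m @ m  # expansion
        np.power(m2, inflation, out=m2)  # inflation
        # prune small entries but always keep each column's maximum
        keep = np.zeros_like(m2, dtype=bool)
        keep[np.argmax(m2, axis=0), np.arange(n)] = True
        m2[(m2 < prune) & ~keep] = 0.0
        m2 = m2 / m2.sum(axis=0)
        diff = np.abs(m2 - m).max()
        m = m2
        if diff < tol:
            break
    else:
        logger.warning("MCL did not converge in %d iterations (component size %d)", max_iter, n)
    return m


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.8,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> list[set[str]]:
    """Markov clustering of the similarity graph.

    Clusters are the connected components of the non-zero pattern of the MCL
    limit matrix; since flow cannot cross between components of the input
    graph, MCL is run independently (and densely) per component. Isolated
    nodes become singleton clusters.
    """
    clusters: list[set[str]] = []
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            clusters.append(set(comp))
            continue
        nodes = sorted(comp)
        a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
        limit = _mcl_component(a, inflation, max_iter, tol, prune)
        pattern = limit > 0
        cc_graph = nx.from_numpy_array(pattern | pattern.T)
        for cc in nx.connected_components(cc_graph):
            clusters.append({nodes[i] for i in cc})
    clusters.sort(key=lambda c: min(c))
    return clusters


def classify_families(
    clusters: Sequence[set[str]],
    genomes: Sequence[str],
    gene_index: Mapping[str, GeneRecord],
) -> list[GeneFamily]:
    """Assign core/dispensable/unique classes and orthologue flags.

    Genes present in ``gene_index`` but absent from every cluster become
    singleton (unique-class) families. Mobilome-containing families are
    excluded from the orthologue pool only; they still count in the
    core/dispensable/unique accounting.
    """
    panel_size = len(set(genomes))
    clustered: set[str] = set()
    for c in clusters:
        for gid in c:
            if gid not in gene_index:
                raise IntegrityError(f"cluster references unknown gene_id {gid!r}")
        clustered.update(c)
    all_clusters = [sorted(c) for c in clusters]
    leftovers = sorted(set(gene_index) - clustered)
    all_clusters.extend([[g] for g in leftovers])
    all_clusters.sort(key=lambda c: c[0])

    families: list[GeneFamily] = []
    width = max(5, len(str(len(all_clusters))))
    for i, member_ids in enumerate(all_clusters, start=1):
        members = [(gid, gene_index[gid].genome_id) for gid in member_ids]
        profile = dict(Counter(genome for _, genome in members))
        n_genomes = len(profile)
        if n_genomes == panel_size:
            fclass = "core"
        elif n_genomes == 1:
            fclass = "unique"
        else:
            fclass = "dispensable"
        mobile = any(gene_index[gid].is_mobile for gid in member_ids)
        single_copy = (
            fclass == "core"
            and all(v == 1 for v in profile.values())
            and not mobile
        )
        families.append(
            GeneFamily(
                family_id=f"FAM{i:0{width}d}",
                members=members,
                copy_profile=profile,
                family_class=fclass,
                is_single_copy_orthologue=single_copy,
                contains_mobile=mobile,
            )
        )
    return families


def family_summary(families: Sequence[GeneFamily]) -> dict:
    """Class counts plus orthologue/paralogue breakdown of the core."""
    n_core = sum(f.family_class == "core" for f in families)
    n_orth = sum(f.is_single_copy_orthologue for f in families)
    n_core_paralogous = sum(
        f.family_class == "core" and any(v > 1 for v in f.copy_profile.values())
        for f in families
    )
    n_core_mobile = sum(f.family_class == "core" and f.contains_mobile for f in families)
    return {
        "n_families": len(families),
        "n_core": n_core,
        "n_dispensable": sum(f.family_class == "dispensable" for f in families),
        "n_unique": sum(f.family_class == "unique" for f in families),
        "n_orthologues": n_orth,
        "n_core_paralogous": n_core_paralogous,
        "n_core_mobile_excluded": n_core_mobile,
        "n_genes": sum(f.size for f in families),
    }


def families_table(families: Sequence[GeneFamily]) -> pd.DataFrame:
    """Long-format membership table (one row per gene)."""
    rows = [
        (f.family_id, gid, genome, f.family_class, f.is_single_copy_orthologue)
        for f in families
        for gid, genome in f.members
    ]
    return pd.DataFrame(
        rows,
        columns=["family_id", "gene_id", "genome_id", "family_class", "is_single_copy_orthologue"],
    )
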