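import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pankit import families, simulate
from pankit.errors import IntegrityError
from pankit.types import GeneRecord, SimilarityHit


def hit(q, s, ident=90.0, aln=100, e=1e-30, qlen=100, slen=100):
    return SimilarityHit(q, s, ident, aln, e, qlen, slen)


class TestFilterHits:
    def test_all_thresholds_cleared(self):
        h = hit("a", "b", ident=85, aln=120, e=1e-50, qlen=130, slen=125)
        assert families.filter_hits([h]) == [h]

    def test_identity_below_50_dropped(self):
        h = hit("a", "b", ident=49.9, aln=200, e=0.0, qlen=200, slen=200)
        assert families.filter_hits([h]) == []

    def test_coverage_of_shorter_protein(self):
        # 60 < 0.5 * min(130, 125): fails coverage of either protein
        h = hit("a", "b", ident=90, aln=60, e=1e-30, qlen=130, slen=125)
        assert families.filter_hits([h]) == []
        # 63 >= 0.5 * 125: covering half the shorter protein suffices
        h2 = hit("a", "b", ident=90, aln=63, e=1e-30, qlen=130, slen=125)
        assert families.filter_hits([h2]) == [h2]

    def test_evalue_threshold(self):
        assert families.filter_hits([hit("a", "b", e=1e-3)]) == []
        assert len(families.filter_hits([hit("a", "b", e=1e-4)])) == 1


class TestBuildGraph:
    def test_weight_is_neg_log10_of_best_evalue(self):
        g = families.build_graph([hit("a", "b", e=1e-50), hit("b", "a", e=1e-40)])
        assert g["a"]["b"]["weight"] == pytest.approx(50.0)

    def test_unidirectional_hit_gives_no_edge(self):
        g = families.build_graph([hit("a", "b")])
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b"}

    def test_zero_evalue_capped_at_200(self):
        g = families.build_graph([hit("a", "b", e=0.0), hit("b", "a", e=0.0)])
        assert g["a"]["b"]["weight"] == 200.0


def _clique_graph(cliques, weight=10.0):
    g = nx.Graph()
    for clique in cliques:
        g.add_nodes_from(clique)
        for i, a in enumerate(clique):
            for b in clique[i + 1 :]:
                g.add_edge(a, b, weight=weight)
    return g


class TestMCL:
    def test_two_disjoint_cliques(self):
        g = _clique_graph([["a", "b", "c"], ["x", "y", "z"]])
        clusters = families.mcl_cluster(g)
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_isolated_node(self):
        g = nx.Graph()
        g.add_node("solo")
        assert families.mcl_cluster(g) == [{"solo"}]

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(12)]
        g = _clique_graph([nodes[:5], nodes[5:9], nodes[9:]])
        for u, v, d in g.edges(data=True):
            d["weight"] = float(rng.uniform(5, 50))
        base = families.mcl_cluster(g)
        mapping = {n: f"z{i}" for i, n in enumerate(reversed(nodes))}
        relabeled = families.mcl_cluster(nx.relabel_nodes(g, mapping))
        back = [{k for k, v in mapping.items() if v in c} for c in relabeled]
        assert sorted(map(sorted, base)) == sorted(map(sorted, back))

    def test_uniform_clique_components_equal_connectivity_oracle(self):
        # on a disjoint union of uniform-weight cliques, MCL must reproduce
        # the connected components (brute-force reachability)
        rng = np.random.default_rng(42)
        for _ in range(5):
            sizes = rng.integers(1, 8, size=rng.integers(2, 6))
            names, cliques = 0, []
            for s in sizes:
                cliques.append([f"g{names + i}" for i in range(s)])
                names += s
            g = _clique_graph(cliques)
            oracle = sorted(sorted(c) for c in nx.connected_components(g))
            assert sorted(map(sorted, families.mcl_cluster(g))) == oracle


def _rec(gid, genome, mobile=False):
    return GeneRecord(gid, genome, "c1", 1, 300, "+", "x", is_mobile=mobile)


class TestClassifyFamilies:
    GENOMES = ["gA", "gB", "gC"]

    def test_core_single_copy_orthologue(self):
        idx = {f"g{i}": _rec(f"g{i}", g) for i, g in enumerate(self.GENOMES)}
        fams = families.classify_families([set(idx)], self.GENOMES, idx)
        f = fams[0]
        assert f.family_class == "core" and f.is_single_copy_orthologue

    def test_two_of_three_genomes_is_dispensable(self):
        idx = {"g0": _rec("g0", "gA"), "g1": _rec("g1", "gB")}
        fams = families.classify_families([{"g0", "g1"}], self.GENOMES, idx)
        assert fams[0].family_class == "dispensable"

    def test_paralogous_core_family_not_orthologue(self):
        idx = {
            "g0": _rec("g0", "gA"), "g1": _rec("g1", "gA"),
            "g2": _rec("g2", "gB"), "g3": _rec("g3", "gC"),
        }
        fams = families.classify_families([set(idx)], self.GENOMES, idx)
        f = fams[0]
        assert f.family_class == "core"
        assert not f.is_single_copy_orthologue
        assert f.copy_profile["gA"] == 2

    def test_mobile_family_excluded_from_orthologue_pool_only(self):
        idx = {
            "g0": _rec("g0", "gA", mobile=True),
            "g1": _rec("g1", "gB"), "g2": _rec("g2", "gC"),
        }
        fams = families.classify_families([set(idx)], self.GENOMES, idx)
        f = fams[0]
        assert f.family_class == "core" and f.contains_mobile
        assert not f.is_single_copy_orthologue

    def test_unclustered_genes_become_unique_singletons(self):
        idx = {"g0": _rec("g0", "gA"), "g1": _rec("g1", "gB"), "lone": _rec("lone", "gC")}
        fams = families.classify_families([{"g0", "g1"}], self.GENOMES, idx)
        by_class = {f.family_class for f in fams}
        assert by_class == {"dispensable", "unique"}
        assert sum(f.size for f in fams) == 3

    def test_unknown_gene_id_raises(self):
        with pytest.raises(IntegrityError, match="ghost"):
            families.classify_families([{"ghost"}], self.GENOMES, {})

    def test_class_counts_partition_families(self, small_panel_families):
        genomes, gene_index, fams = small_panel_families
        s = families.family_summary(fams)
        assert s["n_core"] + s["n_dispensable"] + s["n_unique"] == s["n_families"]
        assert s["n_genes"] == len(gene_index)
        seen = set()
        for f in fams:
            for gid, _ in f.members:
                assert gid not in seen
                seen.add(gid)
        assert seen == set(gene_index)


class TestGroundTruthRecovery:
    def _ari(self, cfg):
        records, hits, pheno, truth = simulate.simulate_panel(cfg)
        genomes = sorted({r.genome_id for r in records})
        clusters = families.mcl_cluster(families.build_graph(families.filter_hits(hits)))
        fams = families.classify_families(clusters, genomes, {r.gene_id: r for r in records})
        pred = {gid: f.family_id for f in fams for gid, _ in f.members}
        genes = sorted(pred)
        return adjusted_rand_score(
            [truth.family_of[g] for g in genes], [pred[g] for g in genes]
        )

    def test_noiseless_panel_recovered_exactly(self):
        cfg = simulate.PanelConfig(
            n_strains=6, n_core=50, n_dispensable=30, n_unique_per_strain=5,
            n_traits=2, causal_cluster_size=2, hgt_block_count=2, hgt_block_size=5,
            spurious_hit_rate=0.0, seed=13,
        )
        assert self._ari(cfg) == 1.0

    def test_spurious_hits_filtered_before_clustering(self):
        cfg = simulate.PanelConfig(
            n_strains=6, n_core=50, n_dispensable=30, n_unique_per_strain=5,
            n_traits=2, causal_cluster_size=2, hgt_block_count=2, hgt_block_size=5,
            spurious_hit_rate=0.02, seed=13,
        )
        assert self._ari(cfg) >= 0.95
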