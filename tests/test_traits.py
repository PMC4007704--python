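import numpy as np
import pandas as pd
import pytest

from pankit import pangenome, simulate, traits
from pankit.errors import ConfigError, IntegrityError
from pankit.pangenome import PresenceMatrix
from pankit.types import PhenotypeTable


def matrix(rows: dict[str, list[int]], strains=None):
    fams = list(rows)
    counts = np.array([rows[f] for f in fams])
    strains = strains or [f"S{i + 1}" for i in range(counts.shape[1])]
    return PresenceMatrix(fams, strains, counts)


def growth_from(cols: dict[str, list[int]]):
    strains = [f"S{i + 1}" for i in range(len(next(iter(cols.values()))))]
    carbs = list(cols)
    g = np.array([[cols[c][i] for c in carbs] for i in range(len(strains))])
    return traits.GrowthMatrix(strains=strains, carbohydrates=carbs, growth=g, cutoff=0.3)


class TestBinarize:
    def test_cutoff_boundary_inclusive(self):
        od = pd.DataFrame(
            [[0.29, 0.30, 0.31]], index=["S1"], columns=["a", "b", "c"]
        )
        g = traits.binarize_growth(PhenotypeTable(od=od))
        assert list(g.growth[0]) == [0, 1, 1]
        assert g.cutoff == 0.3


class TestClusterPatterns:
    def test_exact_grouping(self):
        m = matrix({"f1": [1, 1, 0, 0], "f2": [1, 1, 0, 0], "f3": [1, 0, 0, 0], "f4": [1, 1, 1, 1]})
        clusters, constant = traits.cluster_patterns(m)
        assert [c.member_families for c in clusters] == [["f1", "f2"], ["f3"]]
        assert [c.cluster_id for c in clusters] == ["Cluster1", "Cluster2"]
        assert constant == ["f4"]

    def test_all_core_matrix_yields_no_clusters(self):
        m = matrix({"f1": [1, 1, 1], "f2": [1, 1, 1]})
        clusters, constant = traits.cluster_patterns(m)
        assert clusters == [] and constant == ["f1", "f2"]

    def test_paralog_counts_binarized(self):
        m = matrix({"f1": [3, 1, 0, 0], "f2": [1, 1, 0, 0]})
        clusters, _ = traits.cluster_patterns(m)
        assert len(clusters) == 1 and clusters[0].member_families == ["f1", "f2"]

    def test_hcl_mode_merges_close_patterns_with_majority_tie_to_one(self):
        m = matrix({"f1": [1, 1, 0, 0], "f2": [1, 1, 0, 1]})
        clusters, _ = traits.cluster_patterns(m, mode="hcl", cut_height=1.0)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_families) == ["f1", "f2"]
        assert list(clusters[0].pattern) == [1, 1, 0, 1]  # tie at the last strain -> 1

    def test_hcl_cut_zero_reproduces_exact(self):
        m = matrix({"f1": [1, 1, 0, 0], "f2": [1, 1, 0, 1], "f3": [1, 1, 0, 0]})
        exact, _ = traits.cluster_patterns(m, mode="exact")
        hcl, _ = traits.cluster_patterns(m, mode="hcl", cut_height=0.0)
        assert [c.member_families for c in exact] == [c.member_families for c in hcl]

    def test_requires_two_strains(self):
        with pytest.raises(ConfigError):
            traits.cluster_patterns(matrix({"f1": [1]}), strains=["S1"])


class TestMatchTraits:
    def test_perfect_and_near_matches(self):
        m = matrix({"f1": [1, 1, 0, 0], "f2": [1, 0, 0, 0]})
        clusters, _ = traits.cluster_patterns(m)
        g = growth_from({"ribose": [1, 1, 0, 0]})
        results = traits.match_traits(clusters, g)
        by_cluster = {r.cluster_id: r for r in results}
        assert by_cluster["Cluster1"].distance == 0
        assert by_cluster["Cluster1"].rank == 1
        assert by_cluster["Cluster1"].anti_distance == 4
        assert by_cluster["Cluster2"].distance == 1
        assert by_cluster["Cluster2"].rank == 2

    def test_ties_share_lower_rank(self):
        m = matrix({"f1": [1, 0, 0, 0], "f2": [0, 1, 0, 0]})
        clusters, _ = traits.cluster_patterns(m)
        g = growth_from({"xylose": [1, 1, 0, 0]})
        results = traits.match_traits(clusters, g)
        assert [r.rank for r in results] == [1, 1]

    def test_constant_growth_sugar_excluded(self):
        m = matrix({"f1": [1, 0, 0, 0]})
        clusters, _ = traits.cluster_patterns(m)
        g = growth_from({"glucose": [1, 1, 1, 1], "ribose": [1, 0, 1, 0]})
        results = traits.match_traits(clusters, g)
        assert {r.carbohydrate for r in results} == {"ribose"}
        assert traits.constant_traits(g) == ["glucose"]

    def test_adding_core_family_changes_nothing(self):
        base = {"f1": [1, 1, 0, 0], "f2": [0, 1, 1, 0]}
        g = growth_from({"ribose": [1, 1, 0, 0]})
        res_a = traits.match_traits(traits.cluster_patterns(matrix(base))[0], g)
        with_core = dict(base, core=[1, 1, 1, 1])
        res_b = traits.match_traits(traits.cluster_patterns(matrix(with_core))[0], g)
        assert res_a == res_b

    def test_strain_mismatch_rejected(self):
        m = matrix({"f1": [1, 0, 0]})
        clusters, _ = traits.cluster_patterns(m)
        g = growth_from({"ribose": [1, 0, 0, 1]})
        with pytest.raises(IntegrityError):
            traits.match_traits(clusters, g)


class TestRecovery:
    def test_noiseless_causal_clusters_rank_first_with_distance_zero(
        self, small_panel, small_panel_families
    ):
        cfg, records, hits, pheno, truth = small_panel
        genomes, gene_index, fams = small_panel_families
        m = pangenome.presence_matrix(fams, genomes)
        growth = traits.binarize_growth(pheno)
        clusters, _ = traits.cluster_patterns(m, strains=pheno.strains)
        results = traits.match_traits(clusters, growth)
        fam_name = {}  # predicted family id per gene -> true family id
        for f in fams:
            fam_name[f.family_id] = truth.family_of[f.members[0][0]]
        for trait, causal in truth.causal_cluster_of.items():
            causal_clusters = [
                c.cluster_id
                for c in clusters
                if causal <= {fam_name[f] for f in c.member_families}
            ]
            assert len(causal_clusters) == 1
            res = [
                r for r in results
                if r.carbohydrate == trait and r.cluster_id == causal_clusters[0]
            ]
            assert res and res[0].distance == 0 and res[0].rank == 1


class TestCandidateReport:
    def test_perfect_cluster_listed_first_with_annotations(self):
        m = matrix({"f1": [1, 1, 0, 0], "f2": [0, 1, 1, 0]})
        clusters, _ = traits.cluster_patterns(m)
        g = growth_from({"sorbitol": [1, 1, 0, 0], "glucose": [1, 1, 1, 1]})
        results = traits.match_traits(clusters, g)
        report = traits.candidate_report(
            results, clusters, annotations={"f1": ["alcohol dehydrogenase"]}, g=g, k=2
        )
        top = report["sugars"]["sorbitol"][0]
        assert top["cluster_id"] == "Cluster1" and top["distance"] == 0
        assert top["annotations"]["f1"] == ["alcohol dehydrogenase"]
        assert report["unmatchable_sugars"] == ["glucose"]
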