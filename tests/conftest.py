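import pytest

from pankit import families, simulate


@pytest.fixture(scope="session")
def small_panel():
    """A 9-strain panel small enough for fast tests, with ground truth."""
    cfg = simulate.PanelConfig(
        n_strains=9,
        n_core=50,
        n_dispensable=44,
        n_unique_per_strain=3,
        n_traits=8,
        causal_cluster_size=3,
        hgt_block_count=2,
        hgt_block_size=5,
        seed=3,
    )
    records, hits, pheno, truth = simulate.simulate_panel(cfg)
    return cfg, records, hits, pheno, truth


@pytest.fixture(scope="session")
def small_panel_families(small_panel):
    """Classified families for the small panel (noiseless clustering)."""
    cfg, records, hits, pheno, truth = small_panel
    genomes = sorted({r.genome_id for r in records})
    gene_index = {r.gene_id: r for r in records}
    clusters = families.mcl_cluster(families.build_graph(families.filter_hits(hits)))
    fams = families.classify_families(clusters, genomes, gene_index)
    return genomes, gene_index, fams
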