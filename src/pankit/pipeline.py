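"""One-shot pipeline over a directory layout, driven by a YAML-style config.

Stage order: simulate (optional) -> families -> pangenome -> gc-scan ->
traits -> consensus -> stats. Every output file is listed in a manifest JSON
with a content checksum; re-running with an identical config and inputs
reproduces identical checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path
from typing import Optional

import dendropy

from . import consensus as consensus_mod
from . import families as families_mod
from . import gc_regions, genome_stats, io, pangenome, simulate, traits as traits_mod
from .errors import PankitError

logger = logging.getLogger("pankit.pipeline")

STAGES = ("simulate", "families", "pangenome", "gcscan", "traits", "consensus", "stats")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


class PipelineFailure(PankitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict, outdir: Path) -> dict:
    """Execute all stages; return the manifest (also written to manifest.json).

    On stage failure, partial outputs are moved under ``outdir/failed/`` and a
    PipelineFailure naming the stage is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    outputs: list[Path] = []
    stage = "setup"

    def out(name: str) -> Path:
        p = outdir / name
        outputs.append(p)
        return p

    try:
        # ------------------------------------------------ simulate / inputs
        stage = "simulate"
        sim_cfg = config.get("simulate")
        if sim_cfg is not None:
            cfg = simulate.PanelConfig(**{**sim_cfg, "seed": sim_cfg.get("seed", seed)})
            records, hits, pheno, truth = simulate.simulate_panel(cfg)
            io.write_gene_table(records, out("gene_table.tsv"))
            io.write_fasta(records, out("genes.fna"))
            io.write_hits(hits, out("hits.tsv"))
            io.write_phenotypes(pheno, out("phenotypes.csv"))
            simulate.write_ground_truth(truth, out("ground_truth.json"))
            tns = dendropy.TaxonNamespace()
            species_tree = truth.species_tree(tns)
            io.write_newick([species_tree], out("species_tree.nwk"))
            cons_cfg = config.get("consensus", {})
            gene_trees = simulate.simulate_gene_trees(
                species_tree,
                n_trees=int(cons_cfg.get("n_trees", 100)),
                perturb_prob=float(cons_cfg.get("perturb_prob", 0.1)),
                seed=seed + 1,
            )
            io.write_newick(gene_trees, out("gene_trees.nwk"))
            logger.info("simulate: %d genes, %d hits, %d strains", len(records), len(hits), cfg.n_strains)
        else:
            inputs = config.get("inputs", {})
            for key in ("gene_table", "hits", "phenotypes", "gene_trees"):
                p = inputs.get(key)
                if p is None or not Path(p).exists():
                    raise PankitError(f"missing input file for {key!r}: {p}")
            records = io.read_gene_table(inputs["gene_table"])
            if inputs.get("fasta"):
                records = io.attach_sequences(records, io.read_fasta(inputs["fasta"]))
            hits = io.read_hits(inputs["hits"])
            pheno = io.read_phenotypes(inputs["phenotypes"])
            gene_trees = io.read_newick(inputs["gene_trees"])

        genomes = sorted({r.genome_id for r in records})
        gene_index = {r.gene_id: r for r in records}

        # ------------------------------------------------ families
        stage = "families"
        fam_cfg = config.get("families", {})
        filtered = families_mod.filter_hits(
            hits,
            max_evalue=float(fam_cfg.get("max_evalue", 1e-4)),
            min_identity=float(fam_cfg.get("min_identity", 50.0)),
            min_cov_frac=float(fam_cfg.get("min_cov_frac", 0.5)),
        )
        graph = families_mod.build_graph(filtered)
        clusters = families_mod.mcl_cluster(graph, inflation=float(fam_cfg.get("inflation", 1.8)))
        families = families_mod.classify_families(clusters, genomes, gene_index)
        families_mod.families_table(families).to_csv(out("families.tsv"), sep="\t", index=False)
        summary = families_mod.family_summary(families)
        _dump_json(summary, out("family_summary.json"))
        matrix = pangenome.presence_matrix(families, genomes)
        matrix.to_frame().to_csv(out("presence_matrix.tsv"), sep="\t", index_label="family_id")
        logger.info("families: %s", summary)

        # ------------------------------------------------ pangenome
        stage = "pangenome"
        pan_cfg = config.get("pangenome", {})
        curve = pangenome.accumulation_curves(
            matrix,
            n_permutations=int(pan_cfg.get("n_permutations", 1000)),
            exhaustive_max=int(pan_cfg.get("exhaustive_max", 8)),
            seed=seed,
        )
        fit = pangenome.fit_models(curve)
        pangenome.curves_frame(curve).to_csv(
            out("pangenome_curves.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        _dump_json(pangenome.curve_report(curve, fit, k=int(pan_cfg.get("rate_k", 9))), out("heaps_fit.json"))
        logger.info("pangenome: pan=%d core=%d call=%s", curve.median_pan[-1], curve.median_core[-1], fit.openness_call)

        # ------------------------------------------------ gc scan
        stage = "gcscan"
        gc_cfg = config.get("gc", {})
        profiles = gc_regions.flag_deviant(
            gc_regions.profiles_from_records(records),
            high_threshold=float(gc_cfg.get("high_threshold", 68.0)),
            low_threshold=float(gc_cfg.get("low_threshold", 49.0)),
        )
        regions = gc_regions.aggregate_regions(
            records,
            profiles,
            max_gap_genes=int(gc_cfg.get("max_gap_genes", 5)),
            min_genes=int(gc_cfg.get("min_genes", 5)),
        )
        with open(out("gc_profiles.tsv"), "w") as fh:
            fh.write("gene_id\tgc_percent\tflag\n")
            for p in profiles:
                fh.write(f"{p.gene_id}\t{p.gc_percent:.4f}\t{p.flag}\n")
        with open(out("gc_regions.tsv"), "w") as fh:
            fh.write("region_id\tgenome_id\tcontig_id\tstart\tend\tn_flagged\tgenes\n")
            for reg in regions:
                fh.write(
                    f"{reg.region_id}\t{reg.genome_id}\t{reg.contig_id}\t{reg.start}\t"
                    f"{reg.end}\t{reg.n_flagged}\t{','.join(reg.member_genes)}\n"
                )
        _dump_json(gc_regions.deviation_summary(families, profiles, regions), out("gc_summary.json"))
        logger.info("gcscan: %d regions", len(regions))

        # ------------------------------------------------ traits
        stage = "traits"
        tr_cfg = config.get("traits", {})
        growth = traits_mod.binarize_growth(pheno, cutoff=float(tr_cfg.get("od_cutoff", 0.3)))
        clusters_tr, constant = traits_mod.cluster_patterns(
            matrix,
            strains=pheno.strains,
            mode=tr_cfg.get("mode", "exact"),
            cut_height=float(tr_cfg.get("cut_height", 0.0)),
        )
        results = traits_mod.match_traits(clusters_tr, growth)
        with open(out("growth_matrix.tsv"), "w") as fh:
            fh.write("strain\t" + "\t".join(growth.carbohydrates) + "\n")
            for i, s in enumerate(growth.strains):
                fh.write(s + "\t" + "\t".join(str(v) for v in growth.growth[i]) + "\n")
        with open(out("trait_clusters.tsv"), "w") as fh:
            fh.write("cluster_id\tfamily_id\tpattern\n")
            for c in clusters_tr:
                pat = "".join(str(v) for v in c.pattern)
                for fam in c.member_families:
                    fh.write(f"{c.cluster_id}\t{fam}\t{pat}\n")
        traits_mod.distance_matrix(results).to_csv(out("match_distances.tsv"), sep="\t", index_label="cluster_id")
        annotations = {}
        fam_by_id = {f.family_id: f for f in families}
        for c in clusters_tr:
            for fam in c.member_families:
                anns = sorted({gene_index[g].annotation for g, _ in fam_by_id[fam].members})
                annotations[fam] = anns
        _dump_json(
            traits_mod.candidate_report(results, clusters_tr, annotations, g=growth, k=int(tr_cfg.get("top_k", 3))),
            out("trait_candidates.json"),
        )
        logger.info("traits: %d clusters, %d constant families", len(clusters_tr), len(constant))

        # ------------------------------------------------ consensus
        stage = "consensus"
        cons_cfg = config.get("consensus", {})
        cons = consensus_mod.majority_consensus(
            gene_trees, threshold=float(cons_cfg.get("threshold", 0.5))
        )
        with open(out("consensus_tree.nwk"), "w") as fh:
            fh.write(cons.newick + "\n")
        logger.info("consensus: %d splits retained from %d trees", len(cons.supports), cons.n_trees)

        # ------------------------------------------------ stats
        stage = "stats"
        summaries = []
        for genome in genomes:
            genome_genes = [r for r in records if r.genome_id == genome]
            summaries.append(genome_stats.summarize_genome(genome_genes))
        with open(out("genome_summaries.tsv"), "w") as fh:
            fh.write("genome_id\tgenome_length_bp\tn_genes\tn_trna\tn_is_elements\tpct_hypothetical\tpct_assigned\n")
            for s in summaries:
                fh.write(
                    f"{s.genome_id}\t{s.genome_length_bp}\t{s.n_genes}\t{s.n_trna}\t"
                    f"{s.n_is_elements}\t{s.pct_hypothetical:.2f}\t{s.pct_assigned:.2f}\n"
                )
        avg = genome_stats.panel_averages(summaries)
        _dump_json(
            {**avg.__dict__, "start_codon_freqs": genome_stats.panel_start_codon_freqs(records)},
            out("panel_averages.json"),
        )
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for p in outputs:
            if p.exists():
                shutil.move(str(p), str(failed / p.name))
        raise PipelineFailure(stage, exc) from exc

    manifest = {
        "seed": seed,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs) if p.exists()},
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
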