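"""Seeded synthetic strain panels with known ground truth.

The generator emulates the statistical structure of a bacterial strain panel:
a shared core family set, dispensable families with per-strain presence
probabilities, strain-unique families, occasional paralogues, mobilome genes,
contiguous horizontally-acquired (HGT) blocks with deviated G+C, all-vs-all
similarity hits consistent with family membership (plus optional spurious
cross-family hits), carbohydrate growth phenotypes caused by designated gene
clusters, and gene trees perturbed from a known species tree.

One root seed drives one ``SeedSequence``; independent sub-streams are spawned
per component (presence, layout, sequences, hits, phenotypes, species tree) so
adding a component does not perturb the others.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import GeneRecord, PhenotypeTable, SimilarityHit

#: Start-codon usage of the generator (renormalized at sampling time).
START_CODON_PROBS = {"ATG": 0.87, "GTG": 0.0953, "TTG": 0.0324, "CTG": 0.0008}

MOBILE_ANNOTATIONS = (
    "IS30 family transposase",
    "IS3 family transposase",
    "integrase",
    "phage tail protein",
    "mobile element protein",
)

#: Carbohydrates with strain-variable fermentation in the emulated assay.
VARIABLE_SUGARS = (
    "ribose", "galactan", "sucrose", "melezitose", "cellobiose", "mannitol",
    "sorbitol", "xylose", "pullulan", "amylopectin", "starch", "maltodextrin",
    "fructose",
)


@dataclass
class PanelConfig:
    """Study conditions for one synthetic strain panel."""

    n_strains: int = 13
    n_core: int = 1300
    n_dispensable: int = 900
    presence_prob: Union[float, tuple[float, float]] = 0.5  # scalar or Beta(a, b)
    n_unique_per_strain: int = 50
    paralog_frac: float = 0.14
    mobile_frac: float = 0.02
    gc_mean: float = 58.0
    gc_sd: float = 2.0
    hgt_block_count: int = 8
    hgt_block_size: int = 5
    hgt_gc_low: float = 40.0
    hgt_gc_high: float = 72.0
    n_traits: int = 8
    causal_cluster_size: int = 3
    pheno_flip_prob: float = 0.0
    od_growth_range: tuple[float, float] = (0.5, 1.2)
    od_nogrowth_range: tuple[float, float] = (0.05, 0.25)
    hit_identity_range: tuple[float, float] = (60.0, 100.0)
    spurious_hit_rate: float = 0.0
    gene_length_range: tuple[int, int] = (300, 1500)  # bp, rounded to codons
    intergenic_gap_range: tuple[int, int] = (50, 200)
    hypothetical_frac: float = 0.26
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 3:
            raise ConfigError("n_strains must be >= 3")
        for name in ("paralog_frac", "mobile_frac", "pheno_flip_prob",
                     "spurious_hit_rate", "hypothetical_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if isinstance(self.presence_prob, tuple):
            a, b = self.presence_prob
            if a <= 0 or b <= 0:
                raise ConfigError("Beta presence_prob parameters must be positive")
        elif not 0.0 < self.presence_prob < 1.0:
            raise ConfigError("presence_prob must be in (0, 1)")
        reserved = self.n_traits * self.causal_cluster_size + self.hgt_block_count * self.hgt_block_size
        if reserved > self.n_dispensable:
            raise ConfigError(
                f"infeasible config: {self.n_traits} traits x {self.causal_cluster_size} causal "
                f"families plus {self.hgt_block_count} HGT blocks x {self.hgt_block_size} need "
                f"{reserved} dispensable families, only {self.n_dispensable} configured"
            )
        genes_per_strain_min = self.n_core + self.n_unique_per_strain
        if self.hgt_block_count * self.hgt_block_size > genes_per_strain_min:
            raise ConfigError("infeasible config: HGT blocks exceed the per-strain gene count")
        if self.gene_length_range[0] < 6 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ConfigError("gene_length_range must be increasing and >= 6 bp")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    family_of: dict[str, str]  # gene_id -> family_id
    class_of: dict[str, str]  # family_id -> core | dispensable | unique
    hgt_genes: set[str]
    causal_cluster_of: dict[str, frozenset]  # trait -> causal family ids
    species_tree_newick: str

    def species_tree(self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.species_tree_newick,
            schema="newick",
            taxon_namespace=taxon_namespace,
        )

    def to_json_dict(self) -> dict:
        return {
            "family_of": self.family_of,
            "class_of": self.class_of,
            "hgt_genes": sorted(self.hgt_genes),
            "causal_cluster_of": {t: sorted(v) for t, v in self.causal_cluster_of.items()},
            "species_tree_newick": self.species_tree_newick,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            family_of=dict(d["family_of"]),
            class_of=dict(d["class_of"]),
            hgt_genes=set(d["hgt_genes"]),
            causal_cluster_of={t: frozenset(v) for t, v in d["causal_cluster_of"].items()},
            species_tree_newick=d["species_tree_newick"],
        )


@dataclass
class _FamilyPlan:
    family_id: str
    kind: str  # core | dispensable | unique
    present_in: list[int]  # strain indices
    extra_copy_in: Optional[int]  # strain index with a paralogous second copy
    gc_target: float
    length_bp: int
    aa_len: int
    is_hgt: bool
    hgt_block: Optional[int]
    is_mobile: bool
    annotation: str


def _sample_presence_prob(cfg: PanelConfig, rng: np.random.Generator) -> float:
    if isinstance(cfg.presence_prob, tuple):
        a, b = cfg.presence_prob
        return float(rng.beta(a, b))
    return float(cfg.presence_prob)


def _dispensable_pattern(cfg: PanelConfig, rng: np.random.Generator) -> list[int]:
    """Per-strain presence with 2 <= carriers <= n_strains - 1 (so the family's
    true class is dispensable by construction)."""
    s = cfg.n_strains
    while True:
        p = _sample_presence_prob(cfg, rng)
        mask = rng.random(s) < p
        k = int(mask.sum())
        if 2 <= k <= s - 1:
            return [i for i in range(s) if mask[i]]


def _annotation(cfg: PanelConfig, rng: np.random.Generator, mobile: bool, family_id: str) -> str:
    if mobile:
        return MOBILE_ANNOTATIONS[int(rng.integers(len(MOBILE_ANNOTATIONS)))]
    if rng.random() < cfg.hypothetical_frac:
        return "hypothetical protein"
    return f"conserved protein {family_id}"


def _plan_families(cfg: PanelConfig, rng: np.random.Generator) -> list[_FamilyPlan]:
    plans: list[_FamilyPlan] = []
    s = cfg.n_strains
    n_hgt = cfg.hgt_block_count * cfg.hgt_block_size
    n_causal = cfg.n_traits * cfg.causal_cluster_size
    total = cfg.n_core + cfg.n_dispensable + cfg.n_unique_per_strain * s
    width = max(5, len(str(total)))
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"TF{counter:0{width}d}"

    lo, hi = cfg.gene_length_range

    def fam_length() -> int:
        return int(rng.integers(lo // 3, hi // 3 + 1)) * 3

    def background_gc() -> float:
        return float(np.clip(rng.normal(cfg.gc_mean, cfg.gc_sd), 25.0, 75.0))

    # core families (paralog extra copies assigned below)
    n_paralog = int(round(cfg.paralog_frac * cfg.n_core))
    paralog_set = set(rng.choice(cfg.n_core, size=n_paralog, replace=False)) if n_paralog else set()
    for i in range(cfg.n_core):
        fid = next_id()
        mobile = rng.random() < cfg.mobile_frac
        plans.append(
            _FamilyPlan(
                family_id=fid,
                kind="core",
                present_in=list(range(s)),
                extra_copy_in=int(rng.integers(s)) if i in paralog_set else None,
                gc_target=background_gc(),
                length_bp=(L := fam_length()),
                aa_len=L // 3,
                is_hgt=False,
                hgt_block=None,
                is_mobile=mobile,
                annotation=_annotation(cfg, rng, mobile, fid),
            )
        )

    # causal dispensable families: each trait's families share one pattern
    causal_patterns: list[list[int]] = []
    for _ in range(cfg.n_traits):
        pattern = _dispensable_pattern(cfg, rng)
        causal_patterns.append(pattern)
        for _ in range(cfg.causal_cluster_size):
            fid = next_id()
            plans.append(
                _FamilyPlan(
                    family_id=fid,
                    kind="dispensable",
                    present_in=list(pattern),
                    extra_copy_in=None,
                    gc_target=background_gc(),
                    length_bp=(L := fam_length()),
                    aa_len=L // 3,
                    is_hgt=False,
                    hgt_block=None,
                    is_mobile=False,
                    annotation=_annotation(cfg, rng, False, fid),
                )
            )

    # HGT blocks: block-level presence, alternating low/high G+C targets
    for b in range(cfg.hgt_block_count):
        pattern = _dispensable_pattern(cfg, rng)
        gc = cfg.hgt_gc_low if b % 2 == 0 else cfg.hgt_gc_high
        for _ in range(cfg.hgt_block_size):
            fid = next_id()
            plans.append(
                _FamilyPlan(
                    family_id=fid,
                    kind="dispensable",
                    present_in=list(pattern),
                    extra_copy_in=None,
                    gc_target=gc,
                    length_bp=(L := fam_length()),
                    aa_len=L // 3,
                    is_hgt=True,
                    hgt_block=b,
                    is_mobile=False,
                    annotation=_annotation(cfg, rng, False, fid),
                )
            )

    # free dispensable families
    n_free = cfg.n_dispensable - cfg.n_traits * cfg.causal_cluster_size - cfg.hgt_block_count * cfg.hgt_block_size
    for _ in range(n_free):
        fid = next_id()
        mobile = rng.random() < cfg.mobile_frac
        plans.append(
            _FamilyPlan(
                family_id=fid,
                kind="dispensable",
                present_in=_dispensable_pattern(cfg, rng),
                extra_copy_in=None,
                gc_target=background_gc(),
                length_bp=(L := fam_length()),
                aa_len=L // 3,
                is_hgt=False,
                hgt_block=None,
                is_mobile=mobile,
                annotation=_annotation(cfg, rng, mobile, fid),
            )
        )

    # strain-unique families (unique genes are enriched for the mobilome)
    for strain_idx in range(s):
        for _ in range(cfg.n_unique_per_strain):
            fid = next_id()
            mobile = rng.random() < min(1.0, 4 * cfg.mobile_frac)
            plans.append(
                _FamilyPlan(
                    family_id=fid,
                    kind="unique",
                    present_in=[strain_idx],
                    extra_copy_in=None,
                    gc_target=background_gc(),
                    length_bp=(L := fam_length()),
                    aa_len=L // 3,
                    is_hgt=False,
                    hgt_block=None,
                    is_mobile=mobile,
                    annotation=_annotation(cfg, rng, mobile, fid),
                )
            )
    return plans


def _gene_sequence(rng: np.random.Generator, length_bp: int, gc_target: float) -> str:
    codons = list(START_CODON_PROBS)
    probs = np.array(list(START_CODON_PROBS.values()))
    probs = probs / probs.sum()
    start = codons[int(rng.choice(len(codons), p=probs))]
    body_len = length_bp - 3
    r1 = rng.random(body_len)
    r2 = rng.random(body_len)
    bases = np.empty(body_len, dtype="S1")
    gc_mask = r1 < gc_target / 100.0
    bases[gc_mask & (r2 < 0.5)] = b"G"
    bases[gc_mask & (r2 >= 0.5)] = b"C"
    bases[~gc_mask & (r2 < 0.5)] = b"A"
    bases[~gc_mask & (r2 >= 0.5)] = b"T"
    return start + bases.tobytes().decode("ascii")


def _random_species_tree(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Random binary topology over the strain labels, as a Newick string."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def simulate_panel(
    config: PanelConfig,
) -> tuple[list[GeneRecord], list[SimilarityHit], PhenotypeTable, GroundTruth]:
    """Generate a full synthetic strain panel. Deterministic for a fixed seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_presence, rng_layout, rng_seq, rng_hits, rng_pheno, rng_tree = (
        np.random.default_rng(s) for s in streams
    )
    strains = [f"S{i + 1:02d}" for i in range(config.n_strains)]
    plans = _plan_families(config, rng_presence)
    plan_of = {p.family_id: p for p in plans}

    # --- gene layout: one contig per strain, HGT blocks as contiguous runs ---
    records: list[GeneRecord] = []
    genes_of_family: dict[str, list[tuple[str, int]]] = {p.family_id: [] for p in plans}
    family_of: dict[str, str] = {}
    hgt_genes: set[str] = set()
    gap_lo, gap_hi = config.intergenic_gap_range

    for si, strain in enumerate(strains):
        base_units: list[str] = []  # family ids, copies expanded, non-HGT
        blocks: dict[int, list[str]] = {}
        for p in plans:
            if si not in p.present_in:
                continue
            if p.is_hgt:
                blocks.setdefault(p.hgt_block, []).append(p.family_id)
                continue
            base_units.append(p.family_id)
            if p.extra_copy_in == si:
                base_units.append(p.family_id)
        block_ids = sorted(blocks)
        n_chunks = len(block_ids) + 1
        chunk = max(1, math.ceil(len(base_units) / n_chunks))
        layout: list[str] = []
        for c in range(n_chunks):
            layout.extend(base_units[c * chunk : (c + 1) * chunk])
            if c < len(block_ids):
                layout.extend(blocks[block_ids[c]])

        pos = 0
        for serial, fid in enumerate(layout, start=1):
            p = plan_of[fid]
            gap = int(rng_layout.integers(gap_lo, gap_hi + 1))
            start = pos + gap
            end = start + p.length_bp - 1
            pos = end
            gid = f"{strain}_g{serial:05d}"
            strand = "+" if rng_layout.random() < 0.5 else "-"
            seq = _gene_sequence(rng_seq, p.length_bp, p.gc_target)
            records.append(
                GeneRecord(
                    gene_id=gid,
                    genome_id=strain,
                    contig_id=f"{strain}_contig1",
                    start=start,
                    end=end,
                    strand=strand,
                    annotation=p.annotation,
                    is_mobile=p.is_mobile,
                    nt_seq=seq,
                    aa_len=p.aa_len,
                )
            )
            genes_of_family[fid].append((gid, p.aa_len))
            family_of[gid] = fid
            if p.is_hgt:
                hgt_genes.add(gid)

    # --- all-vs-all hits consistent with family membership ---
    hits: list[SimilarityHit] = []
    id_lo, id_hi = config.hit_identity_range
    n_within_pairs = 0
    for p in plans:
        members = genes_of_family[p.family_id]
        m = len(members)
        if m < 2:
            continue
        n_within_pairs += m * (m - 1) // 2
        k = m * (m - 1)
        idents = rng_hits.uniform(id_lo, id_hi, size=k)
        fracs = rng_hits.uniform(0.8, 1.0, size=k)
        log_e = rng_hits.uniform(-180.0, -20.0, size=k)
        t = 0
        for qi in range(m):
            for sj in range(m):
                if qi == sj:
                    continue
                (qid, qlen), (sid, slen) = members[qi], members[sj]
                aln = max(1, math.ceil(fracs[t] * min(qlen, slen)))
                hits.append(
                    SimilarityHit(
                        query_id=qid,
                        subject_id=sid,
                        pct_identity=round(float(idents[t]), 2),
                        aln_length=aln,
                        e_value=10.0 ** float(log_e[t]),
                        q_len=qlen,
                        s_len=slen,
                    )
                )
                t += 1

    if config.spurious_hit_rate > 0:
        all_genes = [(g.gene_id, g.aa_len) for g in records]
        n_spur = int(round(config.spurious_hit_rate * n_within_pairs))
        made = 0
        while made < n_spur:
            i, j = rng_hits.integers(len(all_genes), size=2)
            gid_a, len_a = all_genes[int(i)]
            gid_b, len_b = all_genes[int(j)]
            if gid_a == gid_b or family_of[gid_a] == family_of[gid_b]:
                continue
            ident = round(float(rng_hits.uniform(25.0, 45.0)), 2)
            e_val = float(rng_hits.uniform(1e-3, 1.0))
            aln = max(1, math.ceil(rng_hits.uniform(0.2, 0.6) * min(len_a, len_b)))
            for q, s, ql, sl in ((gid_a, gid_b, len_a, len_b), (gid_b, gid_a, len_b, len_a)):
                hits.append(
                    SimilarityHit(
                        query_id=q, subject_id=s, pct_identity=ident,
                        aln_length=aln, e_value=e_val, q_len=ql, s_len=sl,
                    )
                )
            made += 1

    # --- phenotypes driven by the causal clusters ---
    trait_names = [
        VARIABLE_SUGARS[i] if i < len(VARIABLE_SUGARS) else f"sugar{i + 1:02d}"
        for i in range(config.n_traits)
    ]
    causal_cluster_of: dict[str, frozenset] = {}
    causal_plans = [p for p in plans if p.kind == "dispensable" and not p.is_hgt]
    od = np.zeros((config.n_strains, config.n_traits))
    glo, ghi = config.od_growth_range
    nlo, nhi = config.od_nogrowth_range
    for t in range(config.n_traits):
        fams = causal_plans[t * config.causal_cluster_size : (t + 1) * config.causal_cluster_size]
        causal_cluster_of[trait_names[t]] = frozenset(p.family_id for p in fams)
        carriers = set(fams[0].present_in)
        for si in range(config.n_strains):
            grows = si in carriers
            if rng_pheno.random() < config.pheno_flip_prob:
                grows = not grows
            od[si, t] = rng_pheno.uniform(glo, ghi) if grows else rng_pheno.uniform(nlo, nhi)
    pheno = PhenotypeTable(od=pd.DataFrame(od, index=strains, columns=trait_names))

    class_of = {p.family_id: p.kind for p in plans if genes_of_family[p.family_id]}
    truth = GroundTruth(
        family_of=family_of,
        class_of=class_of,
        hgt_genes=hgt_genes,
        causal_cluster_of=causal_cluster_of,
        species_tree_newick=_random_species_tree(strains, rng_tree),
    )
    return records, hits, pheno, truth


def _random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """Apply one random nearest-neighbour interchange in place.

    Always changes the unrooted topology: the subtree below the chosen
    internal edge swaps one child with one of its parent's other children.
    """
    candidates = [
        n
        for n in tree.preorder_node_iter()
        if n.parent_node is not None and not n.is_leaf()
    ]
    v = candidates[int(rng.integers(len(candidates)))]
    p = v.parent_node
    siblings = [c for c in p.child_nodes() if c is not v]
    b = siblings[int(rng.integers(len(siblings)))]
    children = v.child_nodes()
    a = children[int(rng.integers(len(children)))]
    v.remove_child(a)
    p.remove_child(b)
    p.add_child(a)
    v.add_child(b)


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    n_trees: int,
    perturb_prob: float,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Copies of the species tree, each independently given one random NNI
    with probability ``perturb_prob``. Deterministic for a fixed seed."""
    if not 0.0 <= perturb_prob <= 1.0:
        raise ConfigError(f"perturb_prob must be in [0, 1], got {perturb_prob}")
    n_leaves = sum(1 for _ in species_tree.leaf_node_iter())
    if n_leaves < 4:
        raise ConfigError("species tree must have at least 4 leaves")
    rng = np.random.default_rng(seed)
    newick = species_tree.as_string(schema="newick", suppress_rooting=True)
    trees: list[dendropy.Tree] = []
    for _ in range(n_trees):
        t = dendropy.Tree.get(
            data=newick, schema="newick", taxon_namespace=species_tree.taxon_namespace
        )
        t.deroot()
        if rng.random() < perturb_prob:
            _random_nni(t, rng)
        trees.append(t)
    return trees


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json_dict(json.load(fh))
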