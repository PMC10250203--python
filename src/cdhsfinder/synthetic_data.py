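"""Synthetic genome collections with known ground truth.

The generator emulates the structure the pipeline assumes in real
bacterial species collections: many isolates of one species sharing a
conserved gene backbone, two marker-flanked hotspot loci whose variable
cargo carries complete defense systems, planted decoys (systems missing
one essential gene), GC-depressed cargo, and a known phylogeny relating
the isolates (backbone and marker genes accumulate substitutions along
the tree). Every emitted file parses under the package's own readers, and
a manifest records exactly what was planted where, so every analysis
stage can be scored against ground truth offline.

Sequences are random-codon fillers except planted system genes and
markers, which are fixed reference sequences (markers additionally
mutated per branch) — this keeps identity-threshold behavior fully
controllable. Substitutions swap bases within their GC class (A<->T,
C<->G), so divergence accumulates without disturbing the configured
GC structure. Determinism: one integer seed drives everything.
"""

from __future__ import annotations

import dataclasses
import json
import os
import random as pyrandom
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from dendropy.simulate import treesim

from . import genome_io
from .genome_io import Genome, GenomeDB, GeneRecord, Replicon
from .hotspot_mapper import MarkerPair
from .search_reduce import Hit
from .system_caller import (
    SystemDefinition,
    SystemGene,
    dump_definitions,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)  # codes 0..3; A<->T=0<->3, C<->G=1<->2


@dataclass
class HotspotSpec:
    """One simulated hotspot: where it sits and how often it is occupied."""

    name: str
    occupancy: float  # probability a locus carries >= 1 complete system
    # backbone gene index the locus follows; None = evenly spaced
    insert_after: int | None = None
    left_is_protein: bool = True
    marker_pad_bp: int = 4500  # spacer between outer backbone gene and marker
    max_systems: int = 2


@dataclass
class SimConfig:
    seed: int
    n_genomes: int = 20
    n_species: int = 1
    n_backbone_genes: int = 120
    backbone_gc: float = 0.65
    cargo_gc_offset: float = -0.06
    n_system_types: int = 10
    decoy_rate: float = 0.3
    substitution_rate: float = 0.01  # per site per unit branch length
    tree_depth: float = 1.0
    hotspots: list[HotspotSpec] = field(
        default_factory=lambda: [
            HotspotSpec("cDHS1", occupancy=0.8),
            HotspotSpec("cDHS2", occupancy=0.15, left_is_protein=False),
        ]
    )

    def validate(self) -> None:
        for h in self.hotspots:
            if not 0 <= h.occupancy <= 1:
                raise ValueError(f"{h.name}: occupancy outside [0,1]")
            if h.occupancy > 0 and self.n_system_types == 0:
                raise ValueError(f"{h.name}: occupancy > 0 with empty system pool")
            if h.insert_after is not None and not (
                0 <= h.insert_after < self.n_backbone_genes - 1
            ):
                raise ValueError(
                    f"{h.name}: insert_after={h.insert_after} outside the "
                    f"backbone (0..{self.n_backbone_genes - 2})"
                )

    def resolved_positions(self) -> dict[int, "HotspotSpec"]:
        """Backbone index -> hotspot, with unplaced hotspots spread evenly."""
        positions: dict[int, HotspotSpec] = {}
        n_auto = sum(h.insert_after is None for h in self.hotspots)
        auto_slot = 0
        for h in self.hotspots:
            if h.insert_after is not None:
                pos = h.insert_after
            else:
                auto_slot += 1
                pos = round(self.n_backbone_genes * auto_slot / (n_auto + 1))
            if pos in positions:
                raise ValueError(f"two hotspots at backbone index {pos}")
            positions[pos] = h
        return positions
        if not 0 <= self.decoy_rate <= 1:
            raise ValueError("decoy_rate outside [0,1]")
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes to relate by a tree")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring the pipeline against."""

    systems: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)
    loci: list[dict] = field(default_factory=list)
    tree_newick: str = ""
    species: dict[str, str] = field(default_factory=dict)
    definitions: list[SystemDefinition] = field(default_factory=list)
    marker_pairs: list[MarkerPair] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def marker_gene_ids(self, hotspot: str | None = None) -> set[str]:
        out = set()
        for locus in self.loci:
            if hotspot is None or locus["hotspot"] == hotspot:
                out.add(locus["left_gene"])
                out.add(locus["right_gene"])
        return out

    def occupancy_fraction(self, hotspot: str) -> float:
        loci = [l for l in self.loci if l["hotspot"] == hotspot]
        if not loci:
            return 0.0
        return sum(l["occupied"] for l in loci) / len(loci)


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def _rand_nt_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    is_gc = rng.random(n) < gc
    pick = rng.random(n) < 0.5
    return np.where(is_gc, np.where(pick, 1, 2), np.where(pick, 0, 3)).astype(
        np.uint8
    )


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


_STOP_REPAIR = {  # GC-class-preserving repairs: TAA->TTA, TAG->TTG, TGA->TGT
    (3, 0, 0): (1, 3),
    (3, 0, 2): (1, 3),
    (3, 2, 0): (2, 3),
}


def _rand_coding_codes(
    rng: np.random.Generator, n_codons: int, gc: float
) -> np.ndarray:
    codes = _rand_nt_codes(rng, 3 * n_codons, gc).reshape(n_codons, 3)
    for stop, (pos, base) in _STOP_REPAIR.items():
        mask = (codes == np.array(stop, dtype=np.uint8)).all(axis=1)
        codes[mask, pos] = base
    return codes.reshape(-1)


def _translate(nt: str) -> str:
    trimmed = nt[: len(nt) - len(nt) % 3]
    return str(Seq(trimmed).translate(table=11)).replace("*", "X")


def _mutate(
    rng: np.random.Generator, codes: np.ndarray, p: float
) -> np.ndarray:
    """Substitute each site with probability p, swapping within GC class."""
    if p <= 0:
        return codes
    out = codes.copy()
    mask = rng.random(out.size) < p
    out[mask] = 3 - out[mask]
    return out


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _simulate_tree(config: SimConfig, genome_ids: list[str]) -> "treesim":
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=config.n_genomes,
        rng=pyrandom.Random(config.seed + 1),
    )
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if depth > 0:
        factor = config.tree_depth / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    for leaf, gid in zip(tree.leaf_node_iter(), genome_ids):
        leaf.taxon.label = gid
    return tree


def _build_system_pool(config: SimConfig, rng: np.random.Generator):
    """System definitions plus concrete gene sequences for each role.

    Half the pool requires two essential genes (quorum by essentials only
    — these are the decoy donors: dropping one essential makes the
    instance uncallable); the other half has one essential plus three
    accessory roles with an accessory threshold, exercising the accessory
    quorum route.
    """
    cargo_gc = config.backbone_gc + config.cargo_gc_offset
    definitions, gene_seqs = [], {}
    decoy_capable = []
    for si in range(config.n_system_types):
        name = f"sys{si:02d}"
        genes = []
        if si < (config.n_system_types + 1) // 2:
            roles = [("core1", "essential"), ("core2", "essential")]
            roles += [(f"acc{j+1}", "accessory")
                      for j in range(int(rng.integers(0, 3)))]
            min_accessory = 0
            decoy_capable.append(name)
        else:
            roles = [("core1", "essential")]
            roles += [(f"acc{j+1}", "accessory") for j in range(3)]
            min_accessory = 2
        for role, status in roles:
            model = f"{name}__{role}"
            genes.append(SystemGene(role=role, model_ids=[model], status=status))
            n_codons = int(rng.integers(200, 301))
            gene_seqs[model] = _rand_coding_codes(rng, n_codons, cargo_gc)
        definitions.append(
            SystemDefinition(
                system_name=name, genes=genes, min_accessory=min_accessory,
                max_intervening=3,
            )
        )
    return definitions, gene_seqs, decoy_capable


class _GenomeAssembler:
    """Lays genes onto a growing replicon sequence, tracking coordinates."""

    def __init__(self, genome_id: str, replicon_id: str,
                 rng: np.random.Generator):
        self.genome_id = genome_id
        self.replicon_id = replicon_id
        self.rng = rng
        self.parts: list[np.ndarray] = []
        self.cursor = 0  # 0-based length so far
        self.genes: list[GeneRecord] = []
        self._n = 0

    def spacer(self, length: int, gc: float) -> None:
        self.parts.append(_rand_nt_codes(self.rng, length, gc))
        self.cursor += length

    def gene(self, codes: np.ndarray, product: str, coding: bool = True) -> GeneRecord:
        gid = f"{self.genome_id}_{self._n:04d}"
        self._n += 1
        strand = "+" if self.rng.random() < 0.5 else "-"
        placed = codes if strand == "+" else (3 - codes)[::-1]
        start = self.cursor + 1
        self.parts.append(placed)
        self.cursor += codes.size
        rec = GeneRecord(
            gene_id=gid,
            genome_id=self.genome_id,
            replicon_id=self.replicon_id,
            ordinal=-1,
            start=start,
            end=self.cursor,
            strand=strand,
            protein_seq=_translate(_codes_to_str(codes)) if coding else "",
            product=product,
        )
        self.genes.append(rec)
        return rec

    def finish(self) -> Replicon:
        seq = _codes_to_str(np.concatenate(self.parts))
        rep = Replicon(
            replicon_id=self.replicon_id,
            genome_id=self.genome_id,
            length_bp=len(seq),
            topology="linear",
            nt_seq=seq,
            genes=self.genes,
        )
        rep.sort_and_index()
        return rep


def simulate(config: SimConfig) -> tuple[GenomeDB, GroundTruth]:
    """Generate a genome collection plus its ground-truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cargo_gc = config.backbone_gc + config.cargo_gc_offset
    genome_ids = [f"g{i:03d}" for i in range(config.n_genomes)]

    definitions, system_gene_seqs, decoy_capable = _build_system_pool(config, rng)
    def_by_name = {d.system_name: d for d in definitions}

    # root sequences for everything that evolves along the tree
    root_seqs: dict[str, np.ndarray] = {}
    backbone_lens = rng.integers(200, 501, size=config.n_backbone_genes)
    for i in range(config.n_backbone_genes):
        root_seqs[f"bb{i}"] = _rand_coding_codes(
            rng, int(backbone_lens[i]), config.backbone_gc
        )
    marker_meta: dict[str, dict] = {}
    for h in config.hotspots:
        left_key, right_key = f"mk:{h.name}:L", f"mk:{h.name}:R"
        if h.left_is_protein:
            root_seqs[left_key] = _rand_coding_codes(rng, 300, config.backbone_gc)
        else:  # non-coding RNA marker (tmRNA-like)
            root_seqs[left_key] = _rand_nt_codes(rng, 350, config.backbone_gc)
        root_seqs[right_key] = _rand_coding_codes(rng, 500, config.backbone_gc)
        marker_meta[h.name] = {"left_key": left_key, "right_key": right_key}

    tree = _simulate_tree(config, genome_ids)
    tree_newick = tree.as_string(schema="newick", suppress_rooting=True).strip()

    # evolve root sequences down the tree (GC-class-preserving substitutions)
    leaf_seqs: dict[str, dict[str, np.ndarray]] = {}

    def _descend(node, seqs):
        for child in node.child_nodes():
            p = config.substitution_rate * (child.edge.length or 0.0)
            child_seqs = {k: _mutate(rng, v, p) for k, v in seqs.items()}
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = child_seqs
            else:
                _descend(child, child_seqs)

    _descend(tree.seed_node, root_seqs)

    truth = GroundTruth(
        tree_newick=tree_newick,
        definitions=definitions,
        config=dataclasses.asdict(config),
    )
    for h in config.hotspots:
        meta = marker_meta[h.name]
        left_root = _codes_to_str(root_seqs[meta["left_key"]])
        truth.marker_pairs.append(
            MarkerPair(
                name=h.name,
                left_marker=_translate(left_root) if h.left_is_protein
                else left_root,
                right_marker=_translate(_codes_to_str(root_seqs[meta["right_key"]])),
                left_is_protein=h.left_is_protein,
            )
        )

    db = GenomeDB()
    hotspot_by_pos = config.resolved_positions()
    for gi, gid in enumerate(genome_ids):
        species = f"sp{gi % config.n_species}"
        truth.species[gid] = species
        asm = _GenomeAssembler(gid, f"{gid}_chr", rng)
        seqs = leaf_seqs[gid]
        for bi in range(config.n_backbone_genes):
            asm.spacer(int(rng.integers(50, 201)), config.backbone_gc)
            asm.gene(seqs[f"bb{bi}"], product=f"backbone protein {bi}")
            h = hotspot_by_pos.get(bi)
            if h is not None:
                _plant_hotspot(
                    asm, h, seqs, marker_meta[h.name], rng, config, cargo_gc,
                    def_by_name, system_gene_seqs, decoy_capable, truth,
                )
        asm.spacer(int(rng.integers(50, 201)), config.backbone_gc)
        rep = asm.finish()
        genome = Genome(genome_id=gid, species=species,
                        replicons={rep.replicon_id: rep})
        db.add(genome)
    return db, truth


def _plant_hotspot(asm, h, seqs, meta, rng, config, cargo_gc, def_by_name,
                   system_gene_seqs, decoy_capable, truth):
    asm.spacer(h.marker_pad_bp, config.backbone_gc)
    left = asm.gene(
        seqs[meta["left_key"]],
        product=f"{h.name} left flank marker",
        coding=h.left_is_protein,
    )

    occupied = bool(rng.random() < h.occupancy)
    planted_types: list[str] = []
    cassettes: list[tuple[str, str]] = []  # (kind, payload)
    if occupied:
        n_sys = int(rng.integers(1, h.max_systems + 1))
        names = sorted(def_by_name)
        picks = rng.choice(len(names), size=n_sys, replace=False)
        for pi in sorted(int(x) for x in picks):
            cassettes.append(("system", names[pi]))
            planted_types.append(names[pi])
    if decoy_capable and rng.random() < config.decoy_rate:
        options = [n for n in decoy_capable if n not in planted_types]
        if options:
            cassettes.append(
                ("decoy", options[int(rng.integers(0, len(options)))])
            )
    for _ in range(int(rng.integers(1, 4))):
        cassettes.append(("neutral", ""))
    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[int(i)] for i in order]

    cargo_records: list[GeneRecord] = []
    for kind, payload in cassettes:
        if kind == "neutral":
            asm.spacer(int(rng.integers(50, 151)), cargo_gc)
            codes = _rand_coding_codes(rng, int(rng.integers(100, 301)), cargo_gc)
            cargo_records.append(asm.gene(codes, product="hypothetical protein"))
            continue
        definition = def_by_name[payload]
        genes = list(definition.genes)
        if kind == "decoy":
            essential_idx = [
                i for i, g in enumerate(genes) if g.status == "essential"
            ]
            drop = essential_idx[int(rng.integers(0, len(essential_idx)))]
            genes = [g for i, g in enumerate(genes) if i != drop]
        members = []
        for g in genes:
            asm.spacer(int(rng.integers(50, 151)), cargo_gc)
            model = g.model_ids[0]
            rec = asm.gene(
                system_gene_seqs[model].copy(),
                product=f"{payload} {g.role} protein",
            )
            members.append((rec, model))
            cargo_records.append(rec)
        entry = {
            "genome_id": asm.genome_id,
            "replicon_id": asm.replicon_id,
            "hotspot": h.name,
            "system_name": payload,
            "gene_ids": [r.gene_id for r, _ in members],
            "gene_models": {r.gene_id: m for r, m in members},
            "span": [min(r.start for r, _ in members),
                     max(r.end for r, _ in members)],
        }
        (truth.systems if kind == "system" else truth.decoys).append(entry)

    asm.spacer(int(rng.integers(50, 151)), cargo_gc)
    right = asm.gene(
        seqs[meta["right_key"]], product=f"{h.name} right flank marker"
    )
    asm.spacer(h.marker_pad_bp, config.backbone_gc)
    truth.loci.append(
        {
            "hotspot": h.name,
            "genome_id": asm.genome_id,
            "replicon_id": asm.replicon_id,
            "left_gene": left.gene_id,
            "right_gene": right.gene_id,
            "size_bp": right.start - left.end - 1,
            "cargo_gene_ids": [r.gene_id for r in cargo_records],
            "occupied": occupied,
            "planted_systems": planted_types,
        }
    )


# ---------------------------------------------------------------------------
# mock hit tables
# ---------------------------------------------------------------------------

def mock_hits(
    db: GenomeDB,
    truth: GroundTruth,
    n_noise: int = 0,
    seed: int = 0,
) -> list[Hit]:
    """Hit table as a perfect search backend would report it.

    One confidently sub-threshold hit (e = 1e-30) per planted system gene
    — decoy genes included, so decoys are visible to the caller yet must
    never be called. Optional noise hits carry e-values of at least 1e-8,
    above the strict 1e-10 cutoff, so the e-value filter removes them all.
    """
    hits = [
        Hit(gene_id=gid, model_id=model, evalue=1e-30, score=100.0,
            source="mock")
        for entry in truth.systems + truth.decoys
        for gid, model in sorted(entry["gene_models"].items())
    ]
    if n_noise > 0:
        rng = np.random.default_rng(seed)
        planted = {h.gene_id for h in hits}
        pool = sorted(g.gene_id for g in db.genes() if g.gene_id not in planted)
        models = sorted({h.model_id for h in hits}) or ["sys00__core1"]
        for _ in range(n_noise):
            gid = pool[int(rng.integers(0, len(pool)))]
            model = models[int(rng.integers(0, len(models)))]
            evalue = float(10 ** rng.uniform(-8, -3))
            hits.append(Hit(gene_id=gid, model_id=model, evalue=evalue,
                            score=5.0, source="mock"))
    return hits


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_outputs(db: GenomeDB, truth: GroundTruth, outdir: str) -> None:
    """Emit GFF3+FASTA per genome, a gembase TSV, the tree, system and
    marker definitions, a noise-free hit table, and the manifest JSON."""
    os.makedirs(outdir, exist_ok=True)
    genomes_dir = os.path.join(outdir, "genomes")
    os.makedirs(genomes_dir, exist_ok=True)
    for gid, genome in sorted(db.genomes.items()):
        genome_io.write_gff3(
            genome,
            os.path.join(genomes_dir, f"{gid}.gff3"),
            os.path.join(genomes_dir, f"{gid}.fna"),
        )
    genome_io.write_gembase(db, os.path.join(outdir, "gembase.tsv"))
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(truth.tree_newick + "\n")
    dump_definitions(truth.definitions, os.path.join(outdir, "systems.yaml"))
    _dump_marker_pairs(truth.marker_pairs, os.path.join(outdir, "markers.yaml"))
    from .search_reduce import write_hits

    write_hits(mock_hits(db, truth), os.path.join(outdir, "hits.tsv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest_dict(truth), fh, indent=1, sort_keys=True)


def manifest_dict(truth: GroundTruth) -> dict:
    return {
        "systems": truth.systems,
        "decoys": truth.decoys,
        "loci": truth.loci,
        "tree_newick": truth.tree_newick,
        "species": truth.species,
        "config": truth.config,
    }


def _dump_marker_pairs(pairs, path: str) -> None:
    import yaml

    docs = [
        {
            "name": p.name,
            "left_marker": p.left_marker,
            "right_marker": p.right_marker,
            "left_is_protein": p.left_is_protein,
            "right_is_protein": p.right_is_protein,
            "search_identity_min": p.search_identity_min,
            "search_coverage_min": p.search_coverage_min,
        }
        for p in pairs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(docs, fh, sort_keys=False)
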