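"""Marker-flanked hotspot locus extraction and statistics.

A core defense hotspot (cDHS) is a chromosomal interval bounded by two
conserved core genes — the marker pair — whose variable cargo is enriched
for defense systems. Given reference sequences for the left and right
markers, orthologs are searched in every genome (protein identity for
coding markers, nucleotide identity for RNA markers such as tmRNA);
contigs carrying both markers yield a locus whose cargo is the genes
strictly between the markers. Per-locus statistics mirror the field's
standard readouts: size (inter-marker gap), GC% of the cargo span versus
the whole genome, occupancy by called defense systems, and the system
inventory across loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd
import yaml

from .genome_io import GeneRecord, GenomeDB, Replicon, gc_fraction
from .search_reduce import global_identity
from .system_caller import SystemCall

logger = logging.getLogger(__name__)

DEFAULT_MARKER_IDENTITY = 0.8
DEFAULT_MARKER_COVERAGE = 0.8


@dataclass
class MarkerPair:
    """Left/right flank markers delimiting one hotspot.

    Markers are reference sequences: amino-acid for protein markers,
    nucleotide for RNA markers (``left_is_protein``/``right_is_protein``).
    """

    name: str
    left_marker: str
    right_marker: str
    left_is_protein: bool = True
    right_is_protein: bool = True
    search_identity_min: float = DEFAULT_MARKER_IDENTITY
    search_coverage_min: float = DEFAULT_MARKER_COVERAGE

    def __post_init__(self) -> None:
        if not self.left_marker or not self.right_marker:
            raise ValueError(f"marker pair {self.name}: empty marker sequence")


@dataclass
class HotspotLocus:
    hotspot_name: str
    genome_id: str
    replicon_id: str
    left_gene: GeneRecord
    right_gene: GeneRecord
    cargo_genes: list[GeneRecord] = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        """Inter-marker gap, exclusive of the marker genes themselves."""
        return max(0, self.right_gene.start - self.left_gene.end - 1)

    @property
    def cargo_span(self) -> tuple[int, int] | None:
        """Nucleotide span between markers (exclusive), if non-empty."""
        lo, hi = self.left_gene.end + 1, self.right_gene.start - 1
        if hi < lo:
            return None
        return (lo, hi)


def _matches_marker(
    gene: GeneRecord, rep: Replicon, marker: str, is_protein: bool,
    identity_min: float, coverage_min: float,
) -> bool:
    query = gene.protein_seq if is_protein else (
        gene.nt_seq(rep) if rep.nt_seq else ""
    )
    if not query:
        return False
    if min(len(query), len(marker)) < coverage_min * max(len(query), len(marker)):
        return False
    return global_identity(query, marker) >= identity_min


def find_marker_orthologs(
    db: GenomeDB,
    pair: MarkerPair,
    backend: Callable[..., bool] | None = None,
) -> dict[str, tuple[list[GeneRecord], list[GeneRecord]]]:
    """Per genome, genes matching the left and right marker.

    The built-in search is a global-identity comparison (edit-distance
    based) with a length-coverage prefilter; ``backend`` may replace the
    per-gene match predicate (same signature as the internal one) to
    plug in an external ortholog search. Absence of a marker in a genome
    is data, not an error.
    """
    match = backend or _matches_marker
    out: dict[str, tuple[list[GeneRecord], list[GeneRecord]]] = {}
    for genome in db.genomes.values():
        left_hits: list[GeneRecord] = []
        right_hits: list[GeneRecord] = []
        for rep in genome.replicons.values():
            for gene in rep.genes:
                if match(gene, rep, pair.left_marker, pair.left_is_protein,
                         pair.search_identity_min, pair.search_coverage_min):
                    left_hits.append(gene)
                if match(gene, rep, pair.right_marker, pair.right_is_protein,
                         pair.search_identity_min, pair.search_coverage_min):
                    right_hits.append(gene)
        out[genome.genome_id] = (left_hits, right_hits)
    return out


def extract_loci(
    db: GenomeDB,
    marker_hits: dict[str, tuple[list[GeneRecord], list[GeneRecord]]],
    hotspot_name: str = "hotspot",
) -> list[HotspotLocus]:
    """Extract one locus per genome contig carrying both markers.

    Only contigs with at least one left AND one right marker qualify.
    When multiple marker copies exist, the pair minimizing the inner
    distance (subject to left-before-right after orientation
    normalization) is chosen, which avoids megabase false loci from
    paralogs. Cargo is the set of genes strictly between the markers.
    """
    loci = []
    for genome_id, (left_hits, right_hits) in sorted(marker_hits.items()):
        genome = db.genomes[genome_id]
        for replicon_id in sorted(genome.replicons):
            lefts = [g for g in left_hits if g.replicon_id == replicon_id]
            rights = [g for g in right_hits if g.replicon_id == replicon_id]
            if not lefts or not rights:
                continue
            best: tuple[int, GeneRecord, GeneRecord] | None = None
            for lg in lefts:
                for rg in rights:
                    if lg.gene_id == rg.gene_id:
                        continue
                    a, b = (lg, rg) if lg.start <= rg.start else (rg, lg)
                    gap = b.start - a.end - 1
                    if gap < 0:
                        continue  # overlapping markers: not a locus
                    if best is None or gap < best[0]:
                        best = (gap, a, b)
            if best is None:
                continue
            if len(lefts) > 1 or len(rights) > 1:
                logger.warning(
                    "%s/%s: multiple %s marker copies; choosing closest pair",
                    genome_id, replicon_id, hotspot_name,
                )
            _, left, right = best
            rep = genome.replicons[replicon_id]
            cargo = [
                g for g in rep.genes
                if g.start > left.end and g.end < right.start
            ]
            loci.append(
                HotspotLocus(
                    hotspot_name=hotspot_name,
                    genome_id=genome_id,
                    replicon_id=replicon_id,
                    left_gene=left,
                    right_gene=right,
                    cargo_genes=cargo,
                )
            )
    return loci


def map_hotspot(
    db: GenomeDB, pair: MarkerPair,
    backend: Callable[..., bool] | None = None,
) -> list[HotspotLocus]:
    """Convenience chain: find markers, then extract loci."""
    return extract_loci(db, find_marker_orthologs(db, pair, backend), pair.name)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _genome_gc(genome) -> float | None:
    seqs = [r.nt_seq for r in genome.replicons.values() if r.nt_seq]
    if not seqs:
        return None
    try:
        return gc_fraction("".join(seqs))
    except ValueError:
        return None


def locus_stats(loci: Sequence[HotspotLocus], db: GenomeDB) -> pd.DataFrame:
    """Per-locus size and GC table.

    GC of the locus is computed on the cargo nucleotide span only
    (markers excluded) and compared with the GC of all replicons of the
    same genome; missing sequence leaves GC columns empty but the size is
    still reported.
    """
    rows = []
    for locus in loci:
        rep = db.replicon(locus.genome_id, locus.replicon_id)
        gc_locus = None
        span = locus.cargo_span
        if rep.nt_seq and span is not None:
            try:
                gc_locus = gc_fraction(rep.nt_seq[span[0] - 1 : span[1]])
            except ValueError:
                gc_locus = None
        gc_genome = _genome_gc(db.genomes[locus.genome_id])
        rows.append(
            {
                "hotspot": locus.hotspot_name,
                "genome_id": locus.genome_id,
                "replicon_id": locus.replicon_id,
                "left_gene": locus.left_gene.gene_id,
                "right_gene": locus.right_gene.gene_id,
                "size_bp": locus.size_bp,
                "n_cargo_genes": len(locus.cargo_genes),
                "gc_locus": gc_locus,
                "gc_genome": gc_genome,
                "gc_delta": (gc_locus - gc_genome)
                if gc_locus is not None and gc_genome is not None
                else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["hotspot", "genome_id", "replicon_id", "left_gene",
                 "right_gene", "size_bp", "n_cargo_genes", "gc_locus",
                 "gc_genome", "gc_delta"],
    )


def locus_summary(stats: pd.DataFrame) -> dict[str, float]:
    """Headline numbers: size range/median (bp) and mean GC delta."""
    out = {
        "n_loci": int(len(stats)),
        "size_min_bp": float(stats["size_bp"].min()) if len(stats) else 0.0,
        "size_max_bp": float(stats["size_bp"].max()) if len(stats) else 0.0,
        "size_median_bp": float(stats["size_bp"].median()) if len(stats) else 0.0,
    }
    deltas = stats["gc_delta"].dropna()
    out["mean_gc_delta"] = float(deltas.mean()) if len(deltas) else float("nan")
    return out


def occupancy(
    loci: Sequence[HotspotLocus], calls: Sequence[SystemCall]
) -> dict:
    """Occupancy fraction, system inventory, and non-defense gene fraction.

    A locus is occupied if its cargo shares at least one gene with a
    system call; the inventory counts each overlapping system call once
    per locus (a locus with two systems counts once for occupancy, twice
    in the inventory).
    """
    calls_by_loc: dict[tuple[str, str], list[SystemCall]] = {}
    for c in calls:
        calls_by_loc.setdefault((c.genome_id, c.replicon_id), []).append(c)
    occupied = 0
    inventory: dict[str, int] = {}
    n_cargo_genes = 0
    n_defense_genes = 0
    for locus in loci:
        cargo_ids = {g.gene_id for g in locus.cargo_genes}
        n_cargo_genes += len(cargo_ids)
        overlapping = [
            c for c in calls_by_loc.get((locus.genome_id, locus.replicon_id), [])
            if cargo_ids & set(c.member_gene_ids)
        ]
        if overlapping:
            occupied += 1
        defense_ids: set[str] = set()
        for c in overlapping:
            inventory[c.system_name] = inventory.get(c.system_name, 0) + 1
            defense_ids |= cargo_ids & set(c.member_gene_ids)
        n_defense_genes += len(defense_ids)
    return {
        "n_loci": len(loci),
        "occupancy": occupied / len(loci) if loci else 0.0,
        "inventory": dict(sorted(inventory.items())),
        "nondefense_gene_fraction": (
            (n_cargo_genes - n_defense_genes) / n_cargo_genes
            if n_cargo_genes else float("nan")
        ),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_marker_pairs(path: str) -> list[MarkerPair]:
    """Marker-pair definition file (YAML): name, left/right sequences,
    marker types and thresholds."""
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    pairs = []
    for item in docs if isinstance(docs, list) else [docs]:
        pairs.append(
            MarkerPair(
                name=item["name"],
                left_marker=item["left_marker"],
                right_marker=item["right_marker"],
                left_is_protein=bool(item.get("left_is_protein", True)),
                right_is_protein=bool(item.get("right_is_protein", True)),
                search_identity_min=float(
                    item.get("search_identity_min", DEFAULT_MARKER_IDENTITY)
                ),
                search_coverage_min=float(
                    item.get("search_coverage_min", DEFAULT_MARKER_COVERAGE)
                ),
            )
        )
    return pairs


def write_locus_table(stats: pd.DataFrame, path: str) -> None:
    stats.to_csv(path, sep="\t", index=False)


def write_inventory(report: dict, path: str) -> None:
    pd.DataFrame(
        [{"system_name": s, "count": c} for s, c in report["inventory"].items()],
        columns=["system_name", "count"],
    ).to_csv(path, sep="\t", index=False)


def export_cargo_gff(locus: HotspotLocus, path: str) -> None:
    """GFF3 slice of one locus' cargo genes (locus-relative untouched:
    coordinates stay replicon-absolute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in locus.cargo_genes:
            ftype = "CDS" if g.protein_seq else "ncRNA"
            fh.write(
                f"{g.replicon_id}\tcdhsfinder\t{ftype}\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id};product={g.product}\n"
            )
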