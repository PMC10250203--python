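"""Genome representation and I/O.

Genomes are represented as ordered, stranded gene tables over replicons
(contigs/chromosomes), the substrate of every downstream stage: homology
search, defense-system calling, neighborhood networks and hotspot mapping.

Two interchange dialects are supported:

* GFF3 + nucleotide FASTA (optionally a companion protein FASTA keyed by
  gene ID) — the canonical format;
* a "gembase"-style TSV that preserves gene order per replicon
  (columns: genome_id, replicon_id, ordinal, gene_id, start, end, strand,
  product, protein_seq).

Coordinates are 1-based inclusive (GFF3 convention). Ordinals are assigned
per replicon by start-coordinate order. RNA genes (tRNA/tmRNA) are kept as
gene records with an empty protein sequence so they can serve as hotspot
flank markers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

GEMBASE_COLUMNS = [
    "genome_id",
    "replicon_id",
    "ordinal",
    "gene_id",
    "start",
    "end",
    "strand",
    "product",
    "protein_seq",
]

#: GFF3 feature types loaded as gene records.
GENE_FEATURE_TYPES = ("CDS", "tRNA", "tmRNA", "rRNA", "ncRNA")


class GenomeParseError(ValueError):
    """Raised when an input annotation file violates the format contract."""


@dataclass
class GeneRecord:
    """One gene on one replicon, with its position in gene order.

    ``ordinal`` is the 0-based index in start-coordinate order on the
    gene's replicon; keeping it explicit is what lets hits found on a
    cluster representative be propagated back to member genes by index.
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    protein_seq: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise GenomeParseError(
                f"gene {self.gene_id}: invalid coordinates "
                f"start={self.start} end={self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise GenomeParseError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def nt_seq(self, replicon: "Replicon") -> str:
        """Extract this gene's nucleotide sequence (strand-aware)."""
        if replicon.nt_seq is None:
            raise ValueError(f"replicon {replicon.replicon_id} has no sequence")
        seq = replicon.nt_seq[self.start - 1 : self.end]
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class Replicon:
    replicon_id: str
    genome_id: str
    length_bp: int
    topology: str = "linear"  # or "circular"
    nt_seq: str | None = None
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def sort_and_index(self) -> None:
        """Sort genes by start coordinate and (re)assign ordinals."""
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(self.genes):
            g.ordinal = i

    def validate(self) -> None:
        for g in self.genes:
            if self.topology == "linear" and g.end > self.length_bp:
                raise GenomeParseError(
                    f"gene {g.gene_id} ends at {g.end} beyond replicon "
                    f"{self.replicon_id} length {self.length_bp}"
                )


@dataclass
class Genome:
    genome_id: str
    species: str = ""
    replicons: dict[str, Replicon] = field(default_factory=dict)

    def genes(self) -> Iterator[GeneRecord]:
        for rep in self.replicons.values():
            yield from rep.genes


@dataclass
class GenomeDB:
    """Collection of genomes with a species index."""

    genomes: dict[str, Genome] = field(default_factory=dict)

    @property
    def species_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for g in self.genomes.values():
            idx.setdefault(g.species, []).append(g.genome_id)
        return idx

    def add(self, genome: Genome) -> None:
        if genome.genome_id in self.genomes:
            raise ValueError(f"duplicate genome_id {genome.genome_id}")
        self.genomes[genome.genome_id] = genome

    def genes(self) -> Iterator[GeneRecord]:
        for g in self.genomes.values():
            yield from g.genes()

    def gene(self, gene_id: str) -> GeneRecord:
        return self._gene_index()[gene_id]

    def _gene_index(self) -> dict[str, GeneRecord]:
        # rebuilt lazily; cheap relative to analysis stages
        if getattr(self, "_idx_cache", None) is None or len(
            self._idx_cache  # type: ignore[has-type]
        ) != sum(1 for _ in self.genes()):
            idx: dict[str, GeneRecord] = {}
            for g in self.genes():
                if g.gene_id in idx:
                    raise GenomeParseError(f"duplicate gene_id {g.gene_id}")
                idx[g.gene_id] = g
            self._idx_cache = idx
        return self._idx_cache

    def replicon(self, genome_id: str, replicon_id: str) -> Replicon:
        return self.genomes[genome_id].replicons[replicon_id]

    def replicon_of(self, gene: GeneRecord) -> Replicon:
        return self.genomes[gene.genome_id].replicons[gene.replicon_id]

    def proteins(self) -> dict[str, str]:
        """gene_id -> protein sequence, for all protein-coding genes."""
        return {g.gene_id: g.protein_seq for g in self.genes() if g.protein_seq}


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def reverse_complement(nt_seq: str) -> str:
    return str(Seq(nt_seq).reverse_complement())


def gc_fraction(nt_seq: str) -> float:
    """(#G + #C) / (#unambiguous A/C/G/T bases), case-insensitive.

    Ambiguous bases (N etc.) are excluded from the denominator. An empty
    or all-ambiguous sequence has no defined GC content and raises
    ``ValueError`` rather than returning 0.
    """
    s = nt_seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("GC fraction undefined for empty/all-ambiguous sequence")
    return gc / (gc + at)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def gene_window(
    replicon: Replicon, span: tuple[int, int], w: int
) -> list[GeneRecord]:
    """Genes overlapping ``span`` widened by ``w`` bp on both sides.

    Genes fully inside the original span are excluded (they are the locus
    itself, not its neighborhood). On linear replicons the window is
    clipped at the contig edges; on circular replicons it wraps.
    """
    start, end = span
    if w < 0:
        raise ValueError("window size must be >= 0")
    if start < 1 or end > replicon.length_bp or end < start:
        raise ValueError(
            f"span {span} outside replicon {replicon.replicon_id} "
            f"(length {replicon.length_bp})"
        )
    lo, hi = start - w, end + w
    segments: list[tuple[int, int]] = []
    L = replicon.length_bp
    if replicon.topology == "circular" and hi - lo + 1 < L:
        # wrap both overhangs
        segments.append((max(lo, 1), min(hi, L)))
        if lo < 1:
            segments.append((lo + L, L))
        if hi > L:
            segments.append((1, hi - L))
    else:
        segments.append((max(lo, 1), min(hi, L)))
    out = []
    for g in replicon.genes:
        if start <= g.start and g.end <= end:
            continue  # fully inside the span
        if any(_overlaps(g.start, g.end, s, e) for s, e in segments):
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------

def _load_one_gff(
    genome_id: str,
    gff_path: str,
    fasta_path: str,
    protein_fasta_path: str | None,
    species: str,
) -> Genome:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    proteins: dict[str, str] = {}
    if protein_fasta_path and os.path.exists(protein_fasta_path):
        proteins = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(protein_fasta_path, "fasta")
        }
    try:
        db = gffutils.create_db(
            gff_path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises several internal types
        raise GenomeParseError(f"{gff_path}: {exc}") from exc

    genome = Genome(genome_id=genome_id, species=species)
    topologies: dict[str, str] = {}
    for feat in db.all_features(featuretype="region"):
        if feat.attributes.get("Is_circular", ["false"])[0] == "true":
            topologies[feat.seqid] = "circular"
    for seqid, seq in seqs.items():
        genome.replicons[seqid] = Replicon(
            replicon_id=seqid,
            genome_id=genome_id,
            length_bp=len(seq),
            topology=topologies.get(seqid, "linear"),
            nt_seq=seq,
        )
    for ftype in GENE_FEATURE_TYPES:
        for feat in db.all_features(featuretype=ftype):
            if feat.seqid not in genome.replicons:
                raise GenomeParseError(
                    f"{gff_path}: feature on unknown sequence {feat.seqid}"
                )
            gid = feat.attributes.get("ID", [None])[0]
            if gid is None:
                raise GenomeParseError(f"{gff_path}: {ftype} feature without ID")
            if feat.end < feat.start:
                raise GenomeParseError(
                    f"{gff_path}: feature {gid} has end < start"
                )
            prot = feat.attributes.get("translation", [""])[0] or proteins.get(
                gid, ""
            )
            product = feat.attributes.get("product", [""])[0]
            rep = genome.replicons[feat.seqid]
            rep.genes.append(
                GeneRecord(
                    gene_id=gid,
                    genome_id=genome_id,
                    replicon_id=feat.seqid,
                    ordinal=-1,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    protein_seq=prot,
                    product=product,
                )
            )
    for rep in genome.replicons.values():
        rep.sort_and_index()
        rep.validate()
    return genome


def load_genomes(
    entries: Sequence[tuple[str, ...] | str],
    species: str | dict[str, str] = "",
) -> GenomeDB:
    """Build a :class:`GenomeDB` from annotation files.

    ``entries`` is a sequence of either

    * ``(gff3_path, fasta_path[, protein_fasta_path])`` tuples — one genome
      per tuple, genome id taken from the GFF filename stem; or
    * gembase-style TSV paths (may hold many genomes each).

    ``species`` is either a single label applied to all genomes or a
    ``genome_id -> species`` mapping.
    """
    db = GenomeDB()
    for entry in entries:
        if isinstance(entry, str):
            for genome in _load_gembase(entry):
                genome.species = _species_for(species, genome.genome_id)
                db.add(genome)
        else:
            gff_path, fasta_path = entry[0], entry[1]
            faa = entry[2] if len(entry) > 2 else None
            genome_id = os.path.splitext(os.path.basename(gff_path))[0]
            genome = _load_one_gff(
                genome_id, gff_path, fasta_path, faa,
                _species_for(species, genome_id),
            )
            db.add(genome)
    # detect cross-file duplicate gene ids eagerly
    db._idx_cache = None
    db._gene_index()
    return db


def _species_for(species: str | dict[str, str], genome_id: str) -> str:
    if isinstance(species, dict):
        return species.get(genome_id, "")
    return species


# ---------------------------------------------------------------------------
# gembase-style TSV
# ---------------------------------------------------------------------------

def _load_gembase(path: str) -> list[Genome]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise GenomeParseError(f"{path}: {exc}") from exc
    missing = set(GEMBASE_COLUMNS) - set(df.columns)
    if missing:
        raise GenomeParseError(f"{path}: missing columns {sorted(missing)}")
    genomes: dict[str, Genome] = {}
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise GenomeParseError(
                f"{path}: non-integer coordinates for gene {row.gene_id}"
            ) from exc
        genome = genomes.setdefault(row.genome_id, Genome(genome_id=row.genome_id))
        rep = genome.replicons.setdefault(
            row.replicon_id,
            Replicon(
                replicon_id=row.replicon_id,
                genome_id=row.genome_id,
                length_bp=0,
            ),
        )
        rep.genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                replicon_id=row.replicon_id,
                ordinal=int(row.ordinal),
                start=start,
                end=end,
                strand=row.strand,
                protein_seq=row.protein_seq,
                product=row.product,
            )
        )
    for genome in genomes.values():
        for rep in genome.replicons.values():
            rep.sort_and_index()
            rep.length_bp = max(g.end for g in rep.genes)
    return list(genomes.values())


def write_gembase(db: GenomeDB, path: str) -> None:
    rows = []
    for g in db.genes():
        rows.append(
            {
                "genome_id": g.genome_id,
                "replicon_id": g.replicon_id,
                "ordinal": g.ordinal,
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
                "protein_seq": g.protein_seq,
            }
        )
    pd.DataFrame(rows, columns=GEMBASE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_protein_fasta(db: GenomeDB, path: str) -> None:
    """Protein FASTA of every coding gene, for external search backends."""
    with open(path, "w") as fh:
        for gid, seq in db.proteins().items():
            fh.write(f">{gid}\n{seq}\n")


def write_gff3(genome: Genome, gff_path: str, fasta_path: str) -> None:
    """Emit a genome as GFF3 (with translation attributes) plus FASTA."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons.values():
            fh.write(
                f"##sequence-region {rep.replicon_id} 1 {rep.length_bp}\n"
            )
            circ = "true" if rep.topology == "circular" else "false"
            fh.write(
                f"{rep.replicon_id}\tcdhsfinder\tregion\t1\t{rep.length_bp}\t.\t+\t.\t"
                f"ID=region-{rep.replicon_id};Is_circular={circ}\n"
            )
            for g in rep.genes:
                ftype = "CDS" if g.protein_seq else "ncRNA"
                attrs = f"ID={g.gene_id};product={g.product}"
                if g.protein_seq:
                    attrs += f";translation={g.protein_seq}"
                fh.write(
                    f"{rep.replicon_id}\tcdhsfinder\t{ftype}\t{g.start}\t{g.end}"
                    f"\t.\t{g.strand}\t0\t{attrs}\n"
                )
    with open(fasta_path, "w") as fh:
        for rep in genome.replicons.values():
            if rep.nt_seq is None:
                raise ValueError(f"replicon {rep.replicon_id} has no sequence")
            fh.write(f">{rep.replicon_id}\n")
            for i in range(0, len(rep.nt_seq), 80):
                fh.write(rep.nt_seq[i : i + 80] + "\n")
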