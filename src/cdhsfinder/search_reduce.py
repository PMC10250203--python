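"""Reduced-database homology search with hit propagation.

Searching every protein of a large genome collection against every gene
model is expensive. The scheme implemented here first clusters the protein
database at high identity (default 0.9), searches only one representative
per cluster through a pluggable backend, and then propagates each
representative's hits to every member of its cluster. For any backend whose
hit decision is the same for all members of a cluster, this is exactly
equivalent to searching the full database — at a fraction of the cost.

Hits are filtered at a strict e-value cutoff (default 1e-10) before system
calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import edlib
import pandas as pd

from .genome_io import GenomeDB

DEFAULT_IDENTITY_THRESHOLD = 0.9
DEFAULT_EVALUE_MAX = 1e-10

HIT_COLUMNS = ["gene_id", "model_id", "evalue", "score", "source", "propagated"]


@dataclass(frozen=True)
class Hit:
    """One homology hit of a gene against a gene-family model."""

    gene_id: str
    model_id: str
    evalue: float
    score: float = 0.0
    source: str = "mock"  # {hmm, blast, mock}
    propagated: bool = False

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class ClusterIndex:
    """Partition of a protein set into identity clusters.

    ``clusters`` maps each representative gene id to the full member list
    (representative included); ``member_to_rep`` is the inverse.
    """

    clusters: dict[str, list[str]] = field(default_factory=dict)
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    @property
    def member_to_rep(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters.items() for m in members}

    @property
    def representatives(self) -> list[str]:
        return list(self.clusters)

    def family_of(self, gene_id: str) -> str:
        """Cluster representative = protein-family id of a gene."""
        return self.member_to_rep[gene_id]

    def validate(self) -> None:
        seen: set[str] = set()
        for rep, members in self.clusters.items():
            if rep not in members:
                raise ValueError(f"representative {rep} not in its own cluster")
            for m in members:
                if m in seen:
                    raise ValueError(f"gene {m} in more than one cluster")
                seen.add(m)


class SearchBackend(Protocol):
    """Homology search contract: deterministic hits for fixed inputs."""

    def search(
        self, proteins: Mapping[str, str], model_ids: Sequence[str]
    ) -> list[Hit]: ...


class MotifBackend:
    """Deterministic mock backend: a gene hits a model iff the model's
    motif occurs as an exact substring of the protein.

    Used for offline testing; cluster-consistent whenever the motif sits in
    a conserved region shared by all cluster members.
    """

    def __init__(self, motifs: Mapping[str, str], evalue: float = 1e-30):
        self.motifs = dict(motifs)
        self.evalue = evalue

    def search(
        self, proteins: Mapping[str, str], model_ids: Sequence[str]
    ) -> list[Hit]:
        hits = []
        for model_id in model_ids:
            motif = self.motifs[model_id]
            for gid, seq in proteins.items():
                if motif in seq:
                    hits.append(
                        Hit(gid, model_id, self.evalue, score=float(len(motif)),
                            source="mock")
                    )
        return hits


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def global_identity(a: str, b: str) -> float:
    """Global percent identity between two sequences.

    Computed from the Needleman–Wunsch edit distance as
    ``1 - dist / max(len(a), len(b))`` — a conservative lower bound on
    alignment-column identity, monotone in divergence.
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def cluster_proteins(
    proteins: Mapping[str, str],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> ClusterIndex:
    """Greedy longest-first clustering at a global-identity threshold.

    Sequences are visited longest first; each joins the first existing
    cluster whose representative it matches at or above the threshold,
    otherwise it seeds a new cluster. This is a deliberate simplification
    of linear-time clustering tools; their TSV output can be ingested
    instead via :func:`read_mmseqs_clusters`.
    """
    if not proteins:
        raise ValueError("empty protein set")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    order = sorted(proteins, key=lambda g: (-len(proteins[g]), g))
    index = ClusterIndex(identity_threshold=identity_threshold)
    by_seq: dict[str, str] = {}  # exact-duplicate shortcut
    reps: list[tuple[str, str]] = []
    for gid in order:
        seq = proteins[gid]
        rep = by_seq.get(seq)
        if rep is None:
            for rep_id, rep_seq in reps:
                # identity can't reach t if lengths differ too much
                if len(seq) < identity_threshold * len(rep_seq):
                    continue
                if global_identity(seq, rep_seq) >= identity_threshold:
                    rep = rep_id
                    break
        if rep is None:
            index.clusters[gid] = [gid]
            reps.append((gid, seq))
            by_seq[seq] = gid
        else:
            index.clusters[rep].append(gid)
    return index


def read_mmseqs_clusters(
    path: str, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> ClusterIndex:
    """Ingest an mmseqs easy-linclust cluster TSV (rep <tab> member)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["rep", "member"],
                     dtype=str)
    index = ClusterIndex(identity_threshold=identity_threshold)
    for rep, member in zip(df["rep"], df["member"]):
        index.clusters.setdefault(rep, [])
        if member not in index.clusters[rep]:
            index.clusters[rep].append(member)
    for rep in index.clusters:
        if rep not in index.clusters[rep]:
            index.clusters[rep].insert(0, rep)
    index.validate()
    return index


# ---------------------------------------------------------------------------
# search + propagation + filtering
# ---------------------------------------------------------------------------

def propagate_hits(hits: Iterable[Hit], index: ClusterIndex) -> list[Hit]:
    """Expand representative hits to every member of their cluster.

    A hit on a cluster representative is considered a hit for all member
    genes; members inherit the representative's model, e-value and score
    and are flagged ``propagated``.
    """
    out = []
    for hit in hits:
        members = index.clusters.get(hit.gene_id)
        if members is None:
            raise KeyError(
                f"hit on {hit.gene_id}, which is not a cluster representative"
            )
        for m in members:
            out.append(replace(hit, gene_id=m, propagated=(m != hit.gene_id)))
    return out


def search_reduced(
    db: GenomeDB,
    index: ClusterIndex,
    backend: SearchBackend,
    model_ids: Sequence[str],
) -> list[Hit]:
    """Search only cluster representatives, then propagate hits to members."""
    proteins = db.proteins()
    missing = set(proteins) - set(index.member_to_rep)
    if missing:
        raise ValueError(
            f"cluster index does not cover {len(missing)} proteins "
            f"(e.g. {sorted(missing)[:3]})"
        )
    if not model_ids:
        return []
    reduced = {rep: proteins[rep] for rep in index.representatives
               if rep in proteins}
    try:
        rep_hits = backend.search(reduced, model_ids)
    except Exception as exc:
        raise RuntimeError(f"search backend failed: {exc}") from exc
    return propagate_hits(rep_hits, index)


def filter_hits(
    hits: Iterable[Hit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[Hit]:
    """Keep hits with e-value strictly below ``evalue_max``.

    The inequality is strict: a hit at exactly the cutoff is dropped.
    Idempotent and order-preserving.
    """
    return [h for h in hits if h.evalue < evalue_max]


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def write_hits(hits: Iterable[Hit], path: str) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "model_id": h.model_id,
                "evalue": h.evalue,
                "score": h.score,
                "source": h.source,
                "propagated": h.propagated,
            }
            for h in hits
        ],
        columns=HIT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_hits(path: str) -> list[Hit]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "model_id": str})
    return [
        Hit(
            gene_id=r.gene_id,
            model_id=r.model_id,
            evalue=float(r.evalue),
            score=float(r.score),
            source=str(r.source),
            propagated=bool(r.propagated),
        )
        for r in df.itertuples(index=False)
    ]


def read_hmmer_tblout(path: str) -> list[Hit]:
    """Parse hmmsearch ``--tblout`` output (whitespace table, # comments)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed tblout line: {line!r}")
            hits.append(
                Hit(
                    gene_id=parts[0],
                    model_id=parts[2],
                    evalue=float(parts[4]),
                    score=float(parts[5]),
                    source="hmm",
                )
            )
    return hits


def read_blast_outfmt6(path: str) -> list[Hit]:
    """Parse BLAST tabular (outfmt 6) output: query = gene, subject = model."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"qseqid": str, "sseqid": str})
    return [
        Hit(gene_id=r.qseqid, model_id=r.sseqid, evalue=float(r.evalue),
            score=float(r.bitscore), source="blast")
        for r in df.itertuples(index=False)
    ]
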