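"""Locus-level horizontal-exchange signals.

Two distances are contrasted per isolate pair: the patristic distance on a
whole-genome phylogeny (vertical signal) and the Mash distance between the
isolates' hotspot locus sequences (locus signal). Distantly related
isolates carrying near-identical loci indicate long-range synteny —
horizontal transfer of the whole locus — while near-clonal isolates with
strongly divergent loci indicate rapid local diversification.

The Mash distance is estimated from bottom-s MinHash sketches of canonical
k-mers: with Jaccard estimate j, d = -(1/k) * ln(2j / (1 + j)), capped at
1.0 when the sketches are disjoint. Hashing is a seeded 64-bit splitmix64
finalizer over 2-bit-encoded k-mers, vectorised and reproducible for a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_HASH_SEED = 42

# classification thresholds (tree distance / locus Mash)
TREE_DIST_HIGH = 0.35
TREE_DIST_LOW = 0.05
LOCUS_SIMILARITY_MIN = 0.9
LOCUS_DIST_MIN = 0.38

LONG_RANGE_SYNTENY = "long_range_synteny"
RAPID_DIVERSIFICATION = "rapid_diversification"
NEITHER = "neither"

_U64 = np.uint64
_CODE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lower case


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer, elementwise on uint64 (wrapping arithmetic)."""
    z = x + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@dataclass
class KmerSketch:
    """Bottom-s MinHash sketch over canonical k-mers."""

    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted ascending, uint64, len <= sketch_size
    source_id: str = ""
    hash_seed: int = DEFAULT_HASH_SEED


def canonical_kmer_hashes(
    nt_seq: str, k: int = DEFAULT_K, hash_seed: int = DEFAULT_HASH_SEED
) -> np.ndarray:
    """Distinct seeded hashes of all canonical k-mers of a sequence.

    The canonical form of a k-mer is the lexicographic minimum of the
    k-mer and its reverse complement (on the 2-bit encoding), so a
    sequence and its reverse complement hash identically. Windows
    containing ambiguous bases are skipped.
    """
    if len(nt_seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = _CODE[np.frombuffer(nt_seq.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    win = win[valid].astype(_U64)
    if win.shape[0] == 0:
        return np.empty(0, dtype=_U64)
    pow_f = _U64(4) ** np.arange(k - 1, -1, -1, dtype=_U64)
    pow_r = _U64(4) ** np.arange(k, dtype=_U64)
    fwd = (win * pow_f).sum(axis=1, dtype=_U64)
    rev = ((_U64(3) - win) * pow_r).sum(axis=1, dtype=_U64)
    canon = np.minimum(fwd, rev)
    seed_mix = _splitmix64(np.array([hash_seed], dtype=_U64))[0]
    return np.unique(_splitmix64(canon ^ seed_mix))


def sketch(
    nt_seq: str,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
    source_id: str = "",
) -> KmerSketch:
    """Bottom-s sketch: the ``sketch_size`` smallest canonical-k-mer
    hashes (all of them when the sequence has fewer distinct k-mers)."""
    hashes = canonical_kmer_hashes(nt_seq, k=k, hash_seed=hash_seed)
    return KmerSketch(
        k=k,
        sketch_size=sketch_size,
        hashes=hashes[:sketch_size].copy(),
        source_id=source_id,
        hash_seed=hash_seed,
    )


def mash_distance(a: KmerSketch, b: KmerSketch) -> float:
    """Mash distance between two compatible sketches.

    Jaccard is estimated on the bottom-s of the sketch union; then
    d = -(1/k) ln(2j/(1+j)), with d = 0 at j = 1 and d capped at 1.0 at
    j = 0 (disjoint sketches carry no resolution beyond "far").
    """
    if a.k != b.k or a.sketch_size != b.sketch_size or a.hash_seed != b.hash_seed:
        raise ValueError("sketches built with different k/size/seed")
    union = np.union1d(a.hashes, b.hashes)
    s = min(a.sketch_size, union.size)
    if s == 0:
        raise ValueError("empty sketches")
    bottom = union[:s]
    shared = np.intersect1d(bottom, a.hashes, assume_unique=True)
    shared = np.intersect1d(shared, b.hashes, assume_unique=True)
    j = shared.size / s
    if j == 0:
        return 1.0
    if j == 1:
        return 0.0
    return min(1.0, -np.log(2 * j / (1 + j)) / a.k)


def sketch_to_json(s: KmerSketch, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "k": s.k,
                "sketch_size": s.sketch_size,
                "hash_seed": s.hash_seed,
                "source_id": s.source_id,
                "hashes": [int(h) for h in s.hashes],
            },
            fh,
        )


def sketch_from_json(path: str) -> KmerSketch:
    with open(path) as fh:
        d = json.load(fh)
    return KmerSketch(
        k=d["k"],
        sketch_size=d["sketch_size"],
        hashes=np.array(sorted(d["hashes"]), dtype=_U64),
        source_id=d.get("source_id", ""),
        hash_seed=d["hash_seed"],
    )


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

@dataclass
class PatristicMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def patristic_distances(newick: str) -> PatristicMatrix:
    """Pairwise sum of branch lengths between every leaf pair.

    ``newick`` is a newick string or a path to one. Internal edges with
    missing branch lengths are an error (the metric is undefined).
    """
    data = newick
    if "(" not in newick:  # path, not a tree string
        with open(newick) as fh:
            data = fh.read()
    tree = dendropy.Tree.get(data=data, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            label = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise ValueError(f"missing branch length above node {label}")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for jx in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[i], taxa[jx])
            d[i, jx] = d[jx, i] = dist
    return PatristicMatrix(taxa=labels, d=d)


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifyThresholds:
    tree_dist_high: float = TREE_DIST_HIGH
    tree_dist_low: float = TREE_DIST_LOW
    locus_similarity_min: float = LOCUS_SIMILARITY_MIN
    locus_dist_min: float = LOCUS_DIST_MIN


def label_pair(
    tree_dist: float,
    locus_dist: float,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> str:
    """Apply the threshold rule table to one (tree, locus) distance pair.

    All inequalities are strict: a pair sitting exactly on a threshold is
    ``neither``. The two tree-distance regions (> high, < low) are
    disjoint, so the labels are mutually exclusive.
    """
    if (
        tree_dist > thresholds.tree_dist_high
        and (1.0 - locus_dist) > thresholds.locus_similarity_min
    ):
        return LONG_RANGE_SYNTENY
    if (
        tree_dist < thresholds.tree_dist_low
        and locus_dist > thresholds.locus_dist_min
    ):
        return RAPID_DIVERSIFICATION
    return NEITHER


@dataclass
class PairClass:
    isolate_a: str
    isolate_b: str
    tree_dist: float
    locus_dist: float
    label: str


def classify_pairs(
    tree: PatristicMatrix,
    loci: Mapping[str, KmerSketch] | Mapping[str, str],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> list[PairClass]:
    """Label every isolate pair by tree vs locus divergence.

    * long-range synteny: tree distance > 0.35 and locus Mash similarity
      (1 - d) > 0.9 — distant relatives, near-identical loci;
    * rapid diversification: tree distance < 0.05 and locus Mash
      distance > 0.38 — close relatives, divergent loci;
    * neither otherwise. All inequalities strict; the two tree-distance
      regions are disjoint, so no pair can receive both labels.

    ``loci`` maps each taxon to a sketch or a raw nucleotide sequence
    (sketched on the fly).
    """
    sketches: dict[str, KmerSketch] = {}
    for taxon, value in loci.items():
        if isinstance(value, KmerSketch):
            sketches[taxon] = value
        else:
            sketches[taxon] = sketch(
                value, k=k, sketch_size=sketch_size, hash_seed=hash_seed,
                source_id=taxon,
            )
    missing = set(tree.taxa) - set(sketches)
    extra = set(sketches) - set(tree.taxa)
    if missing or extra:
        raise ValueError(
            f"taxon mismatch between tree and loci "
            f"(missing {sorted(missing)}, extra {sorted(extra)})"
        )
    out = []
    for i, a in enumerate(tree.taxa):
        for b in tree.taxa[i + 1 :]:
            td = tree.distance(a, b)
            ld = mash_distance(sketches[a], sketches[b])
            out.append(PairClass(a, b, td, ld, label_pair(td, ld, thresholds)))
    return out


def write_pair_classes(pairs: Sequence[PairClass], path: str) -> None:
    pd.DataFrame(
        [
            {
                "isolate_a": p.isolate_a,
                "isolate_b": p.isolate_b,
                "tree_dist": p.tree_dist,
                "locus_dist": p.locus_dist,
                "label": p.label,
            }
            for p in pairs
        ],
        columns=["isolate_a", "isolate_b", "tree_dist", "locus_dist", "label"],
    ).to_csv(path, sep="\t", index=False)
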