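"""Marker-flanked hotspot locus extraction and statistics."""

import numpy as np
import pytest

from cdhsfinder.genome_io import (
    GeneRecord,
    Genome,
    GenomeDB,
    Replicon,
    reverse_complement,
)
from cdhsfinder.hotspot_mapper import (
    HotspotLocus,
    MarkerPair,
    extract_loci,
    find_marker_orthologs,
    locus_stats,
    locus_summary,
    map_hotspot,
    occupancy,
)
from conftest import mutate_nt, random_nt


def test_exact_markers_found_in_fixture(sim_db, sim_truth):
    for pair in sim_truth.marker_pairs:
        hits = find_marker_orthologs(sim_db, pair)
        for gid, (lefts, rights) in hits.items():
            assert lefts and rights, f"{pair.name} markers missed in {gid}"


def test_absent_marker_is_empty_not_error(sim_db, sim_truth):
    pair = MarkerPair(name="ghost", left_marker="MWWWWCCCCHHHHKKKK" * 5,
                      right_marker="MYYYYFFFFDDDDEEEE" * 5)
    hits = find_marker_orthologs(sim_db, pair)
    assert all(not l and not r for l, r in hits.values())


def test_diverged_marker_found_at_threshold(rng):
    """A marker with ~8% substitutions still matches at 0.8 identity."""
    base_nt = random_nt(rng, 900)
    prot = _fake_protein(base_nt)
    db = _single_gene_db(base_nt)
    diverged = "".join(
        c if rng.random() > 0.08 else "A" for c in prot
    )
    pair = MarkerPair(name="h", left_marker=diverged, right_marker=prot,
                      search_identity_min=0.8)
    lefts, rights = find_marker_orthologs(db, pair)["G"]
    assert lefts and rights


def _fake_protein(nt):
    from Bio.Seq import Seq

    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate(table=11)).replace(
        "*", "X")


def _single_gene_db(nt):
    rep = Replicon(replicon_id="c", genome_id="G", length_bp=2000,
                   nt_seq=random_nt(np.random.default_rng(5), 2000))
    rep.genes.append(
        GeneRecord(gene_id="G.0", genome_id="G", replicon_id="c", ordinal=0,
                   start=100, end=99 + len(nt), strand="+",
                   protein_seq=_fake_protein(nt)))
    rep.sort_and_index()
    db = GenomeDB()
    db.add(Genome(genome_id="G", replicons={"c": rep}))
    return db


def _db_with_genes(spans, replicons=("c",), length=60000):
    """spans: list of (replicon, gene_id, start, end, protein)."""
    db = GenomeDB()
    genome = Genome(genome_id="G")
    for rid in replicons:
        genome.replicons[rid] = Replicon(
            replicon_id=rid, genome_id="G", length_bp=length,
            nt_seq=random_nt(np.random.default_rng(1), length))
    for rid, gid, s, e, prot in spans:
        genome.replicons[rid].genes.append(
            GeneRecord(gene_id=gid, genome_id="G", replicon_id=rid,
                       ordinal=0, start=s, end=e, strand="+",
                       protein_seq=prot))
    for rep in genome.replicons.values():
        rep.sort_and_index()
    db.add(genome)
    return db


def _locus_from(db, left_id, right_id, hits_map=None):
    left = db.gene(left_id)
    right = db.gene(right_id)
    return extract_loci(db, hits_map or {"G": ([left], [right])}, "h")


def test_cargo_is_strictly_between_markers():
    spans = [("c", "L", 1000, 1900, "ML")]
    spans += [("c", f"x{i}", 2000 + 700 * i, 2500 + 700 * i, "MX")
              for i in range(7)]
    spans += [("c", "R", 7000, 7900, "MR")]
    db = _db_with_genes(spans)
    loci = _locus_from(db, "L", "R")
    assert len(loci) == 1
    assert [g.gene_id for g in loci[0].cargo_genes] == [f"x{i}" for i in range(7)]
    assert loci[0].size_bp == 7000 - 1900 - 1


def test_markers_on_different_contigs_yield_no_locus():
    db = _db_with_genes(
        [("c1", "L", 1000, 1900, "ML"), ("c2", "R", 1000, 1900, "MR")],
        replicons=("c1", "c2"))
    loci = extract_loci(db, {"G": ([db.gene("L")], [db.gene("R")])}, "h")
    assert loci == []


def test_adjacent_markers_give_empty_cargo_locus():
    db = _db_with_genes(
        [("c", "L", 1000, 1900, "ML"), ("c", "R", 1950, 2800, "MR")])
    loci = _locus_from(db, "L", "R")
    assert len(loci) == 1
    assert loci[0].cargo_genes == []
    assert loci[0].size_bp == 49


def test_paralogous_markers_resolve_to_closest_pair():
    db = _db_with_genes([
        ("c", "L1", 1000, 1900, "ML"),
        ("c", "L2", 30000, 30900, "ML"),
        ("c", "mid", 32000, 32500, "MX"),
        ("c", "R1", 35000, 35900, "MR"),
    ])
    loci = extract_loci(
        db, {"G": ([db.gene("L1"), db.gene("L2")], [db.gene("R1")])}, "h")
    assert len(loci) == 1
    assert loci[0].left_gene.gene_id == "L2"
    assert [g.gene_id for g in loci[0].cargo_genes] == ["mid"]


def test_orientation_normalized_when_right_marker_precedes_left():
    db = _db_with_genes(
        [("c", "R", 1000, 1900, "MR"), ("c", "L", 9000, 9900, "ML"),
         ("c", "mid", 3000, 3500, "MX")])
    loci = _locus_from(db, "L", "R")
    assert len(loci) == 1
    assert loci[0].left_gene.start < loci[0].right_gene.start
    assert [g.gene_id for g in loci[0].cargo_genes] == ["mid"]


def test_fixture_boundaries_sizes_occupancy_match_manifest(
    sim_db, sim_truth, sim_calls,
):
    for pair in sim_truth.marker_pairs:
        loci = map_hotspot(sim_db, pair)
        planted = [l for l in sim_truth.loci if l["hotspot"] == pair.name]
        got = sorted(
            (l.genome_id, l.left_gene.gene_id, l.right_gene.gene_id,
             l.size_bp) for l in loci)
        want = sorted(
            (l["genome_id"], l["left_gene"], l["right_gene"], l["size_bp"])
            for l in planted)
        assert got == want
        report = occupancy(loci, sim_calls)
        assert report["occupancy"] == pytest.approx(
            sim_truth.occupancy_fraction(pair.name))
        assert 0 <= report["occupancy"] <= 1
        assert sum(report["inventory"].values()) >= (
            report["occupancy"] * len(loci) - 1e-9
        )


def test_gc_delta_recovers_configured_offset(sim_db, sim_truth):
    pair = sim_truth.marker_pairs[0]
    loci = map_hotspot(sim_db, pair)
    stats = locus_stats(loci, sim_db)
    offset = sim_truth.config["cargo_gc_offset"]
    assert len(stats) >= 20
    assert stats["gc_delta"].mean() == pytest.approx(offset, abs=0.01)
    summary = locus_summary(stats)
    assert summary["mean_gc_delta"] == pytest.approx(
        stats["gc_delta"].mean())


def test_locus_summary_median():
    import pandas as pd

    stats = pd.DataFrame(
        {"size_bp": [1000, 26000, 224000], "gc_delta": [None, None, None]}
    )
    s = locus_summary(stats)
    assert s["size_median_bp"] == 26000
    assert s["size_min_bp"] == 1000 and s["size_max_bp"] == 224000


def test_occupancy_counts_locus_once_inventory_counts_each_system():
    db = _db_with_genes([
        ("c", "L", 1000, 1900, "ML"),
        ("c", "x1", 2000, 2600, "MX"), ("c", "x2", 2700, 3300, "MX"),
        ("c", "R", 4000, 4900, "MR"),
    ])
    loci = _locus_from(db, "L", "R")
    calls = [
        SystemCallFactory("SysA", ["x1"]),
        SystemCallFactory("SysB", ["x2"]),
    ]
    report = occupancy(loci, calls)
    assert report["occupancy"] == 1.0
    assert report["inventory"] == {"SysA": 1, "SysB": 1}
    assert report["nondefense_gene_fraction"] == 0.0


def SystemCallFactory(name, members):
    from cdhsfinder.system_caller import SystemCall

    return SystemCall(system_name=name, genome_id="G", replicon_id="c",
                      member_gene_ids=members, span=(2000, 3300))


def test_orientation_invariance_under_reverse_complement(sim_db, sim_truth):
    """Reverse-complementing a contig (with coordinates remapped) yields
    the identical locus size and cargo set."""
    pair = sim_truth.marker_pairs[0]
    gid = sorted(sim_db.genomes)[0]
    genome = sim_db.genomes[gid]
    rep = next(iter(genome.replicons.values()))
    L = rep.length_bp
    flipped = Replicon(replicon_id=rep.replicon_id, genome_id=gid,
                       length_bp=L, nt_seq=reverse_complement(rep.nt_seq))
    for g in rep.genes:
        flipped.genes.append(
            GeneRecord(gene_id=g.gene_id, genome_id=gid,
                       replicon_id=g.replicon_id, ordinal=0,
                       start=L - g.end + 1, end=L - g.start + 1,
                       strand="-" if g.strand == "+" else "+",
                       protein_seq=g.protein_seq, product=g.product))
    flipped.sort_and_index()
    db2 = GenomeDB()
    db2.add(Genome(genome_id=gid, replicons={rep.replicon_id: flipped}))
    fwd = [l for l in map_hotspot(sim_db, pair) if l.genome_id == gid]
    rev = map_hotspot(db2, pair)
    assert len(fwd) == len(rev) == 1
    assert fwd[0].size_bp == rev[0].size_bp
    assert {g.gene_id for g in fwd[0].cargo_genes} == {
        g.gene_id for g in rev[0].cargo_genes}
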