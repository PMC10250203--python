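"""Quorum-and-adjacency system calling."""

import itertools

import numpy as np
import pytest

from cdhsfinder.genome_io import GeneRecord, Genome, GenomeDB, Replicon
from cdhsfinder.search_reduce import Hit
from cdhsfinder.system_caller import (
    SystemDefinition,
    SystemGene,
    call_systems,
    validate_definition,
)


def _db_from_layout(layouts):
    """layouts: {replicon_id: [gene labels]} -> one-genome GenomeDB with
    unit-spaced genes (1 kb apart)."""
    genome = Genome(genome_id="G")
    for rid, labels in layouts.items():
        rep = Replicon(replicon_id=rid, genome_id="G",
                       length_bp=1000 * len(labels) + 1000)
        for i, _ in enumerate(labels):
            rep.genes.append(
                GeneRecord(
                    gene_id=f"{rid}.{i}", genome_id="G", replicon_id=rid,
                    ordinal=i, start=1000 * i + 1, end=1000 * i + 900,
                    strand="+", protein_seq="M",
                )
            )
        rep.sort_and_index()
        genome.replicons[rid] = rep
    db = GenomeDB()
    db.add(genome)
    return db


def _hits_for(layouts):
    hits = []
    for rid, labels in layouts.items():
        for i, label in enumerate(labels):
            if label != ".":
                hits.append(Hit(f"{rid}.{i}", label, 1e-30))
    return hits


def _def(name="S", essential=(), accessory=(), min_accessory=0,
         max_intervening=0):
    genes = [SystemGene(role=m, model_ids=[m], status="essential")
             for m in essential]
    genes += [SystemGene(role=m, model_ids=[m], status="accessory")
              for m in accessory]
    return SystemDefinition(system_name=name, genes=genes,
                            min_accessory=min_accessory,
                            max_intervening=max_intervening)


def test_adjacent_essential_pair_is_one_call():
    layouts = {"c": [".", "A", "B", "."]}
    calls = call_systems(_hits_for(layouts), _db_from_layout(layouts),
                         [_def(essential=("A", "B"))])
    assert len(calls) == 1
    assert calls[0].member_gene_ids == ["c.1", "c.2"]
    assert calls[0].complete
    assert calls[0].span == (1001, 2900)


def test_missing_essential_gene_blocks_call():
    layouts = {"c": [".", "A", ".", "."]}
    calls = call_systems(_hits_for(layouts), _db_from_layout(layouts),
                         [_def(essential=("A", "B"))])
    assert calls == []


def test_accessory_quorum_with_intervening_genes():
    """Essential A plus 2 of 3 accessory roles across small gaps."""
    layouts = {"c": ["A", ".", "x", ".", "z"]}
    definition = _def(essential=("A",), accessory=("x", "y", "z"),
                      min_accessory=2, max_intervening=3)
    calls = call_systems(_hits_for(layouts), _db_from_layout(layouts),
                         [definition])
    assert len(calls) == 1
    assert set(calls[0].role_assignments) == {"A", "x", "z"}
    # brute-force oracle: some contiguous window must satisfy the rule
    assert _window_oracle(layouts["c"], definition)


def test_members_on_different_replicons_never_combine():
    layouts = {"c1": ["A"], "c2": ["B"]}
    calls = call_systems(_hits_for(layouts), _db_from_layout(layouts),
                         [_def(essential=("A", "B"), max_intervening=5)])
    assert calls == []


def test_gap_larger_than_max_intervening_splits_candidates():
    layouts = {"c": ["A", ".", ".", ".", "B"]}
    defn = _def(essential=("A", "B"), max_intervening=2)
    assert call_systems(_hits_for(layouts), _db_from_layout(layouts),
                        [defn]) == []
    defn3 = _def(essential=("A", "B"), max_intervening=3)
    assert len(call_systems(_hits_for(layouts), _db_from_layout(layouts),
                            [defn3])) == 1


def test_hit_on_unknown_gene_is_error():
    layouts = {"c": ["A"]}
    with pytest.raises(KeyError):
        call_systems([Hit("ghost", "A", 1e-30)], _db_from_layout(layouts),
                     [_def(essential=("A",))])


def test_output_invariant_to_hit_order(rng):
    layouts = {"c": ["A", ".", "B", "x", ".", "A", "B"]}
    db = _db_from_layout(layouts)
    defs = [_def(essential=("A", "B"), accessory=("x",), max_intervening=2)]
    hits = _hits_for(layouts)
    ref = call_systems(hits, db, defs)
    for _ in range(5):
        shuffled = [hits[i] for i in rng.permutation(len(hits))]
        alt = call_systems(shuffled, db, defs)
        assert [(c.member_gene_ids, c.span) for c in alt] == [
            (c.member_gene_ids, c.span) for c in ref
        ]


def test_validate_definition_reports_violations():
    bad = _def(essential=("A",), accessory=("x",), min_accessory=2)
    assert any("min_accessory" in v for v in validate_definition(bad))
    empty = SystemDefinition(system_name="E", genes=[])
    assert validate_definition(empty)
    dup = SystemDefinition(
        system_name="D",
        genes=[SystemGene("r", ["m"], "essential"),
               SystemGene("r", ["m2"], "accessory")],
    )
    assert any("duplicate" in v for v in validate_definition(dup))
    ok = _def(essential=("A", "B"), accessory=("x",), min_accessory=1)
    assert validate_definition(ok) == []


def test_any_model_of_a_role_fills_it():
    defn = SystemDefinition(
        system_name="S",
        genes=[SystemGene("r1", ["mA", "mB"], "essential"),
               SystemGene("r2", ["mC"], "essential")],
    )
    layouts = {"c": ["mB", "mC"]}
    calls = call_systems(_hits_for(layouts), _db_from_layout(layouts), [defn])
    assert len(calls) == 1 and calls[0].complete


def test_decoys_are_never_called(sim_db, sim_truth, sim_calls):
    """Planted systems missing one essential gene produce hits but no call."""
    called_genes = {g for c in sim_calls for g in c.member_gene_ids}
    decoy_genes = {g for e in sim_truth.decoys for g in e["gene_ids"]}
    assert sim_truth.decoys  # the profile does plant decoys
    assert not called_genes & decoy_genes


def test_fixture_recall_and_precision_are_perfect(sim_truth, sim_calls):
    got = {(c.genome_id, c.system_name, frozenset(c.member_gene_ids))
           for c in sim_calls}
    want = {(e["genome_id"], e["system_name"], frozenset(e["gene_ids"]))
            for e in sim_truth.systems}
    assert got == want


# ---------------------------------------------------------------------------
# exhaustive-window oracle
# ---------------------------------------------------------------------------

def _window_oracle(labels, definition, max_window=50):
    """Independent check of the quorum rule: enumerate every contiguous
    gene window (<= max_window genes), keep maximal member-bounded windows
    whose internal gaps respect max_intervening, and test the quorum on
    the roles present. Returns the set of frozensets of member indices
    that yield a call."""
    member_models = set(definition.model_to_roles())
    m2r = definition.model_to_roles()
    is_member = [lab in member_models for lab in labels]
    n = len(labels)
    results = set()
    for i in range(n):
        if not is_member[i]:
            continue
        for j in range(i, min(n, i + max_window)):
            if not is_member[j]:
                continue
            members = [x for x in range(i, j + 1) if is_member[x]]
            gaps_ok = all(
                b - a - 1 <= definition.max_intervening
                for a, b in zip(members, members[1:])
            )
            if not gaps_ok:
                continue
            # maximality: no member just outside joinable at this gap rule
            prev_members = [x for x in range(i) if is_member[x]]
            next_members = [x for x in range(j + 1, n) if is_member[x]]
            if prev_members and i - prev_members[-1] - 1 <= definition.max_intervening:
                continue
            if next_members and next_members[0] - j - 1 <= definition.max_intervening:
                continue
            roles = set()
            for x in members:
                for role in m2r.get(labels[x], []):
                    roles.add(role)
            essential = set(definition.essential_roles)
            accessory_n = len(roles & set(definition.accessory_roles))
            quorum = (essential and essential <= roles) or (
                definition.min_accessory > 0
                and accessory_n >= definition.min_accessory
            )
            if quorum:
                results.add(frozenset(members))
    return results


def _random_case(rng):
    n_roles = int(rng.integers(1, 5))
    roles = [f"r{k}" for k in range(n_roles)]
    statuses = ["essential" if rng.random() < 0.6 else "accessory"
                for _ in roles]
    if all(s == "accessory" for s in statuses):
        statuses[0] = "essential"
    n_acc = statuses.count("accessory")
    definition = SystemDefinition(
        system_name="S",
        genes=[SystemGene(r, [r], s) for r, s in zip(roles, statuses)],
        min_accessory=int(rng.integers(1, n_acc + 1)) if n_acc else 0,
        max_intervening=int(rng.integers(0, 4)),
    )
    n = int(rng.integers(5, 51))  # runs always fit the 50-gene windows
    labels = [
        roles[int(rng.integers(0, n_roles))] if rng.random() < 0.35 else "."
        for _ in range(n)
    ]
    return labels, definition


@pytest.mark.parametrize("seed", [0, 1])
def test_caller_matches_exhaustive_window_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(150):
        labels, definition = _random_case(rng)
        layouts = {"c": labels}
        calls = call_systems(_hits_for(layouts), _db_from_layout(layouts),
                             [definition])
        got = {
            frozenset(int(g.split(".")[1]) for g in c.member_gene_ids)
            for c in calls
        }
        assert got == _window_oracle(labels, definition), (labels, definition)
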