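"""Defense-system calling by gene quorum within an adjacency window.

A defense system is defined as a set of gene roles, each either essential
or accessory, with a minimum accessory threshold. Member-gene hits on one
replicon are grouped into candidate loci wherever consecutive member genes
are separated by at most ``max_intervening`` non-member genes; a system is
called if the locus contains all essential roles, or enough accessory
roles to reach the threshold. Calls never span replicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .genome_io import GenomeDB
from .search_reduce import Hit

DEFAULT_MAX_INTERVENING = 3

ESSENTIAL = "essential"
ACCESSORY = "accessory"


@dataclass
class SystemGene:
    role: str
    model_ids: list[str]
    status: str  # essential | accessory


@dataclass
class SystemDefinition:
    """Quorum model of one defense-system type."""

    system_name: str
    genes: list[SystemGene]
    min_accessory: int = 0
    max_intervening: int = DEFAULT_MAX_INTERVENING

    @property
    def essential_roles(self) -> list[str]:
        return [g.role for g in self.genes if g.status == ESSENTIAL]

    @property
    def accessory_roles(self) -> list[str]:
        return [g.role for g in self.genes if g.status == ACCESSORY]

    def model_to_roles(self) -> dict[str, list[str]]:
        m2r: dict[str, list[str]] = {}
        for g in self.genes:
            for mid in g.model_ids:
                m2r.setdefault(mid, []).append(g.role)
        return m2r


@dataclass
class SystemCall:
    """A located instance of a defense system."""

    system_name: str
    genome_id: str
    replicon_id: str
    member_gene_ids: list[str]  # ordered by ordinal
    span: tuple[int, int]
    role_assignments: dict[str, str] = field(default_factory=dict)
    complete: bool = False  # all essential roles filled


def validate_definition(definition: SystemDefinition) -> list[str]:
    """Return a list of violations (empty list = well-formed)."""
    violations = []
    if not definition.genes:
        violations.append("definition has no gene roles")
    roles = [g.role for g in definition.genes]
    dup = {r for r in roles if roles.count(r) > 1}
    if dup:
        violations.append(f"duplicate role names: {sorted(dup)}")
    for g in definition.genes:
        if g.status not in (ESSENTIAL, ACCESSORY):
            violations.append(f"role {g.role}: unknown status {g.status!r}")
        if not g.model_ids:
            violations.append(f"role {g.role}: no model ids")
    n_acc = len(definition.accessory_roles)
    if definition.min_accessory < 0 or definition.min_accessory > n_acc:
        violations.append(
            f"min_accessory={definition.min_accessory} outside [0, {n_acc}]"
        )
    if definition.max_intervening < 0:
        violations.append("max_intervening must be >= 0")
    return violations


def _assign_roles(
    definition: SystemDefinition,
    genes_in_order: Sequence[str],
    gene_models: dict[str, set[str]],
) -> dict[str, str]:
    """Greedy role assignment: genes in ordinal order, each fills the first
    unfilled role (in definition order) that one of its models maps to."""
    m2r = definition.model_to_roles()
    role_order = [g.role for g in definition.genes]
    assigned: dict[str, str] = {}
    for gid in genes_in_order:
        candidate_roles = []
        for mid in gene_models[gid]:
            candidate_roles.extend(m2r.get(mid, []))
        for role in role_order:
            if role in candidate_roles and role not in assigned:
                assigned[role] = gid
                break
    return assigned


def call_systems(
    hits: Iterable[Hit],
    db: GenomeDB,
    definitions: Sequence[SystemDefinition],
) -> list[SystemCall]:
    """Scan every replicon for each system definition and emit calls.

    Expects hits already filtered at the e-value cutoff. Member genes are
    grouped into maximal runs with gaps of at most ``max_intervening``
    non-member genes; each quorum-satisfying run yields one call, leftmost
    first, and a gene consumed by a call cannot seed a second call of the
    same system (it may still join a different system's call). Output is
    invariant to hit-list order.
    """
    for definition in definitions:
        violations = validate_definition(definition)
        if violations:
            raise ValueError(
                f"invalid definition {definition.system_name}: {violations}"
            )
    # gene -> set of models hit (canonical regardless of input order)
    gene_models: dict[str, set[str]] = {}
    for h in hits:
        gene_models.setdefault(h.gene_id, set()).add(h.model_id)
    for gid in gene_models:
        db.gene(gid)  # raises KeyError on unknown gene

    calls: list[SystemCall] = []
    for genome in db.genomes.values():
        for rep in genome.replicons.values():
            for definition in definitions:
                calls.extend(
                    _scan_replicon(rep.genes, definition, gene_models,
                                   genome.genome_id, rep.replicon_id)
                )
    calls.sort(key=lambda c: (c.genome_id, c.replicon_id, c.span[0],
                              c.system_name))
    return calls


def _scan_replicon(genes, definition, gene_models, genome_id, replicon_id):
    member_models = set(definition.model_to_roles())
    member_idx = [
        i for i, g in enumerate(genes)
        if gene_models.get(g.gene_id, set()) & member_models
    ]
    if not member_idx:
        return []
    # split into maximal runs: gap = # intervening non-member genes
    runs: list[list[int]] = [[member_idx[0]]]
    for i in member_idx[1:]:
        if i - runs[-1][-1] - 1 <= definition.max_intervening:
            runs[-1].append(i)
        else:
            runs.append([i])
    calls = []
    for run in runs:
        run_genes = [genes[i] for i in run]
        gids = [g.gene_id for g in run_genes]
        models_here = {
            gid: gene_models[gid] & member_models for gid in gids
        }
        assigned = _assign_roles(definition, gids, models_here)
        filled = set(assigned)
        essential = set(definition.essential_roles)
        complete = essential <= filled if essential else False
        accessory_n = len(filled & set(definition.accessory_roles))
        quorum = (essential and essential <= filled) or (
            definition.min_accessory > 0
            and accessory_n >= definition.min_accessory
        )
        if quorum:
            calls.append(
                SystemCall(
                    system_name=definition.system_name,
                    genome_id=genome_id,
                    replicon_id=replicon_id,
                    member_gene_ids=gids,
                    span=(min(g.start for g in run_genes),
                          max(g.end for g in run_genes)),
                    role_assignments=assigned,
                    complete=bool(complete),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# definition-file and call-table I/O
# ---------------------------------------------------------------------------

def load_definitions(path: str) -> list[SystemDefinition]:
    """Read system definitions from a YAML file (list of documents, each:
    name, genes[{role, models, status}], min_accessory, max_intervening)."""
    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    defs = []
    for doc in docs:
        if doc is None:
            continue
        items = doc if isinstance(doc, list) else [doc]
        for item in items:
            defs.append(
                SystemDefinition(
                    system_name=item["name"],
                    genes=[
                        SystemGene(
                            role=g["role"],
                            model_ids=list(g["models"]),
                            status=g["status"],
                        )
                        for g in item["genes"]
                    ],
                    min_accessory=int(item.get("min_accessory", 0)),
                    max_intervening=int(
                        item.get("max_intervening", DEFAULT_MAX_INTERVENING)
                    ),
                )
            )
    return defs


def dump_definitions(definitions: Sequence[SystemDefinition], path: str) -> None:
    docs = [
        {
            "name": d.system_name,
            "genes": [
                {"role": g.role, "models": g.model_ids, "status": g.status}
                for g in d.genes
            ],
            "min_accessory": d.min_accessory,
            "max_intervening": d.max_intervening,
        }
        for d in definitions
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(docs, fh, sort_keys=False)


def write_calls(calls: Sequence[SystemCall], path: str) -> None:
    rows = [
        {
            "genome_id": c.genome_id,
            "replicon_id": c.replicon_id,
            "system_name": c.system_name,
            "start": c.span[0],
            "end": c.span[1],
            "member_gene_ids": ",".join(c.member_gene_ids),
            "roles": ";".join(f"{r}={g}" for r, g in c.role_assignments.items()),
            "complete": c.complete,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["genome_id", "replicon_id", "system_name", "start", "end",
                 "member_gene_ids", "roles", "complete"],
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> list[SystemCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for r in df.itertuples(index=False):
        roles = {}
        if r.roles:
            roles = dict(p.split("=", 1) for p in r.roles.split(";"))
        calls.append(
            SystemCall(
                system_name=r.system_name,
                genome_id=r.genome_id,
                replicon_id=r.replicon_id,
                member_gene_ids=r.member_gene_ids.split(",") if
                r.member_gene_ids else [],
                span=(int(r.start), int(r.end)),
                role_assignments=roles,
                complete=(str(r.complete).lower() == "true"),
            )
        )
    return calls
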