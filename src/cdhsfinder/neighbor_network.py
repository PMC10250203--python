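"""Bipartite system–neighbor network and hub ranking.

For every called defense system, the genes within a window (default 5 kb)
up- and downstream of the system span are its neighbors. Each neighbor
contributes one co-occurrence to the edge between its protein family and
the system type; the same family flanking the same system type in many
loci accumulates edge weight. Neighbor nodes are merged at the protein-
family level (one clustering shared with the reduced search), so a node's
degree counts the number of *different* system types it flanks — the
signature by which conserved hotspot flanks stand out as hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .genome_io import GenomeDB, gene_window
from .search_reduce import ClusterIndex
from .system_caller import SystemCall

DEFAULT_WINDOW_BP = 5000

SYSTEM = "system"
NEIGHBOR = "neighbor"


@dataclass
class BipartiteDefenseNetwork:
    """Weighted bipartite graph: system types x neighbor protein families."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def system_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == SYSTEM}

    @property
    def neighbor_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == NEIGHBOR}

    def edge_weight(self, system: str, family: str) -> int:
        if self.graph.has_edge(system, family):
            return self.graph[system][family]["weight"]
        return 0

    def provenance(self, system: str, family: str) -> list[tuple[str, str, int, int]]:
        return self.graph[system][family].get("provenance", [])

    def is_bipartite(self) -> bool:
        for u, v in self.graph.edges():
            ku = self.graph.nodes[u].get("kind")
            kv = self.graph.nodes[v].get("kind")
            if {ku, kv} != {SYSTEM, NEIGHBOR}:
                return False
        return True


@dataclass
class HubReport:
    rows: pd.DataFrame  # family_id, degree, total_weight, products


def neighbor_family(
    gene, index: ClusterIndex, fallback_by_product: bool = True
) -> str:
    """Family id of a neighbor gene: its cluster representative.

    RNA genes carry no protein and cannot be clustered; they are keyed by
    product annotation (``rna:<product>``) so that non-coding flank markers
    such as tmRNA still form a single network node.
    """
    if gene.protein_seq:
        return index.family_of(gene.gene_id)
    if fallback_by_product:
        return f"rna:{gene.product or gene.gene_id}"
    return gene.gene_id


def build_network(
    calls: Sequence[SystemCall],
    db: GenomeDB,
    index: ClusterIndex,
    w: int = DEFAULT_WINDOW_BP,
) -> BipartiteDefenseNetwork:
    """Accumulate system–neighbor-family co-occurrence edges.

    For each call, the neighbor set is every gene overlapping the widened
    window minus the call's own members; each distinct neighbor family adds
    +1 to the (system type, family) edge. The result is independent of the
    order of the call list. Genes that belong to a *different* co-located
    system call still count as neighbors of the focal system.
    """
    net = BipartiteDefenseNetwork()
    g = net.graph
    for call in sorted(
        calls, key=lambda c: (c.genome_id, c.replicon_id, c.span, c.system_name)
    ):
        genome = db.genomes.get(call.genome_id)
        if genome is None or call.replicon_id not in genome.replicons:
            raise KeyError(
                f"call on unknown replicon {call.genome_id}/{call.replicon_id}"
            )
        rep = genome.replicons[call.replicon_id]
        members = set(call.member_gene_ids)
        neighbors = [
            n for n in gene_window(rep, call.span, w)
            if n.gene_id not in members
        ]
        if call.system_name not in g:
            g.add_node(call.system_name, kind=SYSTEM)
        # one co-occurrence per distinct family per locus: a family that
        # appears twice in one window still flanks this locus once
        families = sorted({neighbor_family(n, index) for n in neighbors})
        for fam in families:
            if fam not in g:
                g.add_node(fam, kind=NEIGHBOR)
            if not g.has_edge(call.system_name, fam):
                g.add_edge(call.system_name, fam, weight=0, provenance=[])
            e = g[call.system_name][fam]
            e["weight"] += 1
            e["provenance"].append(
                (call.genome_id, call.replicon_id, call.span[0], call.span[1])
            )
    return net


def merge_neighbor_nodes(
    net: BipartiteDefenseNetwork, index: ClusterIndex
) -> BipartiteDefenseNetwork:
    """Collapse neighbor nodes that belong to the same protein family.

    Nodes already keyed by family are untouched (idempotent); gene-level
    nodes are remapped to their cluster representative, with edges to the
    same system summed and provenance concatenated. The merged node keeps
    all edge connections of its members, so its degree is the union of
    member degrees.
    """
    merged = BipartiteDefenseNetwork()
    g = merged.graph
    m2r = index.member_to_rep
    for node, data in net.graph.nodes(data=True):
        if data.get("kind") == SYSTEM:
            g.add_node(node, kind=SYSTEM)
    for u, v, data in net.graph.edges(data=True):
        if net.graph.nodes[u].get("kind") == SYSTEM:
            system, neighbor = u, v
        else:
            system, neighbor = v, u
        fam = m2r.get(neighbor, neighbor)
        if fam not in g:
            g.add_node(fam, kind=NEIGHBOR)
        if not g.has_edge(system, fam):
            g.add_edge(system, fam, weight=0, provenance=[])
        e = g[system][fam]
        e["weight"] += data.get("weight", 1)
        e["provenance"].extend(data.get("provenance", []))
    return merged


def rank_hubs(
    net: BipartiteDefenseNetwork,
    db: GenomeDB | None = None,
    min_degree: int = 1,
) -> HubReport:
    """Rank neighbor families by how many distinct systems they flank.

    Sort order is fully deterministic: degree desc, total weight desc,
    family id ascending. ``db`` (optional) supplies example product
    annotations for the report.
    """
    rows = []
    for fam in net.neighbor_nodes:
        degree = net.graph.degree(fam)
        total_weight = sum(
            net.graph[fam][s]["weight"] for s in net.graph.neighbors(fam)
        )
        if degree < min_degree:
            continue
        products = ""
        if db is not None and not fam.startswith("rna:"):
            try:
                products = db.gene(fam).product
            except KeyError:
                products = ""
        elif fam.startswith("rna:"):
            products = fam[len("rna:"):]
        rows.append(
            {"family_id": fam, "degree": degree,
             "total_weight": total_weight, "products": products}
        )
    df = pd.DataFrame(
        rows, columns=["family_id", "degree", "total_weight", "products"]
    )
    df = df.sort_values(
        ["degree", "total_weight", "family_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    return HubReport(rows=df)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_graph(net: BipartiteDefenseNetwork, path: str, fmt: str) -> None:
    """Write the network as ``graphml`` or ``sif`` (edge-list TSV)."""
    if fmt == "graphml":
        g = nx.Graph()
        for node, data in net.graph.nodes(data=True):
            g.add_node(node, kind=data.get("kind", NEIGHBOR))
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v, weight=int(data.get("weight", 1)))
        nx.write_graphml(g, path)
    elif fmt == "sif":
        rows = []
        for u, v, data in net.graph.edges(data=True):
            if net.graph.nodes[u].get("kind") == SYSTEM:
                system, neighbor = u, v
            else:
                system, neighbor = v, u
            rows.append({"system": system, "neighbor_family": neighbor,
                         "weight": int(data.get("weight", 1))})
        pd.DataFrame(
            rows, columns=["system", "neighbor_family", "weight"]
        ).sort_values(["system", "neighbor_family"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def import_graphml(path: str) -> BipartiteDefenseNetwork:
    g = nx.read_graphml(path)
    net = BipartiteDefenseNetwork()
    for node, data in g.nodes(data=True):
        net.graph.add_node(node, kind=data.get("kind", NEIGHBOR))
    for u, v, data in g.edges(data=True):
        net.graph.add_edge(u, v, weight=int(data.get("weight", 1)),
                           provenance=[])
    return net
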