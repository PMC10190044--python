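"""Heterogeneous drug-protein-disease graph construction.

The embedding input integrates four edge layers: drug-drug similarity
(DDS) and protein-protein similarity (PPS) edges weighted by their
similarity value, and curated disease-drug (DDis) and disease-protein
(DisP) association edges with unit weight.  Known drug-target
interaction edges are deliberately absent so the downstream link
classifier never sees its own answer encoded in the graph.

Node identifiers are namespaced by layer (``drug::``, ``protein::``,
``disease::``) so identifiers can never collide across layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .exceptions import UnknownNodeError
from .similarity import SimilarityMatrix

LAYERS = ("drug", "protein", "disease")
EDGE_TYPES = ("DDS", "PPS", "DDis", "DisP")

ASSOC_DISEASE_DRUG = "disease-drug"
ASSOC_DISEASE_PROTEIN = "disease-protein"


def namespaced(layer: str, raw_id: str) -> str:
    return f"{layer}::{raw_id}"


def split_namespace(node_id: str) -> tuple[str, str]:
    layer, _, raw = node_id.partition("::")
    return layer, raw


@dataclass
class AssociationTable:
    """Deduplicated disease association edge list of one kind."""

    edges: list[tuple[str, str]]  # (disease_id, drug_or_protein_id)
    kind: str  # ASSOC_DISEASE_DRUG or ASSOC_DISEASE_PROTEIN

    def __post_init__(self) -> None:
        if self.kind not in (ASSOC_DISEASE_DRUG, ASSOC_DISEASE_PROTEIN):
            raise ValueError(f"unknown association kind {self.kind!r}")
        seen = set()
        deduped = []
        for d, x in self.edges:
            if not d or not x:
                raise ValueError("association endpoints must be non-empty")
            if (d, x) not in seen:
                seen.add((d, x))
                deduped.append((d, x))
        self.edges = deduped

    @classmethod
    def from_tsv(cls, path, kind: str) -> "AssociationTable":
        edges = []
        with open(path) as fh:
            for ln in fh:
                ln = ln.rstrip("\n")
                if not ln.strip() or ln.startswith("#"):
                    continue
                parts = ln.split("\t")
                if parts[0].lower() == "disease_id":
                    continue
                edges.append((parts[0], parts[1]))
        return cls(edges=edges, kind=kind)

    def to_tsv(self, path) -> None:
        other = "drug_id" if self.kind == ASSOC_DISEASE_DRUG else "protein_id"
        with open(path, "w") as fh:
            fh.write(f"disease_id\t{other}\n")
            for d, x in self.edges:
                fh.write(f"{d}\t{x}\n")


def build_hetero_graph(
    dds: SimilarityMatrix,
    pps: SimilarityMatrix,
    ddis: AssociationTable,
    disp: AssociationTable,
    sim_threshold: float = 0.0,
) -> nx.Graph:
    """Assemble the weighted three-layer graph.

    DDS/PPS edges are created for every off-diagonal pair with
    similarity strictly above ``sim_threshold``; association edges get
    weight 1.  The diagonal never becomes a self-loop, and isolated
    nodes are retained so every node receives an embedding.
    """
    if not 0.0 <= sim_threshold < 1.0:
        raise ValueError("sim_threshold must lie in [0, 1)")
    if ddis.kind != ASSOC_DISEASE_DRUG or disp.kind != ASSOC_DISEASE_PROTEIN:
        raise ValueError("association tables passed in the wrong order")

    g = nx.Graph()
    for d in dds.ids:
        g.add_node(namespaced("drug", d), layer="drug")
    for p in pps.ids:
        g.add_node(namespaced("protein", p), layer="protein")

    for sim, layer, etype in ((dds, "drug", "DDS"), (pps, "protein", "PPS")):
        n = len(sim.ids)
        for i in range(n):
            for j in range(i + 1, n):
                w = float(sim.values[i, j])
                if w > sim_threshold:
                    g.add_edge(
                        namespaced(layer, sim.ids[i]),
                        namespaced(layer, sim.ids[j]),
                        weight=w,
                        etype=etype,
                    )

    drug_set = set(dds.ids)
    protein_set = set(pps.ids)
    unknown = sorted(
        {d for _, d in ddis.edges if d not in drug_set}
        | {p for _, p in disp.edges if p not in protein_set}
    )
    if unknown:
        raise UnknownNodeError(
            f"associations reference ids absent from the similarity layers: {unknown}"
        )

    for table, etype, layer in ((ddis, "DDis", "drug"), (disp, "DisP", "protein")):
        for dis, x in table.edges:
            dis_node = namespaced("disease", dis)
            if dis_node not in g:
                g.add_node(dis_node, layer="disease")
            g.add_edge(dis_node, namespaced(layer, x), weight=1.0, etype=etype)
    return g


def graph_stats(g: nx.Graph) -> dict:
    """Node counts per layer and edge counts per type."""
    nodes = {layer: 0 for layer in LAYERS}
    for _, data in g.nodes(data=True):
        nodes[data["layer"]] += 1
    edges = {etype: 0 for etype in EDGE_TYPES}
    for _, _, data in g.edges(data=True):
        edges[data["etype"]] += 1
    return {
        "nodes": nodes,
        "edges": edges,
        "total_nodes": g.number_of_nodes(),
        "total_edges": g.number_of_edges(),
    }


def write_edgelist(g: nx.Graph, path, header_comments: Sequence[str] = ()) -> None:
    """Serialise as ``src<TAB>dst<TAB>weight<TAB>edge_type`` (sorted, deterministic)."""
    rows = sorted(
        (min(u, v), max(u, v), d["weight"], d["etype"]) for u, v, d in g.edges(data=True)
    )
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("src\tdst\tweight\tedge_type\n")
        for u, v, w, t in rows:
            fh.write(f"{u}\t{v}\t{w:.10g}\t{t}\n")
        # isolated nodes kept as degenerate rows so a round-trip preserves them
        for node in sorted(n for n in g.nodes if g.degree(n) == 0):
            fh.write(f"{node}\t{node}\t0\tISOLATED\n")


def read_edgelist(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#") or ln.startswith("src\t"):
                continue
            u, v, w, t = ln.split("\t")
            for node in {u, v}:
                layer, _ = split_namespace(node)
                g.add_node(node, layer=layer)
            if t != "ISOLATED":
                g.add_edge(u, v, weight=float(w), etype=t)
    return g
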