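"""Annotated network construction and serialization.

A submodel becomes a typed directed graph: metabolite and reaction
nodes (plus gene nodes when requested), substrate edges running
metabolite -> reaction, product edges reaction -> metabolite, and
catalysis edges gene -> reaction.  Relative fluxes, occurrence
percentages and differential-expression statistics are attached as node
and edge attributes, and the graph is written in formats that network
visualization tools ingest directly (GraphML, SIF plus attribute
tables, JSON).  Layout and styling are left to those tools; this module
guarantees the attributes the styles bind to.

Node ids are namespaced (``m:``, ``r:``, ``g:``) because SBML keeps
species, reactions and genes in separate id spaces while flat graph
formats do not.

Attribute names (bit-exact, for portable visual styles):
node -- ``node_type``, ``label``, ``compartment``, ``subsystem``,
``is_exchange``, ``reversible``, ``reaction_index``, ``flux``,
``occurrence_pct``, ``log2_fc``, ``p_value``, ``no_data``;
edge -- ``edge_type``, ``stoichiometry``, ``flux``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .efm_io import Efm
from .comparison import BackboneResult
from .model import MetabolicModel
from .selection import GeneStats

FORMATS = ("graphml", "sif", "json")


@dataclass
class AnnotatedGraph:
    """Typed metabolite/reaction/gene network with mapped data."""

    graph: nx.DiGraph

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [
            n
            for n, data in self.graph.nodes(data=True)
            if data.get("node_type") == node_type
        ]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_graph(
    sub: MetabolicModel,
    include_genes: bool = True,
    index_map: Optional[dict[str, int]] = None,
) -> AnnotatedGraph:
    """Bipartite(+gene) graph of a (sub)model.

    ``index_map`` records, per reaction id, the reaction's index in the
    full model so fluxes addressed by full-model indices can be mapped
    later; it defaults to the (sub)model's own 1-based order.

    A reaction is flagged ``is_exchange`` when it touches a boundary
    species or has at most one participant — uptake and release
    reactions demarcate the network's entry and exit points.
    """
    g = nx.DiGraph()
    boundary = {m.id for m in sub.metabolites if m.is_boundary}
    for met in sub.metabolites:
        g.add_node(
            f"m:{met.id}",
            node_type="metabolite",
            label=met.name or met.id,
            compartment=met.compartment,
        )
    for j, rxn in enumerate(sub.reactions, start=1):
        idx = index_map.get(rxn.id, 0) if index_map is not None else j
        g.add_node(
            f"r:{rxn.id}",
            node_type="reaction",
            label=rxn.name or rxn.id,
            subsystem=rxn.subsystem or "",
            reversible=rxn.reversible,
            reaction_index=idx,
            is_exchange=(
                len(rxn.stoichiometry) <= 1
                or any(met in boundary for met in rxn.stoichiometry)
            ),
        )
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                g.add_edge(
                    f"m:{met_id}",
                    f"r:{rxn.id}",
                    edge_type="substrate",
                    stoichiometry=abs(coeff),
                )
            else:
                g.add_edge(
                    f"r:{rxn.id}",
                    f"m:{met_id}",
                    edge_type="product",
                    stoichiometry=abs(coeff),
                )
        if include_genes and rxn.gpr is not None:
            for gene in dict.fromkeys(rxn.gpr.genes()):
                if not g.has_node(f"g:{gene}"):
                    g.add_node(f"g:{gene}", node_type="gene", label=gene)
                g.add_edge(f"g:{gene}", f"r:{rxn.id}", edge_type="catalysis")
    return AnnotatedGraph(graph=g)


def map_fluxes(g: AnnotatedGraph, efm: Efm) -> AnnotatedGraph:
    """Attach |flux| of each reaction to its node and incident edges.

    Every substrate/product edge of one reaction carries that
    reaction's single relative flux magnitude (edge thickness in the
    visualization).
    """
    if efm.relative_fluxes is None:
        raise ValueError(f"EFM {efm.efm_id} carries no relative fluxes")
    missing = []
    for node, data in g.graph.nodes(data=True):
        if data.get("node_type") != "reaction":
            continue
        idx = data.get("reaction_index")
        if idx not in efm.relative_fluxes:
            missing.append(node)
            continue
        flux = abs(efm.relative_fluxes[idx])
        g.graph.nodes[node]["flux"] = flux
        for u, v, edata in list(g.graph.in_edges(node, data=True)) + list(
            g.graph.out_edges(node, data=True)
        ):
            if edata.get("edge_type") in ("substrate", "product"):
                g.graph.edges[u, v]["flux"] = flux
    if missing:
        raise ValueError(
            f"no flux in EFM {efm.efm_id} for reaction nodes: {sorted(missing)}"
        )
    return g


def map_gene_data(g: AnnotatedGraph, stats: GeneStats) -> AnnotatedGraph:
    """Annotate gene nodes with log2 fold change and p-value by id."""
    for node, data in g.graph.nodes(data=True):
        if data.get("node_type") != "gene":
            continue
        record = stats.get(data.get("label", ""))
        if record is None:
            g.graph.nodes[node]["no_data"] = True
        else:
            g.graph.nodes[node]["log2_fc"] = record.log2_fc
            g.graph.nodes[node]["p_value"] = record.p_value
            g.graph.nodes[node]["no_data"] = False
    return g


def map_occurrence(g: AnnotatedGraph, backbone: BackboneResult) -> AnnotatedGraph:
    """Attach backbone occurrence percentages to reaction nodes."""
    for node, data in g.graph.nodes(data=True):
        if data.get("node_type") != "reaction":
            continue
        idx = data.get("reaction_index")
        if idx in backbone.fractions:
            g.graph.nodes[node]["occurrence_pct"] = backbone.occurrence_pct(idx)
    return g


def write_graph(g: AnnotatedGraph, path: str, fmt: str = "graphml") -> list[str]:
    """Serialize the graph; returns the paths written.

    ``sif`` writes the interaction file plus ``<base>_nodes.tsv`` and
    ``<base>_edges.tsv`` attribute tables (the edge_type is the SIF
    interaction token).  Occurrence percentages are formatted to one
    decimal in SIF node tables; GraphML and JSON keep full precision.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {FORMATS}")
    if fmt == "graphml":
        nx.write_graphml(g.graph, path)
        return [path]
    if fmt == "json":
        payload = {
            "nodes": [
                {"id": n, **data} for n, data in g.graph.nodes(data=True)
            ],
            "edges": [
                {"source": u, "target": v, **data}
                for u, v, data in g.graph.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return [path]
    # SIF + attribute tables
    base = path[:-4] if path.endswith(".sif") else path
    sif_path = base + ".sif"
    nodes_path = base + "_nodes.tsv"
    edges_path = base + "_edges.tsv"
    with open(sif_path, "w") as fh:
        for u, v, data in g.graph.edges(data=True):
            fh.write(f"{u}\t{data['edge_type']}\t{v}\n")
        for n in nx.isolates(g.graph):
            fh.write(f"{n}\n")
    node_keys = sorted({k for _, d in g.graph.nodes(data=True) for k in d})
    with open(nodes_path, "w") as fh:
        fh.write("id\t" + "\t".join(node_keys) + "\n")
        for n, data in g.graph.nodes(data=True):
            row = []
            for k in node_keys:
                v = data.get(k, "")
                if k == "occurrence_pct" and v != "":
                    v = f"{v:.1f}"
                row.append(str(v))
            fh.write(n + "\t" + "\t".join(row) + "\n")
    edge_keys = sorted({k for _, _, d in g.graph.edges(data=True) for k in d})
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\t" + "\t".join(edge_keys) + "\n")
        for u, v, data in g.graph.edges(data=True):
            fh.write(
                f"{u}\t{v}\t"
                + "\t".join(str(data.get(k, "")) for k in edge_keys)
                + "\n"
            )
    return [sif_path, nodes_path, edges_path]


def read_graphml(path: str) -> AnnotatedGraph:
    """Load a GraphML file written by write_graph."""
    return AnnotatedGraph(graph=nx.read_graphml(path))
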