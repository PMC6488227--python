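"""Seed mapping and construction of the seed + first-degree-interactor network.

Seed genes (genes encoding differentially expressed proteins) are mapped onto
the interactome; the analysis network consists of the mapped seeds together
with all their direct interactors. By default the network carries the full
interactome-induced subgraph on those nodes, so edges among interactors are
retained — the module structure found later is meaningful only with those
edges present. A seed-incident-only mode is provided for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io import Interactome, normalize_gene_id


@dataclass
class SeedSet:
    """Outcome of mapping requested seed symbols onto the interactome."""

    requested: list
    mapped: set
    unmapped: list


@dataclass
class SeedNetwork:
    """Mapped seeds plus their first-degree interactors, with seed flags.

    ``graph`` is the subgraph on seeds and interactors; every node is either a
    mapped seed or adjacent to one, and edges are a subset of the parent
    interactome's edges.
    """

    graph: nx.Graph
    seeds: frozenset
    parent: Interactome = field(repr=False)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_seed(self, node) -> bool:
        return node in self.seeds


def map_seeds(interactome: Interactome, seeds) -> SeedSet:
    """Intersect a requested seed list with the interactome's node set.

    Symbols are normalized and deduplicated preserving first occurrence;
    unmapped symbols are reported in input order. Zero mapped seeds is fatal.
    """
    if not seeds:
        raise ValidationError("seed list is empty")
    requested, seen = [], set()
    for s in seeds:
        sym = normalize_gene_id(s)
        if sym not in seen:
            seen.add(sym)
            requested.append(sym)
    nodes = interactome.nodes
    mapped = {s for s in requested if s in nodes}
    unmapped = [s for s in requested if s not in nodes]
    if not mapped:
        raise ValidationError("none of the requested seeds map to the interactome",
                              details={"unmapped": unmapped})
    return SeedSet(requested=requested, mapped=mapped, unmapped=unmapped)


def build_seed_network(interactome: Interactome, seedset: SeedSet, *,
                       seed_incident_only: bool = False,
                       min_seed_links: int = 1) -> SeedNetwork:
    """Build the seed + first-degree-interactor network.

    Node set: mapped seeds plus every interactome neighbor of a mapped seed;
    non-seed interactors may be required to touch at least ``min_seed_links``
    seeds (default 1, i.e. no filter). Edge set: all interactome edges with
    both endpoints in the node set, or only seed-incident edges when
    ``seed_incident_only`` is set. Isolated mapped seeds are retained.
    """
    if not seedset.mapped:
        raise ValidationError("seed set has no mapped seeds")
    g = interactome.graph
    seeds = frozenset(seedset.mapped)
    neighbors = {}
    for s in seeds:
        for v in g.neighbors(s):
            if v not in seeds:
                neighbors[v] = neighbors.get(v, 0) + 1
    kept_interactors = {v for v, c in neighbors.items() if c >= min_seed_links}
    node_set = set(seeds) | kept_interactors
    sub = nx.Graph()
    sub.add_nodes_from(node_set)
    for a, b in g.edges(node_set):
        if a in node_set and b in node_set:
            if seed_incident_only and a not in seeds and b not in seeds:
                continue
            sub.add_edge(a, b)
    for v in sub.nodes:
        sub.nodes[v]["is_seed"] = v in seeds
    return SeedNetwork(graph=sub, seeds=seeds, parent=interactome)


def network_summary(net: SeedNetwork) -> dict:
    """Deterministic summary counts for a seed network (the quantities the
    analysis reports: genes, interactions, seed/non-seed split, degree stats,
    connected components)."""
    degrees = np.array([d for _, d in net.graph.degree()], dtype=float)
    n_seeds = sum(1 for v in net.graph.nodes if net.is_seed(v))
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_seeds": n_seeds,
        "n_nonseed": net.n_nodes - n_seeds,
        "degree_min": int(degrees.min()) if degrees.size else 0,
        "degree_max": int(degrees.max()) if degrees.size else 0,
        "degree_mean": float(degrees.mean()) if degrees.size else 0.0,
        "degree_median": float(np.median(degrees)) if degrees.size else 0.0,
        "n_components": nx.number_connected_components(net.graph),
    }


def write_seed_network(net: SeedNetwork, edges_path, nodes_path,
                       clustering=None) -> None:
    """Export a seed network as a sorted edge list plus a node-attribute table
    (node, is_seed, module when a clustering is supplied)."""
    with open(edges_path, "wt", encoding="utf-8") as out:
        out.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            out.write(f"{a}\t{b}\n")
    with open(nodes_path, "wt", encoding="utf-8") as out:
        out.write("gene\tis_seed\tmodule\n")
        for v in sorted(net.graph.nodes):
            module = "" if clustering is None else clustering.assignment[v]
            out.write(f"{v}\t{int(net.is_seed(v))}\t{module}\n")
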