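"""Merged protein-protein interaction network analysis.

Edge lists from several interaction resources are merged into one undirected
simple graph (duplicates and reversals collapsed, self-interactions dropped)
with a designated seed integrin (e.g. ITGB1). Hop distances are
breadth-first shortest-path edge counts from the seed; unreachable proteins
are reported as not connected (NC). Functional-class summaries and
neighbourhood intersections support candidate nomination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .quantify import round_half_up

__all__ = [
    "NC",
    "build_graph",
    "hop_distances",
    "class_summary",
    "neighborhood_intersection",
]

#: Marker for proteins with no path to the seed.
NC = "NC"


@dataclass
class InteractomeGraph:
    graph: nx.Graph
    seed: str
    #: edge (frozenset pair) -> set of source names
    provenance: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_graph(
    edge_lists: list,
    seed: str,
    sources: list[str] | None = None,
    mapping: dict | None = None,
) -> InteractomeGraph:
    """Union of one or more edge lists into a simple undirected graph.

    Parameters
    ----------
    edge_lists
        Each an iterable of (u, v) pairs (one interaction resource each).
    seed
        Seed protein; added as an isolated node if absent from every list.
    sources
        Optional names for the resources, recorded per edge in provenance.
    mapping
        Optional identifier mapping applied to every node before merging.
    """
    if sources is None:
        sources = [f"source_{i}" for i in range(len(edge_lists))]
    g = nx.Graph()
    provenance: dict[frozenset, set] = {}
    n_raw = 0
    for src, edges in zip(sources, edge_lists):
        for u, v in edges:
            n_raw += 1
            if mapping is not None:
                u = mapping.get(u, u)
                v = mapping.get(v, v)
            if u == v:  # self-interactions excluded
                continue
            g.add_edge(u, v)
            provenance.setdefault(frozenset((u, v)), set()).add(src)
    if n_raw == 0:
        raise ValueError("empty edge-list union")
    if seed not in g:
        g.add_node(seed)
    return InteractomeGraph(graph=g, seed=seed, provenance=provenance)


def hop_distances(interactome: InteractomeGraph, nodes=None) -> pd.Series:
    """BFS hop count from the seed for each requested node (NC if unreachable)."""
    g = interactome.graph
    if interactome.seed not in g:
        raise ValueError(f"seed {interactome.seed!r} not in graph")
    sp = nx.single_source_shortest_path_length(g, interactome.seed)
    if nodes is None:
        nodes = list(g.nodes)
    return pd.Series({n: sp.get(n, NC) for n in nodes}, name="hop")


def class_summary(
    assignment: pd.DataFrame,
    log2fc: pd.Series,
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Per functional class: adhesome membership, identification rate and
    median enrichment of identified members.

    Parameters
    ----------
    assignment
        Cluster assignment (index protein); its index defines the identified
        set.
    log2fc
        Per-protein log2 fold change (active/inactive).
    roster
        Adhesome roster indexed by protein with a ``functional_class`` column.

    Classes with no identified member are reported at 0% with median NaN.
    """
    identified = set(assignment.index)
    rows = []
    for cls, members in roster.groupby("functional_class").groups.items():
        members = set(members)
        found = sorted(members & identified, key=str)
        pct = round_half_up(100.0 * len(found) / len(members))
        med = float(np.median([log2fc[p] for p in found])) if found else float("nan")
        rows.append((cls, len(members), len(found), pct, med))
    return pd.DataFrame(
        rows,
        columns=[
            "functional_class",
            "n_in_adhesome",
            "n_identified",
            "pct_identified",
            "median_log2fc",
        ],
    ).set_index("functional_class")


def neighborhood_intersection(
    interactome: InteractomeGraph,
    set_a: set,
    set_b: set,
    radius: int = 1,
) -> set:
    """Nodes within ``radius`` hops of both protein sets, excluding the sets.

    Used to nominate candidates at the intersection of two interaction
    neighbourhoods (e.g. the +TIP and integrin networks).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    g = interactome.graph

    def ball(seeds: set) -> set:
        out: set = set()
        for s in seeds:
            if s in g:
                out.update(nx.single_source_shortest_path_length(g, s, cutoff=radius))
        return out

    return (ball(set(set_a)) & ball(set(set_b))) - (set(set_a) | set(set_b))
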