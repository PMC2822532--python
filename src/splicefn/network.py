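"""Splice-Function Networks: contingency matrix, projection, and statistics.

The contingency matrix counts, per TU and FL, how many of the TU's splice
variants carry that FL. Projecting it through the polyform TUs gives the
SFN: an undirected graph on FL nodes where an edge joins two FLs that
co-occur within at least one polyform TU, weighted by the number of
distinct shared TUs. Hubs of this graph are the most "reused" functions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .model import POLYFORM, OrganismDataset
from .distfit import FrequencyDistribution, histogram


def build_contingency(dataset: OrganismDataset) -> pd.DataFrame:
    """TU × FL contingency matrix (annotated-protein counts per cell).

    Rows are TU ids (TUs with at least one annotated protein), columns FL
    ids; cell (t, f) is the number of annotated proteins of TU t mapped to
    FL f. Empty datasets give an empty frame.
    """
    if dataset.catalogue is None and dataset.tus:
        raise ValueError("catalogue not built")
    cells: dict[str, dict[str, int]] = {}
    for tu in dataset.tus:
        row: dict[str, int] = {}
        for p in tu.proteins:
            if p.fl_id is not None:
                row[p.fl_id] = row.get(p.fl_id, 0) + 1
        if row:
            cells[tu.tu_id] = row
    df = pd.DataFrame.from_dict(cells, orient="index").fillna(0).astype(int)
    return df.sort_index(axis=0).sort_index(axis=1)


def build_sfn(dataset: OrganismDataset, include_isolated: bool = False) -> nx.Graph:
    """Project polyform TUs into the FL co-occurrence graph.

    Every unordered pair of distinct FLs within a polyform TU contributes
    +1 edge weight (one per TU, regardless of how many splice-variant
    pairs realize it). With ``include_isolated``, FLs attributed to some
    TU but to no polyform pair are added as degree-0 nodes — the fringe of
    single-node aggregates seen around the connected clusters.
    """
    if dataset.catalogue is None and dataset.tus:
        raise ValueError("catalogue not built")
    g = nx.Graph()
    for tu in dataset.tus:
        if tu.tu_class != POLYFORM:
            continue
        for u, v in combinations(sorted(tu.fls), 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    if include_isolated:
        attributed = {fl for tu in dataset.tus for fl in tu.fls}
        g.add_nodes_from(attributed - set(g.nodes()))
    return g


@dataclass
class NetworkStats:
    """Topology summary of an SFN.

    Heterogeneity is the coefficient of variation of the degree sequence
    (population variance): 0 for regular graphs, large when a few hubs
    dominate. ``avg_neighbors`` is the mean degree.
    """

    n_nodes: int
    n_edges: int
    heterogeneity: float
    avg_neighbors: float
    degree_distribution: FrequencyDistribution | None
    n_components: int
    component_sizes: list[int]


def network_stats(graph: nx.Graph) -> NetworkStats:
    """Compute SFN summary statistics; raises on an empty graph."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute statistics of an empty graph")
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    mean_deg = float(degrees.mean())
    het = float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0
    positive = [int(d) for d in degrees if d >= 1]
    deg_dist = histogram(positive) if positive else None
    comps = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    return NetworkStats(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        heterogeneity=het,
        avg_neighbors=mean_deg,
        degree_distribution=deg_dist,
        n_components=len(comps),
        component_sizes=comps,
    )


def rank_hubs(
    graph: nx.Graph, n: int, dataset: OrganismDataset | None = None
) -> list[tuple[str, int, tuple[str, ...]]]:
    """Top-*n* FLs by degree (distinct neighbors), ties by FL id.

    Returns (fl_id, degree, keywords); keywords are resolved from the
    dataset's catalogue when one is given, otherwise left empty.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(graph.degree(), key=lambda nd: (-nd[1], nd[0]))[:n]
    out = []
    for fl_id, deg in ranked:
        kws: tuple[str, ...] = ()
        if dataset is not None and dataset.catalogue is not None:
            try:
                kws = dataset.catalogue.keywords_of(fl_id)
            except KeyError:
                kws = ()
        out.append((fl_id, int(deg), kws))
    return out


def weighted_degrees(graph: nx.Graph) -> dict[str, int]:
    """Summed edge weights per node (exported alongside plain degree)."""
    return {n: int(d) for n, d in graph.degree(weight="weight")}


def write_stats(stats: NetworkStats, organism: str, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["organism", "n_nodes", "n_edges", "heterogeneity",
                    "avg_neighbors", "n_components"])
        w.writerow([organism, stats.n_nodes, stats.n_edges,
                    f"{stats.heterogeneity:.4f}", f"{stats.avg_neighbors:.4f}",
                    stats.n_components])


def write_hubs(hubs, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["fl_id", "links", "keywords"])
        for fl_id, deg, kws in hubs:
            w.writerow([fl_id, deg, ";".join(kws)])
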