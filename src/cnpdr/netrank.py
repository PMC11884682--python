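"""ROI networks from selected pairs, and node centralities.

Selected ROI pairs are graphed as a simple undirected network (every ROI is
kept as a node, including isolates) and individual ROIs are ranked by degree,
shortest-path betweenness, eigenvector centrality of the adjacency matrix, or
the Integrated Value of Influence (IVI).

IVI multiplies a "hubness" aggregate (degree, local H-index, neighborhood
connectivity) by a "spreading" aggregate (ClusterRank, betweenness,
collective influence), each component range-scaled to [1, 100], and
range-scales the product back to [1, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "CentralityScores",
    "build_pair_network",
    "centrality",
    "ivi",
    "ivi_components",
]

logger = logging.getLogger(__name__)

CENTRALITY_METHODS = ("degree", "betweenness", "eigenvector", "ivi")

#: sphere radius of the collective-influence component of IVI
CI_RADIUS = 2


@dataclass
class CentralityScores:
    """Per-node scores under one centrality, with a deterministic ranking.

    ``ranking`` sorts nodes by descending score, ties broken by node
    identifier so repeated runs agree exactly.
    """

    method: str
    scores: dict[str, float]

    @property
    def ranking(self) -> list[str]:
        return [n for n, _ in sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))]

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]


def build_pair_network(
    selected_pairs,
    all_rois,
    weights: dict | None = None,
) -> nx.Graph:
    """Simple graph whose edges are the selected ROI pairs.

    Every ROI in ``all_rois`` becomes a node, so isolates keep (zero)
    centrality scores.  Pairs may be (a, b) tuples or "A--B" labels.
    Duplicate edges are collapsed with a warning; self-loops are rejected.
    """
    from .datasets import PAIR_SEP

    known = set(all_rois)
    g = nx.Graph()
    g.add_nodes_from(all_rois)
    n_dup = 0
    for pair in selected_pairs:
        a, b = pair.split(PAIR_SEP) if isinstance(pair, str) else pair
        if a not in known or b not in known:
            raise ValueError(f"pair ({a}, {b}) references unknown ROI(s)")
        if a == b:
            raise ValueError(f"self-loop ({a}, {a}) not allowed")
        if g.has_edge(a, b):
            n_dup += 1
            continue
        attrs = {}
        if weights is not None:
            w = weights.get(pair)
            if w is None and not isinstance(pair, str):
                w = weights.get((b, a))
            if w is not None:
                attrs["weight"] = float(w)
        g.add_edge(a, b, **attrs)
    if n_dup:
        logger.warning("collapsed %d duplicate edge(s)", n_dup)
    return g


def _eigenvector_scores(graph: nx.Graph) -> dict[str, float]:
    # principal eigenvector of the dense adjacency; deterministic, robust to
    # disconnected graphs (scores concentrate on the dominant component)
    nodes = list(graph.nodes)
    if graph.number_of_edges() == 0:
        logger.warning("eigenvector centrality on an edgeless graph; returning zeros")
        return {n: 0.0 for n in nodes}
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    vec /= vec.max() if vec.max() > 0 else 1.0
    return {n: float(s) for n, s in zip(nodes, vec)}


def centrality(graph: nx.Graph, method: str) -> CentralityScores:
    """Score every node of the pair network under a named centrality.

    degree — raw (unnormalized, unweighted) edge count;
    betweenness — unnormalized shortest-path betweenness;
    eigenvector — principal eigenvector of the adjacency, scaled to max 1;
    ivi — see :func:`ivi`.
    """
    if method == "degree":
        scores = {n: float(d) for n, d in graph.degree()}
    elif method == "betweenness":
        scores = {
            n: float(v) for n, v in nx.betweenness_centrality(graph, normalized=False).items()
        }
    elif method == "eigenvector":
        scores = _eigenvector_scores(graph)
    elif method == "ivi":
        return ivi(graph)
    else:
        raise ValueError(
            f"unknown centrality {method!r}; supported: {', '.join(CENTRALITY_METHODS)}"
        )
    return CentralityScores(method, scores)


# -- IVI ----------------------------------------------------------------------


def _range_scale(x: np.ndarray, lo: float = 1.0, hi: float = 100.0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, lo)
    return lo + (hi - lo) * (x - x.min()) / span


def _h_index(values) -> int:
    vals = sorted(values, reverse=True)
    h = 0
    for i, v in enumerate(vals, start=1):
        if v >= i:
            h = i
        else:
            break
    return h


def ivi_components(graph: nx.Graph) -> dict[str, np.ndarray]:
    """The six raw constituent measures of IVI, per node (unscaled).

    hubness side: degree, local H-index (node's H-index plus the sum of its
    neighbors' H-indices), neighborhood connectivity (mean neighbor degree);
    spreading side: ClusterRank (10^-clustering times the sum of neighbor
    degrees + 1), unnormalized betweenness, collective influence with sphere
    radius 2 ((deg-1) times the sum of (deg-1) over the radius-2 frontier).
    """
    nodes = list(graph.nodes)
    deg = dict(graph.degree())
    h = {n: _h_index([deg[v] for v in graph[n]]) for n in nodes}
    lh_index = np.array([h[n] + sum(h[v] for v in graph[n]) for n in nodes], dtype=float)
    neighborhood_connectivity = np.array(
        [np.mean([deg[v] for v in graph[n]]) if deg[n] > 0 else 0.0 for n in nodes]
    )
    clustering = nx.clustering(graph)
    cluster_rank = np.array(
        [10.0 ** (-clustering[n]) * sum(deg[v] + 1 for v in graph[n]) for n in nodes]
    )
    bc = nx.betweenness_centrality(graph, normalized=False)
    betweenness = np.array([bc[n] for n in nodes])
    ci = np.empty(len(nodes))
    for idx, n in enumerate(nodes):
        sphere = nx.single_source_shortest_path_length(graph, n, cutoff=CI_RADIUS)
        frontier = [v for v, dist in sphere.items() if dist == CI_RADIUS]
        ci[idx] = (deg[n] - 1) * sum(deg[v] - 1 for v in frontier)
    return {
        "degree": np.array([deg[n] for n in nodes], dtype=float),
        "local_h_index": lh_index,
        "neighborhood_connectivity": neighborhood_connectivity,
        "cluster_rank": cluster_rank,
        "betweenness": betweenness,
        "collective_influence": ci,
    }


def ivi(graph: nx.Graph) -> CentralityScores:
    """Integrated Value of Influence, range-scaled to [1, 100].

    Each constituent measure is range-scaled to [1, 100]; hubness is the
    rescaled sum of (degree, local H-index, neighborhood connectivity),
    spreading the rescaled sum of (ClusterRank, betweenness, collective
    influence); IVI rescales hubness x spreading.  A graph where every node
    is equivalent (e.g. all isolates) scores the scale minimum everywhere.
    """
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("IVI requires a nonempty node set")
    comp = ivi_components(graph)
    hubness = _range_scale(
        _range_scale(comp["degree"])
        + _range_scale(comp["local_h_index"])
        + _range_scale(comp["neighborhood_connectivity"])
    )
    spreading = _range_scale(
        _range_scale(comp["cluster_rank"])
        + _range_scale(comp["betweenness"])
        + _range_scale(comp["collective_influence"])
    )
    scores = _range_scale(hubness * spreading)
    return CentralityScores("ivi", {n: float(s) for n, s in zip(nodes, scores)})
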