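"""Random-network simulation of case/control differential-correlation data.

The generator plants a "functional" subnetwork inside a random base graph and
emits one correlation matrix per subject.  Connected ROI pairs receive higher
baseline correlations than unconnected pairs; on the selected differential
edges, case correlations are shifted up and control correlations down by half
a Cohen's d each, so the standardized case/control mean difference on those
features equals the configured effect size.  Time series are never simulated —
the correlations themselves are drawn directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datasets import CorrelationDataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_base_network",
    "select_functional_structure",
    "simulate_dataset",
]

#: graph families understood by :func:`generate_base_network`
NETWORK_TYPES = ("erdos_renyi", "user_supplied")

#: sampled correlations are clipped to this open interval
CORR_BOUND = 0.99


@dataclass
class SimulationConfig:
    """Parameters of one simulated case/control correlation dataset.

    Defaults reproduce the benchmark design used throughout the package:
    100 ROIs, 100 cases and 100 controls, 10 functional ROIs on an
    Erdos-Renyi base network with connection probability 0.1, differential
    edges drawn with ``multiway = 5``, and a medium effect of 0.5 Cohen's d.
    """

    n_rois: int = 100
    n_cases: int = 100
    n_controls: int = 100
    n_functional: int = 10
    effect_size: float = 0.5
    network_type: str = "erdos_renyi"
    connection_prob: float = 0.1
    multiway: int | str = 5
    corr_connected_mean: float = 0.5
    corr_unconnected_mean: float = 0.1
    corr_sd: float = 0.1
    seed: int = 0
    #: explicit edge list (ROI index pairs) used when network_type="user_supplied"
    edges: list[tuple[int, int]] | None = None
    #: project each subject matrix to the nearest positive-semidefinite matrix
    nearest_psd: bool = False

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("n_rois must be at least 2")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 1 <= self.n_functional <= self.n_rois:
            raise ValueError("n_functional must be in [1, n_rois]")
        if self.effect_size < 0:
            raise ValueError("effect_size (Cohen's d) must be nonnegative")
        if not 0.0 <= self.connection_prob <= 1.0:
            raise ValueError("connection_prob must be in [0, 1]")
        if self.corr_connected_mean <= self.corr_unconnected_mean:
            raise ValueError(
                "corr_connected_mean must exceed corr_unconnected_mean "
                "(connected ROIs have the higher baseline correlation)"
            )
        if self.corr_sd <= 0:
            raise ValueError("corr_sd must be positive")
        if isinstance(self.multiway, str):
            if self.multiway != "max":
                raise ValueError('multiway must be an integer >= 2 or "max"')
        elif self.multiway < 2:
            raise ValueError("multiway must be an integer >= 2 (the interaction order)")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class GroundTruth:
    """The planted signal a benchmark scores against.

    ``direction`` maps each differential edge to +1, the convention that cases
    carry the higher correlation on that edge and controls the lower one.
    """

    functional_nodes: set[str]
    differential_edges: set[tuple[str, str]]
    direction: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.differential_edges:
            if a not in self.functional_nodes or b not in self.functional_nodes:
                raise ValueError(f"edge ({a}, {b}) has an endpoint outside functional_nodes")
        if not self.direction:
            self.direction = {e: 1 for e in self.differential_edges}


def _roi_names(n_rois: int) -> list[str]:
    width = len(str(n_rois))
    return [f"ROI{i + 1:0{width}d}" for i in range(n_rois)]


def generate_base_network(
    n_rois: int,
    network_type: str = "erdos_renyi",
    connection_prob: float = 0.1,
    seed: int | None = 0,
    edges: list[tuple[int, int]] | None = None,
) -> nx.Graph:
    """Undirected simple base graph on ``n_rois`` integer-labeled nodes.

    ``erdos_renyi`` draws a G(n, p) graph; ``user_supplied`` passes a
    caller-provided edge list through unchanged (isolated nodes retained).
    """
    if n_rois < 2:
        raise ValueError("n_rois must be at least 2")
    if network_type == "erdos_renyi":
        return nx.gnp_random_graph(n_rois, connection_prob, seed=seed)
    if network_type == "user_supplied":
        if edges is None:
            raise ValueError('network_type="user_supplied" requires an edge list')
        g = nx.Graph()
        g.add_nodes_from(range(n_rois))
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop ({a}, {a}) not allowed")
            if not (0 <= a < n_rois and 0 <= b < n_rois):
                raise ValueError(f"edge ({a}, {b}) outside node range 0..{n_rois - 1}")
            g.add_edge(a, b)
        return g
    raise ValueError(
        f"unknown network_type {network_type!r}; supported: {', '.join(NETWORK_TYPES)}"
    )


def select_functional_structure(
    graph: nx.Graph,
    n_functional: int,
    multiway: int | str = "max",
    seed: int | np.random.Generator = 0,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Pick functional nodes and the differential edges among them.

    Functional nodes are a uniform sample from the largest connected component
    of the base graph.  ``multiway`` is the interaction order: the functional
    nodes are partitioned at random into groups of ``multiway`` mutually
    differentially-correlated nodes, and every within-group pair becomes a
    differential edge (a leftover group of one is merged into the previous
    group).  ``multiway="max"`` makes one group of all functional nodes, i.e.
    every functional pair is differential; small values leave only a subset
    of the possible functional pairs differential, in disjoint clusters.
    No functional node ever exceeds ``multiway`` differential edges.

    Returns ``(functional_nodes, differential_edges)`` as node indices, each
    edge ordered ``(low, high)`` and the lists sorted for determinism.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    components = list(nx.connected_components(graph))
    if not components:
        raise ValueError("graph has no nodes")
    largest = max(components, key=len)
    if len(largest) < n_functional:
        raise ValueError(
            f"largest connected component has {len(largest)} nodes, fewer than "
            f"n_functional={n_functional}; increase connection_prob (or supply a "
            "denser network)"
        )
    nodes = rng.choice(sorted(largest), size=n_functional, replace=False)
    nodes = sorted(int(v) for v in nodes)

    size = n_functional if multiway == "max" else int(multiway)
    size = min(size, n_functional)
    if size < 2:
        raise ValueError("multiway must be at least 2 (pairs are the smallest interaction)")
    order = list(nodes)
    rng.shuffle(order)
    groups = [order[i : i + size] for i in range(0, n_functional, size)]
    if len(groups) > 1 and len(groups[-1]) == 1:
        groups[-2].extend(groups.pop())
    edges: set[tuple[int, int]] = set()
    for group in groups:
        group = sorted(group)
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                edges.add((a, b))
    return nodes, sorted(edges)


def _nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping to the positive-semidefinite cone, diagonal reset to 1."""
    w, v = np.linalg.eigh(matrix)
    m = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(m), 1e-12, None))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


def simulate_dataset(config: SimulationConfig) -> tuple[CorrelationDataset, GroundTruth]:
    """Generate one case/control correlation dataset plus its ground truth.

    Baseline correlations are Normal(corr_connected_mean, corr_sd) on base-graph
    edges and Normal(corr_unconnected_mean, corr_sd) elsewhere, clipped to
    (-0.99, 0.99).  On each differential edge the mean is shifted by
    ``+effect_size * corr_sd / 2`` for cases and ``-effect_size * corr_sd / 2``
    for controls.  Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    graph_ss, struct_ss, data_ss = ss.spawn(3)
    graph_seed = int(graph_ss.generate_state(1, np.uint32)[0] % (2**31))

    graph = generate_base_network(
        config.n_rois, config.network_type, config.connection_prob, graph_seed, config.edges
    )
    nodes, edges = select_functional_structure(
        graph, config.n_functional, config.multiway, np.random.default_rng(struct_ss)
    )

    n_rois = config.n_rois
    n = config.n_cases + config.n_controls
    iu = np.triu_indices(n_rois, k=1)
    adj = nx.to_numpy_array(graph, nodelist=range(n_rois))
    connected = adj[iu] > 0
    base_mean = np.where(connected, config.corr_connected_mean, config.corr_unconnected_mean)

    # column position of pair (a, b), a < b, in row-major upper-triangle order
    col_of = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(*iu))}
    diff_cols = np.array([col_of[e] for e in edges], dtype=int)

    shift = config.effect_size * config.corr_sd / 2.0
    means = np.tile(base_mean, (n, 1))
    means[: config.n_cases, diff_cols] += shift
    means[config.n_cases :, diff_cols] -= shift

    rng = np.random.default_rng(data_ss)
    features = rng.normal(means, config.corr_sd)
    np.clip(features, -CORR_BOUND, CORR_BOUND, out=features)

    roi_names = _roi_names(n_rois)
    if config.nearest_psd:
        from .datasets import devectorize_upper_triangle

        for i in range(n):
            m = _nearest_psd(devectorize_upper_triangle(features[i], n_rois))
            features[i] = m[iu]
        np.clip(features, -CORR_BOUND, CORR_BOUND, out=features)

    phenotype = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )
    dataset = CorrelationDataset(features, roi_names, phenotype)
    truth = GroundTruth(
        functional_nodes={roi_names[v] for v in nodes},
        differential_edges={(roi_names[a], roi_names[b]) for a, b in edges},
    )
    return dataset, truth
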