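"""Connectivity of the curated regulatory network against a rewiring null.

Literature-curated TF -> target networks can look highly interconnected
simply because investigators preferentially study genes already suspected
to be related. To separate genuine structure from the degree sequence, the
observed directed network is compared with an empirical null of random
networks obtained by pairwise edge swaps that preserve every node's in- and
out-degree. Three connectivity statistics are scored on the observed and
each permuted network:

* reachable pairs — ordered node pairs (u, v), u != v, joined by at least
  one directed path (global connectivity);
* cliques — complete subgraphs of three or more nodes in the undirected
  projection, counting all cliques rather than only maximal ones (local
  interconnectedness);
* weakly connected components (fragmentation).

One-tailed empirical p-values use the add-one rule (r + 1) / (n + 1), with
ties counted as as-extreme, so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .aggregate import DTRI

__all__ = [
    "DirectedNetwork",
    "ConnectivityMetrics",
    "NullEnsemble",
    "build_network",
    "reachable_pairs",
    "count_cliques",
    "weak_components",
    "rewire_degree_preserving",
    "permutation_null",
    "empirical_pvalue",
    "compute_metrics",
    "ConnectivityPermutationTest",
    "ConnectivityResults",
]


@dataclass(frozen=True)
class DirectedNetwork:
    """Simple directed graph over genes (human Entrez ids).

    Edges are unique ordered pairs; self-loops are permitted in observed
    data (autoregulation) but never introduced by rewiring.
    """

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    allow_self_loops: bool = True

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(self.edges) != len(set(self.edges)):
            raise ValueError("duplicate edges: the network must be simple")
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u}, {v}) references an unknown node")
            if u == v and not self.allow_self_loops:
                raise ValueError(f"self-loop ({u}, {u}) not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[int, int]], allow_self_loops: bool = True
    ) -> "DirectedNetwork":
        edge_list = sorted(set((int(u), int(v)) for u, v in edges))
        nodes = sorted({n for e in edge_list for n in e})
        return cls(nodes=tuple(nodes), edges=tuple(edge_list), allow_self_loops=allow_self_loops)

    @classmethod
    def from_edgelist_tsv(cls, source: str | IO[str]) -> "DirectedNetwork":
        df = pd.read_csv(source, sep="\t")
        for col in ("tf_entrez", "target_entrez"):
            if col not in df.columns:
                raise ValueError(f"edge list missing column {col!r}")
        return cls.from_edges(
            (int(r.tf_entrez), int(r.target_entrez)) for r in df.itertuples(index=False)
        )

    def to_edgelist_tsv(self, sink: IO[str]) -> None:
        sink.write("tf_entrez\ttarget_entrez\n")
        for u, v in self.edges:
            sink.write(f"{u}\t{v}\n")


def build_network(dtris: Sequence[DTRI]) -> DirectedNetwork:
    """Directed network with one edge per DTRI; nodes are all genes that
    appear as TF or target. Deterministic (sorted) ordering."""
    return DirectedNetwork.from_edges(
        (d.tf_human_entrez, d.target_human_entrez) for d in dtris
    )


@dataclass(frozen=True)
class ConnectivityMetrics:
    reachable_pairs: int
    n_cliques: int
    n_components: int

    def as_dict(self) -> dict[str, int]:
        return {
            "reachable_pairs": self.reachable_pairs,
            "n_cliques": self.n_cliques,
            "n_components": self.n_components,
        }


def reachable_pairs(net: DirectedNetwork) -> int:
    """Count ordered pairs (u, v), u != v, with a directed path u -> ... -> v.

    A self-loop does not make a node reachable from itself for this count.
    """
    g = net.to_networkx()
    return sum(len(nx.descendants(g, n) - {n}) for n in g.nodes())


def count_cliques(net: DirectedNetwork, min_size: int = 3) -> int:
    """Number of complete subgraphs of at least ``min_size`` nodes in the
    undirected projection (self-loops removed, reciprocal edges merged).
    All cliques are counted, not only maximal ones."""
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    und = nx.Graph()
    und.add_nodes_from(net.nodes)
    und.add_edges_from((u, v) for u, v in net.edges if u != v)
    return sum(1 for c in nx.enumerate_all_cliques(und) if len(c) >= min_size)


def weak_components(net: DirectedNetwork) -> int:
    """Number of connected components of the undirected projection."""
    if net.n_nodes == 0:
        raise ValueError("empty network has no components")
    return nx.number_weakly_connected_components(net.to_networkx())


def compute_metrics(net: DirectedNetwork) -> ConnectivityMetrics:
    return ConnectivityMetrics(
        reachable_pairs=reachable_pairs(net),
        n_cliques=count_cliques(net),
        n_components=weak_components(net),
    )


def rewire_degree_preserving(
    net: DirectedNetwork,
    swap_multiplier: int = 10,
    rng: np.random.Generator | int | None = None,
) -> DirectedNetwork:
    """Randomize edges by pairwise swaps preserving in- and out-degrees.

    Each attempt picks two distinct edges (a, b), (c, d) and proposes
    (a, d), (c, b); swaps that would create a self-loop or a duplicate edge
    are rejected. The number of attempted swaps is ``swap_multiplier`` times
    the edge count, after which the current edge set is returned.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least two edges")
    rng = np.random.default_rng(rng)
    edges = list(net.edges)
    edge_set = set(edges)
    m = len(edges)
    attempts = swap_multiplier * m
    pairs = rng.integers(0, m, size=(attempts, 2))
    for i, j in pairs:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        e1, e2 = (a, d), (c, b)
        if e1 in edge_set or e2 in edge_set:
            continue  # would create a duplicate edge
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    return DirectedNetwork(
        nodes=net.nodes, edges=tuple(sorted(edge_set)), allow_self_loops=net.allow_self_loops
    )


@dataclass
class NullEnsemble:
    """Connectivity metrics over independently rewired networks."""

    metrics: list[ConnectivityMetrics]
    n_perm: int
    seed: int | None
    swap_multiplier: int

    def values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.metrics], dtype=float)


def permutation_null(
    net: DirectedNetwork,
    n_perm: int = 1000,
    seed: int | None = None,
    swap_multiplier: int = 10,
) -> NullEnsemble:
    """Score ``n_perm`` independent degree-preserving rewires of the
    observed network with all three connectivity metrics."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    metrics = [
        compute_metrics(rewire_degree_preserving(net, swap_multiplier, rng))
        for _ in range(n_perm)
    ]
    return NullEnsemble(
        metrics=metrics, n_perm=n_perm, seed=seed, swap_multiplier=swap_multiplier
    )


def empirical_pvalue(
    observed: float, null_values: Sequence[float], tail: str = "greater"
) -> float:
    """Add-one empirical p-value (r + 1) / (n + 1), ties as-extreme."""
    values = np.asarray(null_values, dtype=float)
    if values.size == 0:
        raise ValueError("null_values must be nonempty")
    if tail == "greater":
        r = int(np.sum(values >= observed))
    elif tail == "less":
        r = int(np.sum(values <= observed))
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    return (r + 1) / (values.size + 1)


# ---------------------------------------------------------------------------
# Model / Results interface

#: Tail of interest per metric: excess connectivity means more reachable
#: pairs, more cliques, and fewer components than the null.
_METRIC_TAILS = {
    "reachable_pairs": "greater",
    "n_cliques": "greater",
    "n_components": "less",
}


class ConnectivityPermutationTest:
    """Permutation test of network connectivity against a degree-preserving
    rewiring null.

    Parameters
    ----------
    network
        The observed directed network.

    Examples
    --------
    >>> net = DirectedNetwork.from_edges([(1, 2), (2, 3), (1, 3)])
    >>> res = ConnectivityPermutationTest(net).fit(n_perm=99, seed=0)
    >>> sorted(res.observed.as_dict())
    ['n_cliques', 'n_components', 'reachable_pairs']
    """

    def __init__(self, network: DirectedNetwork):
        self.network = network

    def fit(
        self,
        n_perm: int = 1000,
        seed: int | None = None,
        swap_multiplier: int = 10,
    ) -> "ConnectivityResults":
        observed = compute_metrics(self.network)
        null = permutation_null(self.network, n_perm, seed, swap_multiplier)
        pvalues = {
            metric: empirical_pvalue(
                getattr(observed, metric), null.values(metric), tail
            )
            for metric, tail in _METRIC_TAILS.items()
        }
        return ConnectivityResults(
            model=self, observed=observed, null=null, pvalues=pvalues
        )


@dataclass
class ConnectivityResults:
    """Observed connectivity, the rewiring null, and empirical p-values."""

    model: ConnectivityPermutationTest
    observed: ConnectivityMetrics
    null: NullEnsemble
    pvalues: dict[str, float]

    def null_mean(self, metric: str) -> float:
        return float(self.null.values(metric).mean())

    def null_sd(self, metric: str) -> float:
        return float(self.null.values(metric).std(ddof=1)) if self.null.n_perm > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric, tail in _METRIC_TAILS.items():
            rows.append(
                {
                    "metric": metric,
                    "observed": getattr(self.observed, metric),
                    "null_mean": self.null_mean(metric),
                    "null_sd": self.null_sd(metric),
                    "tail": tail,
                    "p_value": self.pvalues[metric],
                }
            )
        return pd.DataFrame(rows).set_index("metric")

    def to_report(self) -> dict:
        return {
            "n_nodes": self.model.network.n_nodes,
            "n_edges": self.model.network.n_edges,
            "n_perm": self.null.n_perm,
            "seed": self.null.seed,
            "swap_multiplier": self.null.swap_multiplier,
            "metrics": {
                metric: {
                    "observed": getattr(self.observed, metric),
                    "null_mean": self.null_mean(metric),
                    "null_sd": self.null_sd(metric),
                    "tail": tail,
                    "p_value": self.pvalues[metric],
                }
                for metric, tail in _METRIC_TAILS.items()
            },
        }

    def plot_null_distributions(self, ax=None):
        """Histogram of each null distribution with the observed value marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        else:
            axes = ax
        for a, metric in zip(axes, _METRIC_TAILS):
            a.hist(self.null.values(metric), bins=30, color="0.7")
            a.axvline(getattr(self.observed, metric), color="crimson")
            a.set_title(f"{metric} (p={self.pvalues[metric]:.3g})")
        return axes
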