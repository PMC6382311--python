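"""Gene influence networks and their local exploration.

An influence network is an undirected, weighted gene graph whose edge
weights quantify topological influence between genes, typically derived
from a protein–protein interaction (PPI) network by an insulated
heat-diffusion (random walk with restart) process. Module search is
constrained to *local networks*: bounded breadth-first neighbourhoods of
a reduced influence network whose small-weight edges were removed until
the average degree falls to that of a typical PPI network (15).
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "InfluenceNetwork",
    "LocalNetwork",
    "read_edge_list",
    "read_adjacency",
    "write_edge_list",
    "diffuse_influence",
    "reduce_to_average_degree",
    "extract_local_network",
]


@dataclass(frozen=True)
class LocalNetwork:
    """A BFS neighbourhood of the reduced network around ``center``.

    ``members`` is the BFS discovery order, center first, truncated at the
    size cap used during extraction.
    """

    center: str
    members: tuple[str, ...]


class InfluenceNetwork:
    """Undirected weighted gene graph with a provenance tag.

    Invariants: no self-loops, no duplicate undirected edges, weights
    finite and non-negative.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]] = (),
        name: str = "network",
        nodes: Iterable[str] = (),
    ) -> None:
        self.name = name
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, w in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            w = float(w)
            if not math.isfinite(w) or w < 0:
                raise ValueError(f"edge {a!r}-{b!r} has invalid weight {w}")
            if g.has_edge(a, b):
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            g.add_edge(a, b, weight=w)
        self._g = g

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (a, b, weight) with a < b, sorted — a canonical form."""
        out = []
        for a, b, data in self._g.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, float(data["weight"])))
        return sorted(out)

    def average_degree(self) -> float:
        n = self._g.number_of_nodes()
        return 2 * self._g.number_of_edges() / n if n else 0.0

    def weight(self, a: str, b: str) -> float:
        return float(self._g[a][b]["weight"])


def read_edge_list(path: str | Path, name: str | None = None) -> InfluenceNetwork:
    """Read a weighted edge list: ``gene_a<TAB>gene_b<TAB>weight``.

    A header line whose first field is ``gene_a`` is skipped. Duplicate
    undirected edges keep the larger weight (tolerant ingest of matrices
    exported with both orientations).
    """
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_a":
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            a, b, w = fields[0], fields[1], float(fields[2])
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key not in best or w > best[key]:
                best[key] = w
    return InfluenceNetwork(
        ((a, b, w) for (a, b), w in best.items()),
        name=name or path.stem,
    )


def read_adjacency(path: str | Path) -> nx.Graph:
    """Read an unweighted PPI edge list: ``gene_a<TAB>gene_b``."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_a":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            if fields[0] != fields[1]:
                g.add_edge(fields[0], fields[1])
    return g


def write_edge_list(net: InfluenceNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def diffusion_matrix(adjacency: nx.Graph, beta: float) -> tuple[np.ndarray, list[str]]:
    """Directed influence matrix of the insulated heat-diffusion process.

    With W the column-normalised adjacency, the diffusion fixed point is
    F = beta * (I - (1 - beta) * W)^-1; F[i, j] is the influence of gene j
    on gene i. The returned matrix D is oriented so D[i, j] is the
    influence of gene i on gene j (D = F.T), hence each row sums to 1.
    Isolated nodes are dropped with a warning (no walk is defined there).
    """
    if not 0 < beta < 1:
        raise ValueError("beta (restart probability) must lie in (0, 1)")
    isolated = [n for n in adjacency.nodes if adjacency.degree(n) == 0]
    if isolated:
        warnings.warn(
            f"dropping {len(isolated)} isolated node(s) from diffusion: "
            + ", ".join(sorted(isolated)[:5]),
            stacklevel=2,
        )
    nodes = sorted(n for n in adjacency.nodes if adjacency.degree(n) > 0)
    if not nodes:
        return np.zeros((0, 0)), []
    a = nx.to_numpy_array(adjacency, nodelist=nodes, weight=None)
    w = a / a.sum(axis=0, keepdims=True)  # column-stochastic walk matrix
    n = len(nodes)
    f = beta * np.linalg.inv(np.eye(n) - (1.0 - beta) * w)
    return f.T, nodes


def diffuse_influence(
    adjacency: nx.Graph,
    beta: float = 0.45,
    symmetrize: str = "min",
    name: str = "diffused",
) -> InfluenceNetwork:
    """Derive a weighted influence network from an unweighted PPI graph.

    The directed influences are symmetrised per undirected pair by
    ``min`` (default — both genes must influence each other), ``max`` or
    ``mean``; zero-weight pairs and self-influence are not exported.
    """
    combine = {"min": min, "max": max, "mean": lambda x, y: (x + y) / 2.0}.get(symmetrize)
    if combine is None:
        raise ValueError(f"symmetrize must be min|max|mean, got {symmetrize!r}")
    d, nodes = diffusion_matrix(adjacency, beta)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            w = combine(d[i, j], d[j, i])
            if w > 0:
                edges.append((nodes[i], nodes[j], float(w)))
    return InfluenceNetwork(edges, name=name, nodes=nodes)


def reduce_to_average_degree(
    net: InfluenceNetwork, target_avg_degree: float = 15.0
) -> InfluenceNetwork:
    """Remove small-weight edges until the average degree reaches a target.

    A single global weight cutoff keeps the ceil(target * n / 2)
    heaviest edges; every edge tied with the threshold weight is retained,
    so the achieved average degree may slightly exceed the target. A
    network already at or below the target is returned unchanged.
    """
    if target_avg_degree <= 0:
        raise ValueError("target_avg_degree must be positive")
    n_keep = math.ceil(target_avg_degree * len(net.nodes) / 2.0)
    edges = net.edges()
    if len(edges) <= n_keep:
        return InfluenceNetwork(edges, name=net.name, nodes=net.nodes)
    weights = sorted((w for _, _, w in edges), reverse=True)
    threshold = weights[n_keep - 1]
    kept = [(a, b, w) for a, b, w in edges if w >= threshold]
    return InfluenceNetwork(kept, name=net.name, nodes=net.nodes)


def extract_local_network(
    net: InfluenceNetwork, center: str, max_genes: int = 100
) -> LocalNetwork:
    """Bounded BFS neighbourhood of ``center`` in the (reduced) network.

    Within each expansion the unvisited neighbours of the dequeued node
    are enqueued in descending edge weight from that node, breaking
    weight ties lexicographically — a fully deterministic traversal.
    """
    if center not in net.nodes:
        raise KeyError(f"center gene {center!r} not in network {net.name!r}")
    if max_genes < 1:
        raise ValueError("max_genes must be >= 1")
    g = net.graph
    members = [center]
    seen = {center}
    queue: deque[str] = deque([center])
    while queue and len(members) < max_genes:
        node = queue.popleft()
        neighbors = sorted(
            (nb for nb in g.neighbors(node) if nb not in seen),
            key=lambda nb: (-g[node][nb]["weight"], nb),
        )
        for nb in neighbors:
            seen.add(nb)
            members.append(nb)
            queue.append(nb)
            if len(members) >= max_genes:
                break
    return LocalNetwork(center=center, members=tuple(members))
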