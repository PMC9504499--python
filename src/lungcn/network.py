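"""Pixel complex networks from HU band layers, and their degree metrics.

Each retained pixel of a band layer is a candidate node.  Two pixels are
linked when they have similar attenuation (|dHU| <= 50 by default) and are
spatially close (Euclidean distance strictly below 4 px by default).  Pixels
that acquire no link are detached and dropped from the graph, so the degree
metrics describe connected tissue regions only.

Construction scans the bounded pixel neighbourhood induced by the distance
threshold — with the default radius that is 44 candidate offsets per pixel —
rather than all pixel pairs, which keeps run time linear in the number of
retained pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .banding import BandLayer

DEFAULT_HU_TOLERANCE = 50
DEFAULT_DISTANCE_THRESHOLD = 4.0


def neighborhood_offsets(distance_threshold: float) -> list[tuple[int, int]]:
    """Integer offsets (dr, dc) with 0 < dr^2 + dc^2 < threshold^2.

    These are the only displacements at which two pixel centres can satisfy
    the strict Euclidean proximity rule.  With the default threshold of 4 px
    there are exactly 44 of them, which bounds every node degree.
    """
    if distance_threshold <= 0:
        raise ValueError("distance threshold must be positive")
    reach = int(np.ceil(distance_threshold)) + 1
    limit = distance_threshold**2
    return [
        (dr, dc)
        for dr in range(-reach, reach + 1)
        for dc in range(-reach, reach + 1)
        if 0 < dr * dr + dc * dc < limit
    ]


def _half_offsets(distance_threshold: float) -> list[tuple[int, int]]:
    # one representative per unordered offset pair, to emit each edge once
    return [
        (dr, dc)
        for dr, dc in neighborhood_offsets(distance_threshold)
        if dr > 0 or (dr == 0 and dc > 0)
    ]


@dataclass(frozen=True)
class PixelGraph:
    """Undirected simple graph over the linked pixels of one band layer.

    ``nodes`` is an (n, 3) int array of (row, col, hu); ``edges`` an (m, 2)
    int array of node-index pairs with i < j, unique and self-loop free.
    Detached pixels (no qualifying link) are not present.
    """

    nodes: np.ndarray
    edges: np.ndarray
    band_name: str
    hu_tolerance: int = DEFAULT_HU_TOLERANCE
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=np.int64).reshape(-1, 3)
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= len(nodes):
                raise ValueError("edge references an invalid node index")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.node_count, dtype=np.int64)
        if self.edge_count:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_set(self) -> set[tuple[int, int]]:
        """Edges as a set of (i, j) tuples with i < j."""
        return {(int(i), int(j)) for i, j in self.edges}

    def to_networkx(self):
        """Convert to a networkx.Graph with row/col/hu node attributes."""
        import networkx as nx

        g = nx.Graph()
        for idx, (r, c, h) in enumerate(self.nodes):
            g.add_node(idx, row=int(r), col=int(c), hu=int(h))
        g.add_edges_from((int(i), int(j)) for i, j in self.edges)
        return g


@dataclass(frozen=True)
class NetworkMetrics:
    """The three degree statistics of a pixel network.

    * ``max_degree`` — largest number of links at any single node,
    * ``total_count`` — number of links in the network,
    * ``average_count`` — mean links per node, 2 * total_count / node_count.

    An empty network reports zeros.
    """

    max_degree: int
    total_count: int
    average_count: float
    node_count: int

    def as_dict(self) -> dict[str, float]:
        return {
            "max_degree": self.max_degree,
            "total_count": self.total_count,
            "average_count": self.average_count,
            "node_count": self.node_count,
        }


METRIC_NAMES = ("max_degree", "total_count", "average_count")


def build_network(
    layer: BandLayer,
    hu_tolerance: int = DEFAULT_HU_TOLERANCE,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> PixelGraph:
    """Build the pixel graph of a band layer under the attachment rule.

    Two pixels are linked iff |HU_i - HU_j| <= hu_tolerance and their
    Euclidean centre distance is strictly below distance_threshold.  Pixels
    with no link are detached and excluded from the node set.  An empty
    layer yields an empty graph.
    """
    if hu_tolerance < 0:
        raise ValueError("hu_tolerance must be non-negative")
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")

    n_pix = layer.pixel_count
    if n_pix == 0:
        return PixelGraph(
            nodes=np.empty((0, 3)),
            edges=np.empty((0, 2)),
            band_name=layer.band.name,
            hu_tolerance=hu_tolerance,
            distance_threshold=distance_threshold,
        )

    rows, cols, hus = layer.rows, layer.cols, layer.hus
    n_rows, n_cols = layer.source_shape

    # dense index grid: -1 where the layer has no pixel
    index = np.full((n_rows, n_cols), -1, dtype=np.int64)
    index[rows, cols] = np.arange(n_pix)
    hu_grid = np.zeros((n_rows, n_cols), dtype=np.int32)
    hu_grid[rows, cols] = hus

    edge_parts = []
    for dr, dc in _half_offsets(distance_threshold):
        # overlap of the grid with itself shifted by (dr, dc)
        r0a, r1a = max(0, -dr), min(n_rows, n_rows - dr)
        c0a, c1a = max(0, -dc), min(n_cols, n_cols - dc)
        if r0a >= r1a or c0a >= c1a:
            continue
        ia = index[r0a:r1a, c0a:c1a]
        ib = index[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        ha = hu_grid[r0a:r1a, c0a:c1a]
        hb = hu_grid[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        ok = (ia >= 0) & (ib >= 0) & (np.abs(ha.astype(np.int64) - hb) <= hu_tolerance)
        if ok.any():
            edge_parts.append(np.stack([ia[ok], ib[ok]], axis=1))

    if edge_parts:
        edges = np.concatenate(edge_parts)
        edges = np.sort(edges, axis=1)
    else:
        edges = np.empty((0, 2), dtype=np.int64)

    # drop detached pixels and reindex the survivors
    linked = np.zeros(n_pix, dtype=bool)
    linked[edges.ravel()] = True
    new_index = np.cumsum(linked) - 1
    nodes = np.stack([rows[linked], cols[linked], hus[linked]], axis=1)
    if edges.size:
        edges = new_index[edges]
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]

    return PixelGraph(
        nodes=nodes,
        edges=edges,
        band_name=layer.band.name,
        hu_tolerance=hu_tolerance,
        distance_threshold=distance_threshold,
    )


def build_network_bruteforce(
    layer: BandLayer,
    hu_tolerance: int = DEFAULT_HU_TOLERANCE,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> PixelGraph:
    """All-pairs O(n^2) reference construction.

    Checks every pixel pair directly against the attachment rule.  Intended
    as an independent oracle for small layers; quadratic in pixel count.
    """
    n = layer.pixel_count
    if n == 0:
        return PixelGraph(
            nodes=np.empty((0, 3)),
            edges=np.empty((0, 2)),
            band_name=layer.band.name,
            hu_tolerance=hu_tolerance,
            distance_threshold=distance_threshold,
        )
    pos = np.stack([layer.rows, layer.cols], axis=1).astype(np.float64)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    dhu = np.abs(layer.hus.astype(np.int64)[:, None] - layer.hus[None, :])
    adj = (d2 < distance_threshold**2) & (dhu <= hu_tolerance)
    np.fill_diagonal(adj, False)
    ii, jj = np.nonzero(np.triu(adj))
    edges = np.stack([ii, jj], axis=1)

    linked = np.zeros(n, dtype=bool)
    linked[edges.ravel()] = True
    new_index = np.cumsum(linked) - 1
    nodes = np.stack(
        [layer.rows[linked], layer.cols[linked], layer.hus[linked]], axis=1
    )
    if edges.size:
        edges = new_index[edges]
    return PixelGraph(
        nodes=nodes,
        edges=edges,
        band_name=layer.band.name,
        hu_tolerance=hu_tolerance,
        distance_threshold=distance_threshold,
    )


def compute_metrics(graph: PixelGraph) -> NetworkMetrics:
    """Maximum degree, total link count and average links per node."""
    if graph.node_count == 0:
        return NetworkMetrics(0, 0, 0.0, 0)
    deg = graph.degrees()
    return NetworkMetrics(
        max_degree=int(deg.max()),
        total_count=graph.edge_count,
        average_count=2.0 * graph.edge_count / graph.node_count,
        node_count=graph.node_count,
    )


def export_graph(graph: PixelGraph, prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Write ``<prefix>_nodes.csv`` and ``<prefix>_edges.csv``.

    The node table has columns index, row, col, hu, degree (degree supports
    degree-proportional rendering); the edge list has columns source, target.
    Re-importing with :func:`import_graph` reproduces the graph.
    """
    prefix = Path(prefix)
    node_path = prefix.with_name(prefix.name + "_nodes.csv")
    edge_path = prefix.with_name(prefix.name + "_edges.csv")
    deg = graph.degrees()
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "row", "col", "hu", "degree"])
        for idx, (r, c, h) in enumerate(graph.nodes):
            w.writerow([idx, int(r), int(c), int(h), int(deg[idx])])
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for i, j in graph.edges:
            w.writerow([int(i), int(j)])
    return node_path, edge_path


def import_graph(
    prefix: Union[str, Path],
    band_name: str = "",
    hu_tolerance: int = DEFAULT_HU_TOLERANCE,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> PixelGraph:
    """Read a graph written by :func:`export_graph`."""
    prefix = Path(prefix)
    nodes = []
    with open(prefix.with_name(prefix.name + "_nodes.csv")) as fh:
        for rec in csv.DictReader(fh):
            nodes.append((int(rec["row"]), int(rec["col"]), int(rec["hu"])))
    edges = []
    with open(prefix.with_name(prefix.name + "_edges.csv")) as fh:
        for rec in csv.DictReader(fh):
            edges.append((int(rec["source"]), int(rec["target"])))
    return PixelGraph(
        nodes=np.array(nodes, dtype=np.int64).reshape(-1, 3),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        band_name=band_name,
        hu_tolerance=hu_tolerance,
        distance_threshold=distance_threshold,
    )


def export_graphml(graph: PixelGraph, path: Union[str, Path]) -> None:
    """Write the graph in GraphML interchange format (via networkx)."""
    import networkx as nx

    g = graph.to_networkx()
    deg = graph.degrees()
    for idx in g.nodes:
        g.nodes[idx]["degree"] = int(deg[idx])
    nx.write_graphml(g, str(path))
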