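"""Weighted undirected colony interaction networks and rewired null replicas.

A :class:`WeightedNetwork` couples a symmetric nonnegative interaction-count
matrix with per-node metadata (queen flag, foraging proportion, detection
count).  Null replicas are produced by weighted degree-preserving double-edge
swaps, which destroy community structure while conserving the node set, the
binary degree sequence, the multiset of edge weights and the total weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataFormatError, LookupError_

__all__ = [
    "WeightedNetwork",
    "build_network",
    "node_strength",
    "rewire",
    "read_edgelist_csv",
    "write_edgelist_csv",
    "read_graphml",
    "write_graphml",
]


@dataclass
class WeightedNetwork:
    """Symmetric weighted interaction network with node metadata.

    Parameters
    ----------
    ids
        Node identifiers; their order defines the rows/columns of ``W``.
    W
        Symmetric nonnegative weight matrix with zero diagonal
        (interaction counts).
    is_queen
        Boolean flag per node.  At most one node may be flagged; a network
        without a queen is legal but queen-dependent operations will fail.
    foraging_proportion, detection_count
        Optional per-node metadata (NaN where unknown).
    """

    ids: list
    W: np.ndarray
    is_queen: np.ndarray | None = None
    foraging_proportion: np.ndarray | None = None
    detection_count: np.ndarray | None = None
    colony: str | None = None
    species: str | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise DataFormatError(
                f"weight matrix shape {self.W.shape} does not match {n} ids"
            )
        if not np.allclose(self.W, self.W.T):
            raise DataFormatError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise DataFormatError("weight matrix must have zero diagonal")
        if np.any(self.W < 0):
            raise DataFormatError("weights must be nonnegative")
        if self.is_queen is None:
            self.is_queen = np.zeros(n, dtype=bool)
        else:
            self.is_queen = np.asarray(self.is_queen, dtype=bool)
        if self.is_queen.sum() > 1:
            raise DataFormatError("at most one queen per network")
        if self.foraging_proportion is None:
            self.foraging_proportion = np.full(n, np.nan)
        else:
            self.foraging_proportion = np.asarray(self.foraging_proportion, dtype=float)
        if self.detection_count is None:
            self.detection_count = np.full(n, np.nan)
        else:
            self.detection_count = np.asarray(self.detection_count, dtype=float)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def total_weight(self) -> float:
        """Sum of edge weights m (each undirected edge counted once)."""
        return float(self.W.sum()) / 2.0

    def index_of(self, node: Hashable) -> int:
        try:
            return self.ids.index(node)
        except ValueError:
            raise LookupError_(f"unknown node {node!r}") from None

    @property
    def queen_id(self) -> Hashable | None:
        idx = np.flatnonzero(self.is_queen)
        return self.ids[idx[0]] if idx.size else None

    def strengths(self) -> np.ndarray:
        """Per-node strength: row sums of the weight matrix."""
        return self.W.sum(axis=1)

    def edges(self) -> list[tuple[int, int, float]]:
        """List of (i, j, weight) with i < j and weight > 0 (index based)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.W[iu, ju] > 0
        return list(zip(iu[mask].tolist(), ju[mask].tolist(), self.W[iu, ju][mask]))

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(
            ids=list(self.ids),
            W=self.W.copy(),
            is_queen=self.is_queen.copy(),
            foraging_proportion=self.foraging_proportion.copy(),
            detection_count=self.detection_count.copy(),
            colony=self.colony,
            species=self.species,
            flags=dict(self.flags),
        )

    def subset(self, keep: Sequence[Hashable]) -> "WeightedNetwork":
        """Network restricted to ``keep`` (original node order preserved)."""
        keep_set = set(keep)
        idx = [i for i, a in enumerate(self.ids) if a in keep_set]
        return WeightedNetwork(
            ids=[self.ids[i] for i in idx],
            W=self.W[np.ix_(idx, idx)],
            is_queen=self.is_queen[idx],
            foraging_proportion=self.foraging_proportion[idx],
            detection_count=self.detection_count[idx],
            colony=self.colony,
            species=self.species,
            flags=dict(self.flags),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.ids):
            g.add_node(
                a,
                is_queen=bool(self.is_queen[i]),
                foraging_proportion=float(self.foraging_proportion[i]),
                detection_count=float(self.detection_count[i]),
            )
        for i, j, w in self.edges():
            g.add_edge(self.ids[i], self.ids[j], weight=float(w))
        return g


def build_network(
    count_matrix: pd.DataFrame | np.ndarray,
    metadata: pd.DataFrame | None = None,
    excluded: Iterable[Hashable] = (),
    ids: Sequence[Hashable] | None = None,
    colony: str | None = None,
    species: str | None = None,
) -> WeightedNetwork:
    """Build a :class:`WeightedNetwork`, dropping excluded ants.

    ``count_matrix`` is a square symmetric DataFrame (index = columns = ant
    ids) or an ndarray with ``ids`` given separately.  ``metadata`` may carry
    columns ``is_queen``, ``foraging_proportion`` and ``detection_count``
    indexed by ant id.  Excluded ids are removed from the node set and the
    matrix; isolated nodes are retained so per-ant vectors stay aligned with
    the roster.
    """
    if isinstance(count_matrix, pd.DataFrame):
        if list(count_matrix.index) != list(count_matrix.columns):
            raise DataFormatError("count matrix index and columns must match")
        ids = list(count_matrix.index)
        W = count_matrix.to_numpy(dtype=float)
    else:
        W = np.asarray(count_matrix, dtype=float)
        if ids is None:
            ids = list(range(W.shape[0]))
        ids = list(ids)
    if not np.allclose(W, W.T):
        raise DataFormatError("count matrix must be symmetric")

    excluded = set(excluded)
    keep = [i for i, a in enumerate(ids) if a not in excluded]
    ids_kept = [ids[i] for i in keep]
    W = W[np.ix_(keep, keep)]

    def _col(name, default):
        if metadata is not None and name in metadata.columns:
            return metadata[name].reindex(ids_kept).to_numpy()
        return default

    n = len(ids_kept)
    return WeightedNetwork(
        ids=ids_kept,
        W=W,
        is_queen=np.nan_to_num(
            np.asarray(_col("is_queen", np.zeros(n)), dtype=float)
        ).astype(bool),
        foraging_proportion=_col("foraging_proportion", np.full(n, np.nan)),
        detection_count=_col("detection_count", np.full(n, np.nan)),
        colony=colony,
        species=species,
    )


def node_strength(network: WeightedNetwork, node: Hashable) -> float:
    """Summed weight of all edges incident to ``node``."""
    return float(network.W[network.index_of(node)].sum())


def rewire(
    network: WeightedNetwork,
    n_swap_multiplier: int = 10,
    seed: int | np.random.Generator | None = None,
    strategy: str = "swap",
) -> WeightedNetwork:
    """Degree-preserving weighted rewiring null replica.

    ``strategy="swap"`` performs weighted double-edge swaps: two edges
    (a,b), (c,d) with four distinct endpoints exchange endpoints to (a,d),
    (c,b), each carrying its weight.  Swaps that would create a self-loop or
    land on an existing edge are rejected (weights are never merged).
    ``strategy="swap_shuffle_weights"`` additionally permutes the edge-weight
    multiset over the rewired edge set, redistributing weights across the
    preserved degree structure.

    Both strategies preserve exactly: the node set, the binary degree
    sequence, the multiset of edge weights and the total weight.  On graphs
    too small or degenerate to swap, a copy is returned with
    ``flags["rewire_warning"]`` set.
    """
    if strategy not in ("swap", "swap_shuffle_weights"):
        raise ValueError(f"unknown rewire strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    edges = network.edges()
    out = network.copy()
    if len(edges) < 2:
        out.flags["rewire_warning"] = "fewer than 2 edges; returned unchanged copy"
        return out

    pairs = [(i, j) for i, j, _ in edges]
    weights = [w for _, _, w in edges]
    present = set(pairs)
    n_edges = len(edges)
    n = network.n_nodes
    # a swap needs two vacant pairs; a (near-)complete graph cannot be
    # topologically rewired, only its weights can be redistributed
    n_vacant = n * (n - 1) // 2 - n_edges
    target = n_swap_multiplier * n_edges if n_vacant >= 2 else 0
    accepted = attempts = 0
    max_attempts = 100 * target
    batch = 1024
    while accepted < target and attempts < max_attempts:
        e1s = rng.integers(0, n_edges, size=batch)
        e2s = rng.integers(0, n_edges, size=batch)
        flips = rng.random(batch) < 0.5
        for e1, e2, flip in zip(e1s, e2s, flips):
            attempts += 1
            if e1 == e2:
                continue
            a, b = pairs[e1]
            c, d = pairs[e2]
            if flip:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            p1 = (a, d) if a < d else (d, a)
            p2 = (c, b) if c < b else (b, c)
            if p1 in present or p2 in present:
                continue
            present.discard(pairs[e1])
            present.discard(pairs[e2])
            present.add(p1)
            present.add(p2)
            pairs[e1] = p1
            pairs[e2] = p2
            accepted += 1
            if accepted >= target:
                break
    if accepted < target or (n_vacant < 2 and strategy == "swap"):
        out.flags["rewire_warning"] = (
            f"only {accepted}/{target} swaps accepted "
            f"({n_vacant} vacant pairs available)"
        )

    if strategy == "swap_shuffle_weights":
        weights = [weights[i] for i in rng.permutation(n_edges)]

    W = np.zeros_like(network.W)
    for (i, j), w in zip(pairs, weights):
        W[i, j] = W[j, i] = w
    out.W = W
    return out


# -- serialization ---------------------------------------------------------


def write_edgelist_csv(network: WeightedNetwork, path) -> None:
    """Weighted edge list CSV with a node-attribute side table on the end.

    Format: edge rows (ant_i, ant_j, count) followed by per-node rows keyed
    by a sentinel in ant_j; kept as two CSVs would be cleaner but a single
    file travels better.  Node metadata is stored in a companion file
    ``<path>.nodes.csv``.
    """
    rows = [
        {"ant_i": network.ids[i], "ant_j": network.ids[j], "count": w}
        for i, j, w in network.edges()
    ]
    pd.DataFrame(rows, columns=["ant_i", "ant_j", "count"]).to_csv(path, index=False)
    nodes = pd.DataFrame(
        {
            "ant_id": network.ids,
            "is_queen": network.is_queen.astype(int),
            "foraging_proportion": network.foraging_proportion,
            "detection_count": network.detection_count,
        }
    )
    nodes.to_csv(str(path) + ".nodes.csv", index=False)


def read_edgelist_csv(path, nodes_path=None) -> WeightedNetwork:
    """Read a network written by :func:`write_edgelist_csv`.

    If no companion node file exists, the node set is inferred from the
    edge list (isolated nodes are then lost, unavoidably).
    """
    import os

    df = pd.read_csv(path)
    for col in ("ant_i", "ant_j", "count"):
        if col not in df.columns:
            raise DataFormatError(f"edge list missing column {col!r}")
    nodes_path = nodes_path or (str(path) + ".nodes.csv")
    meta = None
    if os.path.exists(nodes_path):
        meta = pd.read_csv(nodes_path).set_index("ant_id")
        ids = list(meta.index)
    else:
        ids = sorted(set(df["ant_i"]) | set(df["ant_j"]))
    pos = {a: i for i, a in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for _, row in df.iterrows():
        i, j = pos[row["ant_i"]], pos[row["ant_j"]]
        W[i, j] = W[j, i] = row["count"]
    return build_network(W, metadata=meta, ids=ids)


def write_graphml(network: WeightedNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)


def read_graphml(path) -> WeightedNetwork:
    g = nx.read_graphml(path)
    ids = list(g.nodes)
    pos = {a: i for i, a in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for u, v, data in g.edges(data=True):
        W[pos[u], pos[v]] = W[pos[v], pos[u]] = data.get("weight", 1.0)
    n = len(ids)
    return WeightedNetwork(
        ids=ids,
        W=W,
        is_queen=np.array([bool(g.nodes[a].get("is_queen", False)) for a in ids]),
        foraging_proportion=np.array(
            [float(g.nodes[a].get("foraging_proportion", np.nan)) for a in ids]
        ),
        detection_count=np.array(
            [float(g.nodes[a].get("detection_count", np.nan)) for a in ids]
        ),
    )
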