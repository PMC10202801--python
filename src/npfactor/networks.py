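"""Atlas-level characterization of an edge set.

Summarizes a consensus edge set against a node atlas with network
labels: normalized inter/intra-network connection counts, normalized
node degree, and the top-decile hub nodes.  Edges occurring in several
conditions are counted once (union rule) -- the consensus network is a
single graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fc import edge_pairs


@dataclass
class AtlasTable:
    """Node table: contiguous 0-based ids, network labels, optional names."""

    table: pd.DataFrame  # node_id, network [, name, x, y, z]

    def __post_init__(self) -> None:
        t = self.table
        for col in ("node_id", "network"):
            if col not in t.columns:
                raise ValueError(f"atlas table misses column {col!r}")
        ids = np.sort(t["node_id"].to_numpy())
        if not np.array_equal(ids, np.arange(len(t))):
            raise ValueError("node ids must be contiguous 0..P-1")
        if t["network"].isna().any():
            raise ValueError("every node needs a network label")
        self.table = t.sort_values("node_id").reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        return sorted(self.table["network"].unique())

    @property
    def node_network(self) -> np.ndarray:
        return self.table["network"].to_numpy()


def read_atlas(path) -> AtlasTable:
    return AtlasTable(pd.read_csv(path, sep="\t"))


def unique_node_pairs(
    edge_ids_by_condition: dict[str, np.ndarray] | np.ndarray, n_nodes: int
) -> np.ndarray:
    """Deduplicated (i, j) node pairs of an edge set (union over conditions)."""
    if isinstance(edge_ids_by_condition, dict):
        ids = np.unique(
            np.concatenate([np.asarray(v, dtype=int) for v in edge_ids_by_condition.values()])
            if edge_ids_by_condition else np.zeros(0, dtype=int)
        )
    else:
        ids = np.unique(np.asarray(edge_ids_by_condition, dtype=int))
    i, j = edge_pairs(n_nodes)
    return np.column_stack([i[ids], j[ids]]) if ids.size else np.zeros((0, 2), dtype=int)


def network_matrix(
    edge_set: dict[str, np.ndarray] | np.ndarray, atlas: AtlasTable
) -> pd.DataFrame:
    """Normalized network-by-network connection counts.

    Entry (A, B) is the number of unique node pairs linking networks A
    and B (diagonal: within-network), divided by the largest entry, so
    values lie in [0, 1] with a maximum of 1 whenever the set is
    non-empty.  An empty edge set gives an all-zero matrix.
    """
    pairs = unique_node_pairs(edge_set, atlas.n_nodes)
    nets = atlas.networks
    idx = {net: a for a, net in enumerate(nets)}
    counts = np.zeros((len(nets), len(nets)))
    labels = atlas.node_network
    for i, j in pairs:
        a, b = idx[labels[i]], idx[labels[j]]
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1
    peak = counts.max()
    if peak > 0:
        counts = counts / peak
    return pd.DataFrame(counts, index=nets, columns=nets)


def node_degree(
    edge_set: dict[str, np.ndarray] | np.ndarray,
    atlas: AtlasTable,
    decile: float = 0.10,
) -> tuple[pd.Series, list[int]]:
    """Normalized node degree and the top-decile hub list.

    Degree is the count of unique incident node pairs, normalized by the
    maximum degree.  The hub list holds the ``ceil(decile * P)`` nodes
    with the highest degree; ties break by ascending node id so the
    report is deterministic.
    """
    pairs = unique_node_pairs(edge_set, atlas.n_nodes)
    deg = np.zeros(atlas.n_nodes)
    for i, j in pairs:
        deg[i] += 1
        deg[j] += 1
    peak = deg.max()
    norm = deg / peak if peak > 0 else deg
    series = pd.Series(norm, index=np.arange(atlas.n_nodes), name="degree")
    if peak == 0:
        return series, []
    n_top = int(np.ceil(decile * atlas.n_nodes))
    order = np.lexsort((np.arange(atlas.n_nodes), -deg))
    return series, [int(i) for i in order[:n_top]]
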