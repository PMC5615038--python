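"""Edge-list TSV round-tripping for topologies and weight matrices.

Format: three tab-separated columns ``source``, ``target``, ``weight``
with a header line; node indices are 0-based.  Zero entries are not
written, so a matrix round-trips up to its sparsity pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import InvalidParameterError
from .topology import TreeLikeTopology, find_cycle

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_weight_matrix",
    "read_weight_matrix",
    "write_topology",
    "read_topology",
]

_COLUMNS = ["source", "target", "weight"]


def write_edge_list(path, sources, targets, weights) -> None:
    pd.DataFrame(
        {"source": sources, "target": targets, "weight": weights}
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _COLUMNS:
        raise InvalidParameterError(
            f"expected columns {_COLUMNS}, got {list(df.columns)}"
        )
    return df


def write_weight_matrix(path, weights: np.ndarray) -> None:
    w = np.asarray(weights, dtype=float)
    i, j = np.nonzero(w)
    write_edge_list(path, i, j, w[i, j])


def read_weight_matrix(path, n_nodes: int | None = None) -> np.ndarray:
    df = read_edge_list(path)
    S = n_nodes if n_nodes is not None else int(df[["source", "target"]].max().max()) + 1
    w = np.zeros((S, S))
    w[df["source"].to_numpy(), df["target"].to_numpy()] = df["weight"].to_numpy()
    return w


def write_topology(path, topo: TreeLikeTopology) -> None:
    """Write the successor links with unit weights."""
    S = topo.n_nodes
    write_edge_list(path, np.arange(S), topo.successor, np.ones(S))


def read_topology(path) -> TreeLikeTopology:
    df = read_edge_list(path)
    S = int(df[["source", "target"]].max().max()) + 1
    if sorted(df["source"].tolist()) != list(range(S)):
        raise InvalidParameterError("each node needs exactly one outgoing link")
    successor = np.empty(S, dtype=np.intp)
    successor[df["source"].to_numpy()] = df["target"].to_numpy()
    return TreeLikeTopology(successor=successor, loop_length=len(find_cycle(successor)))
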