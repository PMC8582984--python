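"""Cosine-similarity respondent networks.

Respondents are nodes; an undirected edge joins every pair whose cosine
similarity (on their reduced component-score vectors) is strictly greater
than the cutoff (default 0.5).  Isolated respondents stay in the graph —
they are the "dispersed" individuals that never join a cluster.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

DEFAULT_CUTOFF = 0.5


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (|u| |v|): orientation-only similarity in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have identical length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(u @ v / (nu * nv))


def build_graph(scores, cutoff: float = DEFAULT_CUTOFF, node_ids=None,
                node_attrs: pd.DataFrame | None = None,
                block_size: int = 1024) -> nx.Graph:
    """Thresholded cosine-similarity graph over the rows of ``scores``.

    An edge (i, j) exists iff similarity > cutoff (strict, so a pair at
    exactly the cutoff is not connected).  Pairs are evaluated in blocks of
    ``block_size`` rows, so peak transient storage is O(block_size * n)
    rather than n^2.

    ``node_attrs`` (indexed like ``node_ids``) attaches per-node attributes
    such as quartile, gender and age band for export and inspection.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("scores must be a 2-D matrix with at least 2 rows")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = S.shape[0]
    norms = np.linalg.norm(S, axis=1)
    if (norms == 0).any():
        bad = np.nonzero(norms == 0)[0]
        ids = [node_ids[i] if node_ids is not None else i for i in bad]
        raise ValueError(f"zero-norm score vector(s) for respondent(s) {ids[:10]}")
    unit = S / norms[:, None]

    if node_ids is None:
        node_ids = list(range(n))
    else:
        node_ids = list(node_ids)
        if len(node_ids) != n:
            raise ValueError("node_ids must align with score rows")

    graph = nx.Graph(cutoff=float(cutoff))
    for i, nid in enumerate(node_ids):
        attrs = {}
        if node_attrs is not None:
            attrs = {k: _plain(v) for k, v in node_attrs.iloc[i].items()}
        graph.add_node(nid, **attrs)

    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        sims = unit[start:stop] @ unit.T  # (block, n)
        for local, i in enumerate(range(start, stop)):
            row = sims[local, i + 1:]
            js = np.nonzero(row > cutoff)[0] + i + 1
            for j in js:
                graph.add_edge(node_ids[i], node_ids[j],
                               weight=float(sims[local, j]))
    return graph


def _plain(v):
    """Coerce numpy scalars to plain Python for clean GraphML/GEXF export."""
    return v.item() if isinstance(v, np.generic) else v


def export_graph(graph: nx.Graph, path, fmt: str | None = None) -> None:
    """Write the graph as GraphML, GEXF or a plain edge-list CSV.

    The format is inferred from the file suffix when ``fmt`` is omitted.
    The CSV has columns source, target, weight (one row per edge).
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gexf":
        nx.write_gexf(graph, path)
    elif fmt == "csv":
        rows = [(u, v, d.get("weight", np.nan)) for u, v, d in graph.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; use graphml, gexf or csv")


def load_graph(path, fmt: str | None = None) -> nx.Graph:
    """Re-import a graph written by :func:`export_graph` (GraphML/GEXF)."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gexf":
        return nx.read_gexf(path)
    raise ValueError(f"unknown graph format {fmt!r}; use graphml or gexf")
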