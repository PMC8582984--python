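"""Density clustering of the 2-D layout and Fig-6-style cluster profiles.

DBSCAN with the classic core/border/noise semantics: a core point has at
least ``min_pts`` neighbours within ``eps`` (counting itself); clusters are
the density-connected components of core points plus their border points.
The implementation is written here (neighbourhood queries via a KD-tree)
because reporting requires a fully documented deterministic tie rule: a
border point reachable from several clusters joins the cluster of its
smallest-index core neighbour.  Cluster ids are renumbered 1..C by
decreasing size (ties: smallest member index); 0 marks noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .responses import EMOTIONS, MEDIA, ResponseTable

#: label used for unclustered (noise) points
NOISE = 0


@dataclass
class DbscanParams:
    eps: float
    min_pts: int = 10

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


def dbscan(points, params: DbscanParams) -> np.ndarray:
    """Cluster 2-D points; returns labels (1..C by decreasing size, 0 = noise)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=int)

    tree = cKDTree(pts)
    neighbours = tree.query_ball_point(pts, params.eps)
    core = np.array([len(nb) >= params.min_pts for nb in neighbours])

    labels = np.full(n, -1, dtype=int)  # raw component id per core point
    comp = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            i = stack.pop()
            for j in neighbours[i]:
                if core[j] and labels[j] == -1:
                    labels[j] = comp
                    stack.append(j)
        comp += 1

    # border points: smallest-index core neighbour decides the cluster
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        core_nb = [j for j in sorted(neighbours[i]) if core[j]]
        if core_nb:
            labels[i] = labels[core_nb[0]]

    return relabel_by_size(labels)


def relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Renumber raw labels (-1 = noise) to 1..C by decreasing size.

    Ties are broken by the smallest member index, so the numbering is a pure
    function of the partition.
    """
    out = np.zeros_like(raw)
    ids = [c for c in np.unique(raw) if c != -1]
    stats = []
    for c in ids:
        members = np.nonzero(raw == c)[0]
        stats.append((-len(members), members[0], c))
    for rank, (_, _, c) in enumerate(sorted(stats), start=1):
        out[raw == c] = rank
    return out


def suggest_eps(points, k: int = 10) -> tuple:
    """Elbow of the sorted k-nearest-neighbour distance curve.

    Returns ``(eps, curve)`` where ``curve`` is the ascending k-distance
    array.  The elbow is located on the normalised curve (both axes scaled
    to [0, 1]) as the point lying farthest below the end-to-end chord — the
    standard knee criterion for a convex rising curve, marking the distance
    scale where local density ends and sparsity begins.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1)  # first neighbour is the point itself
    curve = np.sort(dist[:, k])
    # the knee is located on the bulk of the curve: the top 2% of
    # k-distances belong to isolated points and would otherwise stretch
    # the chord and drag the elbow into the sparse tail
    bulk = curve[: max(int(np.ceil(0.98 * n)), 2)]
    span = bulk[-1] - bulk[0]
    if span <= 0:
        return float(curve[-1]), curve
    nb = len(bulk)
    xn = np.arange(nb) / (nb - 1)
    yn = (bulk - bulk[0]) / span
    idx = int(np.argmax(xn - yn))
    return float(bulk[idx]), curve


@dataclass
class ClusterProfiles:
    """Tidy per-cluster prevalence table plus the coverage statistic."""

    table: pd.DataFrame
    coverage: float          # fraction of the population in the top_k clusters
    cluster_sizes: pd.Series

    def deltas(self, baseline: str = "population") -> pd.DataFrame:
        col = {"population": "delta_vs_population",
               "clustered": "delta_vs_clustered"}[baseline]
        return self.table.pivot_table(index="group", columns="attribute",
                                      values=col)


def _prevalences(df: pd.DataFrame) -> dict:
    """Attribute -> percent within df (partitioned attrs sum to 100)."""
    if not len(df):
        return {}
    out = {"female_pct": 100.0 * (df["gender"] == "female").mean()}
    for band, share in df["age_band"].value_counts(normalize=True).items():
        out[f"age_{band}_pct"] = 100.0 * share
    for lab in (1, 2, 3, 4):
        out[f"QR{lab}_pct"] = 100.0 * (df["quartile"] == lab).mean()
    for flag in (*EMOTIONS, *MEDIA):
        out[f"{flag}_pct"] = 100.0 * df[flag].mean()
    return out


def profile_clusters(assignment: np.ndarray, responses: ResponseTable,
                     quartiles: np.ndarray, top_k: int = 13) -> ClusterProfiles:
    """Fig-6-style profile of the ``top_k`` largest clusters.

    Each profiled group reports its size, share of the population, and the
    prevalence of gender, age bands, quartiles, emotions and media flags,
    with deltas against two baselines: the full population and the clustered
    (non-noise) subset.  Noise is excluded from coverage and profiled as its
    own row.
    """
    assignment = np.asarray(assignment)
    df = responses.data.copy()
    if len(df) != len(assignment) or len(df) != len(quartiles):
        raise ValueError("assignment, responses and quartiles must align")
    df["age_band"] = responses.age_bands.to_numpy()
    df["quartile"] = np.asarray(quartiles)

    ids = [c for c in np.unique(assignment) if c != NOISE]
    sizes = pd.Series({c: int((assignment == c).sum()) for c in ids}).sort_index()
    if top_k > len(ids):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(ids)} clusters found; returning all",
            stacklevel=2,
        )
        top_k = len(ids)
    top = sorted(ids)[:top_k]  # ids are already ordered by decreasing size

    pop = _prevalences(df)
    clustered_mask = assignment != NOISE
    clustered = _prevalences(df[clustered_mask]) if clustered_mask.any() else pop

    n = len(df)
    rows = []

    def _emit(group, sub):
        prev = _prevalences(sub)
        for attr in pop:
            val = prev.get(attr, 0.0)
            rows.append({
                "group": group,
                "size": len(sub),
                "pct_of_population": 100.0 * len(sub) / n,
                "attribute": attr,
                "percent": val,
                "delta_vs_population": val - pop[attr],
                "delta_vs_clustered": val - clustered.get(attr, np.nan),
            })

    _emit("population", df)
    if (~clustered_mask).any():
        _emit("noise", df[~clustered_mask])
    for c in top:
        _emit(f"cluster_{c}", df[assignment == c])

    coverage = float(np.isin(assignment, top).sum()) / n
    return ClusterProfiles(table=pd.DataFrame(rows), coverage=coverage,
                           cluster_sizes=sizes)


def heterogeneity_summary(assignment: np.ndarray, quartiles: np.ndarray,
                          major_fraction: float = 0.05) -> pd.DataFrame:
    """Per-quartile dispersion of cluster membership.

    For each quartile: the number of clusters holding at least
    ``major_fraction`` of that quartile's members, the share of its members
    in its single largest cluster, and the normalised entropy of its cluster
    membership distribution (0 = all in one cluster, 1 = spread evenly over
    the clusters it occupies).  Noise points are excluded from the
    distribution but counted in ``n``.
    """
    assignment = np.asarray(assignment)
    quartiles = np.asarray(quartiles)
    if len(assignment) != len(quartiles):
        raise ValueError("assignment and quartiles must align")
    rows = []
    for q in sorted(np.unique(quartiles)):
        members = assignment[quartiles == q]
        clustered = members[members != NOISE]
        n_q = len(members)
        if len(clustered) == 0:
            rows.append({"quartile": q, "n": n_q, "n_clustered": 0,
                         "n_major_clusters": 0, "largest_cluster_share": np.nan,
                         "normalized_entropy": np.nan})
            continue
        counts = pd.Series(clustered).value_counts()
        shares_of_quartile = counts / n_q
        probs = (counts / counts.sum()).to_numpy()
        k = len(probs)
        entropy = float(-(probs * np.log(probs)).sum() / np.log(k)) if k > 1 else 0.0
        rows.append({
            "quartile": q,
            "n": n_q,
            "n_clustered": int(counts.sum()),
            "n_major_clusters": int((shares_of_quartile >= major_fraction).sum()),
            "largest_cluster_share": float(counts.iloc[0] / n_q),
            "normalized_entropy": entropy,
        })
    return pd.DataFrame(rows)
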