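"""Force-directed 2-D embedding of the similarity graph (ForceAtlas2 family).

Forces follow the ForceAtlas2 conventions: linear attraction along edges
(magnitude equal to the distance), degree-weighted repulsion between all
node pairs (k_r * (deg_i + 1)(deg_j + 1) / d), classic gravity pulling each
node toward the origin with magnitude g * (deg + 1), and the adaptive
global/local speed scheme driven by per-node "swinging" (oscillation) and
"traction" (steady progress).  Similar respondents are pulled together and
dissimilar ones pushed apart, so homogeneous groups condense into blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd


@dataclass
class LayoutParams:
    """Parameters of the force model and the iteration schedule."""

    kr: float = 2.0               # repulsion scaling
    gravity: float = 1.0          # >= 0; 0 disables gravity
    iterations: int = 1000
    jitter_tolerance: float = 1.0
    barnes_hut: bool | None = None  # None = automatic (exact below threshold)
    barnes_hut_threshold: int = 2000
    theta: float = 0.9            # Barnes-Hut accuracy (smaller = more exact)
    seed: int = 0
    linlog: bool = False          # not supported; rejected explicitly
    prevent_overlap: bool = False  # not supported; rejected explicitly
    ks: float = 0.1               # local speed factor
    ks_max: float = 10.0          # max displacement-per-force cap
    init_radius: float = 10.0     # radius of the initial uniform disc

    def __post_init__(self):
        if self.kr <= 0:
            raise ValueError("repulsion scaling kr must be > 0")
        if self.gravity < 0:
            raise ValueError("gravity must be >= 0")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.linlog:
            raise NotImplementedError("LinLog attraction is not supported")
        if self.prevent_overlap:
            raise NotImplementedError("overlap prevention is not supported")


@dataclass
class Layout:
    """Final node coordinates plus per-iteration convergence diagnostics."""

    node_ids: list
    positions: np.ndarray   # n x 2
    swinging: np.ndarray    # total swinging per iteration
    traction: np.ndarray    # total traction per iteration

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "respondent_id": self.node_ids,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
        })


def attraction_force(d: float) -> float:
    """Edge attraction magnitude: linear in the distance."""
    if np.any(np.asarray(d) < 0):
        raise ValueError("distance must be >= 0")
    return d


def repulsion_force(deg_i: float, deg_j: float, d: float, kr: float) -> float:
    """Pairwise repulsion magnitude: kr * (deg_i + 1)(deg_j + 1) / d."""
    if np.any(np.asarray(d) <= 0):
        raise ValueError("repulsion needs d > 0 (coincident nodes are jittered)")
    return kr * (deg_i + 1.0) * (deg_j + 1.0) / d


def _repulsion_exact(pos: np.ndarray, mass: np.ndarray, kr: float,
                     rng: np.random.Generator) -> np.ndarray:
    delta = pos[:, None, :] - pos[None, :, :]          # i - j
    d2 = np.einsum("ijk,ijk->ij", delta, delta)
    np.fill_diagonal(d2, 1.0)
    coincident = d2 < 1e-18
    np.fill_diagonal(coincident, False)
    if coincident.any():
        # coincident nodes: push apart along a small random direction,
        # antisymmetrised so Newton's third law still holds exactly
        jitter = rng.standard_normal(delta.shape) * 1e-6
        jitter = jitter - np.transpose(jitter, (1, 0, 2))
        delta = np.where(coincident[:, :, None], jitter, delta)
        d2 = np.where(coincident, np.einsum("ijk,ijk->ij", delta, delta), d2)
        d2 = np.maximum(d2, 1e-18)
    coef = kr * (mass[:, None] * mass[None, :]) / d2
    np.fill_diagonal(coef, 0.0)
    return np.einsum("ij,ijk->ik", coef, delta)


class _QuadTree:
    """Flat-array quadtree for Barnes-Hut repulsion."""

    def __init__(self, pos: np.ndarray, mass: np.ndarray):
        self.pos = pos
        self.mass = mass
        lo = pos.min(axis=0)
        hi = pos.max(axis=0)
        centre = (lo + hi) / 2.0
        size = max(float((hi - lo).max()), 1e-9) * 1.0001
        # node storage
        self.cx, self.cy, self.size = [centre[0]], [centre[1]], [size]
        self.m = [0.0]
        self.mx, self.my = [0.0], [0.0]           # mass-weighted position sums
        self.child = [[-1, -1, -1, -1]]
        self.point = [-1]                          # leaf point index, -2 = internal
        for i in range(len(pos)):
            self._insert(0, i)

    def _new(self, cx, cy, size):
        self.cx.append(cx); self.cy.append(cy); self.size.append(size)
        self.m.append(0.0); self.mx.append(0.0); self.my.append(0.0)
        self.child.append([-1, -1, -1, -1]); self.point.append(-1)
        return len(self.cx) - 1

    def _quadrant(self, node, x, y):
        return (1 if x > self.cx[node] else 0) + (2 if y > self.cy[node] else 0)

    def _insert(self, node, i):
        x, y = self.pos[i]
        while True:
            self.m[node] += self.mass[i]
            self.mx[node] += self.mass[i] * x
            self.my[node] += self.mass[i] * y
            if self.point[node] == -1 and self.child[node][0] == -1 \
                    and self.child[node][1] == -1 and self.child[node][2] == -1 \
                    and self.child[node][3] == -1 and self.m[node] == self.mass[i]:
                self.point[node] = i
                return
            if self.point[node] >= 0:
                # occupied leaf: push existing point down (unless degenerate)
                j = self.point[node]
                if self.size[node] < 1e-12:
                    return  # coincident points: aggregate in this leaf
                self.point[node] = -2
                self._push_down(node, j)
            q = self._quadrant(node, x, y)
            if self.child[node][q] == -1:
                half = self.size[node] / 2.0
                ncx = self.cx[node] + (half / 2.0 if q & 1 else -half / 2.0)
                ncy = self.cy[node] + (half / 2.0 if q & 2 else -half / 2.0)
                self.child[node][q] = self._new(ncx, ncy, half)
            node = self.child[node][q]

    def _push_down(self, node, j):
        x, y = self.pos[j]
        q = self._quadrant(node, x, y)
        if self.child[node][q] == -1:
            half = self.size[node] / 2.0
            ncx = self.cx[node] + (half / 2.0 if q & 1 else -half / 2.0)
            ncy = self.cy[node] + (half / 2.0 if q & 2 else -half / 2.0)
            self.child[node][q] = self._new(ncx, ncy, half)
        child = self.child[node][q]
        self.m[child] += self.mass[j]
        self.mx[child] += self.mass[j] * self.pos[j][0]
        self.my[child] += self.mass[j] * self.pos[j][1]
        if self.point[child] == -1 and all(c == -1 for c in self.child[child]) \
                and self.m[child] == self.mass[j]:
            self.point[child] = j
        else:  # only possible through repeated degeneracy; recurse
            if self.point[child] >= 0 and self.size[child] >= 1e-12:
                k = self.point[child]
                self.point[child] = -2
                self._push_down(child, k)

    def force_on(self, i, kr, theta) -> tuple:
        x, y = self.pos[i]
        mi = self.mass[i]
        fx = fy = 0.0
        stack = [0]
        theta2 = theta * theta
        while stack:
            node = stack.pop()
            if self.m[node] == 0.0:
                continue
            leaf = all(c == -1 for c in self.child[node])
            if leaf and self.point[node] == i:
                continue
            comx = self.mx[node] / self.m[node]
            comy = self.my[node] / self.m[node]
            dx = x - comx
            dy = y - comy
            d2 = dx * dx + dy * dy
            if leaf or self.size[node] * self.size[node] < theta2 * d2:
                if d2 < 1e-18:
                    continue  # coincident aggregate (may contain i): skip
                coef = kr * mi * self.m[node] / d2
                fx += coef * dx
                fy += coef * dy
            else:
                for c in self.child[node]:
                    if c != -1:
                        stack.append(c)
        return fx, fy


def _repulsion_barnes_hut(pos, mass, kr, theta, rng) -> np.ndarray:
    tree = _QuadTree(pos, mass)
    out = np.empty_like(pos)
    for i in range(len(pos)):
        out[i] = tree.force_on(i, kr, theta)
    return out


def compute_forces(pos: np.ndarray, edges: np.ndarray, mass: np.ndarray,
                   params: LayoutParams, rng: np.random.Generator,
                   exact: bool) -> np.ndarray:
    """Total force on every node (attraction + repulsion + gravity)."""
    n = len(pos)
    F = (_repulsion_exact if exact else
         lambda p, m, k, r: _repulsion_barnes_hut(p, m, k, params.theta, r)
         )(pos, mass, params.kr, rng)

    if len(edges):
        delta = pos[edges[:, 1]] - pos[edges[:, 0]]  # toward the neighbour
        np.add.at(F, edges[:, 0], delta)
        np.add.at(F, edges[:, 1], -delta)

    if params.gravity > 0:
        dist = np.linalg.norm(pos, axis=1)
        ok = dist > 1e-12
        g = np.zeros_like(pos)
        g[ok] = -params.gravity * mass[ok, None] * pos[ok] / dist[ok, None]
        F += g
    return F


def run_layout(graph: nx.Graph, params: LayoutParams | None = None) -> Layout:
    """Run the force-directed layout for a fixed number of iterations.

    Deterministic given the seed, the parameters and the graph.  Initial
    positions are uniform in a disc.  Raises if coordinates stop being
    finite (diverging configuration).
    """
    params = params or LayoutParams()
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    node_ids = list(graph.nodes())
    index = {v: i for i, v in enumerate(node_ids)}
    n = len(node_ids)
    degrees = np.array([graph.degree(v) for v in node_ids], dtype=float)
    mass = degrees + 1.0
    edges = np.array([[index[u], index[v]] for u, v in graph.edges()],
                     dtype=int).reshape(-1, 2)

    exact = not (params.barnes_hut if params.barnes_hut is not None
                 else n > params.barnes_hut_threshold)

    rng = np.random.default_rng(params.seed)
    r = params.init_radius * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])

    prev_F = np.zeros_like(pos)
    global_speed = 1.0
    swing_hist, tract_hist = [], []

    for it in range(params.iterations):
        F = compute_forces(pos, edges, mass, params, rng, exact)
        swinging = np.linalg.norm(F - prev_F, axis=1)
        traction = np.linalg.norm(F + prev_F, axis=1) / 2.0
        g_swing = float(mass @ swinging)
        g_tract = float(mass @ traction)
        swing_hist.append(g_swing)
        tract_hist.append(g_tract)

        if g_swing > 0:
            target = params.jitter_tolerance * g_tract / g_swing
            global_speed = min(target, 1.5 * global_speed)

        node_speed = params.ks * global_speed / (1.0 + global_speed * np.sqrt(swinging))
        fmag = np.linalg.norm(F, axis=1)
        cap = np.where(fmag > 1e-12, params.ks_max / np.maximum(fmag, 1e-12), np.inf)
        node_speed = np.minimum(node_speed, cap)
        pos = pos + node_speed[:, None] * F
        prev_F = F

        if not np.isfinite(pos).all():
            raise RuntimeError(
                f"layout diverged at iteration {it}: non-finite coordinates"
                f" (global swinging {g_swing:.3g}, traction {g_tract:.3g})"
            )

    return Layout(node_ids=node_ids, positions=pos,
                  swinging=np.asarray(swing_hist), traction=np.asarray(tract_hist))


def plot_layout(layout: Layout, colors=None, ax=None, **scatter_kw):
    """Optional scatter rendering of a layout, coloured e.g. by quartile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(layout.positions[:, 0], layout.positions[:, 1],
                    c=colors, s=scatter_kw.pop("s", 8), **scatter_kw)
    ax.set_aspect("equal")
    if colors is not None:
        ax.figure.colorbar(sc, ax=ax, label="group")
    return ax
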