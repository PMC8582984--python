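"""Force model, equilibrium physics and layout invariants."""

import itertools

import numpy as np
import networkx as nx
import pytest

from perceptrisk.layout import (LayoutParams, attraction_force, compute_forces,
                                repulsion_force, run_layout,
                                _repulsion_barnes_hut, _repulsion_exact)


class TestForceFunctions:
    def test_attraction_linear(self):
        assert attraction_force(0) == 0
        assert attraction_force(2) == 2
        assert attraction_force(5.0) == 2.5 * attraction_force(2.0)

    def test_repulsion_degree_weighting(self):
        assert repulsion_force(0, 0, 1.0, 1.0) == 1.0
        assert repulsion_force(1, 1, 2.0, 1.0) == 2.0

    def test_repulsion_inverse_distance(self):
        f1 = repulsion_force(2, 3, 1.0, 2.0)
        assert repulsion_force(2, 3, 2.0, 2.0) == pytest.approx(f1 / 2)

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError):
            attraction_force(-1)
        with pytest.raises(ValueError):
            repulsion_force(0, 0, 0.0, 1.0)


class TestEquilibrium:
    @pytest.mark.parametrize("kr", [1.0, 2.0, 4.0])
    def test_two_node_separation_is_2_sqrt_kr(self, kr):
        """Linear attraction d balances kr*(1+1)(1+1)/d at d = 2*sqrt(kr)."""
        g = nx.Graph()
        g.add_edge(0, 1)
        layout = run_layout(g, LayoutParams(kr=kr, gravity=0.0,
                                            iterations=2000, seed=3))
        sep = np.linalg.norm(layout.positions[0] - layout.positions[1])
        assert sep == pytest.approx(2 * np.sqrt(kr), rel=0.02)

    def test_isolated_node_pulled_toward_origin(self):
        g = nx.Graph()
        g.add_node(0)
        params = LayoutParams(gravity=1.0, iterations=300, seed=2)
        rng = np.random.default_rng(params.seed)
        r0 = params.init_radius * np.sqrt(rng.uniform(0, 1, 1))[0]
        layout = run_layout(g, params)
        assert np.linalg.norm(layout.positions[0]) < r0

    def test_symmetric_triangle_stays_equilateral(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2)])
        layout = run_layout(g, LayoutParams(gravity=0.0, iterations=3000, seed=1))
        d = [np.linalg.norm(layout.positions[i] - layout.positions[j])
             for i, j in [(0, 1), (1, 2), (0, 2)]]
        assert max(d) - min(d) < 1e-6


def two_clique_graph(size=10):
    g = nx.Graph()
    a = list(range(size))
    b = list(range(size, 2 * size))
    g.add_edges_from(itertools.combinations(a, 2))
    g.add_edges_from(itertools.combinations(b, 2))
    g.add_edge(a[0], b[0])
    return g, a, b


def mean_dist(pos, ix, jx):
    return np.mean([np.linalg.norm(pos[i] - pos[j])
                    for i in ix for j in jx if i != j])


class TestLayoutStructure:
    def test_two_clique_benchmark(self):
        g, a, b = two_clique_graph()
        layout = run_layout(g, LayoutParams(iterations=1000, seed=0))
        pos = layout.positions
        within = (mean_dist(pos, a, a) + mean_dist(pos, b, b)) / 2
        between = mean_dist(pos, a, b)
        assert within < between

    def test_determinism(self):
        g, _, _ = two_clique_graph(6)
        p = LayoutParams(iterations=150, seed=42)
        l1 = run_layout(g, p)
        l2 = run_layout(g, LayoutParams(iterations=150, seed=42))
        assert np.array_equal(l1.positions, l2.positions)

    def test_diagnostics_recorded_each_iteration(self):
        g, _, _ = two_clique_graph(5)
        layout = run_layout(g, LayoutParams(iterations=77, seed=0))
        assert len(layout.swinging) == 77
        assert len(layout.traction) == 77
        assert np.isfinite(layout.swinging).all()

    def test_newtons_third_law_in_exact_mode(self):
        """With gravity off, all pairwise forces cancel: total force is zero."""
        g, _, _ = two_clique_graph(8)
        node_ids = list(g.nodes())
        idx = {v: i for i, v in enumerate(node_ids)}
        edges = np.array([[idx[u], idx[v]] for u, v in g.edges()])
        mass = np.array([g.degree(v) + 1.0 for v in node_ids])
        rng = np.random.default_rng(0)
        pos = rng.uniform(-5, 5, (len(node_ids), 2))
        params = LayoutParams(gravity=0.0)
        F = compute_forces(pos, edges, mass, params, rng, exact=True)
        assert np.abs(F.sum(axis=0)).max() < 1e-9

    def test_barnes_hut_matches_exact_distances(self):
        """Approximate repulsion reproduces the exact layout geometry."""
        g, _, _ = two_clique_graph(30)  # 60 nodes
        exact = run_layout(g, LayoutParams(iterations=300, seed=5,
                                           barnes_hut=False))
        approx = run_layout(g, LayoutParams(iterations=300, seed=5,
                                            barnes_hut=True, theta=0.3))
        de = np.linalg.norm(exact.positions[:, None] - exact.positions[None, :],
                            axis=2)
        da = np.linalg.norm(approx.positions[:, None] - approx.positions[None, :],
                            axis=2)
        iu = np.triu_indices_from(de, k=1)
        rel = np.abs(da[iu] - de[iu]) / de[iu]
        assert np.median(rel) < 0.05

    def test_barnes_hut_forces_close_to_exact(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(-10, 10, (300, 2))
        mass = rng.uniform(1, 5, 300)
        Fe = _repulsion_exact(pos, mass, 2.0, np.random.default_rng(0))
        Fb = _repulsion_barnes_hut(pos, mass, 2.0, 0.3, np.random.default_rng(0))
        rel = np.linalg.norm(Fe - Fb, axis=1) / np.linalg.norm(Fe, axis=1)
        assert np.median(rel) < 0.01

    def test_unsupported_variants_rejected(self):
        with pytest.raises(NotImplementedError):
            LayoutParams(linlog=True)
        with pytest.raises(NotImplementedError):
            LayoutParams(prevent_overlap=True)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_layout(nx.Graph())
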