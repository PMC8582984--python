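"""DBSCAN semantics vs a naive reference, eps suggestion and profiles."""

import numpy as np
import pandas as pd
import pytest

import perceptrisk as pr
from perceptrisk.clustering import (DbscanParams, NOISE, dbscan,
                                    heterogeneity_summary, profile_clusters,
                                    relabel_by_size, suggest_eps)


def naive_dbscan(pts, eps, min_pts):
    """Quadratic reference: full distance matrix, no spatial index."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    nb = [np.nonzero(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(x) >= min_pts for x in nb])
    lab = np.full(n, -1)
    comp = 0
    for s in range(n):
        if not core[s] or lab[s] != -1:
            continue
        stack = [s]
        lab[s] = comp
        while stack:
            i = stack.pop()
            for j in nb[i]:
                if core[j] and lab[j] == -1:
                    lab[j] = comp
                    stack.append(j)
        comp += 1
    for i in range(n):
        if core[i] or lab[i] != -1:
            continue
        core_nb = [j for j in sorted(nb[i]) if core[j]]
        if core_nb:
            lab[i] = lab[core_nb[0]]
    return relabel_by_size(lab)


class TestDbscan:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (20, 2)),
                         rng.normal((100, 0), 0.05, (20, 2))])
        labels = dbscan(pts, DbscanParams(eps=1.0, min_pts=5))
        assert labels.max() == 2
        assert (labels != NOISE).all()

    def test_isolated_point_is_noise(self):
        pts = np.array([[0.0, 0.0], [100.0, 100.0], [100.1, 100.0],
                        [100.0, 100.1]])
        labels = dbscan(pts, DbscanParams(eps=0.5, min_pts=2))
        assert labels[0] == NOISE
        assert labels[1] != NOISE

    @pytest.mark.parametrize("eps,min_pts", [(0.5, 3), (0.8, 5), (1.0, 10),
                                             (1.5, 4), (0.3, 2), (2.0, 15)])
    def test_matches_naive_reference(self, eps, min_pts):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (200, 2))
        assert np.array_equal(dbscan(pts, DbscanParams(eps, min_pts)),
                              naive_dbscan(pts, eps, min_pts))

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 5, (300, 2))
        labels = dbscan(pts, DbscanParams(0.4, 5))
        sizes = np.bincount(labels)
        assert sizes.sum() == 300
        # cluster ids contiguous 1..C with non-increasing sizes
        assert (np.diff(sizes[1:]) <= 0).all()

    def test_permutation_changes_only_numbering(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 5, (150, 2))
        perm = rng.permutation(150)
        a = dbscan(pts, DbscanParams(0.5, 4))
        b = dbscan(pts[perm], DbscanParams(0.5, 4))
        # compare partitions via co-membership of a few hundred random pairs
        inv = np.empty(150, dtype=int)
        inv[perm] = np.arange(150)
        b_aligned = b[inv]
        pairs = rng.integers(0, 150, (500, 2))
        for i, j in pairs:
            assert ((a[i] == a[j]) == (b_aligned[i] == b_aligned[j])) or \
                NOISE in (a[i], a[j])


class TestSuggestEps:
    def test_unit_grid(self):
        gx, gy = np.meshgrid(np.arange(10), np.arange(10))
        grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        eps, curve = suggest_eps(grid, k=4)
        assert eps == pytest.approx(1.0, rel=0.10)
        assert len(curve) == 100

    def test_below_blob_separation(self):
        rng = np.random.default_rng(1)
        blobs = np.vstack([rng.normal(0, 0.5, (50, 2)),
                           rng.normal((50, 50), 0.5, (50, 2))])
        eps, _ = suggest_eps(blobs, k=5)
        assert 0 < eps < 50

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="more than k"):
            suggest_eps(np.zeros((5, 2)), k=5)


class TestProfiles:
    def test_single_cluster_zero_deltas_full_coverage(self, small_survey):
        responses = small_survey.responses
        n = len(responses)
        quartiles = pr.assign_quartiles(
            pr.risk_score(pr.encode_risk_matrix(responses)))
        assignment = np.ones(n, dtype=int)
        prof = profile_clusters(assignment, responses, quartiles, top_k=1)
        assert prof.coverage == 1.0
        cluster_rows = prof.table[prof.table["group"] == "cluster_1"]
        assert np.allclose(cluster_rows["delta_vs_population"], 0.0)

    def test_toy_delta_arithmetic(self, small_survey):
        responses = small_survey.responses
        df = responses.data
        n = len(df)
        # engineer a 10-member cluster with 7 women in a known population
        female = (df["gender"] == "female").to_numpy()
        women = np.nonzero(female)[0][:7]
        men = np.nonzero(~female)[0][:3]
        assignment = np.zeros(n, dtype=int)
        assignment[np.concatenate([women, men])] = 1
        quartiles = pr.assign_quartiles(
            pr.risk_score(pr.encode_risk_matrix(responses)))
        prof = profile_clusters(assignment, responses, quartiles, top_k=1)
        row = prof.table[(prof.table["group"] == "cluster_1") &
                         (prof.table["attribute"] == "female_pct")].iloc[0]
        pop_female = 100.0 * female.mean()
        assert row["percent"] == pytest.approx(70.0)
        assert row["delta_vs_population"] == pytest.approx(70.0 - pop_female)

    def test_profile_conservation(self, small_survey):
        """Size-weighted cluster prevalences reconstruct the population's."""
        responses = small_survey.responses
        n = len(responses)
        rng = np.random.default_rng(0)
        assignment = relabel_by_size(rng.integers(0, 4, n) - 1)  # noise + 3 clusters
        quartiles = pr.assign_quartiles(
            pr.risk_score(pr.encode_risk_matrix(responses)))
        prof = profile_clusters(assignment, responses, quartiles, top_k=3)
        t = prof.table
        pop = t[t["group"] == "population"].set_index("attribute")["percent"]
        parts = t[t["group"] != "population"]
        recon = (parts["percent"] * parts["size"]).groupby(
            parts["attribute"]).sum() / n
        assert np.allclose(recon[pop.index], pop, atol=1e-9)

    def test_top_k_beyond_cluster_count_warns(self, small_survey):
        responses = small_survey.responses
        quartiles = pr.assign_quartiles(
            pr.risk_score(pr.encode_risk_matrix(responses)))
        assignment = np.ones(len(responses), dtype=int)
        with pytest.warns(UserWarning, match="exceeds"):
            prof = profile_clusters(assignment, responses, quartiles, top_k=13)
        assert prof.coverage == 1.0


class TestHeterogeneity:
    def test_single_cluster_zero_entropy(self):
        assignment = np.ones(40, dtype=int)
        quartiles = np.repeat([1, 2, 3, 4], 10)
        het = heterogeneity_summary(assignment, quartiles).set_index("quartile")
        assert het.loc[4, "normalized_entropy"] == 0.0
        assert het.loc[4, "largest_cluster_share"] == 1.0

    def test_even_split_gives_unit_entropy(self):
        assignment = np.tile([1, 2, 3, 4], 10)
        quartiles = np.ones(40, dtype=int)
        het = heterogeneity_summary(assignment, quartiles).set_index("quartile")
        assert het.loc[1, "normalized_entropy"] == pytest.approx(1.0)
        assert het.loc[1, "n_major_clusters"] == 4
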