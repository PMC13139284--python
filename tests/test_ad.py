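"""Applicability-domain and projection-validation contracts, with
brute-force oracles for the embedding metrics."""

import numpy as np
import pandas as pd
import pytest

from mtqsar import ad, featurize, simdata


def _fp(on, n=32):
    v = np.zeros(n, dtype=np.uint8)
    v[list(on)] = 1
    return v


class TestKnnMeanDistance:
    def test_identical_training_member_k1(self):
        q = _fp({1, 2, 3})
        train = np.stack([q, _fp({9, 10})])
        assert ad.knn_mean_distance(q, train, k=1) == 0.0

    def test_hand_computed_mean_of_two(self):
        # distances to query {0,1,2,3}: same->0; one-off->0.4; disjoint->1
        q = _fp({0, 1, 2, 3})
        train = np.stack([_fp({0, 1, 2, 3}), _fp({0, 1, 2, 4}),
                          _fp({10, 11})])
        assert ad.knn_mean_distance(q, train, k=2) == pytest.approx(0.2)

    def test_monotone_in_k(self, small_fps):
        q = small_fps[0]
        train = small_fps[1:40]
        vals = [ad.knn_mean_distance(q, train, k) for k in range(1, 10)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_k_beyond_training_raises(self):
        with pytest.raises(ValueError):
            ad.knn_mean_distance(_fp({1}), np.stack([_fp({1})]), k=2)


class TestKSweep:
    def test_mean_non_decreasing(self, small_fps):
        table = ad.k_sweep(small_fps, ks=range(3, 30, 2))
        assert np.all(np.diff(table["mean"]) >= -1e-12)
        assert table["mean"].iloc[0] <= table["mean"].iloc[-1]

    def test_variance_stable_on_homogeneous_cloud(self):
        # uniform-density random bit vectors: no dense or sparse regions
        rng = np.random.default_rng(0)
        fps = (rng.random((200, 256)) < 0.3).astype(np.uint8)
        table = ad.k_sweep(fps, ks=range(3, 30, 2))
        ratio = table["variance"].max() / table["variance"].min()
        assert ratio < 2.0

    def test_identical_molecules_give_zero_means(self):
        fps = np.tile(_fp({1, 2, 3}), (40, 1))
        table = ad.k_sweep(fps, ks=[3, 5])
        assert np.allclose(table["mean"], 0.0)

    def test_training_too_small_raises(self, small_fps):
        with pytest.raises(ValueError):
            ad.k_sweep(small_fps[:10], ks=[3, 29])


class TestFitThreshold:
    def test_quantile_of_linear_ramp(self, small_fps):
        dists = np.array([0.01 * i for i in range(1, 101)])
        m = ad.fit_threshold(small_fps, k=3, coverage=0.95, distances=dists)
        assert 0.95 < m.threshold < 0.96

    def test_all_equal_distances(self, small_fps):
        m = ad.fit_threshold(small_fps, distances=np.full(50, 0.37))
        assert m.threshold == pytest.approx(0.37)

    def test_full_coverage_is_max(self, small_fps):
        dists = np.array([0.1, 0.5, 0.9, 0.2] * 10)
        m = ad.fit_threshold(small_fps, coverage=1.0, distances=dists)
        assert m.threshold == pytest.approx(0.9)

    def test_degenerate_all_zero_warns(self):
        fps = np.tile(_fp({1, 2}), (30, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            m = ad.fit_threshold(fps, k=3)
        assert m.threshold == 0.0

    def test_coverage_property_in_sample(self, small_fps):
        m = ad.fit_threshold(small_fps, k=3, coverage=0.95)
        inside = ad.classify_insample(m)["inside_ad"].mean()
        assert inside == pytest.approx(0.95, abs=0.02)


class TestClassify:
    def test_training_member_is_inside(self, small_fps):
        m = ad.fit_threshold(small_fps, k=3)
        res = ad.classify(m, small_fps[:5])
        assert res["inside_ad"].all()

    def test_remote_outlier_is_outside(self, small_fps):
        m = ad.fit_threshold(small_fps, k=3)
        # perfluorinated chain: a fragment vocabulary disjoint from the
        # generator's aromatic/aliphatic cores
        outlier = featurize.ecfp("FC(F)(F)C(F)(F)C(F)(F)C(F)(F)F").bits
        res = ad.classify(m, outlier)
        assert not res["inside_ad"].iloc[0]
        assert res["mean_knn_distance"].iloc[0] > m.threshold

    def test_boundary_equality_counts_as_inside(self, small_fps):
        m = ad.fit_threshold(small_fps, k=3)
        res = ad.classify(m, small_fps)
        on_boundary = np.isclose(res["mean_knn_distance"], m.threshold)
        assert res.loc[on_boundary, "inside_ad"].all() or not on_boundary.any()

    def test_monotone_in_threshold(self, small_fps):
        m = ad.fit_threshold(small_fps, k=3)
        res_hi = ad.classify(m, small_fps[:30])
        import dataclasses
        m_lo = dataclasses.replace(m, threshold=m.threshold / 2)
        res_lo = ad.classify(m_lo, small_fps[:30])
        # lowering the threshold never converts outside to inside
        assert not (res_lo["inside_ad"] & ~res_hi["inside_ad"]).any()


# -- embedding metrics -------------------------------------------------------

def _brute_trustworthiness(D, emb, k):
    """Direct implementation of the trustworthiness functional."""
    n = D.shape[0]
    order_orig = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1)
    ranks = np.empty((n, n), dtype=int)
    for i in range(n):
        ranks[i, order_orig[i]] = np.arange(n)
    Demb = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    order_emb = np.argsort(Demb + np.diag(np.full(n, np.inf)), axis=1)
    total = 0.0
    for i in range(n):
        orig_nn = set(order_orig[i, :k])
        for j in order_emb[i, :k]:
            if j not in orig_nn:
                total += ranks[i, j] - k + 1
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * total


def _brute_procrustes_2d(ref, cand):
    """Independent 2-D Procrustes via closed-form rotation/reflection."""
    def standardize(M):
        M = M - M.mean(axis=0)
        return M / np.linalg.norm(M)
    X, Y = standardize(np.asarray(ref)), standardize(np.asarray(cand))
    M = Y.T @ X
    rot = np.hypot(M[0, 0] + M[1, 1], M[1, 0] - M[0, 1])
    refl = np.hypot(M[0, 0] - M[1, 1], M[0, 1] + M[1, 0])
    return 1.0 - max(rot, refl) ** 2


def _brute_silhouette(emb, labels):
    emb = np.asarray(emb, dtype=float)
    labels = np.asarray(labels)
    D = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(len(emb)):
        same = (labels == labels[i])
        same[i] = False
        if not same.any():
            vals.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestTrustworthiness:
    def test_rank_preserving_map_scores_one(self):
        rng = np.random.default_rng(0)
        pts = rng.random((25, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        assert ad.trustworthiness(D, pts, n_neighbors=5) == pytest.approx(1.0)

    def test_shuffled_embedding_scores_lower(self):
        rng = np.random.default_rng(1)
        pts = rng.random((30, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        shuffled = pts[rng.permutation(30)]
        assert (ad.trustworthiness(D, shuffled, 5)
                < ad.trustworthiness(D, pts, 5))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.random((30, 4))
        emb = rng.random((30, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for k in (3, 5, 7):
            assert ad.trustworthiness(D, emb, k) == pytest.approx(
                _brute_trustworthiness(D, emb, k), abs=1e-12)

    def test_neighbor_bound_enforced(self):
        D = np.zeros((10, 10))
        with pytest.raises(ValueError):
            ad.trustworthiness(D, np.zeros((10, 2)), n_neighbors=5)


class TestProcrustes:
    def test_similarity_transform_gives_zero(self):
        rng = np.random.default_rng(3)
        ref = rng.random((12, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        cand = 2.5 * ref @ R.T + np.array([3.0, -1.0])
        assert ad.procrustes_disparity(ref, cand) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_single_moved_point_is_positive(self):
        rng = np.random.default_rng(4)
        ref = rng.random((10, 2))
        cand = ref.copy()
        cand[0] += 1.0
        assert ad.procrustes_disparity(ref, cand) > 0.0

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ref, cand = rng.random((5, 2)), rng.random((5, 2))
            assert ad.procrustes_disparity(ref, cand) == pytest.approx(
                _brute_procrustes_2d(ref, cand), abs=1e-12)

    def test_degenerate_embedding_raises(self):
        with pytest.raises(ValueError):
            ad.procrustes_disparity(np.random.rand(5, 2), np.ones((5, 2)))


class TestSilhouette:
    def test_tight_far_clusters_near_one(self):
        rng = np.random.default_rng(6)
        emb = np.vstack([rng.normal(0, 0.01, (20, 2)),
                         rng.normal(10, 0.01, (20, 2))])
        labels = [0] * 20 + [1] * 20
        assert ad.silhouette(emb, labels) > 0.9

    def test_random_labels_near_zero(self):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            emb = rng.normal(0, 1, (60, 2))
            labels = rng.integers(0, 2, 60)
            vals.append(ad.silhouette(emb, labels))
        assert abs(np.mean(vals)) < 0.1

    def test_coincident_clusters_non_positive(self):
        rng = np.random.default_rng(7)
        emb = np.tile(rng.normal(0, 1, (15, 2)), (2, 1))
        labels = [0] * 15 + [1] * 15
        assert ad.silhouette(emb, labels) <= 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        emb = rng.random((24, 2))
        labels = rng.integers(0, 3, 24)
        assert ad.silhouette(emb, labels) == pytest.approx(
            _brute_silhouette(emb, labels), abs=1e-12)

    def test_single_label_raises(self):
        with pytest.raises(ValueError):
            ad.silhouette(np.random.rand(5, 2), [1] * 5)


@pytest.fixture(scope="module")
def cluster_fixture():
    """Two structurally separated families with a Tanimoto distance
    matrix: aromatic amines vs fluorinated aliphatics."""
    fam_a = ["CN(C)c1ccccc1", "CCN(C)c1ccccc1", "CN(C)c1ccccc1C",
             "CN(C)c1ccc(C)cc1", "CCN(CC)c1ccccc1", "CN(C)c1cccc(C)c1",
             "CN(C)c1ccc(CC)cc1", "CCN(C)c1ccc(C)cc1"] * 4
    fam_b = ["FC(F)(F)CC(F)(F)F", "FC(F)(F)CCC(F)(F)F", "FC(F)(F)CF",
             "FC(F)(F)CCF", "FCC(F)(F)CF", "FC(F)(F)C(F)(F)F",
             "FCCC(F)(F)F", "FCC(F)CF"] * 4
    mols = fam_a[:25] + fam_b[:25]
    labels = [0] * 25 + [1] * 25
    X = featurize.fingerprint_matrix(mols)
    # perturb duplicates apart is unnecessary: distances may be zero
    D = featurize.tanimoto_distance_matrix(X)
    return D, labels


class TestTsneProject:
    def test_seeded_determinism(self, cluster_fixture):
        D, _ = cluster_fixture
        a = ad.tsne_project(D, perplexity=10, seed=42)
        b = ad.tsne_project(D, perplexity=10, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self, cluster_fixture):
        D, labels = cluster_fixture
        emb = ad.tsne_project(D, perplexity=10, seed=0)
        assert ad.silhouette(emb, labels) > 0.5

    def test_tiny_matrix_smoke(self):
        rng = np.random.default_rng(0)
        pts = rng.random((10, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = ad.tsne_project(D, perplexity=2, seed=1)
        assert emb.shape == (10, 2) and np.all(np.isfinite(emb))

    def test_infeasible_perplexity_raises(self):
        with pytest.raises(ValueError):
            ad.tsne_project(np.zeros((5, 5)), perplexity=10, seed=0)


class TestValidateProjections:
    def test_sweep_bookkeeping(self, cluster_fixture):
        D, labels = cluster_fixture
        reports, selected = ad.validate_projections(
            D, labels, perplexities=(5, 10), seeds=(0, 42, 99), max_iter=250)
        assert len(reports) == 6
        refs = [r for r in reports if r.is_reference]
        assert len(refs) == 2
        assert all(r.procrustes_disparity is None for r in refs)
        assert all(r.seed == 0 for r in refs)  # lowest seed is the reference
        assert not selected.is_reference

    def test_forced_identical_embeddings_are_stable(self, cluster_fixture,
                                                    monkeypatch):
        D, labels = cluster_fixture
        fixed = np.random.default_rng(0).random((D.shape[0], 2))
        monkeypatch.setattr(ad, "tsne_project",
                            lambda *a, **k: fixed.copy())
        reports, _ = ad.validate_projections(
            D, labels, perplexities=(5, 10), seeds=(0, 42, 99))
        for r in reports:
            assert r.stable_flag
            if not r.is_reference:
                assert r.procrustes_disparity == pytest.approx(0.0, abs=1e-12)

    def test_selection_deterministic(self, cluster_fixture):
        D, labels = cluster_fixture
        _, sel_a = ad.validate_projections(D, labels, perplexities=(5, 10),
                                           seeds=(0, 42), max_iter=250)
        _, sel_b = ad.validate_projections(D, labels, perplexities=(5, 10),
                                           seeds=(0, 42), max_iter=250)
        assert (sel_a.perplexity, sel_a.seed) == (sel_b.perplexity, sel_b.seed)

    def test_report_frame_shape(self, cluster_fixture):
        D, labels = cluster_fixture
        reports, _ = ad.validate_projections(D, labels, perplexities=(5,),
                                             seeds=(0, 42), max_iter=250)
        frame = ad.reports_to_frame(reports)
        assert list(frame.columns) == [
            "perplexity", "seed", "trustworthiness", "procrustes_disparity",
            "silhouette", "trustworthy_flag", "stable_flag", "is_reference"]
        assert frame["procrustes_disparity"].isna().sum() == 1
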