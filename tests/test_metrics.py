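"""Metric suite: closed forms, null/alternative simulations, oracles."""

from itertools import combinations

import numpy as np
import pytest

from fedbatch.metrics import (
    EmbeddingView,
    MetricResult,
    asw_batch,
    asw_cell,
    compare_methods,
    ebm_score,
    evaluate_embedding,
    f1_from_counts,
    graph_connectivity,
    ilf1_score,
    isolated_labels,
    kbet_acceptance,
    knn_accuracy,
    ari_score,
    lisi,
    louvain_clusters,
    nmi_score,
    pca_embed,
    perf_diff,
)


def _mixed_cloud(n=1000, n_batches=2, d=5, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(n, d))
    batches = rng.integers(0, n_batches, size=n).astype(str)
    types = np.array(["t"] * n, dtype=object)
    return EmbeddingView(coords, batches, types)


def _separated_batches(n=600, d=5, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(n, d))
    coords[n // 2 :, 0] += gap
    batches = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
    types = np.array(["t"] * n, dtype=object)
    return EmbeddingView(coords, batches, types)


def _blobs(sizes, gap=30.0, d=4, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    coords, types = [], []
    for i, s in enumerate(sizes):
        c = rng.normal(size=(s, d))
        c[:, 0] += i * gap
        coords.append(c)
        types += [labels[i] if labels else f"t{i}"] * s
    batches = rng.integers(0, 2, size=sum(sizes)).astype(str)
    return EmbeddingView(np.vstack(coords), batches, np.array(types, dtype=object))


class TestPCA:
    def test_variance_ordering_and_duplicates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 10)) * np.arange(1, 11)
        emb = pca_embed(X, ["A"] * 80, ["t"] * 80, n_components=5)
        var = emb.coords.var(axis=0)
        assert all(var[i] >= var[i + 1] - 1e-12 for i in range(4))
        X2 = np.vstack([X, X[:3]])
        emb2 = pca_embed(X2, ["A"] * 83, ["t"] * 83, n_components=5)
        np.testing.assert_allclose(emb2.coords[:3], emb2.coords[-3:], atol=1e-10)

    def test_degenerate_rank_warns_and_truncates(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        with pytest.warns(UserWarning, match="components"):
            emb = pca_embed(X, ["A"] * 10, ["t"] * 10, n_components=20)
        assert emb.coords.shape[1] == 3


class TestKbet:
    def test_well_mixed_cloud_accepted(self):
        assert kbet_acceptance(_mixed_cloud()) >= 0.9

    def test_separated_batches_rejected(self):
        assert kbet_acceptance(_separated_batches()) <= 0.05

    def test_single_batch_convention(self):
        emb = EmbeddingView(np.zeros((10, 2)), ["A"] * 10, ["t"] * 10)
        assert kbet_acceptance(emb) == 1.0

    def test_small_neighborhoods_skipped(self):
        emb = _mixed_cloud(n=200, n_batches=4)
        with pytest.warns(UserWarning, match="skipped"):
            kbet_acceptance(emb, k_fracs=(0.01, 0.25))


class TestLisi:
    def test_pure_neighborhood_scores_one(self):
        emb = _separated_batches(gap=500.0)
        scores = lisi(emb, emb.batch_labels, perplexity=20)
        assert scores.mean() < 1.05

    def test_well_mixed_two_batches_near_two(self):
        emb = _mixed_cloud(n=1000)
        scores = lisi(emb, emb.batch_labels)
        assert 1.8 <= scores.mean() <= 2.0

    def test_perplexity_reduced_with_warning(self):
        emb = _mixed_cloud(n=60)
        with pytest.warns(UserWarning, match="perplexity"):
            lisi(emb, emb.batch_labels, perplexity=30)

    def test_restriction_subsets_cells(self):
        emb = _mixed_cloud(n=300)
        mask = np.arange(300) < 200
        scores = lisi(emb, emb.batch_labels, perplexity=20, restrict_to=mask)
        assert len(scores) == 200


class TestASW:
    def test_separated_types_score_high(self):
        emb = _blobs([50, 50])
        assert asw_cell(emb) >= 0.9

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(3)
        emb = EmbeddingView(
            rng.normal(size=(400, 4)),
            ["A"] * 400,
            rng.integers(0, 2, size=400).astype(str),
        )
        assert abs(asw_cell(emb) - 0.5) < 0.05

    def test_single_type_rejected(self):
        emb = _mixed_cloud()
        with pytest.raises(ValueError):
            asw_cell(emb)

    def test_batch_asw_mixed_near_one_separated_near_zero(self):
        mixed = _mixed_cloud(n=500)
        assert asw_batch(mixed) >= 0.85
        sep = _separated_batches(gap=100.0)
        assert asw_batch(sep) <= 0.2

    def test_no_type_spanning_batches_rejected(self):
        emb = EmbeddingView(
            np.random.default_rng(0).normal(size=(20, 2)),
            ["A"] * 10 + ["B"] * 10,
            ["t1"] * 10 + ["t2"] * 10,
        )
        with pytest.raises(ValueError):
            asw_batch(emb)


class TestClustering:
    def test_two_blobs_found_and_deterministic(self):
        emb = _blobs([40, 40])
        labels = louvain_clusters(emb, resolution=1.0, seed=0)
        assert len(labels) == 80
        assert len(np.unique(labels)) == 2
        again = louvain_clusters(emb, resolution=1.0, seed=0)
        np.testing.assert_array_equal(labels, again)

    def test_ari_perfect_on_planted_partition(self):
        emb = _blobs([40, 40, 40])
        assert ari_score(emb) == pytest.approx(1.0)

    def test_ari_matches_pair_counting_oracle(self):
        # brute-force pair-count ARI on a 30-cell instance
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 3, size=30)
        n = 30
        same_a = {(i, j) for i, j in combinations(range(n), 2) if a[i] == a[j]}
        same_b = {(i, j) for i, j in combinations(range(n), 2) if b[i] == b[j]}
        n11 = len(same_a & same_b)
        n00 = len(set(combinations(range(n), 2)) - same_a - same_b)
        total = n * (n - 1) / 2
        expected_index = len(same_a) * len(same_b) / total
        max_index = (len(same_a) + len(same_b)) / 2
        oracle = (n11 - expected_index) / (max_index - expected_index)
        assert adjusted_rand_score(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_nmi_maximum_over_grid(self):
        emb = _blobs([50, 50, 50])
        assert nmi_score(emb) == pytest.approx(1.0)
        # grid maximum at least the value at resolution 1.0
        from sklearn.metrics import normalized_mutual_info_score

        at_one = normalized_mutual_info_score(
            emb.type_labels.astype(str),
            louvain_clusters(emb, resolution=1.0, seed=0),
            average_method="arithmetic",
        )
        assert nmi_score(emb) >= at_one - 1e-12


class TestEBM:
    def test_pure_neighborhoods_zero(self):
        assert ebm_score(_separated_batches(gap=500.0)) == pytest.approx(0.0)

    def test_well_mixed_high(self):
        assert ebm_score(_mixed_cloud(n=1000)) >= 0.9

    def test_single_batch_warns_zero(self):
        emb = EmbeddingView(np.random.default_rng(0).normal(size=(50, 3)),
                            ["A"] * 50, ["t"] * 50)
        with pytest.warns(UserWarning):
            assert ebm_score(emb) == 0.0


class TestILF1:
    def test_f1_closed_form(self):
        # precision 0.5, recall 1.0 -> 2/3
        assert f1_from_counts(10, 20, 10) == pytest.approx(2 / 3)
        assert f1_from_counts(0, 5, 5) == 0.0

    def test_pure_complete_cluster_scores_one(self):
        # isolated type forms its own far blob; batches arranged so t2 is
        # present in fewer batches than the others
        emb = _blobs([60, 60, 40], labels=["t0", "t1", "iso"])
        emb.batch_labels[emb.type_labels == "iso"] = "0"
        assert isolated_labels(emb.type_labels, emb.batch_labels) == ["iso"]
        assert ilf1_score(emb) == pytest.approx(1.0)

    def test_matches_exhaustive_cluster_scan(self):
        emb = _blobs([20, 20], labels=["t0", "iso"])
        emb.batch_labels[emb.type_labels == "iso"] = "0"
        got = ilf1_score(emb, resolutions=(1.0,))
        clusters = louvain_clusters(emb, resolution=1.0, seed=0)
        in_label = emb.type_labels.astype(str) == "iso"
        best = max(
            f1_from_counts(
                int(((clusters == c) & in_label).sum()),
                int((clusters == c).sum()),
                int(in_label.sum()),
            )
            for c in np.unique(clusters)
        )
        assert got == pytest.approx(best)

    def test_no_isolated_labels_is_an_error(self):
        emb = _blobs([30, 30])
        with pytest.raises(ValueError, match="isolated"):
            ilf1_score(emb)


class TestGraphConnectivity:
    def test_tight_blobs_fully_connected(self):
        assert graph_connectivity(_blobs([40, 40])) == pytest.approx(1.0)

    def test_split_type_scores_lcc_fraction(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(10, 3)) + 1000.0
        emb = EmbeddingView(np.vstack([a, b]), ["A"] * 40, ["t"] * 40)
        assert graph_connectivity(emb, k=5) == pytest.approx(30 / 40)

    def test_singleton_type_scores_one(self):
        emb = EmbeddingView(np.zeros((3, 2)), ["A"] * 3, ["t", "t", "solo"])
        assert graph_connectivity(emb, k=1) == pytest.approx(1.0)


class TestKnnAccuracy:
    def test_separated_types_perfect(self):
        assert knn_accuracy(_blobs([60, 60])) == pytest.approx(1.0)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(1)
        emb = EmbeddingView(
            rng.normal(size=(800, 4)), ["A"] * 800, rng.integers(0, 2, 800).astype(str)
        )
        assert abs(knn_accuracy(emb) - 0.5) < 0.05

    def test_macro_average_weighs_rare_type_equally(self):
        # rare type far away and pure; majority type noisy
        rng = np.random.default_rng(2)
        coords = np.vstack([rng.normal(size=(180, 2)), rng.normal(size=(20, 2)) + 100])
        types = np.array(["maj"] * 180 + ["rare"] * 20, dtype=object)
        emb = EmbeddingView(coords, ["A"] * 200, types)
        per_cell = []
        from fedbatch.metrics import _knn_indices

        idx = _knn_indices(coords, 15)
        per_cell = (types[idx] == types[:, None]).mean(axis=1)
        macro = 0.5 * (per_cell[:180].mean() + per_cell[180:].mean())
        assert knn_accuracy(emb) == pytest.approx(macro)


class TestComparisonHarness:
    def test_perf_diff_antisymmetry(self):
        a, b = MetricResult("nmi", 0.8), MetricResult("nmi", 0.6)
        assert perf_diff(a, b) == pytest.approx(0.2)
        assert perf_diff(b, a) == pytest.approx(-0.2)
        with pytest.raises(ValueError):
            perf_diff(MetricResult("nmi", 1), MetricResult("ari", 1))

    def test_identical_samples_not_significant(self):
        res = {("nmi", "d1"): [0.5, 0.5, 0.5]}
        table = compare_methods(res, res)
        assert table["p_raw"].iloc[0] == 1.0
        assert not table["significant"].iloc[0]

    def test_bh_monotone_in_rank_order(self):
        rng = np.random.default_rng(0)
        res_a = {(f"m{i}", "d"): rng.normal(0, 1, 6).tolist() for i in range(10)}
        res_b = {k: (np.asarray(v) + (0.1 * i)).tolist()
                 for i, (k, v) in enumerate(res_a.items())}
        table = compare_methods(res_a, res_b)
        t = table.sort_values("p_raw")
        assert t["p_adj"].is_monotonic_increasing
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()


class TestInvariances:
    def test_label_permutation_invariance(self):
        emb = _blobs([40, 40, 40])
        renamed = EmbeddingView(
            emb.coords,
            np.array([{"0": "X", "1": "Y"}[b] for b in emb.batch_labels], dtype=object),
            np.array([{"t0": "u2", "t1": "u0", "t2": "u1"}[t] for t in emb.type_labels],
                     dtype=object),
        )
        for fn in (kbet_acceptance, asw_cell, asw_batch, graph_connectivity, knn_accuracy,
                   ebm_score, ari_score, nmi_score):
            assert fn(emb) == pytest.approx(fn(renamed), abs=1e-9)

    def test_metric_ranges(self):
        emb = _blobs([40, 40])
        values = evaluate_embedding(emb, skip=("ilf1",))
        for name, v in values.items():
            if np.isnan(v):
                continue
            if name in ("ilisi", "clisi"):
                assert 1.0 <= v <= 2.0 + 1e-9
            else:
                assert -1e-9 <= v <= 1.0 + 1e-9
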