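"""Projected distances against brute-force oracles, and neighborhoods."""

import numpy as np
import pytest

from cnpdr import (
    CorrelationDataset,
    corr_diff_design,
    correlation_diff,
    find_neighbor_pairs,
    pair_design,
    pair_diff,
    sample_distances,
)
from cnpdr.datasets import devectorize_upper_triangle


def brute_pair_diff(dataset, i, j, p):
    return abs(dataset.feature_matrix[i, p] - dataset.feature_matrix[j, p])


def brute_correlation_diff(dataset, i, j, r):
    # double loop over the full reconstructed matrices
    mi = devectorize_upper_triangle(dataset.feature_matrix[i], dataset.n_rois)
    mj = devectorize_upper_triangle(dataset.feature_matrix[j], dataset.n_rois)
    return sum(abs(mi[r, k] - mj[r, k]) for k in range(dataset.n_rois) if k != r)


def random_dataset(rng, n_samples, n_rois):
    n_pairs = n_rois * (n_rois - 1) // 2
    x = rng.uniform(-0.95, 0.95, size=(n_samples, n_pairs))
    phen = rng.integers(0, 2, n_samples)
    phen[:2] = [0, 1]  # both classes present
    return CorrelationDataset(x, [f"R{i}" for i in range(n_rois)], phen)


class TestProjectedDistances:
    def test_hand_worked_three_roi_example(self):
        x = np.array([[0.8, 0.2, 0.5], [0.6, 0.4, 0.1]])
        ds = CorrelationDataset(x, ["A", "B", "C"], [1, 0])
        assert pair_diff(ds, 0, 1, 0) == pytest.approx(0.2)
        assert correlation_diff(ds, 0, 1, "A") == pytest.approx(0.4)
        assert correlation_diff(ds, 0, 1, "B") == pytest.approx(0.6)
        assert correlation_diff(ds, 0, 1, "C") == pytest.approx(0.6)

    def test_identity_and_symmetry(self, tiny_dataset):
        assert pair_diff(tiny_dataset, 3, 3, 2) == 0.0
        assert correlation_diff(tiny_dataset, 1, 1, "B") == 0.0
        assert pair_diff(tiny_dataset, 0, 4, 5) == pair_diff(tiny_dataset, 4, 0, 5)

    def test_matches_brute_force_on_random_instances(self):
        # pair-level and node-level diffs against independent double-loop
        # oracles, to within 1e-12, over 100 random instances
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_rois = int(rng.integers(3, 9))
            ds = random_dataset(rng, int(rng.integers(2, 6)), n_rois)
            i, j = rng.integers(0, ds.n_samples, 2)
            p = int(rng.integers(0, ds.n_pairs))
            assert pair_diff(ds, i, j, p) == pytest.approx(
                brute_pair_diff(ds, i, j, p), abs=1e-12
            )
            r = int(rng.integers(0, n_rois))
            assert correlation_diff(ds, i, j, r) == pytest.approx(
                brute_correlation_diff(ds, i, j, r), abs=1e-12
            )

    def test_corr_diff_decomposition_identity(self):
        # sum_r d^CD(r) = 2 sum_p d^p: every pair diff feeds exactly two ROIs
        rng = np.random.default_rng(1)
        for _ in range(100):
            ds = random_dataset(rng, 4, int(rng.integers(3, 9)))
            nb = find_neighbor_pairs(sample_distances(ds), ds.phenotype, "fixed_k", 2)
            pd_ = pair_design(ds, nb)
            cd = corr_diff_design(ds, nb)
            np.testing.assert_allclose(
                cd.values.sum(axis=1), 2 * pd_.values.sum(axis=1), atol=1e-10
            )

    def test_unknown_roi_raises(self, tiny_dataset):
        with pytest.raises(KeyError):
            correlation_diff(tiny_dataset, 0, 1, "nope")


class TestSampleDistances:
    def test_metric_properties_and_duplicates(self, tiny_dataset):
        d = sample_distances(tiny_dataset)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        x = np.vstack([tiny_dataset.feature_matrix, tiny_dataset.feature_matrix[:1]])
        ds2 = CorrelationDataset(
            x, tiny_dataset.roi_names, list(tiny_dataset.phenotype) + [1]
        )
        d2 = sample_distances(ds2)
        assert d2[0, -1] == pytest.approx(0.0)
        # triangle inequality
        n = d2.shape[0]
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    assert d2[a, c] <= d2[a, b] + d2[b, c] + 1e-9

    def test_matches_per_feature_summation(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, 5, 4)
        d = sample_distances(ds, standardize=False)
        i, j = 1, 3
        manual = np.abs(ds.feature_matrix[i] - ds.feature_matrix[j]).sum()
        assert d[i, j] == pytest.approx(manual)

    def test_zero_variance_feature_excluded(self, caplog):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, 5, 4)
        ds.feature_matrix[:, 2] = 0.5
        with caplog.at_level("WARNING"):
            sample_distances(ds)
        assert "zero-variance" in caplog.text


class TestNeighborPairs:
    def test_fixed_k_complete_neighborhood(self, tiny_dataset):
        d = sample_distances(tiny_dataset)
        nb = find_neighbor_pairs(d, tiny_dataset.phenotype, "fixed_k", 5)
        assert len(nb) == 15  # all 6*5/2 unordered pairs
        # delta_y consistent with the phenotype
        for (i, j), dy in zip(nb.pairs, nb.delta_y):
            assert dy == float(tiny_dataset.phenotype[i] != tiny_dataset.phenotype[j])

    def test_k_too_large_rejected(self, tiny_dataset):
        d = sample_distances(tiny_dataset)
        with pytest.raises(ValueError, match="smaller than n_samples"):
            find_neighbor_pairs(d, tiny_dataset.phenotype, "fixed_k", 6)

    def test_separated_clusters_yield_only_hits(self):
        # two tight clusters aligned with the classes; small k keeps all
        # neighbor pairs within-cluster, so every pair is a hit (delta_y = 0)
        rng = np.random.default_rng(7)
        base = rng.uniform(-0.5, 0.5, size=10)
        a = base + rng.normal(0, 0.01, size=(5, 10))
        b = base + 3.0 + rng.normal(0, 0.01, size=(5, 10))
        x = np.clip(np.vstack([a, b]), -0.99, 0.99)
        ds = CorrelationDataset(x, [f"R{i}" for i in range(5)], [1] * 5 + [0] * 5)
        nb = find_neighbor_pairs(
            sample_distances(ds, standardize=False), ds.phenotype, "fixed_k", 2
        )
        assert np.all(nb.delta_y == 0)

    def test_equidistant_adaptive_radius_errors(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="fixed_k"):
            find_neighbor_pairs(d, np.array([1, 1, 0, 0]), "adaptive_radius")

    def test_adaptive_radius_threshold_rule(self):
        rng = np.random.default_rng(8)
        ds = random_dataset(rng, 30, 6)
        d = sample_distances(ds)
        nb = find_neighbor_pairs(d, ds.phenotype, "adaptive_radius")
        pair_set = {tuple(p) for p in nb.pairs}
        n = d.shape[0]
        mask = ~np.eye(n, dtype=bool)
        for i in range(n):
            mu = d[i][mask[i]].mean()
            sd = d[i][mask[i]].std(ddof=1)
            for j in range(n):
                if i != j and d[i, j] < mu - sd / 2:
                    assert (min(i, j), max(i, j)) in pair_set

    def test_designs_are_nonnegative(self, small_sim):
        ds, _ = small_sim
        nb = find_neighbor_pairs(sample_distances(ds), ds.phenotype)
        assert pair_design(ds, nb).values.min() >= 0
        assert corr_diff_design(ds, nb).values.min() >= 0
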