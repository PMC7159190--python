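"""Recurrence quantification: threshold adaptation, plot construction,
diagonal-line features, and full-pipeline agreement with brute force."""

import numpy as np
import pytest

from elemdyn.embedding import EmbeddingParams, takens_embed
from elemdyn.rqa import (
    RQAConfig,
    adaptive_epsilon,
    determinism,
    diagonal_entropy,
    diagonal_histogram,
    mean_diagonal_length,
    recurrence_matrix,
    rqa_features,
)

from conftest import make_series


# ------------------------------------------------------- adaptive epsilon

class TestAdaptiveEpsilon:
    def test_quantile_definition_on_distinct_distances(self, rng):
        pts = rng.uniform(0, 100, size=(100, 1))
        traj = takens_embed(pts.ravel(), EmbeddingParams(1, 1))
        dists = np.sort(
            [abs(pts[i, 0] - pts[j, 0]) for i in range(100) for j in range(i + 1, 100)]
        )
        assert np.unique(dists).size == dists.size  # oracle precondition
        eps = adaptive_epsilon(traj, RQAConfig(target_recurrence_rate=0.10))
        assert eps == pytest.approx(dists[494])  # the 495th smallest of 4950

    def test_target_one_reaches_max_distance(self, rng):
        z = rng.standard_normal(50)
        traj = takens_embed(z, EmbeddingParams(1, 2))
        eps = adaptive_epsilon(traj, RQAConfig(target_recurrence_rate=1.0))
        res = recurrence_matrix(traj, eps, RQAConfig(target_recurrence_rate=1.0))
        assert res.recurrence_rate == 1.0

    def test_degenerate_geometry_rejected(self):
        traj = takens_embed(np.zeros(12), EmbeddingParams(1, 2))
        with pytest.raises(ValueError, match="degenerate"):
            adaptive_epsilon(traj)

    def test_realized_rate_close_to_target(self, rng):
        for _ in range(5):
            z = rng.standard_normal(300)
            traj = takens_embed(z, EmbeddingParams(1, 3))
            eps = adaptive_epsilon(traj)
            rate = recurrence_matrix(traj, eps).recurrence_rate
            assert abs(rate - 0.10) <= 0.005


# ------------------------------------------------------- recurrence matrix

def _brute_matrix(points, eps, theiler, norm="euclidean"):
    n = len(points)
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < theiler:
                continue
            diff = points[i] - points[j]
            # same arithmetic as the vectorised path so the <= boundary is
            # exactly comparable
            d = np.sqrt(np.sum(diff**2)) if norm == "euclidean" else np.max(np.abs(diff))
            out[i, j] = d <= eps
    return out


class TestRecurrenceMatrix:
    def test_matches_bruteforce_exactly(self, rng):
        for norm in ("euclidean", "maximum"):
            for _ in range(10):
                n = int(rng.integers(20, 80))
                m = int(rng.integers(1, 4))
                tau = int(rng.integers(1, 4))
                theiler = int(rng.integers(0, 3))
                z = rng.standard_normal(n + (m - 1) * tau)
                traj = takens_embed(z, EmbeddingParams(tau, m))
                cfg = RQAConfig(norm=norm, theiler_window=theiler)
                eps = adaptive_epsilon(traj, cfg)
                res = recurrence_matrix(traj, eps, cfg)
                np.testing.assert_array_equal(
                    res.matrix, _brute_matrix(traj.points, eps, theiler, norm)
                )

    def test_repeated_point_fills_off_band(self):
        traj = takens_embed(np.zeros(6) + 0.0, EmbeddingParams(1, 1))
        res = recurrence_matrix(traj, 0.1, RQAConfig())
        expected = ~np.eye(6, dtype=bool)
        np.testing.assert_array_equal(res.matrix, expected)

    def test_two_remote_clusters_are_block_diagonal(self):
        z = np.concatenate([np.linspace(0, 0.1, 10), np.linspace(100, 100.1, 10)])
        traj = takens_embed(z, EmbeddingParams(1, 1))
        res = recurrence_matrix(traj, 1.0, RQAConfig())
        assert not res.matrix[:10, 10:].any()
        assert not res.matrix[10:, :10].any()
        assert res.matrix[:10, :10].sum() == 90  # all off-diagonal pairs


# ------------------------------------------------------- diagonal histogram

def _brute_histogram(matrix, theiler):
    """Independent run-length scanner over the upper-triangle diagonals."""
    n = matrix.shape[0]
    hist = {}
    for k in range(max(theiler, 1), n):
        run = 0
        for i in range(n - k):
            if matrix[i, i + k]:
                run += 1
            elif run:
                hist[run] = hist.get(run, 0) + 1
                run = 0
        if run:
            hist[run] = hist.get(run, 0) + 1
    return hist


class TestDiagonalHistogram:
    def test_all_ones_matrix(self):
        P = diagonal_histogram(np.ones((5, 5), dtype=bool), theiler_window=1)
        assert P == {4: 1, 3: 1, 2: 1, 1: 1}

    def test_identity_only_matrix_is_empty(self):
        P = diagonal_histogram(np.eye(5, dtype=bool), theiler_window=1)
        assert P == {}

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 20))
            upper = np.triu(rng.random((n, n)) < 0.4, k=1)
            matrix = upper | upper.T
            theiler = int(rng.integers(0, 3))
            assert diagonal_histogram(matrix, theiler) == _brute_histogram(matrix, theiler)


# ------------------------------------------------------- feature formulas

class TestFeatureFormulas:
    def test_determinism_worked_examples(self):
        assert determinism({5: 1}, lmin=3) == 1.0
        assert determinism({1: 4, 2: 3}, lmin=3) == 0.0
        assert determinism({1: 4, 3: 2}, lmin=3) == pytest.approx(0.6, abs=1e-12)
        assert np.isnan(determinism({}, lmin=3))

    def test_mdl_worked_examples(self):
        assert mean_diagonal_length({3: 2, 5: 1}, lmin=3) == pytest.approx(11 / 3, abs=1e-12)
        assert mean_diagonal_length({4: 7}, lmin=3) == 4.0
        assert np.isnan(mean_diagonal_length({1: 5, 2: 2}, lmin=3))

    def test_entropy_worked_examples(self):
        assert diagonal_entropy({7: 3}, lmin=3) == 0.0
        assert diagonal_entropy({3: 1, 4: 1}, lmin=3) == pytest.approx(np.log(2), abs=1e-12)
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert diagonal_entropy({3: 1, 4: 1, 5: 2}, lmin=3) == pytest.approx(expected, abs=1e-12)
        assert np.isnan(diagonal_entropy({1: 9}, lmin=3))


# ------------------------------------------------------- full pipeline

def _brute_pipeline(z, tau, m, cfg):
    pts = np.array([[z[i + j * tau] for j in range(m)] for i in range(len(z) - (m - 1) * tau)])
    n = len(pts)
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            if j - i >= cfg.theiler_window:
                dists.append(np.sqrt(np.sum((pts[i] - pts[j]) ** 2)))
    dists = np.array(dists)
    k = max(1, int(np.floor(cfg.target_recurrence_rate * len(dists))))
    eps = np.sort(dists)[k - 1]
    matrix = _brute_matrix(pts, eps, cfg.theiler_window)
    P = _brute_histogram(matrix, cfg.theiler_window)
    return eps, matrix, P


class TestPipeline:
    def test_agrees_with_bruteforce_reference(self, rng):
        cfg = RQAConfig()
        for _ in range(5):
            n = int(rng.integers(60, 150))
            z = np.sin(np.arange(n) / 3.0) + 0.3 * rng.standard_normal(n)
            params = EmbeddingParams(delay=3, dimension=2)
            res = rqa_features(z, params=params, config=cfg)
            eps, matrix, P = _brute_pipeline(z, 3, 2, cfg)
            assert res.epsilon == pytest.approx(eps, abs=0)
            np.testing.assert_array_equal(res.matrix, matrix)
            assert res.diag_histogram == P
            assert res.determinism == pytest.approx(determinism(P, 3), abs=1e-12)
            assert res.mean_diagonal_length == pytest.approx(
                mean_diagonal_length(P, 3), abs=1e-12)
            assert res.entropy == pytest.approx(diagonal_entropy(P, 3), abs=1e-12)

    def test_sinusoid_more_deterministic_than_noise(self, sinusoid, white_noise):
        res_sin = rqa_features(sinusoid)
        res_noise = rqa_features(white_noise, params=res_sin.params)
        assert res_sin.determinism > res_noise.determinism
        assert 0.0 <= res_noise.determinism <= 1.0
        assert res_sin.mean_diagonal_length >= 3
        assert res_sin.entropy >= 0

    def test_affine_rescaling_leaves_matrix_invariant(self, rng):
        z = np.sin(np.arange(200) / 5.0) + 0.2 * rng.standard_normal(200)
        params = EmbeddingParams(delay=4, dimension=2)
        a = rqa_features(z, params=params)
        b = rqa_features(5.0 * z + 11.0, params=params)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        assert a.determinism == b.determinism
        assert a.entropy == b.entropy

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="constant|degenerate"):
            rqa_features(make_series(np.full(100, 2.0)))

    def test_config_defaults_as_printed(self):
        cfg = RQAConfig()
        assert cfg.target_recurrence_rate == 0.10
        assert cfg.lmin == 3
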