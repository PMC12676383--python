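"""Distance decoders: Euclidean, shrinkage-Mahalanobis, EMD, constrained EMD."""

import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from cvepkit.decode import (
    ShrinkageConfig,
    cemd_decode,
    constrained_emd,
    emd_cdf,
    emd_decode,
    euclidean_decode,
    mahalanobis_decode,
    normalize_pmf,
)


def _random_pmf(rng, K):
    v = rng.random(K)
    return v / v.sum()


class TestEuclidean:
    def test_exact_row_gives_zero_and_label(self, bank):
        y = bank.codes[2].astype(float)
        dm, labels = euclidean_decode(y, bank)
        assert dm.D[0, 2] == 0.0
        assert labels[0] == 3

    def test_all_half_distance(self, bank):
        dm, _ = euclidean_decode(np.full((1, 63), 0.5), bank)
        assert np.allclose(dm.D, 63 * 0.25)

    def test_ranking_invariant_to_sqrt(self, bank):
        rng = np.random.default_rng(0)
        Y = rng.random((20, 63))
        dm, labels = euclidean_decode(Y, bank)
        labels_sqrt = np.argmin(np.sqrt(dm.D), axis=1) + 1
        assert np.array_equal(labels, labels_sqrt)

    def test_threshold_option(self, bank):
        y = bank.codes[1] * 0.9 + 0.05  # 0.95 for ones, 0.05 for zeros
        dm, labels = euclidean_decode(y, bank, threshold=True)
        assert dm.D[0, 1] == 0.0
        assert labels[0] == 2


class TestMahalanobis:
    def test_identity_covariance_equals_squared_euclidean(self, bank):
        """Sigma = I keeps Sigma_reg = I (alpha = 1), so distances coincide."""
        rng = np.random.default_rng(1)
        Y = rng.random((15, 63))
        dm_m, lab_m = mahalanobis_decode(Y, bank, sigma=np.eye(63))
        dm_e, lab_e = euclidean_decode(Y, bank)
        assert np.allclose(dm_m.D, dm_e.D, atol=1e-10)
        assert np.array_equal(lab_m, lab_e)

    def test_full_shrinkage_is_isotropic(self, bank):
        """lambda = 1 -> Sigma_reg = alpha I: distances proportional to Euclidean."""
        rng = np.random.default_rng(2)
        Y = rng.random((30, 63))
        src = rng.random((100, 63))
        dm_m, lab_m = mahalanobis_decode(
            Y, bank, ShrinkageConfig(lambda_shrink=1.0), cov_source=src
        )
        dm_e, lab_e = euclidean_decode(Y, bank)
        ratio = dm_m.D / dm_e.D
        assert np.allclose(ratio, ratio.flat[0])
        assert np.array_equal(lab_m, lab_e)

    def test_exact_row_gives_zero(self, bank):
        rng = np.random.default_rng(3)
        src = rng.random((100, 63))
        y = bank.codes[4].astype(float)
        dm, labels = mahalanobis_decode(y, bank, cov_source=src)
        assert dm.D[0, 4] == pytest.approx(0.0, abs=1e-10)
        assert labels[0] == 5

    def test_too_few_covariance_rows_rejected(self, bank):
        with pytest.raises(ValueError):
            mahalanobis_decode(np.full((1, 63), 0.5), bank,
                               cov_source=np.full((1, 63), 0.5))


class TestNormalizePmf:
    def test_simple(self):
        assert np.allclose(normalize_pmf([1, 1, 0, 0]), [0.5, 0.5, 0, 0])

    def test_clipping(self):
        assert np.allclose(normalize_pmf([-1, 2]), [0, 1])

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_pmf([0.0, -1.0, 0.0])

    def test_sums_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = normalize_pmf(rng.standard_normal(63))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p >= 0).all()


class TestEMD:
    def test_identical_pmfs(self):
        p = normalize_pmf(np.arange(1.0, 10.0))
        assert emd_cdf(p, p) == 0.0

    def test_adjacent_point_masses(self):
        p, q = np.zeros(63), np.zeros(63)
        p[1] = 1.0
        q[2] = 1.0
        assert emd_cdf(p, q) == pytest.approx(1 / 63)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        p, q = _random_pmf(rng, 63), _random_pmf(rng, 63)
        assert emd_cdf(p, q) == pytest.approx(emd_cdf(q, p))

    def test_matches_scipy_wasserstein(self):
        """CDF-form EMD equals scipy's 1-D Wasserstein distance / K."""
        rng = np.random.default_rng(6)
        pos = np.arange(16)
        for _ in range(50):
            p, q = _random_pmf(rng, 16), _random_pmf(rng, 16)
            w = wasserstein_distance(pos, pos, p, q)
            assert emd_cdf(p, q) == pytest.approx(w / 16, abs=1e-12)

    def test_emd_decode_exact_row(self, bank):
        dm, labels = emd_decode(bank.codes[3].astype(float), bank)
        assert dm.D[0, 3] == pytest.approx(0.0, abs=1e-12)
        assert labels[0] == 4


class TestConstrainedEMD:
    def test_identical_pmfs_zero_cost(self):
        p = normalize_pmf(np.arange(1.0, 9.0))
        for R in (0, 1, 5):
            cost, plan = constrained_emd(p, p, R)
            assert cost == pytest.approx(0.0, abs=1e-10)
            assert plan is not None

    def test_point_masses_beyond_radius_infeasible(self):
        p, q = np.zeros(8), np.zeros(8)
        p[0] = 1.0
        q[3] = 1.0
        cost, plan = constrained_emd(p, q, R=2)
        assert cost == float("inf")
        assert plan is None

    def test_point_masses_within_radius(self):
        p, q = np.zeros(8), np.zeros(8)
        p[0] = 1.0
        q[3] = 1.0
        cost, plan = constrained_emd(p, q, R=3)
        assert cost == pytest.approx(3.0)
        assert plan.X[0, 3] == pytest.approx(1.0)

    def test_marginals_satisfied(self):
        rng = np.random.default_rng(7)
        p, q = _random_pmf(rng, 12), _random_pmf(rng, 12)
        _, plan = constrained_emd(p, q, R=11)
        assert np.allclose(plan.X.sum(axis=1), p, atol=1e-8)
        assert np.allclose(plan.X.sum(axis=0), q, atol=1e-8)

    def test_unconstrained_limit_matches_cdf_form(self):
        """R >= K-1 reduces to the 1-D EMD: LP cost = K * CDF-form distance."""
        rng = np.random.default_rng(8)
        for K in (5, 9, 16):
            p, q = _random_pmf(rng, K), _random_pmf(rng, K)
            cost, _ = constrained_emd(p, q, R=K - 1)
            assert cost == pytest.approx(K * emd_cdf(p, q), abs=1e-8)

    def test_cost_non_increasing_in_radius(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            p, q = _random_pmf(rng, 16), _random_pmf(rng, 16)
            costs = [constrained_emd(p, q, R)[0] for R in (1, 2, 4, 8, 15)]
            finite = [c for c in costs if np.isfinite(c)]
            assert all(a >= b - 1e-10 for a, b in zip(costs, costs[1:])) or (
                np.isinf(costs[0]) and finite == sorted(finite, reverse=True)
            )

    def test_zero_radius(self):
        p = normalize_pmf(np.arange(1.0, 5.0))
        cost, _ = constrained_emd(p, p, R=0)
        assert cost == pytest.approx(0.0)
        q = np.roll(p, 1)
        cost_q, _ = constrained_emd(p, q, R=0)
        assert cost_q == float("inf")

    def test_negative_radius_rejected(self):
        p = np.ones(4) / 4
        with pytest.raises(ValueError):
            constrained_emd(p, p, -1)


class TestCemdDecode:
    def test_exact_row_any_radius(self, bank):
        y = bank.codes[0].astype(float)
        for R in (0, 8):
            dm, labels = cemd_decode(y, bank, R=R)
            assert labels[0] == 1
            assert dm.D[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_large_radius_matches_unconstrained_labels(self, bank):
        rng = np.random.default_rng(10)
        Y = rng.random((10, 63))
        _, lab_c = cemd_decode(Y, bank, R=62)
        _, lab_u = emd_decode(Y, bank)
        assert np.array_equal(lab_c, lab_u)

    def test_all_infeasible_falls_back(self, bank, caplog):
        y = np.zeros(63)
        y[0] = 1.0  # point mass: R=0 infeasible against every spread-out row
        import logging

        with caplog.at_level(logging.WARNING, logger="cvepkit.decode"):
            dm, labels = cemd_decode(y, bank, R=0)
        assert np.isinf(dm.D[0]).all()
        assert labels[0] in range(1, 7)
        assert any("infeasible" in r.message for r in caplog.records)
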