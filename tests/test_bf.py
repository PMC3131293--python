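import math

import numpy as np
import pytest

from reqtl.bf import (
    BlockPrecisions,
    DegenerateSnpError,
    block_precisions,
    shared_coefficient_logbf,
    single_block_logbf,
    snp_model_logbfs,
)
from reqtl.preprocess import PairedPhenotype
from reqtl.quadrature import (
    quadrature_general_logbf,
    quadrature_shared_logbf,
    quadrature_single_block_logbf,
)

from conftest import random_paired

GRID = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6)


class TestBlockPrecisions:
    def test_unit_variance_recovered(self):
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.binomial(2, 0.3, n).astype(float)
        ph = PairedPhenotype(rng.normal(size=n), rng.normal(size=n))
        taus = block_precisions(ph, x)
        # var(d) = 2, var(m) = 1/2 for independent unit-variance conditions
        assert abs(taus.tau_d - 0.5) / 0.5 < 0.05
        assert abs(taus.tau_m - 2.0) / 2.0 < 0.05

    def test_exact_linear_diff_is_degenerate(self):
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        ph = PairedPhenotype(2 * x, np.zeros(6))  # d = 2x exactly
        with pytest.raises((DegenerateSnpError, ValueError)):
            block_precisions(ph, x)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        ph, x = random_paired(rng, n=50)
        t1 = block_precisions(ph, x)
        t2 = block_precisions(PairedPhenotype(2 * ph.treated, 2 * ph.control), x)
        assert t2.tau_d == pytest.approx(t1.tau_d / 4.0, rel=1e-12)
        assert t2.tau_m == pytest.approx(t1.tau_m / 4.0, rel=1e-12)


class TestSingleBlock:
    def test_zero_effect_closed_form(self):
        # response orthogonal to predictor: beta_hat = 0, BF < 1
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0])
        tau, W = 1.3, 0.7
        V = 1.0 / (tau * 2.0)
        expected = 0.5 * math.log10(V / (V + W))
        assert single_block_logbf(y, x, tau, W) == pytest.approx(expected, abs=1e-12)
        assert expected < 0

    def test_zero_prior_limit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert abs(single_block_logbf(y - y.mean(), x - x.mean(), 1.0, 1e-16)) < 1e-6

    def test_sign_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        xc, yc = x - x.mean(), y - y.mean()
        assert single_block_logbf(yc, xc, 1.0, 0.5) == pytest.approx(
            single_block_logbf(-yc, xc, 1.0, 0.5), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + rng.uniform(-1, 1) * x
        xc, yc = x - x.mean(), y - y.mean()
        tau = 1.0 / rng.uniform(0.5, 2.0)
        W = rng.uniform(0.05, 3.0)
        cf = single_block_logbf(yc, xc, tau, W)
        qd = quadrature_single_block_logbf(yc, xc, tau, W)
        assert abs(cf - qd) < 1e-3


class TestSharedCoefficient:
    def test_reduces_to_single_block_when_cm_zero(self):
        rng = np.random.default_rng(4)
        ph, x = random_paired(rng, n=40)
        taus = block_precisions(ph, x)
        d = ph.diff - ph.diff.mean()
        m = ph.avg - ph.avg.mean()
        xc = x - x.mean()
        assert shared_coefficient_logbf(d, m, xc, taus, 1.0, 0.0, 0.5) == pytest.approx(
            single_block_logbf(d, xc, taus.tau_d, 0.5), rel=1e-12
        )

    def test_m2_loading_beats_m3_on_m2_data(self):
        # treated-only effect: the (+1, +1/2) loading should win over
        # (-1, +1/2) in nearly all replicates
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            ph, x = random_paired(rng, n=114, beta_t=np.sqrt(2.0), beta_c=0.0)
            taus = block_precisions(ph, x)
            d = ph.diff - ph.diff.mean()
            m = ph.avg - ph.avg.mean()
            xc = x - x.mean()
            w = 2.0
            bf2 = shared_coefficient_logbf(d, m, xc, taus, 1.0, 0.5, w)
            bf3 = shared_coefficient_logbf(d, m, xc, taus, -1.0, 0.5, w)
            wins += bf2 > bf3
        assert wins >= 95

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(5)
        ph, x = random_paired(rng, n=30)
        taus = block_precisions(ph, x)
        d, m, xc = ph.diff - ph.diff.mean(), ph.avg - ph.avg.mean(), x - x.mean()
        base = shared_coefficient_logbf(d, m, xc, taus, 1.0, 0.5, 0.8)
        perm = rng.permutation(30)
        assert shared_coefficient_logbf(
            d[perm], m[perm], xc[perm], taus, 1.0, 0.5, 0.8
        ) == pytest.approx(base, rel=1e-12)

    def test_zero_loadings_rejected(self):
        taus = BlockPrecisions(1.0, 1.0)
        with pytest.raises(ValueError):
            shared_coefficient_logbf(
                np.zeros(5), np.zeros(5), np.arange(5.0), taus, 0.0, 0.0, 1.0
            )


class TestSnpModelBFs:
    def test_null_data_bfs_typically_negative(self):
        rng = np.random.default_rng(6)
        neg = 0
        for _ in range(50):
            ph, x = random_paired(rng, n=60)
            sbf = snp_model_logbfs(ph, x, GRID)
            neg += np.all(np.isfinite(sbf.log10_bf))
        assert neg == 50

    def test_factorization_identity_m4(self):
        rng = np.random.default_rng(7)
        ph, x = random_paired(rng, n=40, beta_t=0.5, beta_c=-0.3)
        sbf = snp_model_logbfs(ph, x, GRID)
        keep = np.isfinite(x)
        sub = PairedPhenotype(ph.treated[keep], ph.control[keep])
        taus = block_precisions(sub, x)
        sd_y = np.std(np.concatenate([ph.treated, ph.control]), ddof=1)
        d, m, xc = ph.diff - ph.diff.mean(), ph.avg - ph.avg.mean(), x - x.mean()
        for j, sig in enumerate(GRID):
            w = (sig * sd_y) ** 2
            expected = single_block_logbf(d, xc, taus.tau_d, 2 * w) + single_block_logbf(
                m, xc, taus.tau_m, w / 2
            )
            assert sbf.log10_bf_grid[3, j] == pytest.approx(expected, rel=1e-12)

    def test_m1_depends_on_avg_block_only(self):
        # replacing the diff block with fresh noise (same avg block) leaves
        # BF(M1) unchanged once the prior is held at the same absolute scale
        rng = np.random.default_rng(8)
        ph, x = random_paired(rng, n=50, beta_t=0.4, beta_c=0.4)
        sbf = snp_model_logbfs(ph, x, GRID)
        new_d = rng.normal(size=50)
        ph2 = PairedPhenotype(ph.avg + new_d / 2, ph.avg - new_d / 2)
        sd1 = np.std(np.concatenate([ph.treated, ph.control]), ddof=1)
        sd2 = np.std(np.concatenate([ph2.treated, ph2.control]), ddof=1)
        matched_grid = tuple(s * sd1 / sd2 for s in GRID)  # same absolute w
        sbf2 = snp_model_logbfs(ph2, x, matched_grid)
        np.testing.assert_allclose(
            sbf2.log10_bf_grid[0], sbf.log10_bf_grid[0], rtol=1e-10
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        ph, x = random_paired(rng, n=45, beta_t=0.6)
        base = snp_model_logbfs(ph, x, GRID)
        shifted = PairedPhenotype(3.5 * ph.treated + 7.0, 3.5 * ph.control + 7.0)
        other = snp_model_logbfs(shifted, x, GRID)
        np.testing.assert_allclose(other.log10_bf, base.log10_bf, rtol=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        ph, x = random_paired(rng, n=35, beta_t=0.5)
        base = snp_model_logbfs(ph, x, GRID)
        perm = rng.permutation(35)
        other = snp_model_logbfs(
            PairedPhenotype(ph.treated[perm], ph.control[perm]), x[perm], GRID
        )
        np.testing.assert_allclose(other.log10_bf, base.log10_bf, rtol=1e-9)

    def test_zero_prior_limit_all_models(self):
        rng = np.random.default_rng(11)
        ph, x = random_paired(rng, n=30)
        sbf = snp_model_logbfs(ph, x, prior_sd_grid=(1e-9,))
        np.testing.assert_allclose(sbf.log10_bf, 0.0, atol=1e-6)

    def test_constant_dosage_skipped(self):
        rng = np.random.default_rng(12)
        ph = PairedPhenotype(rng.normal(size=10), rng.normal(size=10))
        with pytest.raises(DegenerateSnpError, match="identical"):
            snp_model_logbfs(ph, np.ones(10), GRID)

    def test_minor_allele_count_floor(self):
        rng = np.random.default_rng(13)
        ph = PairedPhenotype(rng.normal(size=10), rng.normal(size=10))
        x = np.array([1.0] + [0.0] * 9)
        with pytest.raises(DegenerateSnpError, match="minor-allele"):
            snp_model_logbfs(ph, x, GRID)

    def test_complete_case_missing_dosages(self):
        rng = np.random.default_rng(14)
        ph, x = random_paired(rng, n=40, beta_t=0.5)
        x_missing = x.copy()
        x_missing[:5] = np.nan
        sbf = snp_model_logbfs(ph, x_missing, GRID)
        sub = PairedPhenotype(ph.treated[5:], ph.control[5:])
        expected = snp_model_logbfs(sub, x[5:], GRID)
        assert sbf.n_used == 35
        np.testing.assert_allclose(sbf.log10_bf, expected.log10_bf, rtol=1e-12)

    def test_m1_simulation_favors_m1_over_m4(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            ph, x = random_paired(rng, n=114, beta_t=1.0, beta_c=1.0)
            sbf = snp_model_logbfs(ph, x, GRID)
            wins += sbf.log10_bf[0] > sbf.log10_bf[3]
        assert wins >= 70


class TestQuadratureAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_models_match_quadrature(self, seed):
        rng = np.random.default_rng(100 + seed)
        ph, x = random_paired(
            rng, n=30, beta_t=rng.uniform(-1, 1), beta_c=rng.uniform(-1, 1)
        )
        sbf = snp_model_logbfs(ph, x, GRID)
        from reqtl.quadrature import quadrature_model_logbfs

        for j, sig in enumerate(GRID):
            qd = quadrature_model_logbfs(ph, x, sig)
            np.testing.assert_allclose(sbf.log10_bf_grid[:, j], qd, atol=1e-3)
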