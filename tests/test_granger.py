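"""VAR fitting, block/conditional GC, surrogates, and the paired test.

The block-GC implementation is checked against an independent scalar
two-regression oracle built directly on lstsq, against the analytic
ln(1 + c^2) limit, and against its own batched variant.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadflow import granger as gc
from tests.conftest import make_var2


def scalar_gc_oracle(Y, i, j, p):
    """Independent two-regression scalar GC(i -> j): plain lstsq fits of the
    full and restricted autoregressions with MLE variances."""
    n, M = Y.shape
    X_full = np.concatenate([Y[p - k : n - k, :] for k in range(1, p + 1)], axis=1)
    t = Y[p:, j]
    n_eff = t.size

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, t, rcond=None)
        r = t - X @ beta
        return float(r @ r) / n_eff

    keep = [k * M + v for k in range(p) for v in range(M) if v != i]
    return np.log(rss(X_full[:, keep]) / rss(X_full))


def simulate_var(A, n, seed, burn=500, noise_cov=None):
    """Simulate a VAR(p) given coefficient stack A of shape (p, M, M)."""
    rng = np.random.default_rng(seed)
    p, M, _ = A.shape
    if noise_cov is None:
        noise = rng.standard_normal((n + burn, M))
    else:
        noise = rng.multivariate_normal(np.zeros(M), noise_cov, size=n + burn)
    Y = np.zeros((n + burn, M))
    for tt in range(p, n + burn):
        Y[tt] = sum(A[k] @ Y[tt - k - 1] for k in range(p)) + noise[tt]
    return Y[burn:]


class TestFitVar:
    def test_recovers_coefficients(self):
        A = np.array([[[0.5, 0.2], [0.0, 0.4]]])
        Y = simulate_var(A, 20000, seed=3)
        model = gc.fit_var_ols(Y, 1)
        assert np.allclose(model.coeffs, A, atol=0.02)
        assert np.allclose(model.resid_cov, np.eye(2), atol=0.05)
        assert model.companion_spectral_radius() < 1.0

    def test_var2_lag_convention(self):
        # y depends only on the second lag of x: A_2[1,0] = 0.6
        A = np.zeros((2, 2, 2))
        A[0, 0, 0] = 0.3
        A[1, 1, 0] = 0.6
        Y = simulate_var(A, 20000, seed=4)
        model = gc.fit_var_ols(Y, 2)
        assert abs(model.coeffs[1, 1, 0] - 0.6) < 0.03
        assert abs(model.coeffs[0, 1, 0]) < 0.03

    def test_insufficient_samples(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            gc.fit_var_ols(rng.standard_normal((13, 3)), 1)

    def test_rank_deficient(self, rng):
        x = rng.standard_normal(200)
        with pytest.raises(np.linalg.LinAlgError):
            gc.fit_var_ols(np.column_stack([x, x]), 1)


class TestSelectOrder:
    def test_finds_true_order(self):
        A = np.zeros((2, 2, 2))
        A[0] = [[0.4, 0.0], [0.2, 0.3]]
        A[1] = [[0.3, 0.0], [0.0, 0.3]]
        Y = simulate_var(A, 4000, seed=5)
        assert gc.select_order(Y, p_max=5) == 2

    def test_white_noise_picks_one(self, rng):
        assert gc.select_order(rng.standard_normal((2000, 3)), p_max=4) == 1

    def test_bad_args(self, rng):
        Y = rng.standard_normal((100, 2))
        with pytest.raises(ValueError):
            gc.select_order(Y, p_max=0)
        with pytest.raises(ValueError):
            gc.select_order(Y, criterion="hqc")


class TestBlockGcAgainstScalarOracle:
    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_two_regression_oracle(self, p, rng):
        for _ in range(10):
            Y = rng.standard_normal((300, 4))
            i, j = rng.choice(4, size=2, replace=False)
            cond = tuple(v for v in range(4) if v not in (i, j))
            ours = gc.block_gc(Y, (int(i),), (int(j),), cond, p).F
            oracle = scalar_gc_oracle(Y, int(i), int(j), p)
            assert abs(ours - max(oracle, 0.0)) < 1e-10

    def test_analytic_limit(self):
        c = 1.0
        Y = make_var2(100_000, c, seed=11)
        f = gc.block_gc(Y, (0,), (1,), (), 1).F
        assert abs(f - np.log(1 + c**2)) < 0.02

    def test_reverse_direction_is_null(self):
        Y = make_var2(100_000, 1.0, seed=12)
        assert gc.block_gc(Y, (1,), (0,), (), 1).F < 1e-3

    def test_disjointness_and_range_checks(self, rng):
        Y = rng.standard_normal((200, 3))
        with pytest.raises(ValueError, match="disjoint"):
            gc.block_gc(Y, (0,), (0,), (), 1)
        with pytest.raises(ValueError, match="out of range"):
            gc.block_gc(Y, (0,), (5,), (), 1)

    def test_clamping_flag(self, rng):
        # exactly collinear restricted/full fits cannot happen with noise, so
        # F >= 0 always holds and clamped marks numerically negative logs
        Y = rng.standard_normal((500, 2))
        v = gc.block_gc(Y, (0,), (1,), (), 1)
        assert v.F >= 0.0


class TestDyadGc:
    def test_coupled_blocks_detected(self):
        # subject b's first node driven by subject a's first node
        A = 0.3 * np.eye(6)[None]
        A[0, 3, 0] = 0.5
        Y = simulate_var(A, 5000, seed=21)
        d = gc.dyad_gc(Y, 1)
        assert d.f_ab.F > 0.1
        assert d.f_ab.pvalue < 1e-6
        assert d.f_ba.F < 0.02
        assert d.summary == pytest.approx(0.5 * (d.f_ab.F + d.f_ba.F))

    def test_needs_six_columns(self, rng):
        with pytest.raises(ValueError, match="6-column"):
            gc.dyad_gc(rng.standard_normal((300, 4)), 1)

    def test_batch_matches_loop(self, rng):
        E = rng.standard_normal((8, 240, 6))
        batch = gc.dyad_gc_batch(E, 2)
        for s in range(8):
            assert abs(batch[s] - gc.dyad_gc(E[s], 2).summary) < 1e-10


class TestPairwiseConditionalGc:
    def test_chain_link_suppressed(self):
        # x -> y -> z: conditional GC x->z|y should vanish, x->y and y->z not
        A = np.zeros((1, 3, 3))
        A[0] = [[0.3, 0.0, 0.0], [0.6, 0.3, 0.0], [0.0, 0.6, 0.3]]
        Y = simulate_var(A, 20000, seed=31)
        res = gc.pairwise_conditional_gc(Y, 1)
        assert res.conditional
        assert res.pvalues[0, 1] < 1e-6
        assert res.pvalues[1, 2] < 1e-6
        assert res.F[0, 2] < 0.005
        assert np.isnan(np.diag(res.F)).all()

    def test_matches_block_gc(self, rng):
        Y = rng.standard_normal((400, 4))
        res = gc.pairwise_conditional_gc(Y, 2)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                cond = tuple(v for v in range(4) if v not in (i, j))
                ref = gc.block_gc(Y, (i,), (j,), cond, 2)
                assert abs(res.F[i, j] - ref.F) < 1e-10
                assert abs(res.pvalues[i, j] - ref.pvalue) < 1e-10

    def test_bivariate_fallback(self, rng):
        res = gc.pairwise_conditional_gc(rng.standard_normal((300, 2)), 1)
        assert not res.conditional
        assert np.isfinite(res.F[0, 1])


class TestChi2Pvalue:
    def test_null_is_uniformish(self, rng):
        # chi2 p-values of null GC should not concentrate near zero
        ps = []
        E = rng.standard_normal((200, 300, 2))
        F, _, _, n_eff = gc._block_gc_batch(E, (0,), (1,), (), 1)
        from scipy import stats

        ps = stats.chi2.sf(n_eff * F, df=1)
        assert 0.01 < np.mean(ps < 0.05) < 0.12

    def test_rejects_negative_f(self):
        with pytest.raises(ValueError):
            gc.gc_chi2_pvalue(-0.1, 100, 1, 1, 1)


class TestSurrogates:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.standard_normal((256, 3))
        ens = gc.phase_randomize_surrogates(x, 5, seed=7)
        amp = np.abs(np.fft.rfft(x, axis=0))
        for s in range(5):
            amp_s = np.abs(np.fft.rfft(ens.data[s], axis=0))
            assert np.max(np.abs(amp_s - amp)) < 1e-8

    def test_cross_dependence_destroyed(self):
        n = 1024
        Y = make_var2(n, 2.0, seed=8)
        ens = gc.phase_randomize_surrogates(Y, 50, seed=9)
        rs = [np.corrcoef(ens.data[s, :-1, 0], ens.data[s, 1:, 1])[0, 1] for s in range(50)]
        assert np.mean(np.abs(rs)) < 3.0 / np.sqrt(n)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((128, 2))
        a = gc.phase_randomize_surrogates(x, 3, seed=5).data
        b = gc.phase_randomize_surrogates(x, 3, seed=5).data
        assert np.array_equal(a, b)
        c = gc.phase_randomize_surrogates(x, 3, seed=6).data
        assert not np.allclose(a, c)

    def test_block_wise_preserves_within_block_structure(self, rng):
        n = 2048
        shared = rng.standard_normal(n)
        Y = np.column_stack(
            [shared, shared + 0.1 * rng.standard_normal(n), rng.standard_normal(n)]
            + [rng.standard_normal(n) for _ in range(3)]
        )
        ens = gc.phase_randomize_surrogates(Y, 10, seed=10, block_wise=True)
        r_within = [np.corrcoef(ens.data[s, :, 0], ens.data[s, :, 1])[0, 1] for s in range(10)]
        assert np.mean(r_within) > 0.9

    @given(st.integers(3, 2**31 - 1), st.booleans())
    @settings(max_examples=15, deadline=None)
    def test_property_mean_and_spectrum(self, seed, block_wise):
        r = np.random.default_rng(seed)
        x = r.standard_normal((r.integers(64, 200), 6))
        ens = gc.phase_randomize_surrogates(x, 2, seed=seed % 1000, block_wise=block_wise)
        # DC bin untouched -> column means preserved
        assert np.allclose(ens.data.mean(axis=1), x.mean(axis=0)[None, :], atol=1e-10)
        amp = np.abs(np.fft.rfft(x, axis=0))
        amp_s = np.abs(np.fft.rfft(ens.data[0], axis=0))
        assert np.max(np.abs(amp_s - amp)) < 1e-8


class TestEmpiricalSurrogateTest:
    def test_coupled_cohort_significant(self):
        real, means = [], []
        A = 0.3 * np.eye(6)[None]
        A[0, 3, 0] = 0.5
        for k in range(8):
            Y = simulate_var(A, 300, seed=200 + k)
            real.append(gc.dyad_gc(Y, 1).summary)
            ens = gc.phase_randomize_surrogates(Y, 40, seed=300 + k)
            means.append(gc.surrogate_gc_means(ens, 1))
        res = gc.empirical_surrogate_test(real, surrogate_means=means)
        assert res.p < 0.01
        assert res.d > 1.0

    def test_needs_three_dyads(self):
        with pytest.raises(ValueError, match="3 dyads"):
            gc.empirical_surrogate_test([0.1, 0.2], surrogate_means=[0.1, 0.2])

    def test_zero_variance_diff(self):
        res = gc.empirical_surrogate_test([0.1] * 4, surrogate_means=[0.1] * 4)
        assert res.t == 0.0 and res.p == 1.0 and res.d == 0.0
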