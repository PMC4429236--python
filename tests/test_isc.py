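import numpy as np
import pytest
from scipy import stats as sps

from trwmap.isc import (
    covariate_regression,
    fdr_threshold,
    isc_pvalue,
    loo_isc,
    loo_isc_stack,
    null_distribution,
    paired_ttest_onetailed,
    phase_randomize,
    twosample_ttest_onetailed,
)


def oracle_loo_r(series):
    """Leave-one-out correlations straight from the textbook formula."""
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    out = []
    for j in range(n):
        others = np.mean(np.delete(x, j, axis=0), axis=0)
        a, b = x[j] - x[j].mean(), others - others.mean()
        denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
        out.append(np.sum(a * b) / denom if denom > 0 else np.nan)
    return np.array(out)


class TestLooIsc:
    def test_identical_subjects_unit_correlation(self):
        x = np.tile(np.array([0.0, 1.0, -1.0, 2.0, 0.5]), (4, 1))
        r, R = loo_isc(x)
        np.testing.assert_allclose(r, 1.0)
        assert R == pytest.approx(1.0)

    def test_matches_formula_oracle_on_fixture(self):
        series = [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]]
        with pytest.warns(RuntimeWarning, match="undefined"):
            r, R = loo_isc(series)
        expected = oracle_loo_r(series)
        np.testing.assert_allclose(r, expected, atol=1e-12)
        assert R == pytest.approx(np.nanmean(expected))

    def test_matches_oracle_on_random_cohort(self, rng):
        x = rng.standard_normal((6, 40))
        r, R = loo_isc(x)
        np.testing.assert_allclose(r, oracle_loo_r(x), atol=1e-12)

    def test_phase_randomized_subjects_near_zero(self, rng):
        base = rng.standard_normal(200)
        x = np.stack([phase_randomize(base, seed=k) for k in range(10)])
        _, R = loo_isc(x)
        assert abs(R) < 3.0 / np.sqrt(200)

    def test_common_affine_rescaling_invariance(self, rng):
        """A common positive affine transform of all time courses leaves ISC
        unchanged; rescaling one subject leaves that subject's own r_j
        unchanged (Pearson invariance)."""
        x = rng.standard_normal((5, 60))
        r1, _ = loo_isc(x)
        r2, _ = loo_isc(2.7 * x + 0.3)
        np.testing.assert_allclose(r1, r2, atol=1e-10)
        y = x.copy()
        y[2] = 5.0 * y[2] - 1.0
        r3, _ = loo_isc(y)
        assert r3[2] == pytest.approx(r1[2], abs=1e-12)

    def test_stack_agrees_with_scalar_path(self, rng):
        data = rng.standard_normal((5, 7, 30))
        r_stack, R_stack = loo_isc_stack(data)
        for v in range(7):
            r, R = loo_isc(data[:, v, :])
            np.testing.assert_allclose(r_stack[:, v], r, atol=1e-12)
            assert R_stack[v] == pytest.approx(R)


class TestPhaseRandomize:
    def test_constant_series_unchanged(self):
        x = np.full(16, 2.5)
        np.testing.assert_allclose(phase_randomize(x, seed=3), x, atol=1e-9)

    def test_magnitude_spectrum_preserved(self, rng):
        x = rng.standard_normal(157)
        s = phase_randomize(x, seed=8)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(s)), np.abs(np.fft.rfft(x)), rtol=1e-9
        )

    def test_variance_preserved(self, rng):
        x = rng.standard_normal(256) * 3.0 + 1.0
        s = phase_randomize(x, seed=1)
        assert s.var() == pytest.approx(x.var(), rel=1e-6)

    def test_autocorrelation_preserved(self, rng):
        x = np.convolve(rng.standard_normal(300), np.ones(5) / 5, mode="same")
        s = phase_randomize(x, seed=2)
        # the power spectrum determines the (circular) autocorrelation
        fx = np.abs(np.fft.rfft(x - x.mean())) ** 2
        fs = np.abs(np.fft.rfft(s - s.mean())) ** 2
        np.testing.assert_allclose(fs, fx, atol=1e-9 * fx.max())

    def test_output_real_and_deterministic(self, rng):
        x = rng.standard_normal(64)
        a = phase_randomize(x, seed=5)
        b = phase_randomize(x, seed=5)
        assert a.dtype.kind == "f"
        np.testing.assert_array_equal(a, b)


class TestNullDistribution:
    def test_same_seed_identical(self, rng):
        data = rng.standard_normal((4, 6, 40))
        a = null_distribution(data, n_perm=20, seed=9)
        b = null_distribution(data, n_perm=20, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_null_mean_centered_at_zero(self, rng):
        data = rng.standard_normal((6, 4, 100))
        null = null_distribution(data, n_perm=400, seed=2)
        for v in range(4):
            se = null[:, v].std() / np.sqrt(null.shape[0])
            assert abs(null[:, v].mean()) < 3 * se + 1e-4

    @pytest.mark.parametrize("n_t", [33, 34])  # odd and even lengths
    def test_spectral_path_matches_time_domain_surrogates(self, rng, n_t):
        """The frequency-domain null equals explicitly inverting the FFT."""
        from trwmap.isc import _parseval_weights, _spectral_loo_R

        data = rng.standard_normal((4, 5, n_t))
        f_full = np.fft.rfft(data, axis=-1)
        w = _parseval_weights(n_t).astype(np.float64)
        g0 = f_full[..., 1:]
        a = np.einsum("nvk,k->nv", g0.real**2 + g0.imag**2, w)

        # identity phases reproduce the observed R exactly
        _, R_obs = loo_isc_stack(data)
        np.testing.assert_allclose(_spectral_loo_R(g0, w, a), R_obs, atol=1e-10)

        # random unit-modulus phases: spectral R == R of the explicit surrogates
        theta = 2 * np.pi * rng.random(g0.shape)
        factors = np.exp(1j * theta)
        if n_t % 2 == 0:
            factors[..., -1] = 1.0
        f_surr = f_full.copy()
        f_surr[..., 1:] *= factors
        surr = np.fft.irfft(f_surr, n=n_t, axis=-1)
        _, R_surr = loo_isc_stack(surr)
        np.testing.assert_allclose(_spectral_loo_R(g0 * factors, w, a), R_surr, atol=1e-10)

    def test_worker_count_does_not_change_results(self, rng):
        data = rng.standard_normal((4, 6, 40))
        a = null_distribution(data, n_perm=12, seed=3, n_jobs=1)
        b = null_distribution(data, n_perm=12, seed=3, n_jobs=2)
        np.testing.assert_array_equal(a, b)

    def test_pvalues_uniform_under_white_noise(self):
        """Empirical p-values are approximately uniform for pure-noise cohorts."""
        data = np.random.default_rng(0).standard_normal((6, 200, 60))
        _, R = loo_isc_stack(data)
        null = null_distribution(data, n_perm=500, seed=100)
        p = isc_pvalue(R, null)
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestIscPvalue:
    def test_estimator_bounds_and_examples(self, rng):
        null = rng.standard_normal(999)
        assert isc_pvalue(null.max() + 1.0, null) == pytest.approx(1 / 1000)
        assert isc_pvalue(np.median(null), null) == pytest.approx(0.5, abs=0.01)

    def test_monotone_nonincreasing_in_r(self, rng):
        null = rng.standard_normal(500)
        grid = np.linspace(-3, 3, 50)
        p = np.array([isc_pvalue(v, null) for v in grid])
        assert np.all(np.diff(p) <= 0)


class TestFdr:
    def test_printed_rule_on_fixture(self):
        d = fdr_threshold([0.001, 0.02, 0.03, 0.5], q_star=0.05)
        assert d.k == 3
        assert d.p_threshold == pytest.approx(0.03)
        np.testing.assert_array_equal(d.mask, [True, True, True, False])

    def test_matches_bruteforce_rule(self, rng):
        """Exhaustive evaluation of the step-up inequality on random p-values."""
        p = rng.uniform(1e-4, 1.0, size=25)
        d = fdr_threshold(p, q_star=0.05)
        sp = np.sort(p)
        ks = [k for k in range(1, 26) if sp[k - 1] < k / 25 * 0.05]
        if ks:
            assert d.k == max(ks)
            assert d.p_threshold == pytest.approx(sp[max(ks) - 1])
        else:
            assert d.k == 0 and not d.mask.any()

    def test_nothing_rejected_when_all_large(self):
        d = fdr_threshold([0.9] * 10)
        assert d.k == 0
        assert d.p_threshold is None
        assert not d.mask.any()

    def test_everything_rejected_when_all_tiny(self):
        p = [0.05 / 100] * 8  # each p < q*/N after any rank
        d = fdr_threshold(p, q_star=0.05)
        assert d.mask.all()

    def test_by_correction_is_more_conservative(self, rng):
        p = rng.uniform(0.0001, 0.2, size=50)
        bh = fdr_threshold(p, q_star=0.05, by_correction=False)
        by = fdr_threshold(p, q_star=0.05, by_correction=True)
        assert by.mask.sum() <= bh.mask.sum()

    def test_agrees_with_statsmodels_on_ties_free_input(self, rng):
        from statsmodels.stats.multitest import multipletests

        # strict "<" vs statsmodels "<=" differ only on exact-boundary ties,
        # which have measure zero for continuous p-values
        p = rng.uniform(1e-6, 1.0, size=200)
        d = fdr_threshold(p, q_star=0.05)
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(d.mask, reject)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold([])


class TestTTests:
    def test_paired_equal_inputs(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        t, p = paired_ttest_onetailed(x, x)
        assert t == 0.0 and p == 0.5

    def test_paired_matches_formula_oracle(self):
        x = np.array([0.52, 0.61, 0.44, 0.70, 0.58])
        y = np.array([0.41, 0.55, 0.46, 0.60, 0.50])
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_oracle = sps.t.sf(t_oracle, df=d.size - 1)
        t, p = paired_ttest_onetailed(x, y)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_paired_swap_maps_p_to_one_minus_p(self, rng):
        x, y = rng.standard_normal(8), rng.standard_normal(8)
        _, p1 = paired_ttest_onetailed(x, y)
        _, p2 = paired_ttest_onetailed(y, x)
        assert p1 + p2 == pytest.approx(1.0)

    def test_twosample_identical_groups(self):
        g = np.array([0.3, 0.5, 0.4, 0.6])
        t, p = twosample_ttest_onetailed(g, g)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_twosample_detects_large_shift(self, rng):
        a = rng.normal(1.0, 0.1, size=15)
        b = rng.normal(0.0, 0.1, size=15)
        _, p = twosample_ttest_onetailed(a, b)
        assert p < 0.001

    def test_twosample_matches_welch_formula_oracle(self):
        a = np.array([0.30, 0.45, 0.52, 0.38])
        b = np.array([0.25, 0.31, 0.29, 0.40])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_oracle = sps.t.sf(t_oracle, df=df)
        t, p = twosample_ttest_onetailed(a, b)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-10)


class TestCovariateRegression:
    def test_perfect_linear_relation(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        slope, r2 = covariate_regression(0.1 + 0.05 * cov, cov)
        assert slope == pytest.approx(0.05)
        assert r2 == pytest.approx(1.0)

    def test_null_simulation_small_r2(self, rng):
        slopes, r2s = [], []
        for _ in range(1000):
            r = rng.normal(0.4, 0.1, size=15)
            cov = rng.integers(1, 6, size=15).astype(float)
            if cov.std() == 0:
                continue
            s, q = covariate_regression(r, cov)
            slopes.append(s)
            r2s.append(q)
        assert np.mean(r2s) < 0.15
        assert abs(np.mean(slopes)) < 0.01

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            covariate_regression([0.1, 0.2, 0.3], [2.0, 2.0, 2.0])

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            covariate_regression([0.1, 0.2], [1.0, 2.0])
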