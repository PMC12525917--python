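"""Multi-trait Gibbs sampler: bookkeeping, conjugacy, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.signal import lfilter

from semgwas import (
    MTModelSpec, autocorrelation, geweke_diagnostic, hpd_interval,
    n_retained_draws, run_gibbs, summarize_posterior,
)
from semgwas.gblup import (
    PosteriorSamples, conditional_genetic_mean, sample_inverse_wishart,
)


def _small_problem(n=30, t=3, seed=4):
    rng = np.random.Generator(np.random.PCG64(seed))
    A = rng.standard_normal((n, n)) / np.sqrt(n)
    G = A @ A.T + 0.5 * np.eye(n)
    y = rng.standard_normal((n, t))
    return y, G


class TestSchedule:
    @pytest.mark.parametrize("iters,burn,thin,expect", [
        (1_000, 0, 1, 1_000),
        (1_000, 200, 10, 80),
        (3_000_000, 300_000, 50, 54_000),
    ])
    def test_retained_count(self, iters, burn, thin, expect):
        assert n_retained_draws(iters, burn, thin) == expect

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(10, 5000), st.integers(0, 5000), st.integers(1, 20))
    def test_retained_count_fuzz(self, iters, burn, thin):
        if burn >= iters:
            burn = burn % iters
        r = n_retained_draws(iters, burn, thin)
        # oracle: explicit enumeration of the sampler's kept iterations
        kept = sum(1 for it in range(iters)
                   if it >= burn and (it - burn + 1) % thin == 0)
        assert r == (iters - burn) // thin == kept

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MTModelSpec(traits=["a"], iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MTModelSpec(traits=["a"], thin=0)
        with pytest.raises(ValueError):
            MTModelSpec(traits=["a", "b"], nu=0.5)


class TestSampler:
    def test_seeded_determinism(self):
        y, G = _small_problem()
        spec = MTModelSpec(traits=["t1", "t2", "t3"], iterations=300,
                           burn_in=100, thin=2, seed=99)
        s1 = run_gibbs(y, G, spec)
        s2 = run_gibbs(y, G, spec)
        np.testing.assert_array_equal(s1.b, s2.b)
        np.testing.assert_array_equal(s1.Sigma_g, s2.Sigma_g)
        np.testing.assert_array_equal(s1.g, s2.g)

    def test_draw_count_and_spd(self):
        y, G = _small_problem()
        spec = MTModelSpec(traits=["t1", "t2", "t3"], iterations=500,
                           burn_in=100, thin=3, seed=0)
        s = run_gibbs(y, G, spec)
        assert s.n_draws == n_retained_draws(500, 100, 3)
        for Sg, Se in zip(s.Sigma_g, s.Sigma_e):
            assert np.linalg.eigvalsh(Sg).min() > 0
            assert np.linalg.eigvalsh(Se).min() > 0

    def test_missing_cells_rejected(self):
        y, G = _small_problem()
        y[0, 0] = np.nan
        spec = MTModelSpec(traits=["t1", "t2", "t3"], iterations=100, burn_in=10)
        with pytest.raises(ValueError, match="missing"):
            run_gibbs(y, G, spec)

    def test_inverse_wishart_moments(self, rng):
        """Bartlett draws match the IW mean scale/(df-p-1) and scipy."""
        S = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, -0.2], [0.0, -0.2, 1.5]])
        df = 12.0
        draws = np.array([sample_inverse_wishart(rng, S, df) for _ in range(4000)])
        np.testing.assert_allclose(draws.mean(axis=0), S / (df - 3 - 1),
                                   atol=0.03)
        sp = stats.invwishart(df=df, scale=S).rvs(4000, random_state=1)
        np.testing.assert_allclose(draws.mean(axis=0), sp.mean(axis=0), atol=0.04)

    def test_univariate_conjugacy_closed_form(self, rng):
        """In 1-d the IW(s, nu) conditional is InvGamma(nu/2, s/2)."""
        s, nu = 3.0, 9.0
        draws = np.array([sample_inverse_wishart(rng, np.array([[s]]), nu)[0, 0]
                          for _ in range(3000)])
        ks = stats.kstest(draws, stats.invgamma(nu / 2, scale=s / 2).cdf)
        assert ks.pvalue > 0.01

    def test_conditional_mean_matches_naive_kron_solve(self, rng):
        """Rotated g-update equals the full mixed-model-equation solve."""
        n, t = 12, 3
        A = rng.standard_normal((n, n))
        G = A @ A.T / n + 0.3 * np.eye(n)
        Sg = np.array([[1.0, 0.4, 0.1], [0.4, 0.8, -0.2], [0.1, -0.2, 1.2]])
        Se = np.array([[0.9, 0.2, 0.0], [0.2, 1.1, 0.3], [0.0, 0.3, 0.7]])
        resid = rng.standard_normal((n, t))
        fast = conditional_genetic_mean(resid, G, Sg, Se)
        P = np.kron(np.linalg.inv(Se), np.eye(n)) + np.kron(
            np.linalg.inv(Sg), np.linalg.inv(G))
        rhs = np.kron(np.linalg.inv(Se), np.eye(n)) @ resid.T.ravel()
        naive = np.linalg.solve(P, rhs).reshape(t, n).T
        np.testing.assert_allclose(fast, naive, atol=1e-8)


class TestSummaries:
    def _fake_samples(self, Sg, Se, r=500):
        t = Sg.shape[0]
        traits = [f"t{i}" for i in range(t)]
        return PosteriorSamples(
            traits=traits,
            b=np.zeros((r, t)),
            Sigma_g=np.tile(Sg, (r, 1, 1)),
            Sigma_e=np.tile(Se, (r, 1, 1)),
            g=None,
        )

    def test_zero_residual_gives_h2_one(self):
        Sg = np.eye(2) + 0.5
        s = self._fake_samples(Sg, np.zeros((2, 2)))
        summ = summarize_posterior(s)
        assert (summ.heritability["mean"] == 1.0).all()

    def test_null_genomic_correlation_not_flagged(self, rng):
        r = 400
        var = 1.0 + 0.1 * rng.random(r)
        cov = 0.01 * rng.standard_normal(r)
        Sg = np.zeros((r, 2, 2))
        Sg[:, 0, 0] = Sg[:, 1, 1] = var
        Sg[:, 0, 1] = Sg[:, 1, 0] = cov
        s = PosteriorSamples(traits=["a", "b"], b=np.zeros((r, 2)),
                             Sigma_g=Sg, Sigma_e=np.tile(np.eye(2), (r, 1, 1)),
                             g=None)
        summ = summarize_posterior(s)
        row = summ.genomic_correlation.iloc[0]
        assert abs(row["mean"]) < 0.05
        assert not row["significant"]


class TestHPD:
    def test_constant_draws(self):
        lo, hi = hpd_interval(np.full(50, 3.14))
        assert (lo, hi) == (3.14, 3.14)

    def test_grid_equals_bruteforce(self):
        x = np.arange(1, 1001, dtype=float)
        lo, hi = hpd_interval(x, 0.95)
        k = int(np.ceil(0.95 * 1000))
        widths = [(x[i + k - 1] - x[i], x[i], x[i + k - 1])
                  for i in range(1000 - k + 1)]
        bw, blo, bhi = min(widths)
        assert hi - lo == pytest.approx(bw)
        assert (lo, hi) == (blo, bhi)

    def test_bruteforce_on_random_draws(self, rng):
        for _ in range(20):
            x = rng.gamma(2.0, size=200)
            lo, hi = hpd_interval(x, 0.9)
            xs = np.sort(x)
            k = int(np.ceil(0.9 * 200))
            best = min((xs[i + k - 1] - xs[i], xs[i], xs[i + k - 1])
                       for i in range(200 - k + 1))
            assert (lo, hi) == (best[1], best[2])

    def test_normal_limit(self, rng):
        x = rng.standard_normal(100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_prob_validation(self, rng):
        with pytest.raises(ValueError):
            hpd_interval(rng.standard_normal(100), 1.5)


class TestDiagnostics:
    def test_geweke_null_calibration(self):
        hits = 0
        for s in range(100):
            rng = np.random.Generator(np.random.PCG64(1000 + s))
            z = geweke_diagnostic(rng.standard_normal(10_000))
            hits += abs(z) < 3
        assert hits >= 95

    def test_geweke_detects_drift(self, rng):
        chain = np.linspace(0, 10, 10_000) + 0.1 * rng.standard_normal(10_000)
        assert abs(geweke_diagnostic(chain)) > 5

    def test_geweke_constant_chain_undefined(self):
        assert np.isnan(geweke_diagnostic(np.ones(500)))

    def test_acf_lag0(self, rng):
        acf = autocorrelation(rng.standard_normal(1000), [0, 1])
        assert acf[0] == 1.0

    def test_acf_ar1_closed_form(self):
        rng = np.random.Generator(np.random.PCG64(2))
        x = lfilter([1.0], [1.0, -0.9], rng.standard_normal(100_000))
        acf = autocorrelation(x, [0, 1])
        assert acf[1] == pytest.approx(0.9, abs=0.02)

    def test_acf_iid_band(self):
        rng = np.random.Generator(np.random.PCG64(3))
        n = 20_000
        acf = autocorrelation(rng.standard_normal(n), [1, 5, 10])
        assert (np.abs(acf) < 3 / np.sqrt(n)).all()

    def test_acf_constant_chain_flagged(self):
        acf = autocorrelation(np.ones(100), [0, 1, 2])
        assert acf[0] == 1.0 and np.isnan(acf[1:]).all()
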