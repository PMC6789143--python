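import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiodyn import simulate_fbm, simulate_lorenz
from cardiodyn.errors import DegenerateInputError, InvalidInputError
from cardiodyn.nonlin import (
    acf_lag,
    capacity_dimension,
    correlation_dimension,
    correlation_integral,
    embed,
    fnn_embedding_dim,
    select_scaling_region,
    steady_value,
    variogram,
)


# ---------------------------------------------------------------------------
# independent O(N^2) oracle for the correlation integral (pure python)
# ---------------------------------------------------------------------------


def naive_correlation_integral(X, n_bins=32):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(math.sqrt(float(((X[i] - X[j]) ** 2).sum())))
    nonzero = [d for d in dists if d > 0]
    r_min, r_max = min(nonzero), max(dists)
    edges = [
        math.exp(math.log(r_min) + k * (math.log(r_max) - math.log(r_min)) / n_bins)
        for k in range(1, n_bins + 1)
    ]
    edges[-1] = r_max
    norm = 2.0 / (n * (n - 1))
    C = [norm * sum(1 for d in dists if d <= e) for e in edges]
    return np.array(edges), np.array(C)


class TestVariogram:
    def test_constant_signal_degenerate(self):
        v = variogram(np.full(64, 5.0))
        assert v.degenerate
        assert np.all(v.gamma == 0.0)

    def test_alternating_signal_gamma1_half(self):
        S = np.tile([0.0, 1.0], 32)
        v = variogram(S, tau_max=4)
        assert v.gamma[0] == pytest.approx(0.5)
        assert v.gamma[1] == pytest.approx(0.0)  # lag 2 pairs are identical

    def test_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            variogram(np.arange(5))

    def test_tau_max_bounds(self):
        with pytest.raises(InvalidInputError):
            variogram(np.arange(32), tau_max=20)

    def test_fbm_h05_slope_near_one(self):
        slopes = []
        for seed in range(5):
            v = capacity_dimension(variogram(simulate_fbm(0.5, 4096, seed=seed)))
            slopes.append(v.P)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.1)


class TestCapacityDimension:
    def test_closed_form_endpoints(self):
        # P = 2 -> D = 1 and P = 0 -> D = 2, via exact power-law variograms
        taus = np.arange(1, 65)
        for P, D_expected in ((2.0, 1.0), (0.0, 2.0)):
            from cardiodyn.nonlin import VariogramResult

            v = VariogramResult(tau=taus, gamma=taus.astype(float) ** P)
            v = capacity_dimension(v, fit_range=(1, 64))
            assert v.P == pytest.approx(P, abs=1e-9)
            assert v.D_capacity_mean == pytest.approx(D_expected, abs=1e-9)

    def test_fbm_h07_capacity(self):
        Ds = [
            capacity_dimension(variogram(simulate_fbm(0.7, 4096, seed=s))).D_capacity_mean
            for s in range(10)
        ]
        assert np.mean(Ds) == pytest.approx(1.3, abs=0.1)

    def test_degenerate_gives_nan_sentinels(self):
        v = capacity_dimension(variogram(np.full(64, 1.0)))
        assert math.isnan(v.P) and math.isnan(v.D_capacity_mean)

    def test_amplitude_invariance(self):
        s = simulate_fbm(0.5, 1024, seed=3)
        p1 = capacity_dimension(variogram(s)).P
        p2 = capacity_dimension(variogram(100.0 * s)).P
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestAcfLag:
    def test_iid_noise_tau_star_one(self, rng):
        assert acf_lag(rng.standard_normal(50_000)).tau_star == 1

    def test_ar1_phi09(self, rng):
        n = 100_000
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + e[i]
        # analytic ACF 0.9^tau crosses 1/e between lags 9 and 10
        assert acf_lag(x).tau_star in (9, 10)

    def test_sine_ceil_formula(self):
        T = 160
        S = np.sin(2 * np.pi * np.arange(16000) / T)
        expected = math.ceil(T * math.acos(1 / math.e) / (2 * math.pi))
        assert acf_lag(S).tau_star == expected == 31

    def test_constant_signal_sentinel(self):
        r = acf_lag(np.full(64, 2.0))
        assert r.warning and math.isnan(r.k)

    def test_never_crossing_warns(self):
        S = np.linspace(0, 1, 64)  # slow trend: ACF crosses 1/e only at lag ~14
        r = acf_lag(S, max_lag=8)
        assert r.warning
        assert r.tau_star == 8

    def test_k_is_reciprocal_of_tau_star(self, rng):
        r = acf_lag(rng.standard_normal(1000))
        assert r.k == pytest.approx(1.0 / r.tau_star)


class TestEmbed:
    def test_basic_rows(self):
        X = embed(np.array([1.0, 2, 3, 4, 5]), m=2, tau=1).X
        assert np.array_equal(X, [[1, 2], [2, 3], [3, 4], [4, 5]])

    def test_m1_equals_series(self):
        S = np.arange(10.0)
        assert np.array_equal(embed(S, 1, 3).X.ravel(), S)

    def test_single_row(self):
        X = embed(np.array([1.0, 2, 3, 4, 5]), m=3, tau=2).X
        assert np.array_equal(X, [[1, 3, 5]])

    def test_too_short_names_minimum(self):
        with pytest.raises(InvalidInputError, match="N >= 11"):
            embed(np.arange(10.0), m=3, tau=5)

    @given(
        n=st.integers(10, 60),
        m=st.integers(1, 4),
        tau=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_row_property(self, n, m, tau):
        S = np.arange(n, dtype=float)
        if n - (m - 1) * tau < 1:
            with pytest.raises(InvalidInputError):
                embed(S, m, tau)
            return
        E = embed(S, m, tau)
        assert E.X.shape == (n - (m - 1) * tau, m)
        j = E.X.shape[0] - 1
        assert np.array_equal(E.X[j], S[j : j + (m - 1) * tau + 1 : tau])


class TestFnn:
    def test_sine_embeds_in_two_dimensions(self):
        S = np.sin(0.04 * np.arange(4000))
        tau = acf_lag(S).tau_star
        assert fnn_embedding_dim(S, tau).m == 2

    def test_lorenz_embeds_in_three_dimensions(self):
        x = simulate_lorenz(8000, dt=0.01, seed_state=0)
        # standard Lorenz delay ~0.1 time units = 10 samples at dt=0.01
        assert fnn_embedding_dim(x, tau=10).m == 3

    def test_noise_has_no_finite_embedding(self, rng):
        r = fnn_embedding_dim(rng.uniform(size=1500), tau=1, m_max=8)
        assert r.warning and r.m == 8

    def test_preconditions(self):
        with pytest.raises(InvalidInputError):
            fnn_embedding_dim(np.arange(100.0), tau=0)
        with pytest.raises(InvalidInputError):
            fnn_embedding_dim(np.arange(100.0), tau=1, m_max=1)


class TestCorrelationIntegral:
    def test_two_points_step_function(self):
        ci = correlation_integral(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert ci.r_min == ci.r_max == 5.0
        assert np.all(ci.C == 1.0)  # normalization 2/(2*1) = 1 above d

    def test_monotone_in_r(self, rng):
        ci = correlation_integral(rng.uniform(size=(200, 2)))
        assert np.all(np.diff(ci.C) >= 0)

    def test_last_bin_is_one(self, rng):
        ci = correlation_integral(rng.standard_normal((150, 3)))
        assert ci.C[-1] == pytest.approx(1.0, abs=1e-12)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateInputError):
            correlation_integral(np.zeros((40, 2)))

    def test_uniform_square_slope_near_two(self, rng):
        X = rng.uniform(size=(500, 2))
        ci = correlation_integral(X)
        _, slope, _ = select_scaling_region(ci)
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_matches_naive_oracle_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(40, 300))
            m = int(rng.integers(1, 5))
            X = rng.standard_normal((n, m))
            ci = correlation_integral(X)
            edges_o, C_o = naive_correlation_integral(X)
            assert np.array_equal(ci.C, C_o)
            # edges agree to the last ulp (independent exp/log code paths)
            assert np.allclose(ci.edges, edges_o, rtol=1e-12, atol=0)

    def test_chunking_does_not_change_result(self, rng):
        X = rng.standard_normal((257, 3))
        a = correlation_integral(X, chunk=16)
        b = correlation_integral(X, chunk=100_000)
        assert np.array_equal(a.C, b.C)

    def test_anti_monotone_in_m(self):
        # adding a delay coordinate can only grow pairwise distances, so on a
        # shared point set C_{m+1}(r) <= C_m(r) at every radius
        from scipy.spatial.distance import pdist

        S = np.sin(0.04 * np.arange(2000))
        for m in (2, 3, 4):
            n_shared = 2000 - m * 31
            Xa = embed(S, m, 31).X[:n_shared]
            Xb = embed(S, m + 1, 31).X
            da, db = pdist(Xa), pdist(Xb)
            assert np.all(db >= da - 1e-12)
            for r in np.exp(np.linspace(np.log(da[da > 0].min()), np.log(da.max()), 8)):
                assert (db <= r).sum() <= (da <= r).sum()

    def test_theiler_window_excludes_temporal_pairs(self):
        S = np.sin(0.04 * np.arange(1000))
        base = correlation_integral(embed(S, 2, 31))
        excl = correlation_integral(embed(S, 2, 31), theiler=31)
        assert excl.counts.sum() < base.counts.sum()


class TestCorrelationDimension:
    def test_sine_plateaus_at_one(self):
        S = np.sin(0.04 * np.arange(4000))
        res = correlation_dimension(S, m_values=range(2, 9))
        assert res.plateau
        assert res.D_steady == pytest.approx(1.0, abs=0.15)

    def test_noise_increases_without_plateau(self, rng):
        x = rng.uniform(size=2000)
        res = correlation_dimension(x, tau=1, m_values=range(2, 9))
        D = res.D_of_m()
        assert np.all(np.diff(D) > 0.1)
        assert not res.plateau

    def test_amplitude_invariance(self):
        S = np.sin(0.04 * np.arange(2000))
        r1 = correlation_dimension(S, m_values=range(2, 6))
        r2 = correlation_dimension(1e3 * S, m_values=range(2, 6))
        for m in r1.slopes:
            assert r1.slopes[m] == pytest.approx(r2.slopes[m], abs=1e-9)

    def test_too_short_embeddings_skipped_with_warning(self):
        S = np.sin(0.04 * np.arange(120))
        res = correlation_dimension(S, tau=30, m_values=range(2, 8))
        assert any("skipped" in w for w in res.warnings)


class TestSteadyValue:
    def test_stated_example(self):
        val, flag = steady_value([1.0, 1.5, 1.9, 2.0, 2.02, 2.01])
        assert flag
        assert val == pytest.approx(2.01, abs=0.005)

    def test_strictly_increasing_no_plateau(self):
        val, flag = steady_value([1.0, 2.0, 3.0, 4.0])
        assert not flag
        assert val == 4.0

    def test_constant_returns_constant(self):
        val, flag = steady_value([1.7, 1.7, 1.7])
        assert flag and val == pytest.approx(1.7)

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_value_within_observed_range(self, d):
        val, _ = steady_value(d)
        assert min(d) - 1e-9 <= val <= max(d) + 1e-9
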