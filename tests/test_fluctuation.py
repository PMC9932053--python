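import numpy as np
import pytest

from pawflux.errors import AnalysisError, DegenerateSeriesError, ParameterError
from pawflux.fluctuation import (
    FluctuationMatrix,
    compute_fluctuation_matrices,
    dcca_coefficients,
    default_scale_grid,
    delay_aligned_matrices,
    delayed_coupling,
    dpcca_coefficients,
    fluctuation_matrix,
    profile,
    scale_correlations,
    sliding_residuals,
    total_squared_displacement,
)
from pawflux.synthetic import gen_power_law_series

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_f2(series, s, order=2):
    """Naive triple-loop Eq.-by-Eq. route: cumsum, per-window polyfit,
    residual products.  Deliberately independent of the library path."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    m, n = series.shape
    profs = np.cumsum(series - series.mean(axis=1, keepdims=True), axis=1)
    t = np.arange(s + 1, dtype=float)
    streams = []
    for j in range(m):
        parts = []
        for i in range(n - s):
            w = profs[j, i : i + s + 1]
            coef = np.polyfit(t, w, order)
            parts.append(w - np.polyval(coef, t))
        streams.append(np.concatenate(parts))
    streams = np.asarray(streams)
    f2 = np.empty((m, m))
    denom = (n - s) * (s + 1)
    for j1 in range(m):
        for j2 in range(m):
            f2[j1, j2] = np.sum(streams[j1] * streams[j2]) / denom
    return f2


def textbook_dfa(x, s, order=2):
    """Independent sliding-window DFA fluctuation function F(s)."""
    x = np.asarray(x, dtype=float)
    prof = np.cumsum(x - x.mean())
    t = np.arange(s + 1, dtype=float)
    total = 0.0
    for i in range(len(x) - s):
        w = prof[i : i + s + 1]
        res = w - np.polyval(np.polyfit(t, w, order), t)
        total += np.sum(res**2)
    return np.sqrt(total / ((len(x) - s) * (s + 1)))


# ---------------------------------------------------------------------------
# profile


class TestProfile:
    def test_cumsum_examples(self):
        np.testing.assert_array_equal(profile([1, 1, 1]), [1, 2, 3])
        np.testing.assert_array_equal(profile([0, 0, 0]), [0, 0, 0])

    def test_differencing_inverts(self, rng):
        x = rng.normal(size=257)
        p = profile(x)
        np.testing.assert_allclose(np.diff(p, prepend=0.0), x, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            profile([])


# ---------------------------------------------------------------------------
# residuals


class TestSlidingResiduals:
    def test_quadratic_profile_nulled(self):
        n = 50
        t = np.arange(n, dtype=float)
        prof = 3.0 + 2.0 * t + 0.5 * t**2
        res = sliding_residuals(prof, s=10, order=2)
        assert np.abs(res).max() < 1e-8

    def test_constant_series_zero_fluctuation(self):
        prof = profile(np.full(40, 7.0))  # linear profile
        res = sliding_residuals(prof, s=8, order=1)
        assert np.abs(res).max() < 1e-9

    def test_single_window_matches_polyfit(self, rng):
        s = 12
        prof = rng.normal(size=s + 1).cumsum()
        res = sliding_residuals(prof, s=s, order=2)
        assert res.shape == (1, 1, s + 1)
        t = np.arange(s + 1, dtype=float)
        expected = prof - np.polyval(np.polyfit(t, prof, 2), t)
        np.testing.assert_allclose(res[0, 0], expected, atol=1e-10)

    def test_residual_count_matches_denominator(self, rng):
        n, s = 80, 9
        res = sliding_residuals(rng.normal(size=n).cumsum(), s=s)
        assert res[0].size == (n - s) * (s + 1)

    def test_window_residuals_sum_to_zero(self, rng):
        res = sliding_residuals(rng.normal(size=60).cumsum(), s=10, order=2)
        np.testing.assert_allclose(res[0].sum(axis=1), 0.0, atol=1e-9)

    def test_scale_too_small_for_order(self, rng):
        with pytest.raises(ParameterError):
            sliding_residuals(rng.normal(size=30), s=2, order=2)


# ---------------------------------------------------------------------------
# fluctuation matrix


class TestFluctuationMatrix:
    def test_diagonal_matches_textbook_dfa(self, rng):
        for _ in range(5):
            x = rng.normal(size=150)
            for s in (8, 16):
                fm = compute_fluctuation_matrices(x, scales=[s])
                f = np.sqrt(fm.f2[0, 0, 0])
                assert abs(f - textbook_dfa(x, s)) < 1e-10 * max(1.0, f)

    def test_identical_series_off_diagonal(self, rng):
        x = rng.normal(size=100)
        fm = compute_fluctuation_matrices(np.stack([x, x]), scales=[10])
        assert fm.f2[0, 0, 1] == pytest.approx(fm.f2[0, 0, 0], rel=1e-12)

    def test_sign_flip(self, rng):
        x = rng.normal(size=100)
        fm = compute_fluctuation_matrices(np.stack([x, -x]), scales=[10])
        assert fm.f2[0, 0, 1] == pytest.approx(-fm.f2[0, 0, 0], rel=1e-12)

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(3, 120))
        for s in (8, 14, 20):
            bf = brute_force_f2(x, s)
            fm = compute_fluctuation_matrices(x, scales=[s])
            np.testing.assert_allclose(fm.f2[0], bf, rtol=1e-10, atol=1e-12)

    def test_explicit_route_agrees_with_fast_route(self, rng):
        x = rng.normal(size=(4, 300))
        profs = profile(x - x.mean(axis=1, keepdims=True))
        for s in (8, 32, 64):
            explicit = fluctuation_matrix(sliding_residuals(profs, s))
            fast = compute_fluctuation_matrices(x, scales=[s]).f2[0]
            np.testing.assert_allclose(fast, explicit, rtol=1e-10)

    def test_fast_route_on_persistent_series(self):
        # strongly persistent input is the cancellation-prone corner
        x = np.stack([gen_power_law_series(4096, 2.0, s) for s in range(2)])
        profs = profile(x - x.mean(axis=1, keepdims=True))
        for s in (8, 64, 512):
            explicit = fluctuation_matrix(sliding_residuals(profs, s))
            fast = compute_fluctuation_matrices(x, scales=[s]).f2[0]
            np.testing.assert_allclose(fast, explicit, rtol=1e-8)

    def test_misaligned_residuals_rejected(self, rng):
        with pytest.raises(AnalysisError):
            fluctuation_matrix(rng.normal(size=(3, 10)))

    def test_symmetry_property(self, rng):
        for _ in range(5):
            x = rng.normal(size=(4, 200))
            fm = compute_fluctuation_matrices(x, scales=[8, 16, 32])
            for k in range(3):
                np.testing.assert_allclose(fm.f2[k], fm.f2[k].T, rtol=1e-12)
                assert (np.diag(fm.f2[k]) >= 0).all()


def test_default_scale_grid_bounds():
    grid = default_scale_grid(1024)
    assert grid[0] == 8
    assert grid[-1] == 256
    assert (np.diff(grid) > 0).all()
    with pytest.raises(ParameterError):
        default_scale_grid(20)


# ---------------------------------------------------------------------------
# DCCA / DPCCA coefficients


class TestDcca:
    def test_diagonal_exactly_one(self, rng):
        x = rng.normal(size=(5, 300))
        fm = compute_fluctuation_matrices(x, scales=[8, 16, 64])
        r = dcca_coefficients(fm.f2)
        for k in range(3):
            assert (np.diag(r[k]) == 1.0).all()

    def test_scale_shift_invariance(self, rng):
        x = rng.normal(size=400)
        fm = compute_fluctuation_matrices(np.stack([x, 3 * x + 17.0]), scales=[16])
        r = dcca_coefficients(fm.f2[0])
        assert r[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_series_null(self):
        n = 2**13
        grid = default_scale_grid(n, s_max=n // 8)
        vals = []
        for seed in range(10):
            x = np.stack(
                [
                    gen_power_law_series(n, 0.5, 1000 + seed),
                    gen_power_law_series(n, 0.5, 2000 + seed),
                ]
            )
            fm = compute_fluctuation_matrices(x, scales=grid)
            vals.append(np.abs(dcca_coefficients(fm.f2)[:, 0, 1]))
        assert np.median(vals, axis=0).max() < 0.1

    def test_constant_series_degenerate(self):
        x = np.stack([np.arange(50.0), np.full(50, 3.0)])
        fm = compute_fluctuation_matrices(x, scales=[8], labels=["a", "b"])
        with pytest.raises(DegenerateSeriesError, match="b"):
            dcca_coefficients(fm.f2, labels=["a", "b"])

    def test_bounds_and_symmetry(self, rng):
        for _ in range(10):
            x = rng.normal(size=(5, 150))
            fm = compute_fluctuation_matrices(x, scales=[8, 16])
            r = dcca_coefficients(fm.f2)
            assert np.abs(r).max() <= 1 + 1e-9
            np.testing.assert_allclose(r, np.swapaxes(r, 1, 2), rtol=1e-12)


class TestDpcca:
    def test_m2_partial_equals_r(self, rng):
        x = rng.normal(size=(2, 300))
        r = dcca_coefficients(compute_fluctuation_matrices(x, scales=[16]).f2[0])
        p = dpcca_coefficients(r)
        assert p[0, 1] == pytest.approx(r[0, 1], abs=1e-12)

    def test_m3_textbook_closed_form(self, rng):
        x = rng.normal(size=(3, 400))
        x[1] += 0.5 * x[0]
        x[2] += 0.3 * x[1]
        r = dcca_coefficients(compute_fluctuation_matrices(x, scales=[20]).f2[0])
        p = dpcca_coefficients(r)
        expected = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
        )
        assert p[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_chain_conditional_independence(self):
        # x -> y -> z: partial x-z correlation vanishes though R_xz is large
        n = 2**12
        p_vals, r_vals = [], []
        for seed in range(10):
            r_ = np.random.default_rng(seed)
            x = gen_power_law_series(n, 0.8, seed)
            y = x + 0.4 * r_.standard_normal(n)
            z = y + 0.4 * r_.standard_normal(n)
            fm = compute_fluctuation_matrices(
                np.stack([x, y, z]), scales=default_scale_grid(n, s_max=n // 8)
            )
            sc = scale_correlations(fm)
            p_vals.append(np.abs(sc.p[:, 0, 2]).max())
            r_vals.append(np.abs(sc.r[:, 0, 2]).min())
        assert np.median(p_vals) < 0.1
        assert np.median(r_vals) > 0.5

    def test_symmetry(self, rng):
        x = rng.normal(size=(5, 200))
        sc = scale_correlations(compute_fluctuation_matrices(x, scales=[8, 16]))
        np.testing.assert_allclose(sc.p, np.swapaxes(sc.p, 1, 2), rtol=1e-10)
        assert (np.diagonal(sc.p, axis1=1, axis2=2) == 1.0).all()


# ---------------------------------------------------------------------------
# delayed coupling


def _residuals_for(x, s, order=2):
    return sliding_residuals(profile(x - x.mean()), s, order=order)[0]


class TestDelayedCoupling:
    def test_autocoupling(self, rng):
        r = _residuals_for(rng.normal(size=200), 20)
        dc = delayed_coupling(r, r)
        assert dc.delay == 0
        assert dc.strength == pytest.approx(1.0, abs=1e-12)

    def test_shift_recovery_exact(self, rng):
        base = rng.normal(size=600).cumsum()
        x1, x2 = base[5:505], base[:500]  # x2 lags x1 by 5 frames
        for s in (10, 14, 30):
            dc = delayed_coupling(_residuals_for(x1, s), _residuals_for(x2, s))
            assert dc.delay == 5

    def test_antisymmetry(self, rng):
        base = rng.normal(size=600).cumsum()
        x1, x2 = base[5:505], base[:500]
        r1, r2 = _residuals_for(x1, 20), _residuals_for(x2, 20)
        assert delayed_coupling(r1, r2).delay == -delayed_coupling(r2, r1).delay

    def test_zero_shift_reproduces_synchronous_value(self, rng):
        x = rng.normal(size=(2, 150))
        profs = profile(x - x.mean(axis=1, keepdims=True))
        res = sliding_residuals(profs, 12)
        f2 = fluctuation_matrix(res)
        dc = delayed_coupling(res[0], res[1])
        k0 = dc.covariances[list(dc.shifts).index(0)]
        expected = f2[0, 1] / np.sqrt(f2[0, 0] * f2[1, 1])
        assert k0 == pytest.approx(expected, abs=1e-12)

    def test_strength_at_delay_dominates_zero_shift(self, rng):
        base = rng.normal(size=600).cumsum()
        dc = delayed_coupling(
            _residuals_for(base[5:505], 20), _residuals_for(base[:500], 20)
        )
        k0 = dc.covariances[list(dc.shifts).index(0)]
        assert dc.strength >= k0

    def test_small_scale_rejected(self, rng):
        r = _residuals_for(rng.normal(size=50), 3)[:, :2]
        with pytest.raises((ParameterError, AnalysisError)):
            delayed_coupling(r, r[:, :1])

    def test_max_shift_capped(self, rng):
        r = _residuals_for(rng.normal(size=100), 10)
        with pytest.raises(ParameterError):
            delayed_coupling(r, r, max_shift=6)

    def test_fft_path_matches_direct(self, rng):
        from pawflux.fluctuation import _window_cross_covariance

        r1 = rng.normal(size=(300, 21))
        r2 = rng.normal(size=(300, 21))
        shifts_d, cov_d = _window_cross_covariance(r1, r2, 10)
        import pawflux.fluctuation as fl

        # force the FFT branch by lowering the direct-path budget
        n_win, w = r1.shape
        assert (2 * 10 + 1) * n_win * w <= 2e8
        from scipy.fft import irfft, next_fast_len, rfft

        nfft = next_fast_len(2 * n_win - 1)
        spec = (np.conj(rfft(r1, n=nfft, axis=0)) * rfft(r2, n=nfft, axis=0)).sum(axis=1)
        c_full = irfft(spec, n=nfft)
        cov_f = c_full[shifts_d % nfft] / ((n_win - np.abs(shifts_d)) * w)
        np.testing.assert_allclose(cov_d, cov_f, rtol=1e-9, atol=1e-12)

    def test_tie_breaking_prefers_small_then_negative(self):
        from pawflux.fluctuation import _argmax_preferring_small_shift

        shifts = np.arange(-3, 4)
        vals = np.ones(7)
        assert shifts[_argmax_preferring_small_shift(shifts, vals)] == 0
        vals = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0])  # ties at -2 and +2
        assert shifts[_argmax_preferring_small_shift(shifts, vals)] == -2


class TestDelayAlignedMatrices:
    def test_structure(self, rng):
        x = rng.normal(size=(3, 300))
        r_al, p_al, delays = delay_aligned_matrices(x, s=16)
        np.testing.assert_allclose(r_al, r_al.T, rtol=1e-12)
        np.testing.assert_array_equal(delays, -delays.T)
        assert (np.diag(r_al) == 1.0).all()

    def test_delay_recovery(self, rng):
        base = rng.normal(size=700).cumsum()
        x = np.stack([base[10:510], base[5:505], base[:500]])
        _, _, delays = delay_aligned_matrices(x, s=24)
        assert delays[0, 1] == 5
        assert delays[0, 2] == 10
        assert delays[1, 2] == 5


# ---------------------------------------------------------------------------
# total squared displacement


class TestTotalSquaredDisplacement:
    def _fm(self, series, scales, labels):
        return compute_fluctuation_matrices(series, scales=scales, labels=labels)

    def test_zero_y_is_identity(self, rng):
        x = rng.normal(size=(2, 200))
        scales = [8, 16]
        fx = self._fm(x, scales, ["a:x", "b:x"])
        fy = FluctuationMatrix(
            scales=np.array(scales), f2=np.zeros_like(fx.f2), labels=["a:y", "b:y"]
        )
        total = total_squared_displacement(fx, fy)
        np.testing.assert_array_equal(total.f2, fx.f2)
        assert total.labels == ["a", "b"]

    def test_iid_axes_double(self):
        ratios = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=(2, 2048))
            scales = [16, 64]
            fx = self._fm(x, scales, ["p:x"])
            fy = self._fm(y, scales, ["p:y"])
            total = total_squared_displacement(fx, fy)
            ratios.append((total.f2 / fx.f2).mean())
        assert 1.8 <= np.median(ratios) <= 2.2

    def test_rotation_invariance(self, rng):
        x, y = rng.normal(size=(2, 500))
        c, s_ = np.cos(np.pi / 4), np.sin(np.pi / 4)
        xr, yr = c * x - s_ * y, s_ * x + c * y
        scales = [8, 32]
        t1 = total_squared_displacement(
            self._fm(x, scales, ["p:x"]), self._fm(y, scales, ["p:y"])
        )
        t2 = total_squared_displacement(
            self._fm(xr, scales, ["p:x"]), self._fm(yr, scales, ["p:y"])
        )
        np.testing.assert_allclose(t1.f2, t2.f2, rtol=0.05)

    def test_mismatched_grids_rejected(self, rng):
        x = rng.normal(size=(1, 200))
        with pytest.raises(AnalysisError):
            total_squared_displacement(
                self._fm(x, [8], ["p:x"]), self._fm(x, [16], ["p:y"])
            )
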