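import numpy as np
import pytest
from scipy.integrate import quad

from paddywave.preprocess import (
    DEFAULT_SCALES,
    continuum_remove,
    cwt_transform,
    first_derivative,
    mexican_hat,
    sg_smooth,
)
from paddywave.spectra_io import CANONICAL_GRID, Spectrum


def _spec(w, r):
    return Spectrum("p", "heading", np.asarray(w, float), np.asarray(r, float))


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        s = _spec(CANONICAL_GRID, np.full(2151, 0.4))
        assert np.allclose(sg_smooth(s).reflectance, 0.4, atol=1e-12)

    def test_cubic_polynomial_preserved(self):
        lam = CANONICAL_GRID
        x = (lam - 1400.0) / 1000.0
        r = 0.3 + 0.1 * x - 0.05 * x ** 2 + 0.02 * x ** 3
        out = sg_smooth(_spec(lam, r), window=11, polyorder=3)
        assert np.max(np.abs(out.reflectance - r)) < 1e-10

    def test_noise_suppressed_at_least_twofold(self):
        rng = np.random.default_rng(0)
        lam = CANONICAL_GRID
        clean = 0.3 + 0.1 * np.sin(2 * np.pi * lam / 300.0)
        noisy = clean + rng.normal(0, 0.01, lam.size)
        out = sg_smooth(_spec(lam, noisy)).reflectance
        assert np.std(out - clean) < 0.5 * np.std(noisy - clean)

    @pytest.mark.parametrize("window,polyorder", [(10, 3), (11, 11), (3001, 3)])
    def test_bad_window_rejected(self, window, polyorder):
        s = _spec(CANONICAL_GRID, np.full(2151, 0.4))
        with pytest.raises(ValueError):
            sg_smooth(s, window, polyorder)


class TestFirstDerivative:
    def test_linear_ramp_constant_slope(self):
        lam = CANONICAL_GRID
        out = first_derivative(_spec(lam, 2e-4 * lam))
        assert np.allclose(out.reflectance, 2e-4, atol=1e-12)

    def test_constant_all_zero(self):
        out = first_derivative(_spec(CANONICAL_GRID, np.full(2151, 0.2)))
        assert np.all(out.reflectance == 0)

    def test_matches_analytic_cosine(self):
        lam = CANONICAL_GRID
        out = first_derivative(_spec(lam, np.sin(2 * np.pi * lam / 200.0)))
        truth = (2 * np.pi / 200.0) * np.cos(2 * np.pi * lam / 200.0)
        assert np.max(np.abs(out.reflectance[1:-1] - truth[1:-1])) < 1e-3

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            first_derivative(_spec([400, 401], [0.1, 0.2]))

    def test_commutes_with_scalar_multiplication(self, smooth_spectrum):
        a = first_derivative(_spec(smooth_spectrum.wavelengths, 3.7 * smooth_spectrum.reflectance))
        b = first_derivative(smooth_spectrum)
        assert np.allclose(a.reflectance, 3.7 * b.reflectance, atol=1e-14)


def _brute_force_hull_continuum(w, r):
    """Oracle: upper envelope from all point pairs (O(n³), tiny n only)."""
    n = len(w)
    best = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            line = r[i] + (r[j] - r[i]) * (w - w[i]) / (w[j] - w[i])
            # chord i-j is part of the hull iff no point lies above it
            if np.all(r <= line + 1e-12):
                seg = (w >= w[i]) & (w <= w[j])
                best[seg] = np.maximum(best[seg], line[seg])
    best[0], best[-1] = r[0], r[-1]
    return np.maximum(best, r)


class TestContinuumRemoval:
    def test_concave_spectrum_removed_everywhere_one(self):
        w = np.arange(400.0, 701.0)
        r = 0.6 - 1e-6 * (w - 550.0) ** 2
        res = continuum_remove(_spec(w, r))
        assert np.allclose(res.removed, 1.0, atol=1e-12)

    def test_v_shape_exact(self):
        res = continuum_remove(_spec([400, 500, 600], [0.5, 0.1, 0.5]))
        assert np.allclose(res.continuum, [0.5, 0.5, 0.5])
        assert np.allclose(res.removed, [1.0, 0.2, 1.0])

    def test_idempotent(self, smooth_spectrum):
        once = continuum_remove(smooth_spectrum)
        twice = continuum_remove(_spec(smooth_spectrum.wavelengths, once.removed))
        assert np.allclose(twice.removed, once.removed, atol=1e-12)
        assert np.allclose(twice.continuum, 1.0, atol=1e-12)

    def test_nonpositive_reflectance_rejected(self):
        with pytest.raises(ValueError):
            continuum_remove(_spec([400, 500, 600], [0.5, 0.0, 0.5]))

    def test_invariants_and_brute_force_match_on_random_spectra(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(5, 21)
            w = np.sort(rng.choice(np.arange(400, 900), n, replace=False)).astype(float)
            r = rng.uniform(0.05, 0.8, n)
            res = continuum_remove(_spec(w, r))
            assert np.all(res.continuum >= r - 1e-12)
            assert np.all((res.removed > 0) & (res.removed <= 1 + 1e-12))
            assert res.removed[0] == 1.0 and res.removed[-1] == 1.0
            oracle = _brute_force_hull_continuum(w, r)
            assert np.allclose(res.continuum, oracle, atol=1e-9)


class TestContinuumRemovalProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(min_value=0.01, max_value=0.95), min_size=4, max_size=40),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_hull_dominates_and_removal_is_idempotent(self, values, offset):
        w = np.arange(400.0 + offset % 100, 400.0 + offset % 100 + len(values))
        r = np.asarray(values)
        res = continuum_remove(_spec(w, r))
        assert np.all(res.continuum >= r - 1e-12)
        assert np.all((res.removed > 0) & (res.removed <= 1 + 1e-12))
        again = continuum_remove(_spec(w, res.removed))
        assert np.allclose(again.removed, res.removed, atol=1e-9)


class TestCWT:
    def test_zero_spectrum_zero_plane(self):
        plane = cwt_transform(_spec(CANONICAL_GRID, np.zeros(2151)))
        assert np.all(plane.coefficients == 0)
        assert plane.coefficients.shape == (10, 2151)

    def test_default_scales_are_dyadic(self):
        plane = cwt_transform(_spec(CANONICAL_GRID, np.full(2151, 0.3)))
        assert list(plane.scales) == [2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0, 1024.0]

    def test_linearity(self):
        rng = np.random.default_rng(1)
        w = np.arange(600.0, 856.0)
        f, g = rng.normal(0.3, 0.05, w.size), rng.normal(0.3, 0.05, w.size)
        pf = cwt_transform(_spec(w, f)).coefficients
        pg = cwt_transform(_spec(w, g)).coefficients
        pc = cwt_transform(_spec(w, 2.0 * f - 0.5 * g)).coefficients
        assert np.max(np.abs(pc - (2.0 * pf - 0.5 * pg))) < 1e-10

    def test_matches_brute_force_discretized_integral(self):
        """All 10 scales agree with a directly-summed mirror-extended
        discretization of the defining integral to 1e-8."""
        rng = np.random.default_rng(0)
        n = 128
        w = np.arange(500.0, 500.0 + n)
        f = rng.normal(0.3, 0.05, n)
        plane = cwt_transform(_spec(w, f))
        idx_ext = lambda L: np.where(
            (np.arange(-L, n + L) % (2 * n)) < n,
            np.arange(-L, n + L) % (2 * n),
            2 * n - 1 - (np.arange(-L, n + L) % (2 * n)),
        )
        for k, a in enumerate(DEFAULT_SCALES):
            L = int(np.ceil(8 * a))
            fe = f[idx_ext(L)]
            pos = np.arange(-L, n + L)
            for b in [0, 17, n // 2, n - 1]:
                val = np.sum(fe * mexican_hat((pos - b) / a)) / np.sqrt(a)
                assert abs(val - plane.coefficients[k, b]) < 1e-8

    def test_gaussian_bump_peak_at_center_matches_quadrature(self):
        c, sig, amp = 1400.0, 80.0, 0.5
        f = lambda lam: amp * np.exp(-0.5 * ((lam - c) / sig) ** 2)
        plane = cwt_transform(_spec(CANONICAL_GRID, f(CANONICAL_GRID)))
        n, period = 2151, 2 * 2151
        def f_ext(lam):
            u = (lam - 350.0) % period
            return np.where(u < n - 0.5, f(350.0 + u), f(350.0 + (period - 1 - u)))
        bidx = int(c - 350)
        for k, a in enumerate(DEFAULT_SCALES):
            if a <= 256:
                # beyond a=256 the wavelet support exceeds the grid and the
                # mirror extension, not the bump, dominates the plane shape
                assert plane.bands[np.argmax(plane.coefficients[k])] == c
            oracle = quad(lambda lam: f_ext(lam) * mexican_hat((lam - c) / a) / np.sqrt(a),
                          c - 9 * a, c + 9 * a, limit=2000)[0]
            assert abs(plane.coefficients[k, bidx] - oracle) / abs(oracle) < 1e-6

    def test_unknown_wavelet_rejected(self, smooth_spectrum):
        with pytest.raises(ValueError, match="wavelet"):
            cwt_transform(smooth_spectrum, wavelet="haar")

    def test_commutes_with_scalar_multiplication(self):
        w = np.arange(700.0, 828.0)
        f = np.sin(w / 20.0) * 0.1 + 0.3
        a = cwt_transform(_spec(w, 2.5 * f)).coefficients
        b = cwt_transform(_spec(w, f)).coefficients
        assert np.allclose(a, 2.5 * b, atol=1e-12)
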