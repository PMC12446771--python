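"""Univariate K / L(r)-r estimators, CSR envelopes, Lmax summaries."""

import math
import warnings

import numpy as np
import pytest

import goldmap as gm


def brute_force_k(pattern, r_grid, correction="isotropic"):
    """Literal double-loop evaluation of K(r) = A n^-2 sum w_ij 1(d<=r)."""
    n = pattern.n
    A = pattern.window.area
    out = np.zeros(len(r_grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if correction == "toroidal":
                dx = abs(pattern.points[i, 0] - pattern.points[j, 0])
                dy = abs(pattern.points[i, 1] - pattern.points[j, 1])
                dx = min(dx, pattern.window.width - dx)
                dy = min(dy, pattern.window.height - dy)
                d, w = math.hypot(dx, dy), 1.0
            else:
                d = float(np.linalg.norm(pattern.points[i] - pattern.points[j]))
                w = 1.0 if d == 0 else gm.edge_weight(pattern.points[i], d, pattern.window)
            out += w * (d <= r_grid)
    return A * out / n**2


class TestKFunction:
    def test_two_interior_points_hand_value(self, window100):
        p = gm.PointPattern(window100, [[40, 50], [60, 50]])
        k = gm.k_function(p)
        assert np.all(k.values[k.r < 20] == 0)
        assert np.all(k.values[k.r >= 20] == pytest.approx(5000.0))

    def test_distant_points_zero_on_grid(self):
        w = gm.SpatialWindow.square(2000.0)
        p = gm.PointPattern(w, [[100, 100], [1500, 1500]])
        assert np.all(gm.k_function(p).values == 0)

    @pytest.mark.parametrize("correction", ["isotropic", "toroidal"])
    def test_matches_brute_force_oracle(self, sheet, correction):
        p = gm.generate_csr(50, window=sheet, seed=21)
        grid = gm.default_grid()
        fast = gm.k_function(p, correction=correction).values
        slow = brute_force_k(p, grid, correction)
        assert np.allclose(fast, slow, rtol=1e-9, atol=1e-9)

    def test_nondecreasing_in_r(self, sheet):
        for seed in (1, 2, 3):
            p = gm.generate_thomas(30, 4, 10.0, window=sheet, seed=seed)
            if p.n < 2:
                continue
            k = gm.k_function(p)
            assert np.all(np.diff(k.values) >= 0)

    def test_insufficient_points(self, window100):
        with pytest.raises(gm.InsufficientPointsError):
            gm.k_function(gm.PointPattern(window100, [[1, 1]]))

    def test_csr_expectation_matches_estimator_mean(self, sheet):
        """Mean K over seeded CSR sims agrees with the estimator's exact
        CSR expectation ((n-1)/n) pi r^2 to within 3 Monte Carlo SEs."""
        n, n_sim = 170, 500
        grid = np.array([20.0, 50.0, 110.0])
        rng_seeds = np.random.SeedSequence(99).spawn(n_sim)
        sims = np.array([
            gm.k_function(
                gm.generate_csr(n, window=sheet, seed=np.random.default_rng(s)),
                r_grid=grid,
            ).values
            for s in rng_seeds
        ])
        mean = sims.mean(axis=0)
        se = sims.std(axis=0, ddof=1) / math.sqrt(n_sim)
        expected = (n - 1) / n * math.pi * grid**2
        assert np.all(np.abs(mean - expected) <= 3 * se)


class TestLMinusR:
    def test_closed_form_value(self, window100):
        p = gm.PointPattern(window100, [[40, 50], [60, 50]])
        l = gm.l_minus_r(gm.k_function(p))
        assert l.values[19] == pytest.approx(math.sqrt(5000 / math.pi) - 20, abs=1e-9)

    def test_zero_k_gives_minus_r(self):
        grid = gm.default_grid()
        l = gm.l_minus_r(gm.RadialCurve(grid, np.zeros_like(grid)))
        assert np.allclose(l.values, -grid)

    def test_csr_identity(self):
        grid = gm.default_grid()
        l = gm.l_minus_r(gm.RadialCurve(grid, math.pi * grid**2))
        assert np.allclose(l.values, 0, atol=1e-9)

    def test_negative_k_rejected(self):
        grid = gm.default_grid()
        with pytest.raises(gm.DomainError):
            gm.l_minus_r(gm.RadialCurve(grid, -np.ones_like(grid)))


class TestEnvelopeAndStandardize:
    def test_envelope_positive_midrange(self, small_envelope):
        grid = small_envelope.r
        mid = (grid >= 10) & (grid <= 110)
        assert np.all(small_envelope.upper[mid] > 0)
        assert np.all(small_envelope.upper[mid] < 20)  # a few nm at this density

    def test_median_envelope_near_zero(self, csr170):
        env = gm.csr_envelope(csr170, n_sim=200, percentile=50, seed=5)
        mid = (env.r >= 20) & (env.r <= 110)
        assert np.abs(env.upper[mid]).max() < 1.5

    def test_too_few_simulations(self, csr170):
        with pytest.raises(gm.InsufficientSimulationsError):
            gm.csr_envelope(csr170, n_sim=50, seed=1)

    def test_boundary_curve_standardizes_to_one(self, small_envelope):
        std = gm.standardize(small_envelope.as_curve(), small_envelope)
        assert np.allclose(std.values[std.defined], 1.0)

    def test_zero_and_linearity(self, small_envelope):
        grid = small_envelope.r
        zero = gm.standardize(gm.RadialCurve(grid, np.zeros_like(grid)), small_envelope)
        assert np.all(zero.values[zero.defined] == 0)
        double = gm.standardize(
            gm.RadialCurve(grid, 2 * small_envelope.upper), small_envelope
        )
        assert np.allclose(double.values[double.defined], 2.0)

    def test_scale_consistency(self, small_envelope):
        """Doubling curve and envelope leaves the standardized curve unchanged."""
        grid = small_envelope.r
        curve = gm.RadialCurve(grid, np.abs(small_envelope.upper) + 1.0)
        a = gm.standardize(curve, small_envelope)
        doubled = gm.NullEnvelope(
            grid, 2 * small_envelope.upper, small_envelope.percentile,
            small_envelope.n_sim, small_envelope.null_model,
        )
        b = gm.standardize(gm.RadialCurve(grid, 2 * curve.values), doubled)
        mask = a.defined & b.defined
        assert np.allclose(a.values[mask], b.values[mask])

    def test_grid_mismatch(self, small_envelope):
        short = gm.RadialCurve(np.arange(1.0, 101.0), np.zeros(100))
        with pytest.raises(gm.GridMismatchError):
            gm.standardize(short, small_envelope)


class TestLmax:
    def _std(self, values):
        grid = gm.default_grid()
        return gm.RadialCurve(grid, values, kind="standardized")

    def test_unit_curve_not_significant(self):
        s = gm.lmax_summary(self._std(np.ones(240)))
        assert s.lmax == 1.0 and not s.significant

    def test_single_peak(self):
        v = np.zeros(240)
        v[23] = 3.2  # r = 24 nm
        s = gm.lmax_summary(self._std(v))
        assert s.lmax == pytest.approx(3.2) and s.r_at_lmax == 24.0 and s.significant

    def test_tie_broken_toward_smaller_r(self):
        v = np.zeros(240)
        v[[29, 59]] = 2.0
        assert gm.lmax_summary(self._std(v)).r_at_lmax == 30.0

    def test_search_range_respected(self):
        v = np.zeros(240)
        v[2] = 9.0  # r = 3 nm, below the default 10 nm search start
        v[49] = 2.0
        assert gm.lmax_summary(self._std(v)).r_at_lmax == 50.0

    def test_all_undefined_errors(self):
        with pytest.raises(gm.UndefinedCurveError):
            gm.lmax_summary(self._std(np.full(240, np.nan)))


class TestUnivariateStudy:
    def test_clustered_images_all_significant(self, sheet):
        pats = [
            gm.generate_oligomer_mixture(
                {1: 50, 2: 60}, spacing=15.0, window=sheet, seed=s,
                image_id=f"dim{s}",
            ).pattern
            for s in range(5)
        ]
        res = gm.univariate_study(pats, n_sim=150, seed=42)
        assert res.fraction_significant == 1.0
        assert res.mean_lmax > 1.0 and res.sd_lmax >= 0

    def test_csr_null_rate_below_clustered_power(self, sheet):
        """Under CSR the per-image significance rate reflects only the
        max-over-r multiplicity of pointwise envelopes (~0.3-0.4), well
        separated from the unit rate on clustered patterns."""
        pats = [gm.generate_csr(170, window=sheet, seed=s, image_id=f"c{s}")
                for s in range(10)]
        res = gm.univariate_study(pats, n_sim=150, seed=7)
        assert res.fraction_significant <= 0.7

    def test_pointwise_envelope_calibration(self, sheet):
        """Exceedance of the estimated 99% envelope at a fixed r stays near
        its nominal 1% (here: at most 3 of 25 CSR images at r = 50 nm)."""
        hits = 0
        for seed in range(25):
            p = gm.generate_csr(170, window=sheet, seed=seed + 40)
            env = gm.csr_envelope(p, n_sim=200, seed=seed + 4000)
            std = gm.standardize(gm.l_minus_r(gm.k_function(p)), env)
            hits += bool(std.values[49] > 1.0)  # r = 50 nm
        assert hits <= 3

    def test_single_image_sd_zero_with_warning(self, sheet):
        pat = gm.generate_csr(100, window=sheet, seed=1, image_id="solo")
        with pytest.warns(UserWarning, match="single image"):
            res = gm.univariate_study([pat], n_sim=100, seed=3)
        assert res.sd_lmax == 0.0 and res.n_images == 1

    def test_empty_collection_rejected(self):
        with pytest.raises(gm.DomainError):
            gm.univariate_study([])
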