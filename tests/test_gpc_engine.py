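"""Legendre-chaos machinery: quadrature, projection, moments, densities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from numpy.polynomial import legendre as npleg

from vesseluq.gpc_engine import (
    GPCExpansion,
    UniformParameter,
    convergence_ratios,
    estimate_pdf,
    evaluate_surrogate,
    gauss_legendre_rule,
    legendre_eval,
    moments,
    parameter_values_from_rule,
    project,
)


class TestGaussLegendreRule:
    @pytest.mark.parametrize(
        "n, nodes, weights",
        [
            (1, [0.0], [1.0]),
            (2, [-1 / np.sqrt(3), 1 / np.sqrt(3)], [0.5, 0.5]),
            (
                4,
                [-0.8611363116, -0.3399810436, 0.3399810436, 0.8611363116],
                [0.1739274226, 0.3260725774, 0.3260725774, 0.1739274226],
            ),
        ],
    )
    def test_tabulated_rules(self, n, nodes, weights):
        rule = gauss_legendre_rule(n)
        np.testing.assert_allclose(rule.nodes, nodes, atol=1e-9)
        np.testing.assert_allclose(rule.weights, weights, atol=1e-9)

    @given(st.integers(min_value=1, max_value=12))
    def test_probability_normalization_and_symmetry(self, n):
        rule = gauss_legendre_rule(n)
        assert abs(rule.weights.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(rule.nodes, -rule.nodes[::-1], atol=1e-12)
        if n >= 2:
            assert np.all(np.abs(rule.nodes) < 1.0)

    def test_rejects_nonpositive_count(self):
        with pytest.raises(ValueError):
            gauss_legendre_rule(0)

    def test_degree_exactness_against_uniform_moments(self):
        """The 4-point rule integrates monomials of degree <= 7 exactly.

        Closed-form moments of the uniform density on [-1, 1]:
        E[zeta^k] = 1/(k+1) for even k, 0 for odd k.
        """
        rule = gauss_legendre_rule(4)
        for k in range(8):
            exact = 1.0 / (k + 1) if k % 2 == 0 else 0.0
            assert abs(np.sum(rule.weights * rule.nodes**k) - exact) < 1e-12
        # degree 8 must not be exact (sanity of the check itself)
        assert abs(np.sum(rule.weights * rule.nodes**8) - 1.0 / 9.0) > 1e-6


class TestParameterMapping:
    def test_unit_center_factors_to_two_decimals(self):
        param = UniformParameter(1.0, 0.23)
        values = parameter_values_from_rule(gauss_legendre_rule(4), param)
        assert [round(v, 2) for v in values] == [1.2, 1.08, 0.92, 0.8]

    def test_image_based_estimate_in_mpa(self):
        """Mapping the 4-point rule around 2.02 MPa: 2.42/2.18/1.86/1.62."""
        param = UniformParameter(2.02e6, 0.23)
        values = parameter_values_from_rule(gauss_legendre_rule(4), param)
        assert [round(v / 1e6, 2) for v in values] == [2.42, 2.18, 1.86, 1.62]
        assert np.all(np.diff(values) < 0)  # descending: x1 largest

    def test_degenerate_interval(self):
        param = UniformParameter(3.3e6, 0.0)
        values = parameter_values_from_rule(gauss_legendre_rule(4), param)
        np.testing.assert_allclose(values, 3.3e6)

    def test_support_bounds(self):
        param = UniformParameter(2.0e6, 0.23)
        assert param.support_low == pytest.approx(0.77 * 2.0e6)
        assert param.support_high == pytest.approx(1.23 * 2.0e6)
        with pytest.raises(ValueError):
            UniformParameter(-1.0, 0.23)


class TestLegendreEval:
    @pytest.mark.parametrize(
        "r, zeta, expected",
        [(0, -0.7, 1.0), (0, 0.2, 1.0), (1, 0.5, 0.5), (2, 1.0, 1.0), (3, -1.0, -1.0)],
    )
    def test_closed_forms(self, r, zeta, expected):
        assert legendre_eval(r, zeta) == pytest.approx(expected)

    def test_quadrature_node_is_root(self):
        rule = gauss_legendre_rule(4)
        for node in rule.nodes:
            assert abs(legendre_eval(4, node)) < 1e-12

    def test_out_of_support(self):
        with pytest.raises(ValueError):
            legendre_eval(2, 1.5)
        with pytest.warns(UserWarning):
            legendre_eval(2, 1.5, extrapolate=True)


class TestProjection:
    def test_constant_model(self):
        rule = gauss_legendre_rule(4)
        exp = project(np.full(4, 3.7), rule, order=3)
        np.testing.assert_allclose(exp.coefficients, [3.7, 0, 0, 0], atol=1e-12)

    def test_reproduces_basis_polynomial(self):
        rule = gauss_legendre_rule(4)
        outputs = npleg.legval(rule.nodes, [0, 0, 1.0])  # P2 at the nodes
        exp = project(outputs, rule, order=3)
        np.testing.assert_allclose(exp.coefficients, [0, 0, 1.0, 0], atol=1e-12)

    def test_exp_against_dense_quadrature_oracle(self):
        """Coefficients of exp(zeta) match a 10^4-point trapezoid integration.

        Oracle: a_r = (2r+1)/2 * integral exp(z) P_r(z) dz on [-1, 1].  An
        8-point rule keeps the discrete-projection aliasing below the
        tolerance (a 4-point rule aliases exp's higher content at ~1e-3,
        which is quantified separately).
        """
        z = np.linspace(-1, 1, 10_001)
        oracle = [
            (2 * r + 1) / 2.0
            * np.trapezoid(np.exp(z) * npleg.legval(z, np.eye(4)[r]), z)
            for r in range(4)
        ]
        rule = gauss_legendre_rule(8)
        exp = project(np.exp(rule.nodes), rule, order=3)
        np.testing.assert_allclose(exp.coefficients, oracle, atol=1e-6)
        # the 4-point (order+1) rule carries a small, bounded aliasing error
        rule4 = gauss_legendre_rule(4)
        exp4 = project(np.exp(rule4.nodes), rule4, order=3)
        np.testing.assert_allclose(exp4.coefficients, oracle, atol=1e-3)

    def test_shape_mismatch(self):
        rule = gauss_legendre_rule(4)
        with pytest.raises(ValueError):
            project(np.zeros(3), rule, order=3)
        with pytest.raises(ValueError):
            project(np.zeros(2), gauss_legendre_rule(2), order=3)

    def test_vectorized_over_time_samples(self):
        rule = gauss_legendre_rule(4)
        t = np.linspace(0, 1, 11)
        outputs = np.outer(rule.nodes, t) + 1.0  # X(z, t) = 1 + z*t
        exp = project(outputs, rule, order=3)
        np.testing.assert_allclose(exp.coefficients[0], np.ones_like(t), atol=1e-12)
        np.testing.assert_allclose(exp.coefficients[1], t, atol=1e-12)
        np.testing.assert_allclose(exp.coefficients[2:], 0, atol=1e-12)


class TestSurrogateEvaluation:
    def test_constant_expansion(self):
        exp = GPCExpansion(np.array([7.0, 0, 0, 0]))
        for zeta in (-1.0, -0.3, 0.0, 0.99):
            assert evaluate_surrogate(exp, zeta) == pytest.approx(7.0)

    def test_cubic_model_reproduced_pointwise(self):
        rule = gauss_legendre_rule(4)
        f = lambda z: 2 * z**3 - z
        exp = project(f(rule.nodes), rule, order=3)
        assert evaluate_surrogate(exp, 0.3) == pytest.approx(-0.246)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_degree_le_order_models_exact_at_random_points(self, seed):
        """Projection + evaluation is the identity on polynomials of degree <= n."""
        rng = np.random.default_rng(seed)
        coefs = rng.normal(size=4)  # random cubic in the power basis
        poly = np.polynomial.Polynomial(coefs)
        rule = gauss_legendre_rule(4)
        exp = project(poly(rule.nodes), rule, order=3)
        zetas = rng.uniform(-1, 1, size=50)
        np.testing.assert_allclose(
            evaluate_surrogate(exp, zetas), poly(zetas), rtol=0, atol=1e-12
        )


class TestMoments:
    def test_identity_model_uniform_moments(self):
        rule = gauss_legendre_rule(4)
        exp = project(rule.nodes.copy(), rule, order=3)
        mean, std = moments(exp)
        assert mean == pytest.approx(0.0, abs=1e-14)
        assert std**2 == pytest.approx(1.0 / 3.0)

    def test_constant_model_zero_std(self):
        exp = GPCExpansion(np.array([5.0, 0.0, 0.0, 0.0]))
        _, std = moments(exp)
        assert std == 0.0

    @pytest.mark.parametrize(
        "f", [np.exp, lambda z: 1.0 / (2.0 + z), lambda z: np.sin(1.0 + z)],
        ids=["exp", "reciprocal", "sin"],
    )
    def test_against_monte_carlo_oracle(self, f):
        """Truncated moments vs 1e5-sample Monte-Carlo of the true model."""
        rule = gauss_legendre_rule(4)
        exp = project(f(rule.nodes), rule, order=3)
        mean, std = moments(exp)
        rng = np.random.default_rng(42)
        samples = f(rng.uniform(-1, 1, 100_000))
        assert mean == pytest.approx(samples.mean(), rel=0.01)
        assert std == pytest.approx(samples.std(), rel=0.01)


class TestEstimatePdf:
    def test_linear_surrogate_flat_density(self):
        a0, a1 = 2.0, 0.5
        exp = GPCExpansion(np.array([a0, a1, 0.0, 0.0]))
        summ = estimate_pdf(exp, n_samples=100_000, seed=3, n_bins=16)
        # affine image of a uniform variable: density 1/(2 a1) on [a0-a1, a0+a1]
        np.testing.assert_allclose(summ.pdf, 1.0 / (2 * a1), rtol=0.06)
        assert summ.bin_centers.min() > a0 - a1 - 0.01
        assert summ.bin_centers.max() < a0 + a1 + 0.01
        assert not summ.point_mass.any()

    def test_constant_surrogate_point_mass(self):
        exp = GPCExpansion(np.array([4.2, 0.0, 0.0, 0.0]))
        summ = estimate_pdf(exp, n_samples=2000, seed=0, n_bins=32)
        assert summ.point_mass.all()

    def test_nonmonotone_cubic_is_bimodal(self):
        """P3 folds at its interior turning points; density develops two lobes.

        Oracle: deterministic dense-grid histogram (midpoint quadrature of
        the change-of-variables density).
        """
        c = np.array([0.0, 0.0, 0.0, 1.0])  # X = P3(zeta), non-monotone
        exp = GPCExpansion(c)
        n_bins = 32
        summ = estimate_pdf(exp, n_samples=200_000, seed=5, n_bins=n_bins)
        zg = np.linspace(-1, 1, 2_000_001)
        vals = npleg.legval(zg, c)
        lo = summ.bin_centers[0] - 0.5 * (summ.bin_centers[1] - summ.bin_centers[0])
        hi = summ.bin_centers[-1] + 0.5 * (summ.bin_centers[1] - summ.bin_centers[0])
        oracle, _ = np.histogram(vals, bins=n_bins, range=(lo, hi), density=True)
        np.testing.assert_allclose(summ.pdf, oracle, atol=0.05 * oracle.max())
        interior = summ.pdf[1:-1]
        peaks = np.sum(
            (interior > summ.pdf[:-2]) & (interior > summ.pdf[2:])
            & (interior > 1.5 * np.median(summ.pdf))
        )
        assert peaks >= 2

    def test_per_column_normalization_for_time_series(self):
        coeffs = np.array([[1.0, 2.0, 3.0], [0.5, 0.0, 0.2], [0, 0, 0], [0, 0, 0]])
        summ = estimate_pdf(GPCExpansion(coeffs), n_samples=50_000, seed=1, n_bins=40)
        width = summ.bin_centers[1] - summ.bin_centers[0]
        integrals = summ.pdf.sum(axis=0) * width
        np.testing.assert_allclose(integrals, 1.0, atol=0.01)
        assert bool(summ.point_mass[1]) is True  # constant column flagged
        assert not summ.point_mass[0]

    def test_rejects_tiny_sample_counts(self):
        with pytest.raises(ValueError):
            estimate_pdf(GPCExpansion(np.zeros(4)), n_samples=10, seed=0)


class TestConvergenceRatios:
    def test_constant_model_all_zero(self):
        ratios, max_r = convergence_ratios(GPCExpansion(np.array([2.0, 0, 0, 0])))
        np.testing.assert_allclose(ratios, 0.0)
        np.testing.assert_allclose(max_r, 0.0)

    def test_shifted_basis_polynomial(self):
        exp = GPCExpansion(np.array([10.0, 0.0, 0.0, 1.0]))  # X = P3 + 10
        ratios, _ = convergence_ratios(exp)
        np.testing.assert_allclose(ratios, [0.0, 0.0, 0.1])

    def test_smooth_model_ratios_decay(self):
        rule = gauss_legendre_rule(6)
        exp = project(np.exp(rule.nodes), rule, order=5)
        _, max_r = convergence_ratios(exp)
        assert np.all(np.diff(max_r) < 0)

    def test_zero_mean_sample_flagged(self):
        exp = GPCExpansion(np.array([0.0, 1.0, 0.0, 0.0]))
        ratios, max_r = convergence_ratios(exp)
        assert np.all(np.isnan(ratios))
        np.testing.assert_allclose(max_r, 0.0)

    def test_warning_on_slow_decay(self):
        exp = GPCExpansion(np.array([1.0, 0.0, 0.0, 0.5]))
        with pytest.warns(UserWarning, match="truncation"):
            convergence_ratios(exp, warn=True)
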