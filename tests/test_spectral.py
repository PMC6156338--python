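"""Propagators, collision matrices, vertex function, critical noise."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

import graphpam as gp


J = 1.0


class TestTransitionMatrix:
    def test_identity_at_zero(self, random_graph4_spectrum):
        P = gp.transition_matrix(random_graph4_spectrum, J, 0.0)
        assert np.abs(P - np.eye(4)).max() < 1e-12

    def test_two_node_closed_form(self, two_node_spectrum):
        for t in (0.1, 0.7, 2.5):
            P = gp.transition_matrix(two_node_spectrum, J, t)
            assert P[0, 0] == pytest.approx((1 + np.exp(-2 * J * t)) / 2, abs=1e-12)

    def test_long_time_uniform(self, random_graph4_spectrum):
        P = gp.transition_matrix(random_graph4_spectrum, J, 200.0)
        assert np.abs(P - 0.25).max() < 1e-8

    def test_stochasticity(self, random_graph4_spectrum):
        for t in (0.0, 0.3, 5.0):
            P = gp.transition_matrix(random_graph4_spectrum, J, t)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-8
            assert P.min() > -1e-10

    def test_negative_time_rejected(self, random_graph4_spectrum):
        with pytest.raises(ValueError):
            gp.transition_matrix(random_graph4_spectrum, J, -0.1)


class TestReturnProbability:
    def test_isolated_node_constant(self, single_node_spectrum):
        curve = gp.return_probability(single_node_spectrum, J, np.linspace(0.1, 5, 10))
        assert np.allclose(curve.values, 1.0)

    def test_two_node_monotone_closed_form(self, two_node_spectrum):
        t = np.linspace(0.01, 6, 40)
        curve = gp.return_probability(two_node_spectrum, J, t)
        expect = (1 + np.exp(-2 * J * t)) / 2
        assert np.abs(curve.node_average - expect).max() < 1e-12
        assert np.all(np.diff(curve.node_average) < 0)

    def test_complete_graph_two_eigenvalue_form(self):
        n = 8
        spec = gp.build_laplacian(gp.generate_mean_field(n))
        t = np.linspace(0.05, 10, 30)
        curve = gp.return_probability(spec, J, t)
        expect = 1.0 / n + (1 - 1.0 / n) * np.exp(-J * t)
        assert np.abs(curve.node_average - expect).max() < 1e-10

    def test_empty_grid_rejected(self, two_node_spectrum):
        with pytest.raises(ValueError):
            gp.return_probability(two_node_spectrum, J, np.array([]))


class TestSpectralDimension:
    def test_constant_curve_dimension_zero(self):
        W = np.zeros((5, 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = gp.build_laplacian(gp.WeightedGraph(W))
        curve = gp.return_probability(spec, J, np.linspace(0.5, 20, 12))
        est = gp.estimate_spectral_dimension(curve, (0.5, 20))
        assert est.d_tilde == pytest.approx(0.0, abs=1e-12)

    def test_ring_heat_kernel_dimension(self):
        spec = gp.build_laplacian(gp.generate_torus(1, 400))
        t = np.geomspace(1.0, 80.0, 40)
        curve = gp.return_probability(spec, J, t)
        est = gp.estimate_spectral_dimension(curve, (5.0, 50.0))
        assert est.d_tilde == pytest.approx(1.0, rel=0.15)

    def test_saturated_window_warns_and_shrinks(self):
        spec = gp.build_laplacian(gp.generate_torus(1, 12))
        t = np.geomspace(0.5, 400, 60)
        curve = gp.return_probability(spec, J, t)
        with pytest.warns(UserWarning, match="saturation"):
            est = gp.estimate_spectral_dimension(curve, (1.0, 400.0))
        assert est.fit_window[1] < 400.0


class TestCollisionMatrix:
    def test_time_domain_identity_at_zero(self, random_graph4_spectrum):
        I = gp.collision_matrix_time(random_graph4_spectrum, J, 0.0)
        assert np.abs(I.matrix - np.eye(4)).max() < 1e-12

    def test_two_node_square_of_closed_form(self, two_node_spectrum):
        t = 0.9
        I = gp.collision_matrix_time(two_node_spectrum, J, t)
        assert I.matrix[0, 0] == pytest.approx(
            ((1 + np.exp(-2 * J * t)) / 2) ** 2, abs=1e-12
        )

    def test_rows_bounded_by_one(self, random_graph4_spectrum):
        I = gp.collision_matrix_time(random_graph4_spectrum, J, 0.4)
        assert np.all(I.row_sums() <= 1.0 + 1e-12)

    def test_laplace_single_node(self, single_node_spectrum):
        I = gp.collision_matrix_laplace(single_node_spectrum, J, 0.8)
        assert I.matrix[0, 0] == pytest.approx(1.0 / 0.8, abs=1e-12)

    def test_laplace_two_node_closed_form(self, two_node_spectrum):
        s = 0.6
        I = gp.collision_matrix_laplace(two_node_spectrum, J, s)
        expect = 0.25 * (1 / s + 2 / (s + 2 * J) + 1 / (s + 4 * J))
        assert I.matrix[0, 0] == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("s", [0.3, 1.0, 4.0])
    def test_row_sum_identity(self, random_graph4_spectrum, s):
        """Master oracle: sum_k I~_ik(s) = (1/2) P~_ii(s/2)."""
        spec = random_graph4_spectrum
        I = gp.collision_matrix_laplace(spec, J, s)
        phi2 = spec.eigenvectors**2
        half = 0.5 * (phi2 @ (1.0 / (s / 2 + J * spec.eigenvalues)))
        assert np.abs(I.row_sums() - half).max() < 1e-8

    def test_laplace_matches_quadrature(self, two_node_spectrum):
        """Independent oracle: numerical Laplace transform of P_ij(t)^2."""
        s = 1.1
        I = gp.collision_matrix_laplace(two_node_spectrum, J, s)
        for i in range(2):
            for j in range(2):
                val, _ = quad(
                    lambda t: gp.transition_matrix(two_node_spectrum, J, t)[i, j] ** 2
                    * np.exp(-s * t),
                    0.0,
                    80.0,
                )
                assert I.matrix[i, j] == pytest.approx(val, abs=1e-6)


class TestResolventCriterion:
    def test_zero_noise(self, random_graph4_spectrum):
        assert gp.resolvent_criterion(random_graph4_spectrum, J, 0.0, 1.0) == 0.0

    def test_single_node(self, single_node_spectrum):
        assert gp.resolvent_criterion(single_node_spectrum, J, 1.0, 0.5) == pytest.approx(2.0)

    def test_two_node_arithmetic(self, two_node_spectrum):
        val = gp.resolvent_criterion(two_node_spectrum, 1.0, 1.0, 2.0)
        assert val == pytest.approx(1 / 2 + 1 / 6, abs=1e-12)


class TestVertexFunction:
    def test_first_order_term(self, two_node_spectrum):
        vf = gp.vertex_function_series(two_node_spectrum, J, 0.2, 1.0, l_max=1)
        # Eq-form first order: (2 sigma^2 / N^2) * N
        assert vf.partial_sums[0] == pytest.approx(2 * 0.2 / 2, abs=1e-12)

    def test_scalar_geometric_sum(self, single_node_spectrum):
        s, s2 = 1.0, 0.3
        vf = gp.vertex_function_series(single_node_spectrum, J, s2, s, l_max=300)
        assert vf.partial_sums[-1] == pytest.approx(2 * s2 / (1 - s2 / s), rel=1e-9)
        cf = gp.vertex_function_closed(single_node_spectrum, J, s2, s)
        assert cf.closed_form == pytest.approx(2 * s2 / (1 - s2 / s), rel=1e-12)
        assert cf.closed_form_trace == pytest.approx(cf.closed_form, rel=1e-12)

    def test_partial_sums_increasing(self, random_graph4_spectrum):
        vf = gp.vertex_function_series(random_graph4_spectrum, J, 0.15, 1.0, l_max=50)
        assert np.all(np.diff(vf.partial_sums) > 0)

    def test_converged_series_matches_closed_form(self, random_graph4_spectrum):
        vf = gp.vertex_function_series(random_graph4_spectrum, J, 0.1, 1.2, l_max=300)
        assert vf.converged
        assert vf.partial_sums[-1] == pytest.approx(vf.closed_form, abs=1e-8)

    def test_zero_noise_closed_form(self, random_graph4_spectrum):
        cf = gp.vertex_function_closed(random_graph4_spectrum, J, 0.0, 1.0)
        assert cf.closed_form == 0.0

    def test_divergent_regime_flagged_not_raised(self, single_node_spectrum):
        vf = gp.vertex_function_series(single_node_spectrum, J, 2.0, 1.0, l_max=40)
        assert vf.diverged and not vf.converged
        assert np.all(np.isfinite(vf.partial_sums))

    def test_torus_series_matches_closed(self):
        spec = gp.build_laplacian(gp.generate_torus(3, 3))
        vf = gp.vertex_function_series(spec, J, 0.5, 1.0, l_max=400)
        assert vf.converged
        assert vf.partial_sums[-1] == pytest.approx(vf.closed_form, abs=1e-6)


class TestCriticalSigma:
    def test_single_node_recurrent_like(self, single_node_spectrum):
        s_seq = 2.0 ** (-np.arange(8.0))
        res = gp.critical_sigma(single_node_spectrum, J, s_seq)
        assert np.allclose(res.sigma_c_sq_values, s_seq)
        assert res.verdict == "recurrent"

    def test_rejects_nondecreasing_sequence(self, two_node_spectrum):
        with pytest.raises(ValueError):
            gp.critical_sigma(two_node_spectrum, J, np.array([0.1, 0.5]))

    def test_ring_family_recurrent(self):
        s_seq = 2.0 ** (-np.arange(13.0))
        fam = gp.critical_sigma_family(
            [gp.torus_eigenvalues(1, n) for n in (128, 256, 512)], J, s_seq
        )
        assert fam["verdict"] == "recurrent"

    def test_torus3d_family_transient(self):
        s_seq = 2.0 ** (-np.arange(13.0))
        fam = gp.critical_sigma_family(
            [gp.torus_eigenvalues(3, n) for n in (6, 8, 12)], J, s_seq
        )
        assert fam["verdict"] == "transient"
        assert fam["sigma_c_sq"] > 0

    def test_dense_and_uniform_paths_agree(self):
        spec = gp.build_laplacian(gp.generate_torus(3, 4))
        s_seq = 2.0 ** (-np.arange(8.0))
        dense = gp.critical_sigma(spec, J, s_seq)
        uniform = gp.critical_sigma_uniform(gp.torus_eigenvalues(3, 4), J, s_seq)
        assert np.abs(dense.sigma_c_sq_values - uniform.sigma_c_sq_values).max() < 1e-8


class TestAsymptotics:
    def test_zero_noise(self):
        assert gp.asymptotic_vertex(3.0, 1.0, 0.0, 0.5) == 0.0

    def test_printed_formula_arithmetic(self):
        # d~ = 4: choose B so the denominator term is 1/2 at s = 1, sigma^2 = 1
        B = -1.0  # B/(2-4) * 1 = 1/2
        assert gp.asymptotic_vertex(4.0, B, 1.0, 1.0) == pytest.approx(4.0)

    def test_marginal_dimension_rejected(self):
        with pytest.raises(ValueError, match="marginal|diverges"):
            gp.asymptotic_vertex(2.0, 1.0, 0.5, 0.5)

    def test_fitted_prefactor_reproduces_row_sums(self):
        spec = gp.build_laplacian(gp.generate_torus(3, 6))
        s_grid = np.geomspace(0.4, 4.0, 12)
        fit = gp.fit_asymptotic_prefactor(spec, J, 3.0, s_grid)
        phi2 = spec.eigenvectors**2
        for s in s_grid:
            measured = 0.5 * float(
                (phi2 @ (1.0 / (s / 2 + J * spec.eigenvalues))).mean()
            )
            assert fit.row_sum(s) == pytest.approx(measured, rel=0.10)

    def test_critical_dimension_threshold(self):
        assert gp.critical_dimension() == pytest.approx(2.0, abs=1e-9)


class TestBasisCovariance:
    def test_degenerate_eigenspace_rotation_invariance(self):
        """Outputs must not depend on the basis chosen inside a degenerate
        eigenspace (ring spectra are doubly degenerate)."""
        spec = gp.build_laplacian(gp.generate_torus(1, 6))
        lam, phi = spec.eigenvalues, spec.eigenvectors.copy()
        rng = np.random.default_rng(5)
        groups = []
        i = 0
        while i < lam.size:
            j = i
            while j + 1 < lam.size and abs(lam[j + 1] - lam[i]) < 1e-9:
                j += 1
            groups.append((i, j + 1))
            i = j + 1
        for a, b in groups:
            if b - a > 1:
                q, _ = np.linalg.qr(rng.normal(size=(b - a, b - a)))
                phi[:, a:b] = phi[:, a:b] @ q
        rotated = gp.LaplacianSpectrum(
            laplacian=spec.laplacian, eigenvalues=lam, eigenvectors=phi
        )
        for t in (0.3, 1.5):
            assert np.abs(
                gp.transition_matrix(spec, J, t) - gp.transition_matrix(rotated, J, t)
            ).max() < 1e-8
        s = 0.7
        assert np.abs(
            gp.collision_matrix_laplace(spec, J, s).matrix
            - gp.collision_matrix_laplace(rotated, J, s).matrix
        ).max() < 1e-8
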