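"""Matrix-normal density, EM estimation, model selection and criteria."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from conftest import assert_monotone_trace, random_correlation
from triclust.matnorm_mixture import (
    ComponentParams,
    CovarianceSpec,
    MatrixMixtureModel,
    ar1_correlation,
    bic,
    bic_conventional,
    count_parameters,
    em_fit,
    entropy,
    icl,
    map_assign,
    matnorm_logpdf,
    mixture_loglik,
    posterior_probs,
    refit_ar1,
    select_k,
)
from triclust.postprocess import adjusted_rand_index
from triclust.simulate import sample_from_model


def random_component(j, t, rng):
    return ComponentParams(
        M=rng.normal(size=(j, t)),
        sigma2=rng.uniform(0.3, 2.0, size=j),
        psi=random_correlation(t, rng),
    )


class TestDensity:
    def test_standard_normal_at_mode(self):
        comp = ComponentParams(M=np.zeros((1, 1)), sigma2=np.ones(1), psi=np.ones((1, 1)))
        assert matnorm_logpdf(np.zeros((1, 1)), comp) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-10)

    @pytest.mark.parametrize("j,t", [(1, 2), (2, 3), (3, 6)])
    def test_kronecker_oracle(self, j, t, rng):
        """Matches the vec(Y) multivariate normal with explicit Psi (x) Sigma."""
        for _ in range(20):
            comp = random_component(j, t, rng)
            y = rng.normal(size=(j, t))
            cov = np.kron(comp.psi, np.diag(comp.sigma2))
            expected = multivariate_normal(mean=comp.M.T.ravel(), cov=cov
                                           ).logpdf(y.T.ravel())
            assert matnorm_logpdf(y, comp) == pytest.approx(expected, abs=1e-8)

    def test_density_integrates_to_one(self):
        """Quadrature oracle at J=1, Tc=2."""
        comp = ComponentParams(M=np.zeros((1, 2)), sigma2=np.array([0.7]),
                               psi=ar1_correlation(0.4, 2), rho=0.4)
        grid = np.linspace(-6, 6, 301)
        h = grid[1] - grid[0]
        xs, ys = np.meshgrid(grid, grid, indexing="ij")
        pts = np.stack([xs.ravel(), ys.ravel()], axis=-1)[:, None, :]  # (m,1,2)
        mass = np.exp(matnorm_logpdf(pts, comp)).sum() * h * h
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_non_pd_psi_reports_smallest_eigenvalue(self):
        psi = np.array([[1.0, 2.0], [2.0, 1.0]])  # symmetric, unit diag, not PD
        comp = ComponentParams.__new__(ComponentParams)
        comp.M, comp.sigma2, comp.psi, comp.rho = np.zeros((1, 2)), np.ones(1), psi, None
        with pytest.raises(ValueError, match="eigenvalue"):
            matnorm_logpdf(np.zeros((1, 2)), comp)

    def test_shape_mismatch(self, rng):
        comp = random_component(2, 3, rng)
        with pytest.raises(ValueError, match="shape"):
            matnorm_logpdf(np.zeros((3, 2)), comp)


class TestMixtureLoglik:
    def test_single_component_reduces_to_sum(self, rng):
        comp = random_component(2, 3, rng)
        model = MatrixMixtureModel(K=1, pi=np.array([1.0]), components=[comp])
        Y = rng.normal(size=(7, 2, 3))
        expected = float(np.sum(matnorm_logpdf(Y, comp)))
        assert mixture_loglik(Y, model) == pytest.approx(expected, abs=1e-10)

    def test_duplication_doubles_loglik(self, rng, two_component_model):
        Y, _ = sample_from_model(two_component_model, 20, seed=0)
        ll = mixture_loglik(Y.data, two_component_model)
        ll2 = mixture_loglik(np.concatenate([Y.data, Y.data]), two_component_model)
        assert ll2 == pytest.approx(2 * ll, rel=1e-12)

    def test_brute_force_two_component(self, rng):
        comps = [random_component(1, 2, rng) for _ in range(2)]
        pi = np.array([0.3, 0.7])
        model = MatrixMixtureModel(K=2, pi=pi, components=comps)
        Y = rng.normal(size=(3, 1, 2))
        direct = sum(
            np.log(pi[0] * np.exp(matnorm_logpdf(y, comps[0]))
                   + pi[1] * np.exp(matnorm_logpdf(y, comps[1])))
            for y in Y
        )
        assert mixture_loglik(Y, model) == pytest.approx(float(direct), abs=1e-10)


class TestEmFit:
    def test_single_component_closed_form(self, rng):
        Y = rng.normal(size=(50, 2, 3))
        fit = em_fit(Y, K=1, seed=0)
        np.testing.assert_allclose(fit.model.components[0].M, Y.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(fit.tau, 1.0)
        assert fit.loglik == pytest.approx(
            mixture_loglik(Y, fit.model), abs=1e-8)
        assert_monotone_trace(fit.loglik_trace)

    def test_two_component_recovery(self, two_component_model):
        data, truth = sample_from_model(two_component_model, 400, seed=11)
        fit = em_fit(data, K=2, n_starts=4, seed=2)
        labels = map_assign(fit.tau)
        assert adjusted_rand_index(truth, labels) >= 0.95
        # align by mean sign and compare entrywise
        est = sorted(fit.model.components, key=lambda c: c.M.sum())
        tru = sorted(two_component_model.components, key=lambda c: c.M.sum())
        for e, t in zip(est, tru):
            assert np.max(np.abs(e.M - t.M)) < 0.15
        assert_monotone_trace(fit.loglik_trace)

    def test_permutation_invariance_of_loglik(self, two_component_model, rng):
        data, _ = sample_from_model(two_component_model, 100, seed=5)
        fit = em_fit(data.data, K=2, n_starts=2, seed=3)
        perm = rng.permutation(100)
        ll_perm = mixture_loglik(data.data[perm], fit.model)
        assert ll_perm == pytest.approx(fit.loglik, rel=1e-12)

    def test_posterior_rows_sum_to_one(self, two_component_model):
        data, _ = sample_from_model(two_component_model, 80, seed=9)
        fit = em_fit(data, K=2, n_starts=2, seed=0)
        np.testing.assert_allclose(fit.tau.sum(axis=1), 1.0, atol=1e-12)

    def test_identifiability_constraint_after_fit(self, two_component_model):
        data, _ = sample_from_model(two_component_model, 150, seed=4)
        for spec in (CovarianceSpec("general"), CovarianceSpec("ar1")):
            fit = em_fit(data, K=2, spec=spec, n_starts=2, seed=1)
            for comp in fit.model.components:
                np.testing.assert_allclose(np.diag(comp.psi), 1.0, atol=1e-10)
                if spec.column_structure == "ar1":
                    np.testing.assert_allclose(
                        comp.psi, ar1_correlation(comp.rho, comp.psi.shape[0]),
                        atol=1e-12)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            em_fit(rng.normal(size=(5, 1, 2)), K=5)


class TestAr1Refit:
    def test_nesting(self, two_component_model):
        """AR1 is a submodel: its likelihood embeds exactly into the general
        family, and cannot beat the general optimum beyond the finite
        convergence tolerance of either fit."""
        data, _ = sample_from_model(two_component_model, 200, seed=21)
        full = em_fit(data, K=2, n_starts=2, seed=0)
        restricted = refit_ar1(data, full)
        # exact submodel embedding: same components viewed as a general model
        embedded = MatrixMixtureModel(
            K=2, pi=restricted.model.pi, components=restricted.model.components,
            spec=CovarianceSpec("general"))
        assert mixture_loglik(data, embedded) == pytest.approx(
            restricted.loglik, rel=1e-12)
        # nesting: the submodel cannot beat the general fit
        assert restricted.loglik <= full.loglik + 1e-6
        assert restricted.nu < full.nu
        assert_monotone_trace(restricted.loglik_trace)

    def test_rho_recovery_independent_columns(self, rng):
        comp = ComponentParams(M=np.zeros((2, 4)), sigma2=np.array([0.5, 0.8]),
                               psi=np.eye(4), rho=0.0)
        model = MatrixMixtureModel(K=1, pi=np.array([1.0]), components=[comp])
        data, _ = sample_from_model(model, 500, seed=8)
        full = em_fit(data, K=1, seed=0)
        restricted = refit_ar1(data, full)
        assert abs(restricted.model.components[0].rho) < 0.1

    def test_rho_recovery_strong_correlation(self):
        comp = ComponentParams(M=np.zeros((2, 4)), sigma2=np.array([1.0, 1.0]),
                               psi=ar1_correlation(0.7, 4), rho=0.7)
        model = MatrixMixtureModel(K=1, pi=np.array([1.0]), components=[comp])
        data, _ = sample_from_model(model, 500, seed=13)
        restricted = refit_ar1(data, em_fit(data, K=1, seed=0))
        assert abs(restricted.model.components[0].rho - 0.7) < 0.1

    def test_exact_ar1_full_fit_is_fixed_point(self):
        """When the general fit's Psi is already AR1, the refit matches it."""
        comp = ComponentParams(M=np.zeros((1, 3)), sigma2=np.array([1.0]),
                               psi=ar1_correlation(0.5, 3), rho=0.5)
        model = MatrixMixtureModel(K=1, pi=np.array([1.0]), components=[comp])
        data, _ = sample_from_model(model, 300, seed=3)
        full = em_fit(data, K=1, seed=0)
        restricted = refit_ar1(data, full)
        # the general fit's correlation is near-AR1; refit loses almost nothing
        assert full.loglik - restricted.loglik < 0.5
        assert restricted.loglik <= full.loglik + 1e-6
        assert abs(restricted.model.components[0].rho - 0.5) < 0.1


class TestParameterCount:
    def test_separate_versus_vectorised_example(self):
        assert count_parameters(1, 2, 5, "separate-covariances") == 18
        assert count_parameters(1, 2, 5, "vectorised-covariance") == 55

    def test_workflow_minimal_ar1(self):
        # 1 mean + 1 variance + 1 rho
        assert count_parameters(1, 1, 1, CovarianceSpec("ar1")) == 3

    @pytest.mark.parametrize("k,j,t", [(2, 2, 3), (5, 2, 5), (3, 4, 2)])
    def test_workflow_counts_by_enumeration(self, k, j, t):
        general = k * j * t + (k - 1) + k * j + k * t * (t - 1) // 2
        ar1 = k * j * t + (k - 1) + k * j + k
        assert count_parameters(k, j, t, CovarianceSpec("general")) == general
        assert count_parameters(k, j, t, CovarianceSpec("ar1")) == ar1

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown"):
            count_parameters(1, 2, 2, "bogus")


class TestCriteria:
    def test_k1_entropy_zero_icl_equals_bic(self, rng):
        fit = em_fit(rng.normal(size=(40, 1, 2)), K=1, seed=0)
        assert entropy(fit.tau) == 0.0
        assert icl(fit) == pytest.approx(bic(fit))

    def test_hard_posteriors_entropy_zero(self):
        tau = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert entropy(tau) == pytest.approx(0.0)

    def test_entropy_hand_sum(self):
        tau = np.array([[0.5, 0.5], [0.9, 0.1], [0.2, 0.8]])
        by_hand = -(2 * 0.5 * np.log(0.5) + 0.9 * np.log(0.9) + 0.1 * np.log(0.1)
                    + 0.2 * np.log(0.2) + 0.8 * np.log(0.8)) / 3
        assert entropy(tau) == pytest.approx(by_hand, abs=1e-12)

    def test_icl_at_least_bic(self, two_component_model):
        data, _ = sample_from_model(two_component_model, 60, seed=1)
        fit = em_fit(data, K=2, n_starts=2, seed=0)
        assert icl(fit) >= bic(fit)
        # per-observation and conventional forms rank identically: same argmin
        assert bic_conventional(fit) == pytest.approx(
            2 * fit.n * (bic(fit)), rel=1e-12)

    def test_criteria_invariant_to_relabelling(self, two_component_model):
        data, _ = sample_from_model(two_component_model, 60, seed=2)
        fit = em_fit(data, K=2, n_starts=2, seed=0)
        flipped = type(fit)(
            model=MatrixMixtureModel(K=2, pi=fit.model.pi[::-1].copy(),
                                     components=fit.model.components[::-1],
                                     spec=fit.model.spec),
            tau=fit.tau[:, ::-1].copy(), loglik=fit.loglik,
            loglik_trace=fit.loglik_trace, nu=fit.nu, converged=fit.converged,
            n_iter=fit.n_iter)
        assert bic(flipped) == pytest.approx(bic(fit))
        assert icl(flipped) == pytest.approx(icl(fit))


class TestSelectK:
    def test_single_component_data_selects_one(self):
        comp = ComponentParams(M=np.zeros((2, 3)), sigma2=np.array([1.0, 1.0]),
                               psi=ar1_correlation(0.3, 3), rho=0.3)
        model = MatrixMixtureModel(K=1, pi=np.array([1.0]), components=[comp])
        data, _ = sample_from_model(model, 300, seed=17)
        fit, table = select_k(data, CovarianceSpec("general"), [1, 2, 3],
                              criterion="ICL", seed=0, n_starts=2)
        assert fit.model.K == 1
        assert set(table.columns) >= {"K", "loglik", "nu", "BIC", "ICL", "converged"}

    def test_singleton_range_returns_that_fit(self, two_component_model):
        data, _ = sample_from_model(two_component_model, 80, seed=6)
        fit, table = select_k(data, CovarianceSpec("general"), [2], seed=0, n_starts=2)
        assert fit.model.K == 2 and len(table) == 1

    def test_ar1_route_refits_from_general(self, two_component_model):
        data, _ = sample_from_model(two_component_model, 120, seed=7)
        fit, _ = select_k(data, CovarianceSpec("ar1"), [2], seed=0, n_starts=2)
        assert fit.model.spec.column_structure == "ar1"
        assert all(c.rho is not None for c in fit.model.components)


class TestMapAssign:
    def test_identity_posteriors(self):
        tau = np.eye(3)
        np.testing.assert_array_equal(map_assign(tau), [0, 1, 2])

    def test_tie_breaks_to_lowest_index(self):
        assert map_assign(np.array([[0.5, 0.5]]))[0] == 0

    def test_matches_brute_force_argmax(self, rng):
        tau = rng.dirichlet(np.ones(4), size=50)
        expected = [int(np.argmax(row)) for row in tau]
        np.testing.assert_array_equal(map_assign(tau), expected)

    def test_rejects_unnormalised_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            map_assign(np.array([[0.5, 0.2]]))


class TestSerialisation:
    def test_model_round_trip(self, tmp_path, two_component_model):
        from triclust.matnorm_mixture import model_from_json, model_to_json

        data, _ = sample_from_model(two_component_model, 60, seed=0)
        fit = em_fit(data, K=2, spec=CovarianceSpec("ar1"), n_starts=2, seed=0)
        model_to_json(fit, tmp_path / "model.json")
        back = model_from_json(tmp_path / "model.json")
        assert back.K == 2 and back.spec.column_structure == "ar1"
        for a, b in zip(back.components, fit.model.components):
            np.testing.assert_allclose(a.M, b.M, atol=1e-12)
            np.testing.assert_allclose(a.psi, b.psi, atol=1e-12)
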