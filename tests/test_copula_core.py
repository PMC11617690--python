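"""Copula families: CDFs, densities, estimation, rotation, simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import copot as cp
from copot.copula_core import CopulaModel, bvn_cdf, flip_v
from copot.exceptions import (
    DataError,
    ParameterDomainError,
    UnsupportedDependenceError,
)

ALL_MODELS = [
    CopulaModel("gumbel", 1.169),
    CopulaModel("gumbel", 2.5),
    CopulaModel("clayton", 0.338),
    CopulaModel("clayton", 3.0),
    CopulaModel("gaussian", 0.225),
    CopulaModel("gaussian", -0.6),
]


class TestCopulaCdf:
    def test_independence_gumbel(self):
        assert cp.copula_cdf(CopulaModel("gumbel", 1.0), 0.3, 0.5) == pytest.approx(0.15)

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_uniform_margins_and_groundedness(self, model):
        for t in (0.12, 0.42, 0.9):
            assert cp.copula_cdf(model, t, 1.0) == pytest.approx(t, abs=1e-9)
            assert cp.copula_cdf(model, 1.0, t) == pytest.approx(t, abs=1e-9)
            assert cp.copula_cdf(model, t, 0.0) == 0.0
            assert cp.copula_cdf(model, 0.0, t) == 0.0

    def test_gaussian_median_closed_form(self):
        rho = 0.225
        expect = 0.25 + np.arcsin(rho) / (2 * np.pi)
        assert cp.copula_cdf(CopulaModel("gaussian", rho), 0.5, 0.5) == pytest.approx(
            expect, abs=1e-12
        )

    def test_gaussian_matches_scipy_mvn(self):
        rho = 0.225
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        for u, v in [(0.3, 0.7), (0.05, 0.95), (0.5, 0.2)]:
            ours = cp.copula_cdf(CopulaModel("gaussian", rho), u, v)
            ref = mvn.cdf([stats.norm.ppf(u), stats.norm.ppf(v)])
            assert ours == pytest.approx(ref, abs=1e-6)

    @pytest.mark.parametrize("model", ALL_MODELS)
    @given(
        u1=st.floats(0.01, 0.99), u2=st.floats(0.01, 0.99),
        v1=st.floats(0.01, 0.99), v2=st.floats(0.01, 0.99),
    )
    def test_frechet_bounds_and_two_increasing(self, model, u1, u2, v1, v2):
        ua, ub = sorted((u1, u2))
        va, vb = sorted((v1, v2))
        C = lambda u, v: cp.copula_cdf(model, u, v)
        assert max(ua + va - 1, 0) - 1e-12 <= C(ua, va) <= min(ua, va) + 1e-12
        vol = C(ub, vb) - C(ua, vb) - C(ub, va) + C(ua, va)
        assert vol >= -1e-10

    def test_domain_validation(self):
        with pytest.raises(ParameterDomainError):
            CopulaModel("gumbel", 0.5)
        with pytest.raises(ParameterDomainError):
            CopulaModel("clayton", 0.0)
        with pytest.raises(ParameterDomainError):
            CopulaModel("gaussian", 1.5)
        with pytest.raises(ParameterDomainError):
            cp.copula_cdf(CopulaModel("gumbel", 1.5), 1.2, 0.5)


class TestCopulaPdf:
    def test_independence_density_is_one(self):
        m = CopulaModel("gumbel", 1.0)
        assert cp.copula_pdf(m, 0.3, 0.8) == pytest.approx(1.0)

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_mixed_partial_of_cdf(self, model):
        h = 1e-4
        grid = np.linspace(0.15, 0.85, 5)
        for u in grid:
            for v in grid:
                num = (
                    cp.copula_cdf(model, u + h, v + h)
                    - cp.copula_cdf(model, u + h, v - h)
                    - cp.copula_cdf(model, u - h, v + h)
                    + cp.copula_cdf(model, u - h, v - h)
                ) / (4 * h * h)
                assert num == pytest.approx(cp.copula_pdf(model, u, v), abs=1e-5)

    @pytest.mark.parametrize(
        "model",
        [CopulaModel("gumbel", 1.6), CopulaModel("clayton", 1.2), CopulaModel("gaussian", 0.4)],
    )
    def test_density_integrates_to_one(self, model):
        # 400-node Gauss-Legendre product rule on the open unit square
        x, w = np.polynomial.legendre.leggauss(400)
        u = 0.5 * (x + 1)
        wu = 0.5 * w
        U, V = np.meshgrid(u, u)
        dens = cp.copula_pdf(model, U.ravel(), V.ravel()).reshape(U.shape)
        val = wu @ dens @ wu
        assert val == pytest.approx(1.0, abs=1e-3)


class TestPseudoObservations:
    def test_empirical_ranks_over_m_plus_one(self):
        p = cp.pseudo_observations([0.5, 0.2, 0.9], [3.0, 1.0, 2.0])
        np.testing.assert_allclose(p.v, [3 / 4, 1 / 4, 2 / 4])

    def test_parametric_margin_hand_computed(self, printed_fit):
        x = np.array([-4.5, -3.0, -1.0, 0.0, 0.2])
        y = np.arange(5.0)
        p = cp.pseudo_observations(x, y, margin_x=printed_fit)
        eps = 0.5 / 6
        expect = np.clip(
            1 - (1 - 0.493 * (x + 4.84) / 2.60) ** (1 / 0.493), eps, 1 - eps
        )
        np.testing.assert_allclose(p.u, expect, atol=1e-12)
        assert p.margin_x == "parametric-gp"

    def test_boundary_clamped_interior(self, printed_fit):
        x = np.full(5, -4.84)  # exactly at threshold: parametric CDF = 0
        p = cp.pseudo_observations(x, np.arange(5.0), margin_x=printed_fit)
        assert np.all(p.u > 0)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            cp.pseudo_observations([1.0, 2.0], [1.0])

    def test_below_threshold_rejected(self, printed_fit):
        with pytest.raises(DataError):
            cp.pseudo_observations([-10.0], [1.0], margin_x=printed_fit)


class TestEmpiricalCopula:
    def test_worked_example(self):
        p = cp.PseudoObservations(
            u=np.array([0.25, 0.5, 0.75]), v=np.array([0.25, 0.5, 0.75])
        )
        assert cp.empirical_copula(p, 0.5, 0.5) == pytest.approx(2 / 3)
        assert cp.empirical_copula(p, 1.0, 1.0) == 1.0
        assert cp.empirical_copula(p, 0.3, 0.0) == 0.0

    def test_against_double_loop(self, rng):
        u = rng.random(50)
        v = rng.random(50)
        p = cp.PseudoObservations(u=u, v=v)
        for uq, vq in [(0.2, 0.8), (0.5, 0.5), (0.9, 0.1)]:
            brute = sum(1 for a, b in zip(u, v) if a <= uq and b <= vq) / 50
            assert cp.empirical_copula(p, uq, vq) == pytest.approx(brute)


class TestSampleKendallTau:
    def test_perfect_concordance_and_discordance(self):
        u = np.linspace(0.1, 0.9, 9)
        assert cp.sample_kendall_tau(cp.PseudoObservations(u=u, v=u)) == 1.0
        assert cp.sample_kendall_tau(cp.PseudoObservations(u=u, v=1 - u)) == -1.0

    def test_against_pair_count(self, rng):
        u = rng.random(6)
        v = rng.random(6)
        conc = disc = 0
        for i in range(6):
            for j in range(i + 1, 6):
                s = np.sign((u[i] - u[j]) * (v[i] - v[j]))
                conc += s > 0
                disc += s < 0
        expect = (conc - disc) / (6 * 5 / 2)
        tau = cp.sample_kendall_tau(cp.PseudoObservations(u=u, v=v))
        assert tau == pytest.approx(expect)


class TestTauParamMaps:
    def test_independence_and_comonotone(self):
        assert cp.tau_from_param("gumbel", 1.0) == 0.0
        assert cp.tau_from_param("gaussian", 1.0) == pytest.approx(1.0)
        assert cp.param_from_tau("gaussian", 0.0) == 0.0

    def test_reference_estimates_encode_one_tau(self):
        """All three printed parameter estimates invert the same sample tau."""
        tau = cp.tau_from_param("gumbel", 1.169)
        assert abs(cp.tau_from_param("clayton", 0.338) - tau) < 2e-4
        assert abs(cp.tau_from_param("gaussian", 0.225) - tau) < 2e-4
        assert round(cp.param_from_tau("clayton", tau), 3) == 0.338
        assert round(cp.param_from_tau("gaussian", tau), 3) == 0.225

    @pytest.mark.parametrize("family", ["gumbel", "clayton", "gaussian"])
    def test_roundtrip_identity(self, family, rng):
        taus = rng.uniform(0.01, 0.95, 100)
        if family == "gaussian":
            taus = rng.uniform(-0.95, 0.95, 100)
        for t in taus:
            assert cp.tau_from_param(family, cp.param_from_tau(family, t)) == pytest.approx(
                t, abs=1e-12
            )

    def test_negative_tau_guidance(self):
        with pytest.raises(UnsupportedDependenceError, match="transform"):
            cp.param_from_tau("gumbel", -0.2)
        with pytest.raises(UnsupportedDependenceError):
            cp.param_from_tau("clayton", -0.1)

    @pytest.mark.parametrize(
        "family,param",
        [("gumbel", 1.169), ("gumbel", 3.0), ("clayton", 0.338), ("gaussian", 0.225)],
    )
    def test_closed_form_vs_integral_definition(self, family, param):
        """tau = 4 E[C(U,V)] - 1, estimated from simulated pairs."""
        m = CopulaModel(family, param)
        s = cp.simulate_copula(m, 50000, 7)
        mc = 4 * np.mean(cp.copula_cdf(m, s.u, s.v)) - 1
        assert mc == pytest.approx(cp.tau_from_param(family, param), abs=0.01)


class TestRotation:
    def test_rotation_of_independence(self):
        r = cp.rotate_copula(CopulaModel("gumbel", 1.0))
        for u, v in [(0.2, 0.7), (0.5, 0.5)]:
            assert r.cdf(u, v) == pytest.approx(u * v, abs=1e-12)

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_margins_preserved(self, model):
        r = cp.rotate_copula(model)
        for t in (0.1, 0.6, 0.95):
            assert r.cdf(t, 1.0) == pytest.approx(t, abs=1e-9)
            assert r.cdf(1.0, t) == pytest.approx(t, abs=1e-9)
            assert r.cdf(t, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_is_two_increasing(self, rng):
        r = cp.rotate_copula(CopulaModel("clayton", 2.0))
        for _ in range(200):
            ua, ub = np.sort(rng.random(2))
            va, vb = np.sort(rng.random(2))
            vol = r.cdf(ub, vb) - r.cdf(ua, vb) - r.cdf(ub, va) + r.cdf(ua, va)
            assert vol >= -1e-10

    def test_rotation_preserves_tau(self, gumbel_ref):
        """180-degree rotation preserves concordance: same Kendall tau."""
        s = cp.simulate_copula(gumbel_ref, 20000, 11)
        rotated = cp.PseudoObservations(u=1 - s.u, v=1 - s.v)
        t1 = cp.sample_kendall_tau(s)
        t2 = cp.sample_kendall_tau(rotated)
        assert t1 == pytest.approx(t2, abs=1e-12)
        r = cp.rotate_copula(gumbel_ref)
        mc = 4 * np.mean(r.cdf(1 - s.u, 1 - s.v)) - 1
        assert mc == pytest.approx(gumbel_ref.tau, abs=0.02)

    def test_flip_v_identity(self, gumbel_ref):
        f = flip_v(gumbel_ref)
        for u, v in [(0.3, 0.4), (0.8, 0.2)]:
            assert f.cdf(u, v) == pytest.approx(
                u - cp.copula_cdf(gumbel_ref, u, 1 - v), abs=1e-12
            )
        # flipping reverses the sign of tau
        s = cp.simulate_copula(gumbel_ref, 20000, 3)
        flipped = cp.PseudoObservations(u=s.u, v=1 - s.v)
        assert cp.sample_kendall_tau(flipped) == pytest.approx(
            -cp.sample_kendall_tau(s), abs=1e-12
        )


class TestSimulation:
    def test_independence_tau_near_zero(self):
        s = cp.simulate_copula(CopulaModel("gumbel", 1.0), 10000, 5)
        assert abs(cp.sample_kendall_tau(s)) < 0.02

    def test_reference_gumbel_tau(self, gumbel_ref):
        s = cp.simulate_copula(gumbel_ref, 10000, 5)
        assert cp.sample_kendall_tau(s) == pytest.approx(1 - 1 / 1.169, abs=0.02)

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_uniform_margins_ks(self, model):
        s = cp.simulate_copula(model, 5000, 13)
        assert stats.kstest(s.u, "uniform").pvalue > 0.01
        assert stats.kstest(s.v, "uniform").pvalue > 0.01

    def test_deterministic_under_seed(self, gumbel_ref):
        a = cp.simulate_copula(gumbel_ref, 100, 77)
        b = cp.simulate_copula(gumbel_ref, 100, 77)
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.v, b.v)


class TestFitting:
    def test_ml_recovery(self):
        s = cp.simulate_copula(CopulaModel("gumbel", 1.5), 2000, 21)
        fit = cp.fit_ml(s, "gumbel")
        assert fit.model.param == pytest.approx(1.5, abs=0.1)

    def test_independence_data_boundary(self):
        s = cp.simulate_copula(CopulaModel("gumbel", 1.0), 2000, 22)
        fit = cp.fit_ml(s, "gumbel")
        assert fit.model.param < 1.1

    def test_ml_at_least_as_good_as_tau_inversion(self):
        s = cp.simulate_copula(CopulaModel("clayton", 1.0), 1000, 23)
        ml = cp.fit_ml(s, "clayton")
        ti = cp.fit_tau(s, "clayton")
        ll_ti = np.sum(np.log(cp.copula_pdf(ti.model, s.u, s.v)))
        assert ml.loglik >= ll_ti - 1e-8

    def test_tau_inversion_consistency(self):
        """Median |theta_hat - theta| shrinks as the sample grows."""
        theta = 1.8
        med = []
        for n in (200, 2000, 20000):
            errs = []
            for seed in range(5):
                s = cp.simulate_copula(CopulaModel("gumbel", theta), n, 100 + seed)
                errs.append(abs(cp.fit_tau(s, "gumbel").model.param - theta))
            med.append(np.median(errs))
        assert med[2] < med[0]
        assert med[1] < med[0] + 0.02


class TestBvn:
    @pytest.mark.parametrize("rho", [-0.9, -0.3, 0.225, 0.7, 0.99])
    def test_against_scipy(self, rho):
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        pts = [(-1.2, 0.3), (0.0, 0.0), (1.5, -0.7), (2.0, 2.0)]
        for h, k in pts:
            assert bvn_cdf(h, k, rho) == pytest.approx(mvn.cdf([h, k]), abs=5e-7)
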