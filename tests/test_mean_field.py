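"""Self-consistency map, Gibbs free energy, susceptibility, fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genspin import (
    ModelParams,
    find_fixed_points,
    gibbs_free_energy,
    iterate_map,
    select_equilibrium,
    self_consistency_rhs,
    single_site_thermal_average,
    susceptibility,
)


def params(beta=1.0, sigma=1.0, tau=0.0, k=1):
    return ModelParams(beta=beta, sigma=sigma, tau=tau, k=k)


class TestSelfConsistencyRhs:
    def test_symmetric_point_vanishes(self):
        for k in (1, 2, 3, 10):
            assert self_consistency_rhs(0.0, params(beta=2, tau=0.0, k=k), 5.0) == 0.0

    def test_two_state_model_is_tanh(self):
        p = params(beta=1.7, sigma=0.4, tau=0.2, k=0.5)
        mus = np.linspace(-1, 1, 41)
        expected = np.tanh(1.7 * (0.2 + 0.4 * mus * 3.0))
        np.testing.assert_allclose(self_consistency_rhs(mus, p, 3.0), expected,
                                   atol=1e-15)

    def test_seven_state_value(self):
        # frozen from the direct 4-term half-set sum at gamma = 0.3
        p = params(beta=3.0, sigma=1.0, tau=0.3, k=3)
        assert self_consistency_rhs(0.0, p, 2.0) == pytest.approx(
            0.3328678790460872, abs=1e-12)

    def test_direct_sum_oracle(self):
        # independent evaluation of the printed formula, term by term
        k, beta, gamma = 3, 1.3, 0.7
        xs = [0, 1/3, 2/3, 1.0]
        num = sum(x * np.sinh(x * beta * gamma) for x in xs)
        den = sum(np.cosh(x * beta * gamma) for x in xs)
        p = params(beta=beta, sigma=0.0, tau=gamma, k=k)
        assert self_consistency_rhs(0.12, p, 4.0) == pytest.approx(num / den,
                                                                   rel=1e-12)

    def test_overflow_guarded(self):
        p = params(beta=5.0, sigma=1.0, tau=100.0, k=2000)
        val = self_consistency_rhs(0.9, p, 10.0)
        assert np.isfinite(val) and abs(val) < 1.0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(mu=st.floats(-1, 1), tau=st.floats(-3, 3),
           k=st.sampled_from([0.5, 1, 3, 10]),
           beta=st.floats(0, 8), sd=st.floats(0, 5))
    def test_odd_symmetry_and_bounded(self, mu, tau, k, beta, sd):
        """f(-mu; -tau) = -f(mu; tau), and |f| < 1 always."""
        p = params(beta=beta, sigma=sd, tau=tau, k=k)
        f = self_consistency_rhs(mu, p, 1.0)
        f_neg = self_consistency_rhs(-mu, p.replace(tau=-tau), 1.0)
        assert f_neg == pytest.approx(-f, abs=1e-12)
        assert abs(f) < 1.0

    def test_monotone_in_effective_field(self):
        for k in (0.5, 1, 3):
            gammas = np.linspace(-4, 4, 81)
            p = [self_consistency_rhs(0.0, params(beta=1.5, sigma=0.0, tau=g, k=k), 0.0)
                 for g in gammas]
            assert np.all(np.diff(p) > 0)


class TestGibbsFreeEnergy:
    def test_even_at_zero_field(self):
        p = params(beta=2.0, tau=0.0, k=3)
        mus = np.linspace(0, 1, 11)
        np.testing.assert_allclose(gibbs_free_energy(mus, p, 10, 4.0),
                                   gibbs_free_energy(-mus, p, 10, 4.0),
                                   atol=1e-12)

    def test_beta_zero_rejected(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(0.1, params(beta=0.0), 5, 2.0)

    def test_double_well_shape(self, double_well_params):
        """Supercritical with a small field: two local minima, one maximum."""
        mus = np.linspace(-1, 1, 801)
        g = gibbs_free_energy(mus, double_well_params, 1, 2.0)
        interior = np.arange(1, len(mus) - 1)
        minima = interior[(g[interior] < g[interior - 1]) & (g[interior] < g[interior + 1])]
        maxima = interior[(g[interior] > g[interior - 1]) & (g[interior] > g[interior + 1])]
        assert len(minima) == 2 and len(maxima) == 1

    @pytest.mark.parametrize("k,beta,sigma,tau,d", [
        (1, 3.0, 1.0, 0.0, 2.0),
        (2, 3.0, 1.0, 0.2, 2.0),
        (3, 3.0, 1.0, 0.3, 2.0),
        (3, 5.0, 0.1, 0.0, 10.0),
        (0.5, 2.0, 1.0, 0.1, 1.5),
    ])
    def test_stationarity_at_every_fixed_point(self, k, beta, sigma, tau, d):
        """The variational family is consistent: fixed points of the map are
        exactly the stationary points of G (checked by central difference)."""
        p = params(beta=beta, sigma=sigma, tau=tau, k=k)
        fps = find_fixed_points(p, d)
        assert len(fps) >= 1
        h = 1e-6
        for q in fps:
            dg = (gibbs_free_energy(q.mu + h, p, 1, d)
                  - gibbs_free_energy(q.mu - h, p, 1, d)) / (2 * h)
            assert abs(dg) <= 1e-8

    def test_every_gibbs_stationary_point_is_a_fixed_point(self, double_well_params):
        mus = np.linspace(-1, 1, 4001)
        g = gibbs_free_energy(mus, double_well_params, 1, 2.0)
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(g)))) > 0)
        assert sign_changes == len(find_fixed_points(double_well_params, 2.0))


class TestSusceptibility:
    def test_disordered_limit_equals_beta_r(self):
        for k in (1, 2, 3, 10):
            r = (2 * k + 1) / (6 * k)
            p = params(beta=1.4, sigma=0.0, tau=0.0, k=k)
            assert susceptibility(0.0, p, 0.0) == pytest.approx(1.4 * r, rel=1e-12)

    def test_seven_state_value(self):
        p = params(beta=1.0, sigma=0.0, tau=0.0, k=3)
        assert susceptibility(0.0, p, 0.0) == pytest.approx(7 / 18, rel=1e-12)

    def test_two_state_form(self):
        p = params(beta=1.6, sigma=0.5, tau=0.3, k=0.5)
        mu = np.tanh(1.6 * (0.3 + 0.5 * 0.4 * 2.0))
        expected = 1.6 * (1 - mu ** 2)
        assert susceptibility(mu, p.replace(tau=0.3), 2.0) == pytest.approx(
            expected, rel=1e-9)

    def test_nonnegative_at_self_consistent_mu(self):
        """chi >= 0 whenever mu is the map's own output."""
        for k in (1, 2, 3, 10):
            for beta in (0.5, 2.0, 10.0):
                for gamma in np.linspace(-5, 5, 21):
                    p = params(beta=beta, sigma=0.0, tau=gamma, k=k)
                    mu = self_consistency_rhs(0.0, p, 0.0)
                    assert susceptibility(mu, p, 0.0) >= 0.0


class TestFixedPoints:
    def test_supercritical_with_field_has_three(self, double_well_params):
        fps = find_fixed_points(double_well_params, 2.0)
        assert len(fps) == 3
        assert [q.stability for q in fps] == ["attracting", "repelling",
                                              "attracting"]

    def test_subcritical_single_zero(self):
        # r*beta*sigma*d = 7/18 < 1
        p = params(beta=1.0, sigma=0.1, tau=0.0, k=3)
        fps = find_fixed_points(p, 10.0)
        assert len(fps) == 1
        assert fps.points[0].mu == pytest.approx(0.0, abs=1e-12)

    def test_supercritical_symmetric_triple(self):
        p = params(beta=5.0, sigma=0.1, tau=0.0, k=3)
        fps = find_fixed_points(p, 10.0)
        mus = fps.mus()
        assert len(fps) == 3
        assert mus[1] == pytest.approx(0.0, abs=1e-12)
        assert mus[2] > 0
        assert mus[0] == pytest.approx(-mus[2], abs=1e-10)

    def test_residual_tolerance(self, double_well_params):
        for q in find_fixed_points(double_well_params, 2.0):
            resid = self_consistency_rhs(q.mu, double_well_params, 2.0) - q.mu
            assert abs(resid) <= 1e-12

    def test_stability_matches_free_energy_curvature(self, double_well_params):
        h = 1e-5
        for q in find_fixed_points(double_well_params, 2.0):
            curv = (gibbs_free_energy(q.mu + h, double_well_params, 1, 2.0)
                    - 2 * gibbs_free_energy(q.mu, double_well_params, 1, 2.0)
                    + gibbs_free_energy(q.mu - h, double_well_params, 1, 2.0)) / h**2
            if q.stability == "attracting":
                assert curv > 0  # local minimum of G
            else:
                assert curv < 0  # local maximum of G

    def test_more_categories_pull_minima_inward(self, double_well_params):
        """At the same settings the 7-state minima sit closer to 0 than the
        two-state minima."""
        fps_k3 = find_fixed_points(double_well_params, 2.0)
        fps_reg = find_fixed_points(double_well_params.replace(k=0.5), 2.0)
        mags_k3 = sorted(abs(q.mu) for q in fps_k3.attracting())
        mags_reg = sorted(abs(q.mu) for q in fps_reg.attracting())
        assert all(a < b for a, b in zip(mags_k3, mags_reg))

    def test_iterate_map_converges_to_attracting_point(self, double_well_params):
        orbit = iterate_map(0.5, double_well_params, 2.0, n_steps=200)
        assert len(orbit) == 201
        target = find_fixed_points(double_well_params, 2.0).mus()[2]
        assert orbit[-1] == pytest.approx(target, abs=1e-9)


class TestSelectEquilibrium:
    def test_single_point_returned(self):
        p = params(beta=1.0, sigma=0.1, tau=0.0, k=3)
        assert select_equilibrium(find_fixed_points(p, 10.0)) == pytest.approx(0.0)

    def test_field_selects_aligned_branch(self, double_well_params):
        eq = select_equilibrium(find_fixed_points(double_well_params, 2.0))
        assert eq > 0.9  # positive branch has lower G under tau > 0

    def test_symmetric_tie_broken_to_nonnegative(self):
        p = params(beta=5.0, sigma=0.1, tau=0.0, k=3)
        assert select_equilibrium(find_fixed_points(p, 10.0)) > 0


class TestSingleSiteOracle:
    def test_matches_tanh_for_two_state(self):
        assert single_site_thermal_average(0.5, 1.3, 0.6) == pytest.approx(
            np.tanh(1.3 * 0.6), rel=1e-12)

    def test_differs_from_half_set_map_for_integer_k(self):
        """The printed map weights the zero state doubly; the exact one-site
        average does not. They must disagree for integer k at gamma != 0."""
        p = params(beta=2.0, sigma=0.0, tau=0.8, k=3)
        half = self_consistency_rhs(0.0, p, 0.0)
        exact = single_site_thermal_average(3, 2.0, 0.8)
        assert abs(half - exact) > 1e-3
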